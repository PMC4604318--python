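"""RPKM computation, expression-profile distances and RT-qPCR quantities.

The method rests on one observation: if two unigenes are fragments of
the same transcript, the reads mapping to each are drawn from the same
transcript population, so after normalising for fragment length and
library depth their expression estimates coincide — RPKM₁ = RPKM₂ in
every sample, up to sampling noise. Expression *pattern* across samples
is therefore the first filter for candidate fragment pairs.

RPKM (reads per kilobase of exon model per million mapped reads) for a
unigene with ``C`` mapped reads, library total ``N`` and length ``L``
nt is ``10⁹·C/(N·L)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ExpressionMatrix, ReadCountTable

__all__ = [
    "rpkm",
    "rpkm_matrix",
    "ExpressionProfile",
    "profile_distance",
    "ddct_relative_quantity",
]

#: pseudocount added before the log2 transform so zero RPKM stays finite
LOG_PSEUDOCOUNT = 1.0


def rpkm(C: float, N: float, L: float) -> float:
    """Reads per kilobase per million mapped reads: ``1e9 * C / (N * L)``.

    Parameters are the mapped-read count ``C`` (≥ 0), the library's
    total mapped reads ``N`` (> 0) and the unigene length ``L`` in nt
    (> 0). Length is the unigene length exactly as assembled; no
    effective-length correction is applied.
    """
    if N <= 0:
        raise ValueError("total mapped reads N must be positive")
    if L <= 0:
        raise ValueError("unigene length L must be positive")
    if C < 0:
        raise ValueError("read count C must be non-negative")
    return 1e9 * C / (N * L)


def rpkm_matrix(table: ReadCountTable) -> ExpressionMatrix:
    """Element-wise RPKM over a read-count table; sample order preserved."""
    table.validate()
    data = {
        s: [
            rpkm(table.counts[(u, s)], table.totals[s], table.lengths[u])
            for u in table.unigene_order
        ]
        for s in table.sample_order
    }
    df = pd.DataFrame(data, index=table.unigene_order, columns=table.sample_order)
    return ExpressionMatrix(df)


@dataclass(frozen=True)
class ExpressionProfile:
    """One unigene's RPKM vector over the shared sample order."""

    unigene_id: str
    values: tuple[float, ...]
    sample_order: tuple[str, ...]

    @property
    def log_vector(self) -> np.ndarray:
        return np.log2(np.asarray(self.values, dtype=float) + LOG_PSEUDOCOUNT)

    @classmethod
    def from_matrix(cls, matrix: ExpressionMatrix, unigene_id: str) -> "ExpressionProfile":
        return cls(unigene_id, tuple(matrix.profile(unigene_id)), tuple(matrix.sample_order))


def profile_distance(
    a: ExpressionProfile, b: ExpressionProfile, metric: str = "correlation"
) -> float:
    """Distance between two expression patterns.

    Default is 1 − Pearson correlation of the log2(RPKM + 1) vectors,
    which lies in [0, 2] and is invariant to multiplicative scaling of
    the RPKM values (up to the pseudocount). Alternatives: "spearman"
    (1 − rank correlation) and "euclidean" (on log vectors).

    Zero-variance log vectors carry no pattern information: the distance
    is 0 if both vectors are constant and equal, else 2.
    """
    if a.sample_order != b.sample_order:
        raise ValueError("profiles must share the same sample order")
    x, y = a.log_vector, b.log_vector
    if metric == "euclidean":
        return float(np.linalg.norm(x - y))
    if metric in ("correlation", "spearman"):
        if metric == "spearman":
            x = stats.rankdata(x)
            y = stats.rankdata(y)
        sx, sy = np.std(x), np.std(y)
        if sx == 0 or sy == 0:
            return 0.0 if np.array_equal(x, y) else 2.0
        r = float(np.corrcoef(x, y)[0, 1])
        return 1.0 - r
    raise ValueError(f"unknown metric {metric!r}")


def ddct_relative_quantity(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ΔΔCt = (Ct_target − Ct_reference) under treatment minus the same
    difference in the calibrator condition; the calibrator's own
    relative quantity is 1 by construction.
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_calibrator, ct_ref_calibrator)
    if not all(np.isfinite(cts)):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))
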