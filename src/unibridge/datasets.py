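"""Bundled reference tables from the transporter bridging study.

The package ships the published worked example that motivated it: the
candidate unigene pairs selected for the nitrate-transporter (NRT) and
phosphate-transporter (PHT) families of *Salicornia europaea* — each
with its reference-protein location string, possible gap, bridging
primers and designed/estimated product sizes — together with the
family protein-length ranges and the reports for the eight sequences
that were experimentally merged. These tables are desk-scale inputs:
the whole size/gap arithmetic of the method can be recomputed from
them, and they double as regression fixtures.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "candidate_pairs",
    "family_ranges",
    "assembled_reports",
    "validation_success_rate",
]

_FAMILY_SETS = {"NRT": "nrt_candidate_pairs.tsv", "PHT": "pht_candidate_pairs.tsv"}


def _load(name: str) -> pd.DataFrame:
    with resources.files("unibridge.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def candidate_pairs(family_set: str = "NRT") -> pd.DataFrame:
    """Candidate unigene pairs for one family set ("NRT" or "PHT").

    Columns include ``reference_location`` (e.g. ``12-101+208-3'``),
    ``gap_aa`` ("none" or an integer, as published), the bridging
    primer pair and the designed/estimated product sizes in bp, plus a
    ``validated`` flag marking pairs whose bridging PCR product was
    obtained and sequenced.
    """
    try:
        return _load(_FAMILY_SETS[family_set.upper()])
    except KeyError:
        raise ValueError(f"unknown family set {family_set!r}; use 'NRT' or 'PHT'") from None


def family_ranges() -> pd.DataFrame:
    """Protein-length ranges (aa) of the reference homolog families."""
    return _load("family_ranges.tsv")


def assembled_reports() -> pd.DataFrame:
    """Reports for the eight experimentally merged sequences: component
    lengths, merged length, encoded protein size and the published
    complete-CDS call."""
    return _load("assembled_unigenes.tsv")


def validation_success_rate(family_set: str = "NRT") -> float:
    """Percentage of candidate pairs whose bridging product validated."""
    df = candidate_pairs(family_set)
    return 100.0 * (df["validated"] == "yes").sum() / len(df)
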