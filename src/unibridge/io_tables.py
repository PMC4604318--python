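"""Readers and writers for every external format the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`UnigeneRecord`, :class:`ReadCountTable`, :class:`ExpressionMatrix`,
:class:`AlignmentRow` and :class:`ReferenceInfo`.

Conventions
-----------
* All file coordinates are 1-based inclusive (BLAST convention); the
  in-memory representation is identical.
* Unigene sequences are uppercased on read and ``U`` is mapped to ``T``.
  ``N`` characters are allowed; primer sites and overlap windows that
  contain ``N`` are rejected downstream, not here.
* Alignment tables are tab-separated. Two dialects are accepted, told
  apart by column count: the standard 12-column tabular layout with a
  13th frame column appended, or a compact 10-column layout
  (qseqid, sseqid, pident, length, qstart, qend, sstart, send, evalue,
  frame).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "UnigeneRecord",
    "ReadCountTable",
    "ExpressionMatrix",
    "AlignmentRow",
    "ReferenceInfo",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_alignments",
    "write_alignments",
    "read_reference_info",
    "write_reference_info",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_pair_report",
    "write_assembly_report",
]

_VALID_NT = set("ACGTN")


class TableFormatError(ValueError):
    """Raised when an input file violates the documented format."""


@dataclass(frozen=True)
class UnigeneRecord:
    """One assembled unigene: id, nucleotide sequence, family annotation."""

    id: str
    seq: str
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise TableFormatError(f"unigene {self.id!r} has an empty sequence")
        bad = set(self.seq) - _VALID_NT
        if bad:
            raise TableFormatError(
                f"unigene {self.id!r} contains non-nucleotide characters {sorted(bad)}"
            )

    @property
    def length_nt(self) -> int:
        return len(self.seq)


@dataclass
class ReadCountTable:
    """Mapped-read counts per (unigene, sample), library totals, lengths.

    ``counts[(unigene_id, sample_id)] = C``; ``totals[sample_id] = N`` is
    the total number of mapped reads in that library; ``lengths`` holds
    unigene lengths in nt. These are the three quantities entering the
    RPKM formula.
    """

    counts: dict[tuple[str, str], int]
    totals: dict[str, int]
    lengths: dict[str, int]
    sample_order: list[str]
    unigene_order: list[str]

    def validate(self) -> None:
        for (uid, sid), c in self.counts.items():
            if c < 0:
                raise TableFormatError(f"negative count for ({uid}, {sid})")
            if uid not in self.lengths:
                raise TableFormatError(f"unigene {uid!r} has a count but no length")
        for sid in self.sample_order:
            if sid not in self.totals:
                raise TableFormatError(f"sample {sid!r} has no total mapped reads")
            if self.totals[sid] <= 0:
                raise TableFormatError(f"sample {sid!r} total must be positive")
            colsum = sum(self.counts.get((u, sid), 0) for u in self.unigene_order)
            if colsum > self.totals[sid]:
                raise TableFormatError(
                    f"sample {sid!r}: column sum {colsum} exceeds total {self.totals[sid]}"
                )


@dataclass
class ExpressionMatrix:
    """RPKM values per unigene per sample, with a fixed sample order."""

    values: pd.DataFrame  # index: unigene ids, columns: sample ids

    @property
    def sample_order(self) -> list[str]:
        return list(self.values.columns)

    @property
    def unigene_ids(self) -> list[str]:
        return list(self.values.index)

    def profile(self, unigene_id: str) -> np.ndarray:
        return self.values.loc[unigene_id].to_numpy(dtype=float)

    def validate(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise TableFormatError("RPKM values must be non-negative")
        if self.values.isna().any().any():
            raise TableFormatError("RPKM matrix has missing cells")


@dataclass(frozen=True)
class AlignmentRow:
    """One translated-alignment HSP of a unigene against a reference protein.

    ``frame`` follows the translated-search convention: positive frames
    read the query forward strand, negative frames the reverse
    complement. Subject coordinates are amino acids, query coordinates
    nucleotides, both 1-based inclusive.
    """

    query_id: str
    subject_id: str
    subject_start_aa: int
    subject_end_aa: int
    query_start_nt: int
    query_end_nt: int
    frame: int
    percent_identity: float = 100.0
    evalue: float = 0.0
    reverse_strand: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.frame not in {-3, -2, -1, 1, 2, 3}:
            raise TableFormatError(f"frame {self.frame} outside {{-3..3}}\\{{0}}")
        if self.subject_start_aa < 1:
            raise TableFormatError("subject_start_aa must be >= 1")

    def normalized(self) -> "AlignmentRow":
        """Swap subject coordinates if reversed; record the orientation.

        Idempotent: applying it twice equals applying it once.
        """
        rev = self.frame < 0
        s, e = self.subject_start_aa, self.subject_end_aa
        if s > e:
            s, e = e, s
        return AlignmentRow(
            self.query_id, self.subject_id, s, e,
            min(self.query_start_nt, self.query_end_nt),
            max(self.query_start_nt, self.query_end_nt),
            self.frame, self.percent_identity, self.evalue,
            reverse_strand=rev,
        )


@dataclass
class ReferenceInfo:
    """Reference protein lengths and family protein-length ranges."""

    protein_lengths: dict[str, int]
    family_ranges: dict[str, tuple[int, int]]

    def validate(self) -> None:
        for pid, n in self.protein_lengths.items():
            if n < 1:
                raise TableFormatError(f"protein {pid!r} length must be positive")
        for fam, (lo, hi) in self.family_ranges.items():
            if lo > hi:
                raise TableFormatError(f"family {fam!r} range {lo}-{hi} inverted")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[UnigeneRecord]:
    """Read unigenes from FASTA.

    Sequences are uppercased and ``U`` is mapped to ``T``. A
    ``family=<label>`` token in the description, if present, becomes the
    record's annotation. Duplicate ids raise an error naming the id.
    """
    records: list[UnigeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise TableFormatError(f"duplicate unigene id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        m = re.search(r"family=(\S+)", rec.description)
        records.append(UnigeneRecord(rec.id, seq, m.group(1) if m else ""))
    return records


def write_fasta(records: Iterable[UnigeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}"
            if r.annotation:
                header += f" family={r.annotation}"
            fh.write(header + "\n")
            for i in range(0, len(r.seq), 70):
                fh.write(r.seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Read counts

def read_counts(counts_path: str | Path, totals_path: str | Path) -> ReadCountTable:
    """Read a per-sample read-count table plus its totals sidecar.

    ``counts_path``: TSV with columns ``unigene_id``, ``length_nt``, then
    one column per sample, integer cells. ``totals_path``: TSV with
    columns ``sample_id``, ``total_mapped_reads``.
    """
    df = pd.read_csv(counts_path, sep="\t", dtype={"unigene_id": str})
    if "unigene_id" not in df.columns or "length_nt" not in df.columns:
        raise TableFormatError("counts table needs 'unigene_id' and 'length_nt' columns")
    samples = [c for c in df.columns if c not in ("unigene_id", "length_nt")]
    for c in samples:
        if not np.issubdtype(df[c].dtype, np.integer):
            raise TableFormatError(f"non-integer count cells in column {c!r}")
    tot = pd.read_csv(totals_path, sep="\t", dtype={"sample_id": str})
    totals = dict(zip(tot["sample_id"], tot["total_mapped_reads"].astype(int)))
    uids = list(df["unigene_id"])
    counts = {
        (uid, s): int(c)
        for s in samples
        for uid, c in zip(uids, df[s].to_numpy())
    }
    lengths = dict(zip(df["unigene_id"], df["length_nt"].astype(int)))
    table = ReadCountTable(counts, totals, lengths, samples, list(df["unigene_id"]))
    table.validate()
    return table


def write_counts(table: ReadCountTable, counts_path: str | Path, totals_path: str | Path) -> None:
    rows = []
    for uid in table.unigene_order:
        row = {"unigene_id": uid, "length_nt": table.lengths[uid]}
        for s in table.sample_order:
            row[s] = table.counts[(uid, s)]
        rows.append(row)
    pd.DataFrame(rows).to_csv(counts_path, sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": table.sample_order,
         "total_mapped_reads": [table.totals[s] for s in table.sample_order]}
    ).to_csv(totals_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrix

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    m = ExpressionMatrix(df.astype(float))
    m.validate()
    return m


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="unigene_id")


# ---------------------------------------------------------------------------
# Alignments

_ALN_COLS_13 = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "frame",
]
_ALN_COLS_10 = [
    "qseqid", "sseqid", "pident", "length",
    "qstart", "qend", "sstart", "send", "evalue", "frame",
]


def read_alignments(
    path: str | Path, best_hsp_only: bool = True
) -> list[AlignmentRow]:
    """Read a translated-alignment table (tab-separated, 1-based coords).

    When multiple HSPs exist per query, only the lowest-evalue HSP per
    query is kept by default (the pipeline uses a single reference
    location per unigene); pass ``best_hsp_only=False`` to keep all.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 13:
        df.columns = _ALN_COLS_13
    elif df.shape[1] == 10:
        df.columns = _ALN_COLS_10
    else:
        raise TableFormatError(
            f"alignment table has {df.shape[1]} columns; expected 10 or 13"
        )
    rows = [
        AlignmentRow(
            str(r.qseqid), str(r.sseqid),
            int(r.sstart), int(r.send), int(r.qstart), int(r.qend),
            int(r.frame), float(r.pident), float(r.evalue),
        ).normalized()
        for r in df.itertuples(index=False)
    ]
    if best_hsp_only:
        best: dict[str, AlignmentRow] = {}
        for row in rows:
            cur = best.get(row.query_id)
            if cur is None or row.evalue < cur.evalue:
                best[row.query_id] = row
        rows = [best[q] for q in dict.fromkeys(r.query_id for r in rows)]
    return rows


def write_alignments(rows: Iterable[AlignmentRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.subject_id, r.percent_identity,
                        r.query_end_nt - r.query_start_nt + 1,
                        r.query_start_nt, r.query_end_nt,
                        r.subject_start_aa, r.subject_end_aa,
                        r.evalue, r.frame,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Reference info

def read_reference_info(lengths_path: str | Path, ranges_path: str | Path) -> ReferenceInfo:
    lg = pd.read_csv(lengths_path, sep="\t", dtype={"protein_id": str})
    rg = pd.read_csv(ranges_path, sep="\t", dtype={"family": str})
    info = ReferenceInfo(
        dict(zip(lg["protein_id"], lg["length_aa"].astype(int))),
        {r.family: (int(r.min_aa), int(r.max_aa)) for r in rg.itertuples(index=False)},
    )
    info.validate()
    return info


def write_reference_info(info: ReferenceInfo, lengths_path: str | Path, ranges_path: str | Path) -> None:
    pd.DataFrame(
        {"protein_id": list(info.protein_lengths),
         "length_aa": list(info.protein_lengths.values())}
    ).to_csv(lengths_path, sep="\t", index=False)
    pd.DataFrame(
        [{"family": f, "min_aa": lo, "max_aa": hi} for f, (lo, hi) in info.family_ranges.items()]
    ).to_csv(ranges_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reports

_PAIR_HEADER = [
    "number", "unigene_pair", "reference_location", "possible_gap",
    "primer_forward_reverse", "designed_size_bp", "estimated_size_bp",
]


def _gap_str(gap_aa: int | None) -> str:
    return "none" if gap_aa is None else f"{gap_aa} aa"


def write_pair_report(pairs: Sequence, primers: Mapping, path: str | Path) -> None:
    """Write the candidate-pair report.

    One row per candidate pair: serial number, member ids joined with
    " + ", reference-location string, gap ("none" or "<g> aa"), primer
    pair joined with "/", designed and estimated product sizes in bp.
    Pairs with no feasible primers leave the primer/size columns empty.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_PAIR_HEADER) + "\n")
        for i, pair in enumerate(pairs, start=1):
            pr = primers.get((pair.five_prime_id, pair.three_prime_id))
            if pr is not None:
                primer_col = f"{pr.forward_seq}/{pr.reverse_seq}"
                designed = str(pr.designed_size_bp)
                estimated = str(pr.estimated_size_bp)
            else:
                primer_col = designed = estimated = ""
            fh.write(
                "\t".join(
                    [
                        str(i),
                        f"{pair.five_prime_id} + {pair.three_prime_id}",
                        pair.reference_location,
                        _gap_str(pair.gap_aa),
                        primer_col,
                        designed,
                        estimated,
                    ]
                )
                + "\n"
            )


_ASSEMBLY_HEADER = [
    "assembly", "five_prime_unigene_bp", "three_prime_unigene_bp",
    "assembled_length_bp", "encoded_protein_aa", "complete_cds", "annotation",
]


def write_assembly_report(results: Sequence, path: str | Path) -> None:
    """Write the merged-sequence report (component lengths, ORF, CDS call)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_ASSEMBLY_HEADER) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.assembly_id,
                        str(r.five_prime_length_nt),
                        str(r.three_prime_length_nt),
                        str(r.assembled_length_nt),
                        str(r.orf.protein_length_aa if r.orf else ""),
                        "yes" if r.complete_cds else "no",
                        r.annotation,
                    ]
                )
                + "\n"
            )
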