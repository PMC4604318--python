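"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the situation the method targets: a de novo
assembled transcriptome in which some transcripts are represented by
two unigenes — a 5′ fragment and a 3′ fragment separated by an
unassembled gap (or a short overlap) — whose per-sample read counts are
proportional to fragment length times transcript abundance, so the two
fragments share an expression pattern. Decoy paralogs with diverged
overlap regions exercise the mismatched-overlap exclusion.

What it emulates: fragment/gap geometry on a reference protein,
length-proportional counts, lognormal per-sample abundances, Poisson
count noise, Sanger-like bridge reads with point errors and random
strand. What it does not: read-level simulation, mapping ambiguity,
positional coverage bias, isoforms, chimeric assemblies.

Coding sequences are drawn from a uniform non-stop codon model with a
fixed ATG start and one stop; family protein-length ranges are derived
from the generated references ±10%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_tables import (
    AlignmentRow,
    ReadCountTable,
    ReferenceInfo,
    UnigeneRecord,
    write_alignments,
    write_counts,
    write_fasta,
    write_reference_info,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "TruePair",
    "generate",
    "simulate_bridge",
]

_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_DEFAULT_SAMPLES = ("200S", "CKS", "200R", "CKR")
_FAMILIES = ("NRT1/PTR", "NRT2", "PHT1", "PHT3")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated transcriptome.

    Defaults: 20 transcripts over 4 samples (shoot/root under salt or
    control, as in the motivating study), 6 of them split into true
    fragment pairs of which roughly one in six overlaps instead of
    gapping; 3 decoy paralogs at 12% divergence; no count noise (the
    idealised proportional-sampling regime the method assumes).
    """

    n_transcripts: int = 20
    n_samples: int = 4
    n_pairs: int = 6
    gap_range_aa: tuple[int, int] = (30, 250)
    overlap_fraction: float = 1 / 6
    overlap_range_aa: tuple[int, int] = (10, 40)
    n_decoys: int = 3
    decoy_divergence: float = 0.12
    noise: float = 0.0
    background_reads: int = 5_000_000
    protein_length_range_aa: tuple[int, int] = (420, 650)
    sample_names: tuple[str, ...] = _DEFAULT_SAMPLES


@dataclass(frozen=True)
class TranscriptTruth:
    seq: str
    reference_id: str
    family: str
    cds_start_nt: int  # 1-based first base of ATG
    protein_length_aa: int


@dataclass(frozen=True)
class FragmentTruth:
    transcript_id: str
    start_nt: int  # 1-based inclusive on the transcript
    end_nt: int
    strand: int  # +1 as transcript, -1 emitted reverse-complemented
    kind: str  # five | three | single | decoy


@dataclass(frozen=True)
class TruePair:
    five_prime_id: str
    three_prime_id: str
    transcript_id: str
    gap_aa: int | None  # start3 - end5 convention; None when overlapping
    overlap_aa: int


@dataclass
class SyntheticTruth:
    """Everything the generator knows, for oracle-style assertions."""

    config: SimulationConfig
    transcripts: dict[str, TranscriptTruth]
    fragment_map: dict[str, FragmentTruth]
    true_pairs: list[TruePair]
    records: list[UnigeneRecord]
    counts: ReadCountTable
    alignments: list[AlignmentRow]
    reference: ReferenceInfo
    abundance: dict[tuple[str, str], int] = field(default_factory=dict)

    def true_product_size(
        self, pair: TruePair, forward_start_nt: int, reverse_end_nt: int
    ) -> int:
        """Length of the PCR product on the real transcript, for primers
        at ``forward_start_nt`` on the 5′ fragment and a reverse site
        ending at ``reverse_end_nt`` on the 3′ fragment."""
        frag3 = self.fragment_map[pair.three_prime_id]
        t_end = (frag3.start_nt - 1) + reverse_end_nt
        return t_end - forward_start_nt + 1

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "unigenes": outdir / "unigenes.fasta",
            "counts": outdir / "counts.tsv",
            "totals": outdir / "totals.tsv",
            "alignments": outdir / "alignments.tsv",
            "reference_lengths": outdir / "reference_lengths.tsv",
            "family_ranges": outdir / "family_ranges.tsv",
            "truth_pairs": outdir / "truth_pairs.tsv",
        }
        write_fasta(self.records, paths["unigenes"])
        write_counts(self.counts, paths["counts"], paths["totals"])
        write_alignments(self.alignments, paths["alignments"])
        write_reference_info(
            self.reference, paths["reference_lengths"], paths["family_ranges"]
        )
        with open(paths["truth_pairs"], "w") as fh:
            fh.write("five_prime_id\tthree_prime_id\ttranscript_id\tgap_aa\toverlap_aa\n")
            for p in self.true_pairs:
                fh.write(
                    f"{p.five_prime_id}\t{p.three_prime_id}\t{p.transcript_id}\t"
                    f"{'none' if p.gap_aa is None else p.gap_aa}\t{p.overlap_aa}\n"
                )
        return paths


def _random_transcript(
    rng: np.random.Generator, protein_aa: int
) -> tuple[str, int]:
    """Random transcript sequence and 1-based CDS start."""
    utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 90))))
    utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(40, 120))))
    body = "".join(rng.choice(_CODONS, size=protein_aa - 1))
    stop = str(rng.choice(("TAA", "TAG", "TGA")))
    return utr5 + "ATG" + body + stop + utr3, len(utr5) + 1


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute exactly round(rate * len) positions (chosen without
    replacement), so the realised divergence equals the nominal rate."""
    n_mut = int(round(rate * len(seq)))
    if n_mut <= 0:
        return seq
    chars = list(seq)
    for i in rng.choice(len(chars), size=n_mut, replace=False):
        choices = [b for b in "ACGT" if b != chars[i]]
        chars[i] = choices[int(rng.integers(3))]
    return "".join(chars)


def generate(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Build one deterministic synthetic transcriptome with full truth.

    Read counts are ``length_nt x abundance`` per unigene (exactly
    proportional, so fragments of one transcript have identical RPKM in
    every sample) with optional multiplicative lognormal noise followed
    by Poisson sampling when ``config.noise > 0``.
    """
    cfg = config or SimulationConfig()
    if cfg.n_pairs > cfg.n_transcripts:
        raise ValueError("more pairs requested than transcripts")
    if cfg.gap_range_aa[0] < 1:
        raise ValueError("gap range must be positive")
    rng = np.random.default_rng(seed)
    samples = list(cfg.sample_names[: cfg.n_samples])
    if len(samples) < cfg.n_samples:
        samples += [f"S{k}" for k in range(len(samples), cfg.n_samples)]

    transcripts: dict[str, TranscriptTruth] = {}
    fragment_map: dict[str, FragmentTruth] = {}
    true_pairs: list[TruePair] = []
    records: list[UnigeneRecord] = []
    alignments: list[AlignmentRow] = []
    protein_lengths: dict[str, int] = {}
    fam_proteins: dict[str, list[int]] = {f: [] for f in _FAMILIES}
    abundance: dict[tuple[str, str], int] = {}

    n_overlap = round(cfg.n_pairs * cfg.overlap_fraction)
    n_decoys_emitted = 0

    def emit_unigene(
        uid: str, tid: str, start_nt: int, end_nt: int, kind: str,
        seq: str, family: str, subject: str,
        sub_start: int, sub_end: int, q_cds_start: int, pident: float,
    ) -> None:
        """Register one unigene, possibly reverse-complemented, plus its
        alignment row. ``q_cds_start`` is the 1-based position in ``seq``
        of the first base of subject codon ``sub_start``."""
        strand = 1 if rng.random() < 0.7 else -1
        qlen = len(seq)
        qs = q_cds_start
        qe = q_cds_start + 3 * (sub_end - sub_start + 1) - 1
        if strand == 1:
            out_seq = seq
            frame = (qs - 1) % 3 + 1
        else:
            out_seq = _revcomp(seq)
            qs, qe = qlen - qe + 1, qlen - qs + 1
            frame = -((qlen - qe) % 3 + 1)
        fragment_map[uid] = FragmentTruth(tid, start_nt, end_nt, strand, kind)
        records.append(UnigeneRecord(uid, out_seq, family))
        alignments.append(
            AlignmentRow(uid, subject, sub_start, sub_end, qs, qe, frame,
                         pident, 1e-80).normalized()
        )

    for t in range(cfg.n_transcripts):
        tid = f"tr{t:03d}"
        family = _FAMILIES[t % len(_FAMILIES)]
        P = int(rng.integers(*cfg.protein_length_range_aa))
        seq, cds_start = _random_transcript(rng, P)
        ref_id = f"REF{t:03d}"
        transcripts[tid] = TranscriptTruth(seq, ref_id, family, cds_start, P)
        protein_lengths[ref_id] = P
        fam_proteins[family].append(P)
        for s in samples:
            abundance[(tid, s)] = max(1, int(round(rng.lognormal(3.5, 1.0))))

        c0 = cds_start - 1  # 0-based first base of ATG
        if t < cfg.n_pairs:
            overlapping = t < n_overlap
            e5 = int(rng.integers(P // 4, P // 2))
            if overlapping:
                ov = int(rng.integers(*cfg.overlap_range_aa))
                s3 = e5 - ov + 1
            else:
                gap = int(rng.integers(cfg.gap_range_aa[0], cfg.gap_range_aa[1] + 1))
                # keep the 3' fragment long enough for primer placement
                if e5 + gap > P - 80:
                    gap = max(1, P - 80 - e5)
                s3 = e5 + gap
            if not 1 < s3 < P:
                raise ValueError("infeasible split: gap larger than transcript")
            a = c0 + 3 * e5  # 0-based exclusive end of fragment 1
            b = c0 + 3 * (s3 - 1)  # 0-based start of fragment 2
            uid5, uid3 = f"u{t:03d}a", f"u{t:03d}b"
            emit_unigene(
                uid5, tid, 1, a, "five", seq[:a], family, ref_id,
                1, e5, cds_start, 100.0,
            )
            emit_unigene(
                uid3, tid, b + 1, len(seq), "three", seq[b:], family, ref_id,
                s3, P, 1, 100.0,
            )
            gap_aa = None if overlapping else s3 - e5
            overlap_aa = e5 - s3 + 1 if overlapping else 0
            true_pairs.append(TruePair(uid5, uid3, tid, gap_aa, overlap_aa))
            if not overlapping and n_decoys_emitted < cfg.n_decoys:
                n_decoys_emitted += 1
                d_lo = max(16, e5 - 30)
                # keep the decoy clear of the 3' terminus so only the
                # overlap-mismatch rule can exclude it
                d_hi = min(P - 20, s3 + 30)
                d_start = c0 + 3 * (d_lo - 1)
                d_end = c0 + 3 * d_hi
                d_seq = _mutate(rng, seq[d_start:d_end], cfg.decoy_divergence)
                emit_unigene(
                    f"u{t:03d}x", tid, d_start + 1, d_end, "decoy", d_seq,
                    family, ref_id, d_lo, d_hi, 1,
                    100.0 * (1 - cfg.decoy_divergence),
                )
        else:
            emit_unigene(
                f"u{t:03d}", tid, 1, len(seq), "single", seq, family, ref_id,
                1, P, cds_start, 100.0,
            )

    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        frag = fragment_map[rec.id]
        for s in samples:
            mean = rec.length_nt * abundance[(frag.transcript_id, s)]
            if cfg.noise > 0:
                mean = mean * rng.lognormal(0.0, cfg.noise)
                counts[(rec.id, s)] = int(rng.poisson(mean))
            else:
                counts[(rec.id, s)] = int(mean)
    totals = {
        s: cfg.background_reads + sum(counts[(r.id, s)] for r in records)
        for s in samples
    }
    table = ReadCountTable(
        counts, totals, {r.id: r.length_nt for r in records},
        samples, [r.id for r in records],
    )
    family_ranges = {
        f: (math.floor(0.9 * min(ps)), math.ceil(1.1 * max(ps)))
        for f, ps in fam_proteins.items()
        if ps
    }
    truth = SyntheticTruth(
        cfg, transcripts, fragment_map, true_pairs, records, table,
        alignments, ReferenceInfo(protein_lengths, family_ranges), abundance,
    )
    truth.counts.validate()
    return truth


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_bridge(
    truth: SyntheticTruth,
    pair: TruePair,
    flank_overlap_nt: int = 250,
    error_rate: float = 0.0,
    seed: int = 0,
) -> str:
    """A Sanger-like bridging read: the transcript segment spanning the
    gap plus ``flank_overlap_nt`` into each fragment, with point errors
    at ``error_rate`` and random strand."""
    if pair not in truth.true_pairs:
        raise ValueError("pair is not one of the generator's true pairs")
    rng = np.random.default_rng(seed)
    frag5 = truth.fragment_map[pair.five_prime_id]
    frag3 = truth.fragment_map[pair.three_prime_id]
    T = truth.transcripts[pair.transcript_id].seq
    e1 = frag5.end_nt          # 0-based exclusive end of fragment 1
    s2 = frag3.start_nt - 1    # 0-based start of fragment 2
    lo = min(e1, s2) - flank_overlap_nt
    hi = max(e1, s2) + flank_overlap_nt
    if lo < 0 or hi > len(T):
        raise ValueError("flank_overlap exceeds a fragment length")
    bridge = _mutate(rng, T[lo:hi], error_rate)
    if rng.random() < 0.5:
        bridge = _revcomp(bridge)
    return bridge
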