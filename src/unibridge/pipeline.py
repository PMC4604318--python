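"""End-to-end orchestration: counts -> RPKM -> groups -> pairs -> primers.

This is the library face of the workflow; the command-line interface is
a thin wrapper around :func:`run_pipeline`. Every filtering stage
reports its counts so a run can be audited: unigenes in, families,
groups, combinations considered, exclusions by reason, candidate pairs
out.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from . import expression, grouping, pair_selection, primer_design
from .io_tables import AlignmentRow, ReferenceInfo, UnigeneRecord

logger = logging.getLogger("unibridge")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and knobs for one pipeline run."""

    metric: str = "correlation"
    linkage: str = "average"
    group_min: int = 2
    group_max: int = 5
    min_overlap_identity: float = pair_selection.DEFAULT_MIN_OVERLAP_IDENTITY
    max_pairs_per_group: int | None = None
    design_primers: bool = True
    primer_constraints: primer_design.PrimerConstraints = field(
        default_factory=primer_design.PrimerConstraints
    )

    def validate(self) -> None:
        if not 0 < self.min_overlap_identity <= 1:
            raise ValueError("min_overlap_identity must be in (0, 1]")
        if not 2 <= self.group_min <= self.group_max:
            raise ValueError("need 2 <= group_min <= group_max")


@dataclass
class PipelineResult:
    groups: list[grouping.ExpressionGroup]
    pairs: list[pair_selection.CandidatePair]
    exclusions: list[pair_selection.ExclusionRecord]
    primers: dict[tuple[str, str], primer_design.PrimerPair]
    infeasible_primers: dict[tuple[str, str], primer_design.InfeasiblePrimers]
    spans: dict[str, pair_selection.ProteinSpan]
    stage_counts: dict[str, int]


def run_pipeline(
    records: list[UnigeneRecord],
    matrix: expression.ExpressionMatrix,
    alignments: list[AlignmentRow],
    reference: ReferenceInfo,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run grouping, pair selection and primer design over loaded inputs.

    Unigenes are partitioned by their annotation label (family);
    families are clustered separately on the expression matrix and cut
    into groups of ``group_min``..``group_max`` members; within each
    group all pairs are considered against their reference-protein
    footprints.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    by_id = {r.id: r for r in records}

    rows = {a.query_id: a for a in alignments if a.query_id in by_id}
    spans = {
        uid: pair_selection.build_span(row, by_id[uid], reference)
        for uid, row in rows.items()
    }

    families: dict[str, list[str]] = {}
    for r in records:
        families.setdefault(r.annotation or "unannotated", []).append(r.id)

    groups: list[grouping.ExpressionGroup] = []
    for fam in sorted(families):
        ids = [u for u in families[fam] if u in matrix.unigene_ids]
        profiles = [expression.ExpressionProfile.from_matrix(matrix, u) for u in ids]
        dendro = (
            grouping.cluster_family(profiles, cfg.metric, cfg.linkage, family=fam)
            if len(profiles) >= 2
            else None
        )
        fam_groups = grouping.extract_groups(dendro, cfg.group_min, cfg.group_max)
        logger.info("family %s: %d unigenes -> %d groups", fam, len(ids), len(fam_groups))
        groups.extend(fam_groups)

    pairs: list[pair_selection.CandidatePair] = []
    exclusions: list[pair_selection.ExclusionRecord] = []
    for g in groups:
        p, e = pair_selection.enumerate_pairs(
            g, spans,
            min_identity=cfg.min_overlap_identity,
            max_pairs_per_group=cfg.max_pairs_per_group,
        )
        pairs.extend(p)
        exclusions.extend(e)

    primers: dict[tuple[str, str], primer_design.PrimerPair] = {}
    infeasible: dict[tuple[str, str], primer_design.InfeasiblePrimers] = {}
    if cfg.design_primers:
        for p in pairs:
            result = primer_design.pick_primers(
                p,
                spans[p.five_prime_id].oriented_seq,
                spans[p.three_prime_id].oriented_seq,
                cfg.primer_constraints,
            )
            key = (p.five_prime_id, p.three_prime_id)
            if isinstance(result, primer_design.PrimerPair):
                primers[key] = result
            else:
                infeasible[key] = result
                logger.info("pair %s: no primers (%s)", key, result.violated_constraint)

    by_reason = Counter(e.reason for e in exclusions)
    stage_counts = {
        "unigenes_in": len(records),
        "unigenes_with_span": len(spans),
        "families": len(families),
        "groups": len(groups),
        "combinations_considered": len(pairs) + len(exclusions),
        "candidate_pairs": len(pairs),
        **{f"excluded_{r}": n for r, n in sorted(by_reason.items())},
    }
    for k, v in stage_counts.items():
        logger.info("%s: %d", k, v)
    for e in exclusions:
        logger.debug("excluded %s + %s: %s", e.first_id, e.second_id, e.reason)
    return PipelineResult(groups, pairs, exclusions, primers, infeasible, spans, stage_counts)
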