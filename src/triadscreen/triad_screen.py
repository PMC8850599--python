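"""The seven-stage candidate-selection cascade producing lncRNA–miRNA–mRNA
("ceRNA triad") candidates with a full per-stage audit trail.

Stage order (fixed; matches the study narrative):

  A. strong_validation     keep disease-linked miRNAs with strong experimental
                           evidence (reporter assay / western blot / qPCR)
  B. lncrna_targets        map the miRNAs to their sponged lncRNAs, gated on
                           the interaction score
  C. tissue                keep lncRNAs expressed in every required tissue
                           (blood AND brain by default)
  D. degree_and_known      drop lncRNAs already reported for the disease, and
                           lncRNAs sponging fewer than the minimum number of
                           stage-A miRNAs
  E. pd_gene_link          keep lncRNAs whose miRNAs target an important
                           disease gene above the prediction-score gate
  F. specificity           drop lncRNAs associated with other (excluded)
                           neurodegenerative diseases
  G. cis_pairing           emit (lncRNA, miRNA, gene) triads whose producing
                           gene loci lie within the cis distance threshold

All thresholds come from :class:`~triadscreen.knowledge_base.ScreenConfig`;
this module contains no numeric gate values.  Score gates are strict
inequalities; entities lacking a required annotation (tissue record, locus)
fail the corresponding filter rather than erroring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .knowledge_base import (
    DiseaseAssociation,
    GeneLocus,
    KnowledgeBase,
    KnowledgeBaseError,
    MirnaGeneInteraction,
    MirnaLncrnaInteraction,
    MirnaRecord,
    ScreenConfig,
    TissueExpressionRecord,
    genomic_gap,
)

__all__ = [
    "CandidateTriad",
    "CascadeResult",
    "STAGES",
    "filter_strong_validation",
    "mirna_to_lncrna",
    "filter_tissue",
    "exclude_known_and_low_degree",
    "filter_pd_gene_link",
    "filter_specificity",
    "pair_cis",
    "run_cascade",
]

STAGES = (
    "strong_validation",
    "lncrna_targets",
    "tissue",
    "degree_and_known",
    "pd_gene_link",
    "specificity",
    "cis_pairing",
)


@dataclass(frozen=True)
class CandidateTriad:
    """A surviving (lncRNA, miRNA, gene) triple with its supporting scores."""

    lncrna_id: str
    mirna_id: str
    gene_id: str
    lncbase_score: float
    gene_prediction_score: float
    cis_gap_bp: int


@dataclass
class CascadeResult:
    """Per-stage survivors, counts, final triads, and elimination audit.

    ``eliminated`` maps each removed entity to ``(stage, reason)`` for the
    first stage that removed it; miRNAs can only be removed at stage A,
    lncRNAs at stages B–G.
    """

    survivors: dict[str, frozenset[str]] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    triads: list[CandidateTriad] = field(default_factory=list)
    eliminated: dict[str, tuple[str, str]] = field(default_factory=dict)
    n_triads: int = 0


# ---------------------------------------------------------------------------
# stage filters
# ---------------------------------------------------------------------------

def filter_strong_validation(mirna_records: list[MirnaRecord],
                             config: ScreenConfig) -> frozenset[str]:
    """Stage A: disease-flagged miRNAs whose evidence intersects the strong
    whitelist."""
    if not config.strong_evidence_methods:
        raise KnowledgeBaseError("strong_evidence_methods whitelist is empty")
    return frozenset(
        rec.mirna_id
        for rec in mirna_records
        if rec.pd_related and rec.evidence_methods & config.strong_evidence_methods
    )


def mirna_to_lncrna(mirna_ids: frozenset[str] | set[str],
                    interactions: list[MirnaLncrnaInteraction],
                    config: ScreenConfig) -> dict[str, frozenset[str]]:
    """Stage B: sponged-lncRNA mapping, lncRNA-keyed.

    An interaction (m, L) enters the mapping iff m is in the input miRNA set
    and its score clears the gate (strictly, when the gate is enabled).
    """
    mapping: dict[str, set[str]] = {}
    for inter in interactions:
        if inter.mirna_id not in mirna_ids:
            continue
        if config.apply_lncbase_score_gate and not (
            inter.score > config.min_lncbase_score
        ):
            continue
        mapping.setdefault(inter.lncrna_id, set()).add(inter.mirna_id)
    return {lnc: frozenset(ms) for lnc, ms in mapping.items()}


def filter_tissue(lncrna_ids: frozenset[str] | set[str],
                  tissue_records: list[TissueExpressionRecord],
                  config: ScreenConfig) -> frozenset[str]:
    """Stage C: keep entities whose tissue set covers every required tissue.

    An entity without a tissue record is treated as expressed nowhere.
    """
    by_entity = {rec.entity_id: rec.tissues for rec in tissue_records}
    return frozenset(
        lnc for lnc in lncrna_ids
        if config.required_tissues <= by_entity.get(lnc, frozenset())
    )


def exclude_known_and_low_degree(
    mapping: dict[str, frozenset[str]],
    pd_lncrna_set: frozenset[str] | set[str],
    config: ScreenConfig,
) -> dict[str, frozenset[str]]:
    """Stage D: drop already-reported disease lncRNAs and low-degree sponges.

    Degree counts only the miRNAs present in the mapping values, i.e. the
    stage-A survivors that reached this lncRNA through the score gate.
    """
    return {
        lnc: mirnas
        for lnc, mirnas in mapping.items()
        if lnc not in pd_lncrna_set and len(mirnas) >= config.min_mirna_degree
    }


def _gene_gate_passes(inter: MirnaGeneInteraction, config: ScreenConfig) -> bool:
    if inter.gene_id not in config.pd_gene_set:
        return False
    if config.apply_gene_score_gate:
        return inter.prediction_score > config.min_gene_prediction_score
    return True


def filter_pd_gene_link(
    mapping: dict[str, frozenset[str]],
    mirna_gene_table: list[MirnaGeneInteraction],
    config: ScreenConfig,
) -> dict[str, frozenset[str]]:
    """Stage E: keep lncRNAs whose miRNA set targets an important disease
    gene above the prediction gate."""
    if not config.pd_gene_set:
        raise KnowledgeBaseError("pd_gene_set is empty")
    hitters = frozenset(
        inter.mirna_id for inter in mirna_gene_table if _gene_gate_passes(inter, config)
    )
    return {lnc: ms for lnc, ms in mapping.items() if ms & hitters}


def filter_specificity(
    mapping: dict[str, frozenset[str]],
    disease_associations: list[DiseaseAssociation],
    config: ScreenConfig,
) -> dict[str, frozenset[str]]:
    """Stage F: drop lncRNAs linked to any excluded (non-specific) disease."""
    tainted = frozenset(
        assoc.entity_id
        for assoc in disease_associations
        if assoc.disease in config.excluded_disease_labels
    )
    return {lnc: ms for lnc, ms in mapping.items() if lnc not in tainted}


def pair_cis(
    mapping: dict[str, frozenset[str]],
    loci: list[GeneLocus],
    config: ScreenConfig,
    mirna_gene_table: list[MirnaGeneInteraction],
) -> tuple[list[CandidateTriad], dict[str, str]]:
    """Stage G: cis pairing of surviving lncRNAs with target genes.

    Emits (L, m, G) whenever m is in L's miRNA set, (m, G) clears the gene
    gate with G in the disease gene set, and the producing loci of L and G
    lie strictly closer than the cis threshold.  Returns the triads and an
    audit of lncRNAs that could not pair (missing locus / no cis partner).
    """
    locus_by_id = {l.entity_id: l for l in loci}
    gene_links: dict[str, list[MirnaGeneInteraction]] = {}
    for inter in mirna_gene_table:
        if _gene_gate_passes(inter, config):
            gene_links.setdefault(inter.mirna_id, []).append(inter)
    triads: list[CandidateTriad] = []
    audit: dict[str, str] = {}
    for lnc in sorted(mapping):
        lnc_locus = locus_by_id.get(lnc)
        if lnc_locus is None:
            audit[lnc] = "no locus"
            continue
        paired = False
        for mirna in sorted(mapping[lnc]):
            for inter in gene_links.get(mirna, []):
                gene_locus = locus_by_id.get(inter.gene_id)
                if gene_locus is None:
                    continue
                gap = genomic_gap(lnc_locus, gene_locus)
                if gap < config.max_cis_gap_bp:
                    triads.append(
                        CandidateTriad(
                            lncrna_id=lnc,
                            mirna_id=mirna,
                            gene_id=inter.gene_id,
                            lncbase_score=float("nan"),  # filled by run_cascade
                            gene_prediction_score=inter.prediction_score,
                            cis_gap_bp=int(gap),
                        )
                    )
                    paired = True
        if not paired:
            audit[lnc] = "no cis partner"
    return triads, audit


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_cascade(kb: KnowledgeBase, config: ScreenConfig) -> CascadeResult:
    """Apply the seven stages in study order with a complete audit trail.

    Deterministic given (kb, config).  The lncRNA-track survivor counts are
    non-increasing from stage B onward, and at every stage
    ``|survivors| + |eliminated at stage| == |stage inputs|``.
    """
    result = CascadeResult()
    score_by_pair = {(i.mirna_id, i.lncrna_id): i.score for i in kb.mirna_lncrna}

    # A — miRNA track
    strong = filter_strong_validation(kb.mirnas, config)
    for rec in kb.mirnas:
        if rec.mirna_id not in strong:
            result.eliminated[rec.mirna_id] = (
                "strong_validation",
                "not disease-flagged with strong evidence",
            )
    result.survivors["strong_validation"] = strong
    result.stage_counts["strong_validation"] = len(strong)

    # B — lncRNA track opens
    mapping = mirna_to_lncrna(strong, kb.mirna_lncrna, config)
    all_lncrnas = frozenset(i.lncrna_id for i in kb.mirna_lncrna)
    for lnc in all_lncrnas - frozenset(mapping):
        result.eliminated[lnc] = (
            "lncrna_targets", "no qualifying interaction with a stage-A miRNA"
        )
    result.survivors["lncrna_targets"] = frozenset(mapping)
    result.stage_counts["lncrna_targets"] = len(mapping)

    # C — tissue
    in_tissue = filter_tissue(frozenset(mapping), kb.tissues, config)
    for lnc in frozenset(mapping) - in_tissue:
        result.eliminated[lnc] = ("tissue", "not expressed in all required tissues")
    mapping = {lnc: ms for lnc, ms in mapping.items() if lnc in in_tissue}
    result.survivors["tissue"] = frozenset(mapping)
    result.stage_counts["tissue"] = len(mapping)

    # D — known-disease lncRNAs and low degree
    pd_lncrnas = frozenset(
        assoc.entity_id
        for assoc in kb.diseases
        if assoc.disease == config.pd_disease_label and assoc.entity_id in mapping
    )
    kept = exclude_known_and_low_degree(mapping, pd_lncrnas, config)
    for lnc in frozenset(mapping) - frozenset(kept):
        reason = (
            "already reported for the disease"
            if lnc in pd_lncrnas
            else "sponges fewer miRNAs than required"
        )
        result.eliminated[lnc] = ("degree_and_known", reason)
    mapping = kept
    result.survivors["degree_and_known"] = frozenset(mapping)
    result.stage_counts["degree_and_known"] = len(mapping)

    # E — important-gene link
    kept = filter_pd_gene_link(mapping, kb.mirna_gene, config)
    for lnc in frozenset(mapping) - frozenset(kept):
        result.eliminated[lnc] = (
            "pd_gene_link", "no miRNA targets an important disease gene"
        )
    mapping = kept
    result.survivors["pd_gene_link"] = frozenset(mapping)
    result.stage_counts["pd_gene_link"] = len(mapping)

    # F — specificity
    kept = filter_specificity(mapping, kb.diseases, config)
    for lnc in frozenset(mapping) - frozenset(kept):
        result.eliminated[lnc] = ("specificity", "associated with an excluded disease")
    mapping = kept
    result.survivors["specificity"] = frozenset(mapping)
    result.stage_counts["specificity"] = len(mapping)

    # G — cis pairing
    triads, pair_audit = pair_cis(mapping, kb.loci, config, kb.mirna_gene)
    triads = [
        CandidateTriad(
            lncrna_id=t.lncrna_id,
            mirna_id=t.mirna_id,
            gene_id=t.gene_id,
            lncbase_score=score_by_pair.get((t.mirna_id, t.lncrna_id), float("nan")),
            gene_prediction_score=t.gene_prediction_score,
            cis_gap_bp=t.cis_gap_bp,
        )
        for t in triads
    ]
    for lnc, reason in pair_audit.items():
        result.eliminated[lnc] = ("cis_pairing", reason)
    result.triads = sorted(
        triads, key=lambda t: (t.lncrna_id, t.mirna_id, t.gene_id)
    )
    result.survivors["cis_pairing"] = frozenset(t.lncrna_id for t in result.triads)
    result.stage_counts["cis_pairing"] = len(result.survivors["cis_pairing"])
    result.n_triads = len(result.triads)
    return result
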