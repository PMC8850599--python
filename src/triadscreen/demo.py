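"""Demonstration fixture: a hand-written reconstruction of the published
screening facts, so the headline results reproduce end-to-end without any
database download.

Everything here is a *reconstruction*, not a database snapshot: the named
entities (linc01128, linc00938, hsa-miR-24-3p, hsa-miR-30c-5p, ATP13A2,
LRRK2) and the printed interaction scores (0.79 on the 0–1 scale; 88 and 93
on the 0–100 scale) are real published values, while the genomic
coordinates, the auxiliary interaction scores needed to satisfy the degree
filter, and the Fig-8-style target lists are synthetic stand-ins chosen to
be consistent with the published counts.
"""

from __future__ import annotations

import pandas as pd

from .knowledge_base import (
    DiseaseAssociation,
    GeneLocus,
    KnowledgeBase,
    LncrnaGeneInteraction,
    MirnaGeneInteraction,
    MirnaLncrnaInteraction,
    MirnaRecord,
    ScreenConfig,
    TissueExpressionRecord,
)

__all__ = [
    "demo_knowledge_base",
    "demo_screen_config",
    "demo_network_table",
    "DEMO_COMMON_TARGETS",
    "DEMOGRAPHICS",
    "demographics_consistency",
]

_STRONG = frozenset({"reporter-assay", "western-blot", "qPCR"})


def demo_screen_config() -> ScreenConfig:
    """Default thresholds with the familial parkinsonism gene panel."""
    return ScreenConfig(
        pd_gene_set=frozenset({"LRRK2", "ATP13A2", "SNCA", "PRKN", "PINK1"}),
        excluded_disease_labels=frozenset(
            {"Alzheimer disease", "Huntington disease",
             "Amyotrophic lateral sclerosis"}
        ),
    )


def demo_knowledge_base() -> KnowledgeBase:
    """The two-triad reconstruction.

    Running the cascade on this knowledge base with
    :func:`demo_screen_config` yields exactly the two published triads:
    (linc01128, hsa-miR-24-3p, ATP13A2) and (linc00938, hsa-miR-30c-5p,
    LRRK2).
    """
    kb = KnowledgeBase()
    kb.mirnas = [
        MirnaRecord("hsa-miR-24-3p", _STRONG, True),
        MirnaRecord("hsa-miR-30c-5p", _STRONG, True),
    ]
    kb.mirna_lncrna = [
        # 0.79 is the published immunoprecipitation score; the other three
        # are synthetic, set above the 0.7 gate so both lncRNAs sponge both
        # miRNAs (degree 2)
        MirnaLncrnaInteraction("hsa-miR-30c-5p", "linc00938", 0.79,
                               "immunoprecipitation"),
        MirnaLncrnaInteraction("hsa-miR-24-3p", "linc00938", 0.72,
                               "immunoprecipitation"),
        MirnaLncrnaInteraction("hsa-miR-24-3p", "linc01128", 0.75,
                               "immunoprecipitation"),
        MirnaLncrnaInteraction("hsa-miR-30c-5p", "linc01128", 0.73,
                               "immunoprecipitation"),
    ]
    kb.mirna_gene = [
        MirnaGeneInteraction("hsa-miR-24-3p", "ATP13A2", 88.0),   # published
        MirnaGeneInteraction("hsa-miR-30c-5p", "LRRK2", 93.0),    # published
    ]
    kb.lncrna_gene = [
        # two predicted RNA:RNA interactions between linc01128 and ATP13A2
        LncrnaGeneInteraction("linc01128", "ATP13A2", 2),
    ]
    # synthetic coordinates: each lncRNA on the same chromosome as its
    # partner gene, within the 50 kb cis window; cross pairs on different
    # chromosomes
    kb.loci = [
        GeneLocus("linc01128", "chr1", 1_000_000, 1_010_000, "+"),
        GeneLocus("ATP13A2", "chr1", 1_030_000, 1_055_000, "-"),
        GeneLocus("linc00938", "chr12", 2_000_000, 2_012_000, "+"),
        GeneLocus("LRRK2", "chr12", 2_020_000, 2_160_000, "+"),
    ]
    kb.tissues = [
        TissueExpressionRecord("linc01128", frozenset({"blood", "brain"})),
        TissueExpressionRecord("linc00938", frozenset({"blood", "brain"})),
    ]
    kb.diseases = [
        DiseaseAssociation("LRRK2", "Parkinson disease", "database"),
        DiseaseAssociation("ATP13A2", "Parkinson disease", "database"),
    ]
    return kb


# ---------------------------------------------------------------------------
# Fig-8-style network fixture
# ---------------------------------------------------------------------------

DEMO_COMMON_TARGETS = ("C9orf79", "EPHB2", "IL1A", "LHFPL2", "NEFM")


def demo_network_table(n_targets_a: int = 131, n_targets_b: int = 34,
                       n_common: int = 5) -> pd.DataFrame:
    """miRNA→gene edge table with the published degree structure.

    hsa-miR-30c-5p targets ``n_targets_a`` genes, hsa-miR-24-3p targets
    ``n_targets_b``, sharing ``n_common`` (the five published common
    targets by default, synthetic ids beyond five).  The resulting network
    has ``2 + n_targets_a + n_targets_b − n_common`` nodes.
    """
    common = list(DEMO_COMMON_TARGETS[:n_common])
    common += [f"COMMON-{i:03d}" for i in range(len(common), n_common)]
    only_a = [f"TARGET-A-{i:03d}" for i in range(n_targets_a - n_common)]
    only_b = [f"TARGET-B-{i:03d}" for i in range(n_targets_b - n_common)]
    rows = [("hsa-miR-30c-5p", g) for g in common + only_a]
    rows += [("hsa-miR-24-3p", g) for g in common + only_b]
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id"])


# ---------------------------------------------------------------------------
# published demographic summary (reconstruction of the printed table)
# ---------------------------------------------------------------------------

DEMOGRAPHICS = {
    "control": {"n": 20, "age_mean": 59.45, "age_sd": 8.15,
                "bmi_mean": 27.57, "bmi_sd": 5.55, "males": 10, "females": 10},
    "early": {"n": 27, "age_mean": 65.11, "age_sd": 10.40,
              "duration_mean": 43.85, "duration_sd": 31.69,
              "bmi_mean": 26.05, "bmi_sd": 4.60},
    "late": {"n": 11, "age_mean": 62.82, "age_sd": 12.59,
             "duration_mean": 99.27, "duration_sd": 77.04,
             "bmi_mean": 25.38, "bmi_sd": 3.24},
    "pd_overall": {"n": 38, "age_mean": 64.45, "bmi_mean": 25.86,
                   "duration_mean": 59.90, "males": 21, "females": 17},
}


def _weighted(field: str) -> float:
    early, late = DEMOGRAPHICS["early"], DEMOGRAPHICS["late"]
    total = early["n"] + late["n"]
    return (early["n"] * early[field] + late["n"] * late[field]) / total


def demographics_consistency() -> dict:
    """Recompute the overall patient summary from the stage subgroups.

    The overall mean of a quantity must equal the n-weighted average of the
    early/late subgroup means, and the sex percentages must round to the
    printed integers — an internal-consistency check of the demographic
    summary table.
    """
    overall = DEMOGRAPHICS["pd_overall"]
    male_pct = 100.0 * overall["males"] / overall["n"]
    female_pct = 100.0 * overall["females"] / overall["n"]
    return {
        "age_weighted": _weighted("age_mean"),
        "age_printed": overall["age_mean"],
        "bmi_weighted": _weighted("bmi_mean"),
        "bmi_printed": overall["bmi_mean"],
        "duration_weighted": _weighted("duration_mean"),
        "duration_printed": overall["duration_mean"],
        "male_percent": male_pct,
        "male_percent_rounded": round(male_pct),
        "female_percent": female_pct,
        "female_percent_rounded": round(female_pct),
    }
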