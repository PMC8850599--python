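import itertools

import pytest

from triadscreen.knowledge_base import (
    GeneLocus,
    KnowledgeBaseError,
    MirnaGeneInteraction,
    MirnaLncrnaInteraction,
    MirnaRecord,
    ScreenConfig,
    TissueExpressionRecord,
)
from triadscreen.simulate import SynthConfig, generate_knowledge_base
from triadscreen.triad_screen import (
    STAGES,
    exclude_known_and_low_degree,
    filter_pd_gene_link,
    filter_specificity,
    filter_strong_validation,
    filter_tissue,
    mirna_to_lncrna,
    pair_cis,
    run_cascade,
)

from conftest import brute_force_triads, random_kb


def _cfg(**kwargs) -> ScreenConfig:
    defaults = dict(pd_gene_set=frozenset({"LRRK2", "ATP13A2"}),
                    excluded_disease_labels=frozenset({"Alzheimer disease"}))
    defaults.update(kwargs)
    return ScreenConfig(**defaults)


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def test_strong_validation_keeps_reporter_assay_drops_microarray():
    records = [
        MirnaRecord("m1", frozenset({"reporter-assay"}), True),
        MirnaRecord("m2", frozenset({"microarray"}), True),
        MirnaRecord("m3", frozenset({"reporter-assay"}), False),  # not disease-linked
    ]
    assert filter_strong_validation(records, _cfg()) == {"m1"}


def test_empty_strong_whitelist_is_a_configuration_error():
    with pytest.raises(KnowledgeBaseError):
        filter_strong_validation(
            [MirnaRecord("m1", frozenset({"qPCR"}), True)],
            _cfg(strong_evidence_methods=frozenset()),
        )


def test_score_gate_is_strict_at_the_boundary():
    interactions = [
        MirnaLncrnaInteraction("m1", "L1", 0.79),
        MirnaLncrnaInteraction("m1", "L2", 0.69),
        MirnaLncrnaInteraction("m1", "L3", 0.70),  # boundary fails
    ]
    mapping = mirna_to_lncrna({"m1"}, interactions, _cfg())
    assert mapping == {"L1": frozenset({"m1"})}


def test_empty_mirna_set_gives_empty_mapping():
    assert mirna_to_lncrna(set(), [MirnaLncrnaInteraction("m", "L", 0.9)],
                           _cfg()) == {}


def test_zero_threshold_retains_every_positive_interaction():
    # brute-force check that the mapping inverts the interaction list
    interactions = [
        MirnaLncrnaInteraction(f"m{i}", f"L{i % 3}", 0.1 * (i + 1))
        for i in range(9)
    ]
    cfg = _cfg(min_lncbase_score=0.0)
    mapping = mirna_to_lncrna({f"m{i}" for i in range(9)}, interactions, cfg)
    expected: dict[str, set[str]] = {}
    for inter in interactions:
        if inter.score > 0.0:
            expected.setdefault(inter.lncrna_id, set()).add(inter.mirna_id)
    assert {k: set(v) for k, v in mapping.items()} == expected


def test_tissue_filter_requires_superset():
    records = [
        TissueExpressionRecord("L1", frozenset({"blood", "brain"})),
        TissueExpressionRecord("L2", frozenset({"blood"})),
        TissueExpressionRecord("L3", frozenset({"brain", "liver"})),
    ]
    kept = filter_tissue({"L1", "L2", "L3", "L4"}, records, _cfg())
    assert kept == {"L1"}  # L4 has no record: expressed nowhere
    assert filter_tissue(set(), records, _cfg()) == frozenset()


def test_degree_and_known_filter():
    mapping = {"L1": frozenset({"m1"}), "L2": frozenset({"m1", "m2"}),
               "L3": frozenset({"m1", "m2", "m3"})}
    out = exclude_known_and_low_degree(mapping, {"L3"}, _cfg())
    assert set(out) == {"L2"}
    # min_degree 0 and no known set is the identity
    out = exclude_known_and_low_degree(mapping, set(), _cfg(min_mirna_degree=0))
    assert out == mapping


def test_gene_link_filter_boundary_and_membership():
    mapping = {"L1": frozenset({"m1"}), "L2": frozenset({"m2"}),
               "L3": frozenset({"m3"})}
    table = [
        MirnaGeneInteraction("m1", "LRRK2", 93.0),     # in panel, above gate
        MirnaGeneInteraction("m2", "OTHER", 99.0),     # not in panel
        MirnaGeneInteraction("m3", "ATP13A2", 80.0),   # boundary fails
    ]
    assert set(filter_pd_gene_link(mapping, table, _cfg())) == {"L1"}
    with pytest.raises(KnowledgeBaseError):
        filter_pd_gene_link(mapping, table, _cfg(pd_gene_set=frozenset()))


def test_gene_link_filter_matches_exhaustive_predicate(planted_kb):
    kb, manifest = planted_kb
    cfg = manifest.screen_config
    mapping = mirna_to_lncrna(
        filter_strong_validation(kb.mirnas, cfg), kb.mirna_lncrna, cfg
    )
    kept = set(filter_pd_gene_link(mapping, kb.mirna_gene, cfg))
    expected = {
        L for L, ms in mapping.items()
        if any(
            g.mirna_id in ms and g.gene_id in cfg.pd_gene_set
            and g.prediction_score > cfg.min_gene_prediction_score
            for g in kb.mirna_gene
        )
    }
    assert kept == expected


def test_specificity_filter():
    from triadscreen.knowledge_base import DiseaseAssociation

    mapping = {"L1": frozenset({"m"}), "L2": frozenset({"m"})}
    assocs = [DiseaseAssociation("L1", "Alzheimer disease")]
    assert set(filter_specificity(mapping, assocs, _cfg())) == {"L2"}
    none_excluded = _cfg(excluded_disease_labels=frozenset())
    assert filter_specificity(mapping, assocs, none_excluded) == mapping


def test_cis_pairing_strict_threshold_and_missing_locus():
    cfg = _cfg()
    mapping = {"Lnear": frozenset({"m"}), "Lfar": frozenset({"m"}),
               "Lnolocus": frozenset({"m"})}
    table = [MirnaGeneInteraction("m", "LRRK2", 90.0)]
    loci = [
        GeneLocus("Lnear", "chr1", 0, 1000),
        GeneLocus("Lfar", "chr1", 200_000, 201_000),
        GeneLocus("LRRK2", "chr1", 50_999, 60_000),  # gap to Lnear = 49,999
    ]
    triads, audit = pair_cis(mapping, loci, cfg, table)
    assert [(t.lncrna_id, t.gene_id) for t in triads] == [("Lnear", "LRRK2")]
    assert triads[0].cis_gap_bp == 49_999
    assert audit["Lnolocus"] == "no locus"
    assert audit["Lfar"] == "no cis partner"
    # gap exactly at the threshold is excluded
    loci[2] = GeneLocus("LRRK2", "chr1", 51_000, 60_000)  # gap = 50,000
    triads, audit = pair_cis(mapping, loci, cfg, table)
    assert triads == []


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def test_empty_knowledge_base_yields_all_zero_counts():
    from triadscreen.knowledge_base import KnowledgeBase

    result = run_cascade(KnowledgeBase(), _cfg())
    assert all(count == 0 for count in result.stage_counts.values())
    assert result.triads == []


def test_planted_triads_recovered_and_decoys_eliminated_at_design_stage(planted_kb):
    kb, manifest = planted_kb
    result = run_cascade(kb, manifest.screen_config)
    found = {(t.lncrna_id, t.mirna_id, t.gene_id) for t in result.triads}
    assert found == set(manifest.planted_triads)
    for entity, stage in manifest.decoy_stages.items():
        assert result.eliminated[entity][0] == stage, entity


def test_cascade_equals_bruteforce_on_random_knowledge_bases():
    for seed in range(30):
        kb, manifest = random_kb(seed)
        cfg = manifest.screen_config
        result = run_cascade(kb, cfg)
        found = {(t.lncrna_id, t.mirna_id, t.gene_id) for t in result.triads}
        assert found == brute_force_triads(kb, cfg), f"seed {seed}"


def test_audit_completeness_at_every_stage(planted_kb):
    kb, manifest = planted_kb
    result = run_cascade(kb, manifest.screen_config)
    eliminated_at = {}
    for entity, (stage, _) in result.eliminated.items():
        eliminated_at.setdefault(stage, set()).add(entity)
    # miRNA track
    all_mirnas = {r.mirna_id for r in kb.mirnas}
    assert result.survivors["strong_validation"] | eliminated_at.get(
        "strong_validation", set()) == all_mirnas
    # lncRNA track: at each stage, survivors + eliminated == previous survivors
    all_lncrnas = {i.lncrna_id for i in kb.mirna_lncrna}
    prev = all_lncrnas
    for stage in STAGES[1:]:
        survivors = set(result.survivors[stage])
        gone = eliminated_at.get(stage, set())
        assert survivors | gone == prev and not survivors & gone, stage
        prev = survivors


def test_lncrna_counts_non_increasing(planted_kb):
    kb, manifest = planted_kb
    result = run_cascade(kb, manifest.screen_config)
    counts = [result.stage_counts[s] for s in STAGES[1:]]
    assert counts == sorted(counts, reverse=True)


def test_relaxing_any_threshold_never_shrinks_the_triad_set():
    kb, manifest = random_kb(99)
    cfg = manifest.screen_config
    base = {(t.lncrna_id, t.mirna_id, t.gene_id)
            for t in run_cascade(kb, cfg).triads}
    relaxations = [
        dict(min_lncbase_score=max(0.0, cfg.min_lncbase_score - 0.3)),
        dict(min_gene_prediction_score=cfg.min_gene_prediction_score - 30),
        dict(min_mirna_degree=max(0, cfg.min_mirna_degree - 1)),
        dict(max_cis_gap_bp=cfg.max_cis_gap_bp * 4),
        dict(excluded_disease_labels=frozenset()),
    ]
    for change in relaxations:
        relaxed = ScreenConfig(
            **{**_as_dict(cfg), **change}
        )
        bigger = {(t.lncrna_id, t.mirna_id, t.gene_id)
                  for t in run_cascade(kb, relaxed).triads}
        assert base <= bigger, change


def _as_dict(cfg: ScreenConfig) -> dict:
    import dataclasses

    return dataclasses.asdict(cfg)


def test_commuting_filters_are_order_insensitive():
    """Tissue, specificity and known-disease removal commute; any order
    gives the same survivor set."""
    kb, manifest = random_kb(7)
    cfg = manifest.screen_config
    strong = filter_strong_validation(kb.mirnas, cfg)
    mapping = mirna_to_lncrna(strong, kb.mirna_lncrna, cfg)
    known_pd = frozenset(
        a.entity_id for a in kb.diseases
        if a.disease == cfg.pd_disease_label
    )

    def by_tissue(m):
        kept = filter_tissue(frozenset(m), kb.tissues, cfg)
        return {k: v for k, v in m.items() if k in kept}

    def by_known(m):
        return {k: v for k, v in m.items() if k not in known_pd}

    def by_specificity(m):
        return filter_specificity(m, kb.diseases, cfg)

    outcomes = set()
    for order in itertools.permutations([by_tissue, by_known, by_specificity]):
        m = dict(mapping)
        for f in order:
            m = f(m)
        outcomes.add(frozenset(m))
    assert len(outcomes) == 1


def test_demo_fixture_reproduces_the_published_triads(demo_kb, demo_config):
    result = run_cascade(demo_kb, demo_config)
    found = {(t.lncrna_id, t.mirna_id, t.gene_id) for t in result.triads}
    assert found == {
        ("linc01128", "hsa-miR-24-3p", "ATP13A2"),
        ("linc00938", "hsa-miR-30c-5p", "LRRK2"),
    }
    by_pair = {(t.mirna_id, t.gene_id): t for t in result.triads}
    assert by_pair[("hsa-miR-30c-5p", "LRRK2")].lncbase_score == 0.79
    assert by_pair[("hsa-miR-30c-5p", "LRRK2")].gene_prediction_score == 93.0
    assert by_pair[("hsa-miR-24-3p", "ATP13A2")].gene_prediction_score == 88.0


def test_cascade_is_deterministic(planted_kb):
    kb, manifest = planted_kb
    a = run_cascade(kb, manifest.screen_config)
    b = run_cascade(kb, manifest.screen_config)
    assert a.triads == b.triads
    assert a.stage_counts == b.stage_counts
    assert a.eliminated == b.eliminated
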