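import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triadscreen.qpcr import (
    QpcrConfig,
    collapse_replicates,
    compare_groups,
    hodges_lehmann,
    marker_report,
    relative_expression,
    roc_analysis,
    select_test,
)
from triadscreen.simulate import SynthConfig, generate_ct_dataset


# ---------------------------------------------------------------------------
# replicate collapsing
# ---------------------------------------------------------------------------

def _long(sample, gene, cts):
    return pd.DataFrame(
        [{"sample_id": sample, "gene_id": gene, "replicate": i + 1, "ct": c}
         for i, c in enumerate(cts)]
    )


def test_triplicate_mean_unflagged_below_sd_threshold():
    out = collapse_replicates(_long("s1", "g", [24.0, 24.2, 24.4]), 0.5)
    assert out.loc[0, "mean_ct"] == pytest.approx(24.2)
    assert not out.loc[0, "qc_flag"]


def test_discordant_duplicate_is_flagged_not_dropped():
    out = collapse_replicates(_long("s1", "g", [24.0, 26.0]), 0.5)
    assert out.loc[0, "mean_ct"] == pytest.approx(25.0)
    assert out.loc[0, "qc_flag"]


def test_single_replicate_has_undefined_sd_and_no_flag():
    out = collapse_replicates(_long("s1", "g", [30.0]), 0.5)
    assert out.loc[0, "mean_ct"] == 30.0
    assert math.isnan(out.loc[0, "replicate_sd"])
    assert not out.loc[0, "qc_flag"]


def test_no_measurements_is_an_error():
    with pytest.raises(ValueError):
        collapse_replicates(pd.DataFrame(columns=["sample_id", "gene_id", "ct"]))


def test_ct_outside_detection_range_rejected():
    with pytest.raises(ValueError, match="Ct out of"):
        collapse_replicates(_long("s1", "g", [46.0]))


# ---------------------------------------------------------------------------
# comparative-CT arithmetic
# ---------------------------------------------------------------------------

def _ct_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "mean_ct"])


def test_delta_delta_ct_forced_arithmetic():
    # baseline sample: target 23, refs 20/22 → ΔCt 2; test sample ΔCt 3
    ct = _ct_table([
        ("base", "GAPDH", 20.0), ("base", "18S", 22.0), ("base", "tgt", 23.0),
        ("case", "GAPDH", 20.0), ("case", "18S", 22.0), ("case", "tgt", 24.0),
    ])
    meta = pd.DataFrame({"sample_id": ["base", "case"],
                         "group": ["control", "PD"]})
    rel = relative_expression(ct, meta, {"tgt": ("GAPDH", "18S")})
    by_sample = rel.set_index("sample_id")
    assert by_sample.loc["case", "delta_ct"] == pytest.approx(3.0)
    assert by_sample.loc["case", "delta_delta_ct"] == pytest.approx(1.0)
    assert by_sample.loc["case", "rq"] == pytest.approx(0.5)
    assert by_sample.loc["base", "rq"] == pytest.approx(1.0)  # ΔΔCt 0 → rq 1


def test_missing_reference_gene_names_the_marker():
    ct = _ct_table([("s", "tgt", 24.0)])
    meta = pd.DataFrame({"sample_id": ["s"], "group": ["control"]})
    with pytest.raises(ValueError, match="tgt"):
        relative_expression(ct, meta, {"tgt": ("U6",)})


def test_baseline_geometric_mean_rq_is_one():
    """By the ΔΔCt construction the baseline group's rq values have
    geometric mean exactly 1."""
    ct, meta, _ = generate_ct_dataset(SynthConfig(seed=4))
    rel = relative_expression(collapse_replicates(ct), meta)
    controls = set(meta.loc[meta["group"] == "control", "sample_id"])
    for _, sub in rel.groupby("gene_id"):
        rq = sub.loc[sub["sample_id"].isin(controls), "rq"]
        assert np.log2(rq).mean() == pytest.approx(0.0, abs=1e-10)


def test_zero_noise_planted_shift_reproduced_exactly():
    cfg = SynthConfig(seed=0, biological_sd=0.0, technical_sd=0.0,
                      marker_shifts={"linc01128": -1.0})
    ct, meta, _ = generate_ct_dataset(cfg)
    rel = relative_expression(collapse_replicates(ct), meta,
                              {"linc01128": ("GAPDH", "18S")})
    pd_samples = set(meta.loc[meta["group"] == "PD", "sample_id"])
    rq = rel.set_index("sample_id")["rq"]
    for sid in pd_samples:
        assert rq[sid] == pytest.approx(2.0, abs=1e-9)


# ---------------------------------------------------------------------------
# adaptive test selection
# ---------------------------------------------------------------------------

def test_gaussian_groups_route_parametric_and_match_the_gate_oracle():
    rng = np.random.default_rng(42)
    a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
    # independent oracle: run the normality gate directly
    assert stats.normaltest(a).pvalue >= 0.05
    assert stats.normaltest(b).pvalue >= 0.05
    assert select_test([a, b]) == "unpaired t"
    assert select_test([a, b, rng.normal(0, 1, 20)]) == "ordinary one-way ANOVA"


def test_heavy_tailed_groups_route_nonparametric():
    rng = np.random.default_rng(3)
    a, b = rng.lognormal(0, 1.5, 20), rng.lognormal(0, 1.5, 20)
    assert min(stats.normaltest(a).pvalue, stats.normaltest(b).pvalue) < 0.05
    assert select_test([a, b]) == "Mann–Whitney"
    assert select_test([a, b, rng.lognormal(0, 1.5, 20)]) == "Kruskal–Wallis"


def test_small_groups_never_trust_the_normality_statistic():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
    assert select_test([a, b], min_n_for_normality=8) == "Mann–Whitney"


def test_group_below_three_values_is_an_error():
    with pytest.raises(ValueError):
        select_test([[1.0, 2.0], [1.0, 2.0, 3.0]])


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def test_identical_groups_give_null_effect_and_large_p():
    vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    (res,) = compare_groups({"a": vals, "b": vals.copy()})
    assert res.effect == pytest.approx(0.0)
    assert res.p_value > 0.9
    assert not res.significant


def test_fully_separated_groups_exact_rank_p_value():
    # U = 0; exact two-sided p = 2 / C(10,5) = 2/252
    (res,) = compare_groups(
        {"a": np.arange(1.0, 6.0), "b": np.arange(6.0, 11.0)}
    )
    assert res.test_name == "Mann–Whitney"
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(2 / 252)
    assert res.significant


def test_three_group_parametric_returns_omnibus_plus_tukey():
    rng = np.random.default_rng(8)
    groups = {
        "Controls": rng.normal(0, 1, 20),
        "Early": rng.normal(1, 1, 27),
        "Late": rng.normal(1, 1, 11),
    }
    results = compare_groups(groups)
    assert results[0].test_name == "ordinary one-way ANOVA"
    assert [r.comparison for r in results[1:]] == [
        "Controls vs. Early", "Controls vs. Late", "Early vs. Late"
    ]
    for r in results[1:]:
        assert r.test_name == "Tukey post hoc"
        assert r.ci_low <= r.effect <= r.ci_high
        assert r.significant == (r.p_value < 0.05)


def test_three_group_nonparametric_returns_dunn_mean_rank_differences():
    rng = np.random.default_rng(12)
    groups = {
        "Controls": rng.lognormal(0, 1.2, 20),
        "Early": rng.lognormal(0.8, 1.2, 27),
        "Late": rng.lognormal(0.8, 1.2, 11),
    }
    results = compare_groups(groups)
    assert results[0].test_name == "Kruskal–Wallis"
    dunn = results[1:]
    assert all(r.test_name == "Dunn post hoc" for r in dunn)
    # effect is the mean-rank difference (second − first); recompute directly
    pooled = np.concatenate(list(groups.values()))
    ranks = stats.rankdata(pooled)
    mean_ranks, offset = {}, 0
    for label, vals in groups.items():
        mean_ranks[label] = ranks[offset:offset + len(vals)].mean()
        offset += len(vals)
    by_pair = {r.comparison: r.effect for r in dunn}
    assert by_pair["Controls vs. Early"] == pytest.approx(
        mean_ranks["Early"] - mean_ranks["Controls"]
    )


def test_hodges_lehmann_recovers_a_pure_shift():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 40)
    est, lo, hi = hodges_lehmann(x, x + 2.5)
    assert est == pytest.approx(2.5, abs=1e-9)
    assert lo <= est <= hi


def test_effect_sign_convention_is_second_minus_first():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    b = a + 10
    (res,) = compare_groups({"a": a, "b": b})
    assert res.effect > 0
    (res,) = compare_groups({"b": b, "a": a})
    assert res.effect < 0


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def test_roc_perfect_separation():
    r = roc_analysis(np.array([1, 2, 3, 10, 11, 12.0]),
                     np.array([0, 0, 0, 1, 1, 1], dtype=bool))
    assert r.auc == 1.0
    assert not r.flipped


def test_roc_all_tied_values():
    r = roc_analysis(np.ones(10), np.array([0, 1] * 5, dtype=bool))
    assert r.auc == 0.5


def test_roc_small_example_concordant_pairs():
    # cases {3,5}, controls {1,4}: 3 of 4 pairs concordant
    r = roc_analysis(np.array([1.0, 4.0, 3.0, 5.0]),
                     np.array([0, 0, 1, 1], dtype=bool))
    assert r.auc == pytest.approx(0.75)


def test_roc_flips_inverted_markers_to_auc_above_half():
    rng = np.random.default_rng(2)
    controls = rng.normal(1.0, 0.5, 30)
    cases = rng.normal(0.0, 0.5, 30)
    r = roc_analysis(np.concatenate([controls, cases]),
                     np.repeat([False, True], 30))
    assert r.flipped
    assert r.auc >= 0.5


def test_roc_single_class_is_an_error():
    with pytest.raises(ValueError):
        roc_analysis(np.arange(5.0), np.ones(5, dtype=bool))


def test_roc_curve_endpoints_and_monotonicity():
    rng = np.random.default_rng(7)
    vals = rng.normal(0, 1, 50)
    labels = rng.random(50) < 0.4
    r = roc_analysis(vals, labels)
    assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
    assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
    assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)


def test_auc_equals_u_statistic_on_tie_free_data():
    rng = np.random.default_rng(31)
    for _ in range(25):
        n1, n2 = rng.integers(5, 40, 2)
        cases = rng.normal(0.6, 1, n1)
        controls = rng.normal(0, 1, n2)
        u = stats.mannwhitneyu(cases, controls, alternative="two-sided").statistic
        auc_from_u = u / (n1 * n2)
        r = roc_analysis(np.concatenate([controls, cases]),
                         np.repeat([False, True], [n2, n1]))
        expected = max(auc_from_u, 1 - auc_from_u)  # after orientation
        assert abs(r.auc - expected) < 1e-12


def test_auc_invariant_under_strictly_monotone_transform():
    rng = np.random.default_rng(9)
    vals = rng.normal(2, 1, 60)
    labels = rng.random(60) < 0.5
    base = roc_analysis(vals, labels).auc
    for transform in (np.exp, lambda v: v**3, lambda v: 5 * v - 1):
        assert roc_analysis(transform(vals), labels).auc == pytest.approx(base)


# ---------------------------------------------------------------------------
# marker report
# ---------------------------------------------------------------------------

def test_marker_report_recovers_planted_directions():
    ct, meta, manifest = generate_ct_dataset(SynthConfig(seed=20))
    rel = relative_expression(collapse_replicates(ct), meta)
    report = marker_report(rel, meta)
    assert set(report) == set(manifest.marker_shifts)
    for marker, shift in manifest.marker_shifts.items():
        expected = "down" if shift > 0 else "up"
        assert report[marker]["direction"] == expected, marker
        assert report[marker]["roc"].auc >= 0.5
        head = report[marker]["comparisons"][0]
        assert head.comparison == "Controls vs. PD"
    # three-group block is present with the omnibus + three post hocs
    comps = report["LRRK2"]["comparisons"]
    assert len(comps) == 1 + 4


def test_marker_report_empty_input_gives_empty_report():
    rel = pd.DataFrame(columns=["sample_id", "gene_id", "rq"])
    meta = pd.DataFrame(columns=["sample_id", "group", "stage_class"])
    assert marker_report(rel, meta) == {}


def test_bh_correction_only_raises_p_values():
    ct, meta, _ = generate_ct_dataset(SynthConfig(seed=21))
    rel = relative_expression(collapse_replicates(ct), meta)
    raw = marker_report(rel, meta)
    adj = marker_report(rel, meta, QpcrConfig(bh_correct=True))
    for marker in raw:
        assert adj[marker]["comparisons"][0].p_value >= \
            raw[marker]["comparisons"][0].p_value - 1e-12
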