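"""Comparative-CT relative quantification and adaptive group statistics.

Quantification follows the ΔΔCt convention: for each sample,
``ΔCt = Ct_target − mean(Ct of the marker's reference genes)``;
``ΔΔCt = ΔCt − mean ΔCt over the baseline group``; the relative quantity is
``rq = 2^−ΔΔCt``.  miRNA markers normalize to U6, mRNA/lncRNA markers to
GAPDH + 18S by default (configurable per marker).

Group comparison mimics GraphPad-style adaptive testing: a
D'Agostino–Pearson normality gate routes each marker to the parametric
branch (unpaired t for two groups, ordinary one-way ANOVA with Tukey post
hoc for three or more) or the nonparametric branch (Mann–Whitney;
Kruskal–Wallis with Dunn's mean-rank post hoc).  ROC analysis evaluates
each marker as a case/control classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "QpcrConfig",
    "GroupComparisonResult",
    "RocResult",
    "collapse_replicates",
    "relative_expression",
    "select_test",
    "compare_groups",
    "hodges_lehmann",
    "dunn_posthoc",
    "roc_analysis",
    "marker_report",
    "DEFAULT_REFERENCE_MAP",
]

# default marker → reference-gene map: small RNAs to the U6 snRNA, long
# transcripts to the GAPDH + 18S pair
DEFAULT_REFERENCE_MAP: dict[str, tuple[str, ...]] = {
    "hsa-miR-24-3p": ("U6",),
    "hsa-miR-30c-5p": ("U6",),
    "linc01128": ("GAPDH", "18S"),
    "linc00938": ("GAPDH", "18S"),
    "LRRK2": ("GAPDH", "18S"),
    "ATP13A2": ("GAPDH", "18S"),
}


@dataclass
class QpcrConfig:
    """Statistical and normalization settings.

    alpha: significance level for all group tests.
    alpha_normality: level of the D'Agostino–Pearson gate.
    min_n_for_normality: smallest group size at which the normality
        statistic is trusted; smaller groups go nonparametric.
    max_replicate_sd: technical-replicate SD (cycles) above which a
        (sample, gene) mean Ct is QC-flagged (never dropped).
    reference_map: marker id → tuple of reference gene ids.
    bh_correct: apply Benjamini–Hochberg across markers in marker_report.
    """

    alpha: float = 0.05
    alpha_normality: float = 0.05
    min_n_for_normality: int = 8
    max_replicate_sd: float = 0.5
    reference_map: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_MAP)
    )
    baseline_group: str = "control"
    bh_correct: bool = False


@dataclass
class GroupComparisonResult:
    marker_id: str
    comparison: str
    test_name: str
    statistic: float
    p_value: float
    effect: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    significant: bool = False


@dataclass
class RocResult:
    marker_id: str
    auc: float
    flipped: bool
    fpr: np.ndarray
    tpr: np.ndarray


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def collapse_replicates(ct_long: pd.DataFrame,
                        max_replicate_sd: float = 0.5) -> pd.DataFrame:
    """Average technical replicates to one Ct per (sample, gene).

    Expects long-format columns ``sample_id, gene_id, ct`` (a ``replicate``
    column is allowed and ignored).  Returns columns ``sample_id, gene_id,
    mean_ct, replicate_sd, n_replicates, qc_flag``; the SD of a single
    replicate is NaN and unflagged.
    """
    if ct_long.empty:
        raise ValueError("no Ct measurements supplied")
    bad = ct_long[(ct_long["ct"] <= 0) | (ct_long["ct"] > 45)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"Ct out of (0, 45] for sample {row['sample_id']} gene {row['gene_id']}"
        )
    grouped = ct_long.groupby(["sample_id", "gene_id"], sort=True)["ct"]
    out = grouped.agg(mean_ct="mean", replicate_sd="std", n_replicates="size")
    out = out.reset_index()
    out["qc_flag"] = (out["replicate_sd"] > max_replicate_sd).fillna(False)
    return out


def relative_expression(
    ct_table: pd.DataFrame,
    sample_meta: pd.DataFrame,
    reference_map: Mapping[str, Sequence[str]] | Sequence[str] | None = None,
    baseline_group: str = "control",
) -> pd.DataFrame:
    """Comparative-CT quantification of every non-reference gene.

    ``ct_table`` holds one mean Ct per (sample, gene) — the output of
    :func:`collapse_replicates` or an equivalent frame with columns
    ``sample_id, gene_id, mean_ct``.  ``sample_meta`` must map sample_id to
    ``group``; baseline ΔCt means are taken over ``baseline_group``.

    Returns columns ``sample_id, gene_id, delta_ct, delta_delta_ct, rq,
    reference_genes``.  By construction the geometric mean of rq over the
    baseline group is exactly 1 for every marker.
    """
    if reference_map is None:
        reference_map = DEFAULT_REFERENCE_MAP
    ct = ct_table.pivot(index="sample_id", columns="gene_id", values="mean_ct")
    meta = sample_meta.set_index("sample_id")
    missing_meta = set(ct.index) - set(meta.index)
    if missing_meta:
        raise ValueError(f"samples without metadata: {sorted(missing_meta)}")
    group = meta.loc[ct.index, "group"]
    if not (group == baseline_group).any():
        raise ValueError(f"baseline group {baseline_group!r} has no samples")

    all_refs: set[str] = set()
    if isinstance(reference_map, Mapping):
        for refs in reference_map.values():
            all_refs.update(refs)
        markers = [g for g in ct.columns if g in reference_map]
    else:
        all_refs = set(reference_map)
        markers = [g for g in ct.columns if g not in all_refs]

    rows = []
    for gene in markers:
        refs = (
            tuple(reference_map[gene])
            if isinstance(reference_map, Mapping)
            else tuple(sorted(all_refs))
        )
        missing_refs = [r for r in refs if r not in ct.columns]
        if missing_refs:
            raise ValueError(
                f"reference gene(s) {missing_refs} absent for marker {gene}"
            )
        ref_ct = ct[list(refs)]
        samples_missing = ct.index[ref_ct.isna().all(axis=1)]
        if len(samples_missing):
            raise ValueError(
                f"sample {samples_missing[0]} is missing all reference genes"
            )
        delta_ct = ct[gene] - ref_ct.mean(axis=1)
        baseline_mean = delta_ct[group == baseline_group].mean()
        ddct = delta_ct - baseline_mean
        rq = np.exp2(-ddct)
        for sample_id in ct.index:
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene_id": gene,
                    "delta_ct": delta_ct[sample_id],
                    "delta_delta_ct": ddct[sample_id],
                    "rq": rq[sample_id],
                    "reference_genes": ",".join(refs),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# adaptive testing
# ---------------------------------------------------------------------------

def _all_groups_normal(groups: Sequence[np.ndarray], alpha: float,
                       min_n: int) -> bool:
    for g in groups:
        if len(g) < min_n:
            return False
        if np.ptp(g) == 0:  # degenerate: constant group, gate cannot pass
            return False
        if stats.normaltest(g).pvalue < alpha:
            return False
    return True


def select_test(groups: Sequence[np.ndarray], alpha_normality: float = 0.05,
                min_n_for_normality: int = 8) -> str:
    """Route to the parametric or nonparametric branch.

    Parametric only when every group has at least ``min_n_for_normality``
    observations and passes the D'Agostino–Pearson omnibus test at
    ``alpha_normality``.  Pure function of its inputs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 3:
            raise ValueError("each group needs at least 3 values")
    normal = _all_groups_normal(groups, alpha_normality, min_n_for_normality)
    if len(groups) == 2:
        return "unpaired t" if normal else "Mann–Whitney"
    return "ordinary one-way ANOVA" if normal else "Kruskal–Wallis"


def hodges_lehmann(x: np.ndarray, y: np.ndarray,
                   confidence: float = 0.95) -> tuple[float, float, float]:
    """Hodges–Lehmann shift estimate (median of y−x pairwise differences)
    with the distribution-free CI from the Mann–Whitney normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    diffs = np.sort((y[:, None] - x[None, :]).ravel())
    est = float(np.median(diffs))
    n1, n2 = len(x), len(y)
    n_pairs = n1 * n2
    z = stats.norm.ppf(0.5 + confidence / 2)
    c = n_pairs / 2 - z * math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    k = max(0, int(math.floor(c)))
    lo = float(diffs[k]) if k < n_pairs else float(diffs[0])
    hi = float(diffs[n_pairs - 1 - k]) if k < n_pairs else float(diffs[-1])
    return est, lo, hi


def dunn_posthoc(groups: Mapping[str, np.ndarray]) -> list[dict]:
    """Dunn's rank-based multiple comparisons after Kruskal–Wallis.

    Pools all observations, ranks with midranks for ties, and compares mean
    ranks pairwise with the tie-corrected z statistic; p-values carry a
    Bonferroni family correction over the number of comparisons.
    """
    labels = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in labels]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    offset = 0
    for label, vals in zip(labels, values):
        n = len(vals)
        mean_ranks[label] = float(ranks[offset:offset + n].mean())
        sizes[label] = n
        offset += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            diff = mean_ranks[a] - mean_ranks[b]
            se = math.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1)))
                * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            z = diff / se if se > 0 else 0.0
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
            out.append(
                {"pair": (a, b), "mean_rank_diff": diff, "z": z, "p_value": p}
            )
    return out


def compare_groups(values_by_group: Mapping[str, np.ndarray],
                   config: QpcrConfig | None = None,
                   marker_id: str = "") -> list[GroupComparisonResult]:
    """Adaptive comparison of two or more groups.

    Two groups yield a single result; three or more yield the omnibus test
    followed by all pairwise post-hoc results (Tukey after ANOVA; Dunn
    after Kruskal–Wallis).  The effect is always
    ``second group − first group`` of the comparison label: mean difference
    with a 95% CI on the parametric branch, the Hodges–Lehmann median
    difference with a distribution-free CI for Mann–Whitney, and the mean
    rank difference (no CI) for Dunn.
    """
    config = config or QpcrConfig()
    labels = list(values_by_group)
    groups = [np.asarray(values_by_group[k], dtype=float) for k in labels]
    test = select_test(groups, config.alpha_normality, config.min_n_for_normality)
    alpha = config.alpha
    results: list[GroupComparisonResult] = []

    if len(groups) == 2:
        a_label, b_label = labels
        a, b = groups
        comparison = f"{a_label} vs. {b_label}"
        if test == "unpaired t":
            res = stats.ttest_ind(b, a)
            ci = res.confidence_interval(0.95)
            effect = float(b.mean() - a.mean())
            results.append(GroupComparisonResult(
                marker_id, comparison, "unpaired t", float(res.statistic),
                float(res.pvalue), effect, float(ci.low), float(ci.high),
            ))
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            est, lo, hi = hodges_lehmann(a, b)
            results.append(GroupComparisonResult(
                marker_id, comparison, "Mann–Whitney", float(res.statistic),
                float(res.pvalue), est, lo, hi,
            ))
    else:
        if test == "ordinary one-way ANOVA":
            omnibus = stats.f_oneway(*groups)
            results.append(GroupComparisonResult(
                marker_id, " vs. ".join(labels), "ordinary one-way ANOVA",
                float(omnibus.statistic), float(omnibus.pvalue), math.nan,
            ))
            tukey = stats.tukey_hsd(*groups)
            ci = tukey.confidence_interval(0.95)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    # tukey statistic[i, j] = mean_i − mean_j; we report j − i
                    results.append(GroupComparisonResult(
                        marker_id, f"{labels[i]} vs. {labels[j]}",
                        "Tukey post hoc", float(-tukey.statistic[i, j]),
                        float(tukey.pvalue[i, j]),
                        float(groups[j].mean() - groups[i].mean()),
                        float(-ci.high[i, j]), float(-ci.low[i, j]),
                    ))
        else:
            omnibus = stats.kruskal(*groups)
            results.append(GroupComparisonResult(
                marker_id, " vs. ".join(labels), "Kruskal–Wallis",
                float(omnibus.statistic), float(omnibus.pvalue), math.nan,
            ))
            for row in dunn_posthoc(dict(zip(labels, groups))):
                a_label, b_label = row["pair"]
                results.append(GroupComparisonResult(
                    marker_id, f"{a_label} vs. {b_label}", "Dunn post hoc",
                    float(row["z"]), float(row["p_value"]),
                    float(-row["mean_rank_diff"]),  # second − first
                ))
    for r in results:
        r.significant = bool(r.p_value < alpha) if not math.isnan(r.p_value) else False
    return results


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_analysis(values: np.ndarray, case_labels: np.ndarray,
                 marker_id: str = "") -> RocResult:
    """Rank/trapezoid ROC with ties counted half.

    If the raw AUC is below 0.5 the scores are negated (``flipped=True``)
    so that the reported AUC is always >= 0.5, mirroring how biomarkers with
    either effect direction are evaluated.
    """
    values = np.asarray(values, dtype=float)
    case_labels = np.asarray(case_labels, dtype=bool)
    if case_labels.all() or (~case_labels).all():
        raise ValueError("ROC needs both classes present")

    def _auc_rank(v: np.ndarray) -> float:
        # Mann–Whitney identity: AUC = U / (n1 * n2), midranks halve ties
        ranks = stats.rankdata(v)
        n_case = int(case_labels.sum())
        n_ctrl = len(v) - n_case
        u = ranks[case_labels].sum() - n_case * (n_case + 1) / 2.0
        return float(u / (n_case * n_ctrl))

    auc = _auc_rank(values)
    flipped = auc < 0.5
    if flipped:
        values = -values
        auc = _auc_rank(values)
    fpr, tpr, _ = _sk_roc_curve(case_labels.astype(int), values)
    return RocResult(marker_id=marker_id, auc=auc, flipped=flipped,
                     fpr=fpr, tpr=tpr)


# ---------------------------------------------------------------------------
# assembled per-marker report
# ---------------------------------------------------------------------------

def _sem(v: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    return float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else math.nan


def marker_report(rel_expr: pd.DataFrame, sample_meta: pd.DataFrame,
                  config: QpcrConfig | None = None) -> dict:
    """Full per-marker analysis: group summaries (mean ± SEM), the four
    standard comparisons (control vs PD; control/early/late omnibus with all
    pairwise post hocs), ROC, and the up/down direction call in PD.

    Returns ``{marker: {"summaries": ..., "comparisons": [...],
    "roc": RocResult, "direction": "up"|"down"}}``.  With ``bh_correct``
    the control-vs-PD p-values get a Benjamini–Hochberg adjustment across
    markers (off by default).
    """
    config = config or QpcrConfig()
    meta = sample_meta.set_index("sample_id")
    report: dict[str, dict] = {}
    for marker, sub in rel_expr.groupby("gene_id", sort=True):
        sub = sub.set_index("sample_id")
        rq = sub["rq"]
        grp = meta.loc[rq.index, "group"]
        stage_class = meta.loc[rq.index, "stage_class"]
        control = rq[grp == config.baseline_group].to_numpy()
        pd_all = rq[grp != config.baseline_group].to_numpy()
        early = rq[stage_class == "early"].to_numpy()
        late = rq[stage_class == "late"].to_numpy()

        summaries = {
            name: {"n": len(v), "mean": float(np.mean(v)) if len(v) else math.nan,
                   "sem": _sem(v)}
            for name, v in (("control", control), ("PD", pd_all),
                            ("early", early), ("late", late))
        }
        comparisons = compare_groups(
            {"Controls": control, "PD": pd_all}, config, marker_id=marker
        )
        if len(early) >= 3 and len(late) >= 3:
            comparisons += compare_groups(
                {"Controls": control, "Early": early, "Late": late},
                config, marker_id=marker,
            )
        roc = roc_analysis(
            rq.to_numpy(), (grp != config.baseline_group).to_numpy(), marker
        )
        direction = "up" if np.log2(pd_all).mean() > np.log2(control).mean() else "down"
        report[marker] = {
            "summaries": summaries,
            "comparisons": comparisons,
            "roc": roc,
            "direction": direction,
        }
    if config.bh_correct and report:
        markers = sorted(report)
        pvals = [report[m]["comparisons"][0].p_value for m in markers]
        adjusted = stats.false_discovery_control(pvals, method="bh")
        for m, p_adj in zip(markers, adjusted):
            head = report[m]["comparisons"][0]
            head.p_value = float(p_adj)
            head.significant = bool(p_adj < config.alpha)
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a marker_report into the tabular comparison layout."""
    rows = []
    for marker, entry in report.items():
        for comp in entry["comparisons"]:
            rows.append({
                "marker": marker,
                "comparison": comp.comparison,
                "test": comp.test_name,
                "statistic": comp.statistic,
                "effect": comp.effect,
                "ci_low": comp.ci_low,
                "ci_high": comp.ci_high,
                "p_value": comp.p_value,
                "significant": comp.significant,
            })
    return pd.DataFrame(rows)
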