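"""Canonical miRNA seed-site scanning, wild-type/mutant construct
verification, and dual-luciferase reporter analytics.

Seed matching uses the canonical site classes: with miRNA positions
numbered 5'→3', a target window Watson–Crick complementary to positions
2–7 is a 6mer; an additional match to position 8 upgrades it to 7mer-m8;
an adenosine in the target opposite position 1 (the 3' end of the site)
upgrades to 7mer-A1; both give the 8mer.  Sites are reported once, at
their maximal class, on 0-based half-open target coordinates.  A hook for
an external duplex-energy predictor is declared but not implemented.

The reporter side normalizes each well's insert-fused ("signal") luciferase
by its co-transfected control luciferase and compares condition means to a
reference (negative control), reporting percent inhibition and a
two-sample t-test per condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeedSite",
    "SITE_CLASS_ORDER",
    "find_seed_sites",
    "verify_mutant_disruption",
    "normalize_reporter",
    "compare_reporter_conditions",
    "reverse_complement",
]

SITE_CLASS_ORDER = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_CLASS_RANK = {c: i for i, c in enumerate(SITE_CLASS_ORDER)}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# declared extension point: an external thermodynamic duplex predictor may
# replace the canonical classes here; none is bundled
DuplexPredictor = Callable[[str, str], list["SeedSite"]]


@dataclass(frozen=True)
class SeedSite:
    """A canonical seed-match site on the target, 0-based half-open."""

    start: int
    end: int
    site_class: str
    mirna_id: str = ""

    @property
    def rank(self) -> int:
        return _CLASS_RANK[self.site_class]


def _normalize(seq: str, what: str) -> str:
    """Uppercase RNA alphabet; T is treated as U, case carries no meaning."""
    seq = seq.strip().upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters in {what}: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    seq = _normalize(seq, "sequence")
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def find_seed_sites(mirna_sequence: str, target_sequence: str,
                    mirna_id: str = "") -> list[SeedSite]:
    """All canonical seed sites of the miRNA on the target.

    Every window complementary to the seed (miRNA positions 2–7) is located,
    then upgraded by the m8 match and/or the position-1 adenosine; each
    window is reported once at its maximal class.  Overlapping sites are all
    reported.  DNA input is accepted (T == U); matching is case-insensitive.
    """
    mirna = _normalize(mirna_sequence, "miRNA sequence")
    target = _normalize(target_sequence, "target sequence")
    if len(mirna) < 8:
        raise ValueError("miRNA sequence shorter than 8 nt")
    core = reverse_complement(mirna[1:7])      # opposite miRNA positions 2–7
    m8_base = _COMPLEMENT[mirna[7]]            # target base opposite position 8

    sites: list[SeedSite] = []
    for c in range(len(target) - len(core) + 1):
        if target[c:c + 6] != core:
            continue
        has_m8 = c >= 1 and target[c - 1] == m8_base
        has_a1 = c + 6 < len(target) and target[c + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(c - 1, c + 7, "8mer", mirna_id))
        elif has_m8:
            sites.append(SeedSite(c - 1, c + 6, "7mer-m8", mirna_id))
        elif has_a1:
            sites.append(SeedSite(c, c + 7, "7mer-A1", mirna_id))
        else:
            sites.append(SeedSite(c, c + 6, "6mer", mirna_id))
    return sites


@dataclass
class DisruptionVerdict:
    disrupted: bool
    wt_sites: list[SeedSite]
    mt_sites: list[SeedSite]
    surviving_sites: list[SeedSite]


def verify_mutant_disruption(wt_sequence: str, mt_sequence: str,
                             mirna_sequence: str,
                             min_class: str = "7mer-m8") -> DisruptionVerdict:
    """Check that mutagenesis removed the binding site.

    True iff the wild type carries at least one site of class >= min_class
    and the mutant has no such site overlapping any wild-type site's
    coordinates.  Surviving sites are returned for diagnostics.  Indel
    mutants (different lengths) are allowed; coordinates are compared on
    each sequence's own frame.
    """
    if min_class not in _CLASS_RANK:
        raise ValueError(f"unknown site class {min_class!r}")
    threshold = _CLASS_RANK[min_class]
    wt_sites = [s for s in find_seed_sites(mirna_sequence, wt_sequence)
                if s.rank >= threshold]
    mt_all = find_seed_sites(mirna_sequence, mt_sequence)
    mt_sites = [s for s in mt_all if s.rank >= threshold]
    surviving = [
        m for m in mt_sites
        if any(m.start < w.end and w.start < m.end for w in wt_sites)
    ]
    disrupted = bool(wt_sites) and not surviving
    return DisruptionVerdict(disrupted, wt_sites, mt_all, surviving)


# ---------------------------------------------------------------------------
# dual-luciferase analytics
# ---------------------------------------------------------------------------

def normalize_reporter(wells: pd.DataFrame,
                       signal: str = "renilla") -> pd.DataFrame:
    """Per-well signal/control luciferase ratios with per-condition stats.

    ``wells`` needs columns ``condition, replicate, renilla, firefly``.  In
    the psiCHECK-2 design the insert is fused to Renilla, so the default
    signal channel is ``renilla`` and firefly normalizes transfection
    efficiency; pass ``signal="firefly"`` for the opposite convention.
    Blank wells are excluded from ratio computation.
    """
    if signal not in {"renilla", "firefly"}:
        raise ValueError("signal channel must be 'renilla' or 'firefly'")
    control = "firefly" if signal == "renilla" else "renilla"
    sub = wells[wells["condition"].str.lower() != "blank"].copy()
    nonpos = sub[(sub[control] <= 0) | (sub[signal] <= 0)]
    if len(nonpos):
        row = nonpos.iloc[0]
        raise ValueError(
            f"non-positive luminescence in well "
            f"({row['condition']}, replicate {row['replicate']})"
        )
    counts = sub.groupby("condition").size()
    low = counts[counts < 2]
    if len(low):
        raise ValueError(
            f"condition {low.index[0]!r} has fewer than 2 replicate wells"
        )
    sub["ratio"] = sub[signal] / sub[control]
    return sub[["condition", "replicate", "ratio"]].reset_index(drop=True)


def compare_reporter_conditions(normalized: pd.DataFrame,
                                reference_condition: str = "NC",
                                p_adjust: str | None = "bonferroni",
                                ) -> pd.DataFrame:
    """Percent activity change of each condition versus the reference.

    ``percent_change = 100 * (1 − mean ratio / mean reference ratio)``; a
    positive value is a decrease (inhibition).  Each condition is also
    compared to the reference with a two-sample t-test on the replicate
    ratios.  Because every construct is tested against the same reference
    wells, the reported p-values are Bonferroni-corrected across the tested
    conditions by default (``p_adjust=None`` reports raw p-values).
    Invariant to rescaling all wells by a common factor.
    """
    if p_adjust not in (None, "bonferroni"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    if reference_condition not in set(normalized["condition"]):
        raise ValueError(f"reference condition {reference_condition!r} missing")
    ref = normalized.loc[
        normalized["condition"] == reference_condition, "ratio"
    ].to_numpy()
    rows = []
    for condition, sub in normalized.groupby("condition", sort=True):
        vals = sub["ratio"].to_numpy()
        if condition == reference_condition:
            change, t_stat, p = 0.0, math.nan, math.nan
        else:
            change = 100.0 * (1.0 - vals.mean() / ref.mean())
            if np.ptp(vals) == 0 and np.ptp(ref) == 0 and vals.mean() == ref.mean():
                t_stat, p = 0.0, 1.0
            else:
                res = stats.ttest_ind(vals, ref)
                t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append({
            "condition": condition,
            "n": len(vals),
            "mean_ratio": float(vals.mean()),
            "sd_ratio": float(vals.std(ddof=1)) if len(vals) > 1 else math.nan,
            "percent_change": float(change),
            "t_statistic": t_stat,
            "p_value": p,
        })
    table = pd.DataFrame(rows)
    if p_adjust == "bonferroni":
        n_tests = int(table["p_value"].notna().sum())
        if n_tests > 1:
            table["p_value"] = (table["p_value"] * n_tests).clip(upper=1.0)
    return table
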