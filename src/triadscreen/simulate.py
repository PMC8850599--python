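"""Seeded generators for every input the pipeline consumes, with planted
ground truth.

Each generator is a pure function of its configuration (seed included) and
returns a :class:`GroundTruthManifest` describing exactly what was planted,
so recovery tests can close the loop: the screening cascade must find the
planted triads and eliminate each decoy at its designed stage; the qPCR
engine must recover the planted Ct shifts, effect directions and AUCs; the
reporter analytics must recover the planted inhibition; the seed scanner
must find the implanted site.

The default study design mirrors a case/control blood-biomarker study:
20 controls and 38 patients split into an early stage group of 27
(10 stage I + 17 stage II) and a late group of 11 (10 stage III + 1
stage IV); six markers with |ΔΔCt| = 0.5 cycles (three down-regulated,
three up-regulated in patients; a positive Ct shift means lower
expression).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
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
    write_knowledge_base,
)
from .reporter_seed import SITE_CLASS_ORDER, find_seed_sites, reverse_complement

__all__ = [
    "SynthConfig",
    "GroundTruthManifest",
    "generate_knowledge_base",
    "generate_ct_dataset",
    "generate_reporter_plate",
    "generate_sequences",
    "DEFAULT_MARKER_SHIFTS",
]

# positive shift (cycles) = later amplification = lower expression in patients
DEFAULT_MARKER_SHIFTS: dict[str, float] = {
    "linc01128": +0.5,
    "hsa-miR-24-3p": +0.5,
    "hsa-miR-30c-5p": +0.5,
    "linc00938": -0.5,
    "LRRK2": -0.5,
    "ATP13A2": -0.5,
}

# baseline cycle thresholds per gene (cycles); references first
_BASELINE_CT: dict[str, float] = {
    "U6": 20.0, "GAPDH": 18.0, "18S": 12.0,
    "linc01128": 28.0, "linc00938": 29.0,
    "hsa-miR-24-3p": 24.0, "hsa-miR-30c-5p": 25.0,
    "LRRK2": 26.0, "ATP13A2": 27.0,
}

_MARKER_REFS: dict[str, tuple[str, ...]] = {
    "linc01128": ("GAPDH", "18S"),
    "linc00938": ("GAPDH", "18S"),
    "LRRK2": ("GAPDH", "18S"),
    "ATP13A2": ("GAPDH", "18S"),
    "hsa-miR-24-3p": ("U6",),
    "hsa-miR-30c-5p": ("U6",),
}

# demographic targets per group: mean, SD (truncation bounds applied)
_AGE = {"control": (59.45, 8.15), "early": (65.11, 10.40), "late": (62.82, 12.59)}
_BMI = {"control": (27.57, 5.55), "early": (26.05, 4.60), "late": (25.38, 3.24)}
_DURATION = {"early": (43.85, 31.69), "late": (99.27, 77.04)}  # months, right-skewed
# males per stage group (control, I, II, III, IV) summing to 10 + 21
_MALES = {"control": 10, "I": 6, "II": 9, "III": 5, "IV": 1}
_STAGE_SIZES = {"I": 10, "II": 17, "III": 10, "IV": 1}
_UPDRS_RANGES = {"I": (0.0, 25.0), "II": (25.0, 50.0),
                 "III": (50.0, 75.0), "IV": (75.0, 100.0)}


@dataclass
class SynthConfig:
    """Knobs of every generator; the seed is mandatory for stochastic ones."""

    seed: int = 0
    # knowledge base
    n_planted_triads: int = 2
    include_decoys: bool = True
    n_random_lncrnas: int = 0
    n_random_mirnas: int = 0
    n_random_genes: int = 0
    # qPCR study design
    n_control: int = 20
    stage_sizes: dict[str, int] = field(default_factory=lambda: dict(_STAGE_SIZES))
    marker_shifts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_SHIFTS)
    )
    biological_sd: float = 0.5   # cycles, per-sample marker noise
    technical_sd: float = 0.1    # cycles, per-replicate noise (all genes)
    n_replicates: int = 3
    # reporter plate
    inhibition: dict[str, float] = field(
        default_factory=lambda: {"WT": 0.70, "MT": 0.0}
    )
    reporter_cv: float = 0.05
    n_wells: int = 6
    # sequences
    target_length: int = 140
    site_class: str = "8mer"
    mirna_length: int = 22

    def __post_init__(self) -> None:
        if self.n_planted_triads < 0:
            raise ValueError("n_planted_triads must be >= 0")
        if self.biological_sd < 0 or self.technical_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if any(n < 0 for n in self.stage_sizes.values()) or self.n_control < 0:
            raise ValueError("group sizes must be >= 0")
        for cond, f in self.inhibition.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"inhibition for {cond} outside [0, 1): {f}")
        if self.site_class not in SITE_CLASS_ORDER:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.target_length < 10:
            raise ValueError("target_length too short to hold a site")


@dataclass
class GroundTruthManifest:
    """What a generator planted; the key for every recovery test."""

    planted_triads: list[tuple[str, str, str]] = field(default_factory=list)
    decoy_stages: dict[str, str] = field(default_factory=dict)
    screen_config: ScreenConfig | None = None
    marker_shifts: dict[str, float] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)
    site_start: int | None = None
    site_end: int | None = None
    site_class: str | None = None
    mirna_sequence: str | None = None
    inhibition: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        cfg = payload.pop("screen_config")
        if cfg is not None:
            payload["screen_config"] = {
                k: sorted(v) if isinstance(v, (set, frozenset)) else v
                for k, v in cfg.items()
            }
        return json.dumps(payload, indent=2, default=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# knowledge base
# ---------------------------------------------------------------------------

_EXCLUDED_DISEASES = frozenset({"Alzheimer disease", "Huntington disease"})
_TISSUE_POOL = ("blood", "brain", "liver", "cortex", "muscle")


def generate_knowledge_base(
    config: SynthConfig, out_dir: str | Path | None = None
) -> tuple[KnowledgeBase, GroundTruthManifest]:
    """Synthetic seven-table knowledge base with planted triads and decoys.

    Each planted triad satisfies every cascade predicate; each decoy
    violates exactly its designated predicate and satisfies all others.
    Optional random background entities (sizes in the config) have fully
    random attributes and may or may not survive — they are the fodder for
    brute-force oracle-equivalence tests, not for exact-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    kb = KnowledgeBase()
    manifest = GroundTruthManifest()
    pd_genes: set[str] = set()

    def add_supported_lncrna(tag: str, *, scores=(None, None), tissues=("blood", "brain"),
                             gene_score: float | None = None, cis_gap: int | None = None,
                             diseases=(), n_mirnas: int = 2) -> tuple[str, str, str]:
        """One lncRNA with n strong miRNAs, a target gene, locus and
        annotations; keyword overrides introduce single-predicate defects."""
        lnc = f"LNC-{tag}"
        gene = f"GENE-{tag}"
        mirnas = [f"MIR-{tag}-{chr(ord('a') + i)}" for i in range(n_mirnas)]
        for m in mirnas:
            kb.mirnas.append(MirnaRecord(m, frozenset({"reporter-assay", "qPCR"}), True))
        for i, m in enumerate(mirnas):
            score = scores[i] if i < len(scores) and scores[i] is not None \
                else float(rng.uniform(0.75, 0.95))
            kb.mirna_lncrna.append(
                MirnaLncrnaInteraction(m, lnc, round(score, 3), "immunoprecipitation")
            )
        kb.tissues.append(TissueExpressionRecord(lnc, frozenset(tissues)))
        gscore = gene_score if gene_score is not None else float(rng.uniform(85, 99))
        kb.mirna_gene.append(MirnaGeneInteraction(mirnas[0], gene, round(gscore, 1)))
        pd_genes.add(gene)
        kb.lncrna_gene.append(
            LncrnaGeneInteraction(lnc, gene, int(rng.integers(1, 4)))
        )
        chrom = f"chr-{tag}"
        lnc_start = int(rng.integers(10_000, 50_000))
        lnc_end = lnc_start + int(rng.integers(1_000, 5_000))
        gap = cis_gap if cis_gap is not None else int(rng.integers(0, 49_000))
        kb.loci.append(GeneLocus(lnc, chrom, lnc_start, lnc_end))
        kb.loci.append(
            GeneLocus(gene, chrom, lnc_end + gap, lnc_end + gap + 2_000)
        )
        for d in diseases:
            kb.diseases.append(DiseaseAssociation(lnc, d, "database"))
        return lnc, mirnas[0], gene

    # planted triads: pass everything
    for i in range(config.n_planted_triads):
        lnc, mir, gene = add_supported_lncrna(f"planted{i}")
        manifest.planted_triads.append((lnc, mir, gene))

    if config.include_decoys:
        # stage A: a disease-flagged miRNA without strong evidence
        kb.mirnas.append(
            MirnaRecord("MIR-weak-evidence", frozenset({"microarray"}), True)
        )
        manifest.decoy_stages["MIR-weak-evidence"] = "strong_validation"
        # stage B: interaction scores at/below the gate
        lnc, _, _ = add_supported_lncrna("lowscore", scores=(0.5, 0.65))
        manifest.decoy_stages[lnc] = "lncrna_targets"
        # stage C: blood only
        lnc, _, _ = add_supported_lncrna("bloodonly", tissues=("blood",))
        manifest.decoy_stages[lnc] = "tissue"
        # stage D: already reported for the disease
        lnc, _, _ = add_supported_lncrna("knownpd", diseases=("Parkinson disease",))
        manifest.decoy_stages[lnc] = "degree_and_known"
        # stage D: sponges a single miRNA
        lnc, _, _ = add_supported_lncrna("lowdegree", n_mirnas=1)
        manifest.decoy_stages[lnc] = "degree_and_known"
        # stage E: gene prediction at the gate (boundary fails: strict >)
        lnc, _, _ = add_supported_lncrna("weakgene", gene_score=80.0)
        manifest.decoy_stages[lnc] = "pd_gene_link"
        # stage F: linked to another neurodegenerative disease
        lnc, _, _ = add_supported_lncrna("alzheimer", diseases=("Alzheimer disease",))
        manifest.decoy_stages[lnc] = "specificity"
        # stage G: locus beyond the cis threshold
        lnc, _, _ = add_supported_lncrna("farlocus", cis_gap=60_000)
        manifest.decoy_stages[lnc] = "cis_pairing"

    # random background entities with fully random attributes
    rand_mirnas = [f"RMIR-{i:03d}" for i in range(config.n_random_mirnas)]
    rand_lncrnas = [f"RLNC-{i:03d}" for i in range(config.n_random_lncrnas)]
    rand_genes = [f"RGENE-{i:03d}" for i in range(config.n_random_genes)]
    methods_pool = ("reporter-assay", "western-blot", "qPCR", "microarray",
                    "sequencing")
    for m in rand_mirnas:
        n_methods = int(rng.integers(0, 3))
        methods = frozenset(
            rng.choice(methods_pool, size=n_methods, replace=False).tolist()
        )
        kb.mirnas.append(MirnaRecord(m, methods, bool(rng.random() < 0.7)))
    for lnc in rand_lncrnas:
        for m in rand_mirnas:
            if rng.random() < 0.3:
                kb.mirna_lncrna.append(MirnaLncrnaInteraction(
                    m, lnc, float(np.round(rng.uniform(0, 1), 3)), "immunoprecipitation"
                ))
        n_tis = int(rng.integers(0, 4))
        if n_tis:
            kb.tissues.append(TissueExpressionRecord(
                lnc, frozenset(rng.choice(_TISSUE_POOL, size=n_tis,
                                          replace=False).tolist())
            ))
        if rng.random() < 0.3:
            disease = str(rng.choice(
                ["Parkinson disease", "Alzheimer disease", "Huntington disease"]
            ))
            kb.diseases.append(DiseaseAssociation(lnc, disease, "database"))
        if rng.random() < 0.8:
            start = int(rng.integers(0, 200_000))
            kb.loci.append(GeneLocus(
                lnc, f"chr{int(rng.integers(1, 4))}", start,
                start + int(rng.integers(500, 5_000))
            ))
    for g in rand_genes:
        if rng.random() < 0.5:
            pd_genes.add(g)
        for m in rand_mirnas:
            if rng.random() < 0.2:
                kb.mirna_gene.append(MirnaGeneInteraction(
                    m, g, float(np.round(rng.uniform(0, 100), 1))
                ))
        if rng.random() < 0.8:
            start = int(rng.integers(0, 200_000))
            kb.loci.append(GeneLocus(
                g, f"chr{int(rng.integers(1, 4))}", start,
                start + int(rng.integers(500, 5_000))
            ))

    if not pd_genes:
        # the cascade requires a non-empty disease-gene panel; anchor gene
        # has no interactions, so it never creates a triad
        pd_genes.add("GENE-panel-anchor")
    manifest.screen_config = ScreenConfig(
        pd_gene_set=frozenset(pd_genes),
        excluded_disease_labels=_EXCLUDED_DISEASES,
    )
    if out_dir is not None:
        write_knowledge_base(kb, out_dir)
        manifest.write(Path(out_dir) / "manifest.json")
    return kb, manifest


# ---------------------------------------------------------------------------
# qPCR dataset
# ---------------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float, high: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < low) | (out > high)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, low, high)


def _lognormal_from_moments(rng: np.random.Generator, mean: float, sd: float,
                            size: int) -> np.ndarray:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def generate_ct_dataset(
    config: SynthConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthManifest]:
    """Long-format Ct table plus sample metadata for the default study design.

    Reference genes are generated shift-free; each marker's patient samples
    carry the configured group-specific Ct shift plus per-sample biological
    noise, and every replicate of every gene carries technical noise.
    Metadata emulates the study demographics (ages, BMI, right-skewed
    disease duration, per-stage sex counts, MoCA >= 26, stage-specific
    motor-score percentages).
    """
    rng = np.random.default_rng(config.seed)

    samples = []
    for i in range(config.n_control):
        samples.append({"sample_id": f"C{i + 1:02d}", "group": "control",
                        "stage": "none", "stage_class": "none"})
    p = 0
    for stage, n in config.stage_sizes.items():
        stage_class = "early" if stage in ("I", "II") else "late"
        for _ in range(n):
            p += 1
            samples.append({"sample_id": f"P{p:02d}", "group": "PD",
                            "stage": stage, "stage_class": stage_class})
    meta = pd.DataFrame(samples)

    # demographics
    for col, table, bounds in (("age", _AGE, (30.0, 95.0)),
                               ("bmi", _BMI, (15.0, 45.0))):
        vals = np.empty(len(meta))
        for key, (mean, sd) in table.items():
            mask = (meta["stage_class"] == key) if key != "control" \
                else (meta["group"] == "control").to_numpy()
            mask = np.asarray(mask)
            vals[mask] = np.round(
                _trunc_normal(rng, mean, sd, *bounds, int(mask.sum())), 1
            )
        meta[col] = vals
    duration = np.full(len(meta), np.nan)
    for key, (mean, sd) in _DURATION.items():
        mask = (meta["stage_class"] == key).to_numpy()
        duration[mask] = np.round(
            _lognormal_from_moments(rng, mean, sd, int(mask.sum())), 1
        )
    meta["disease_duration"] = duration
    sexes = []
    for stage, males in _MALES.items():
        if stage == "control":
            n = config.n_control
        else:
            n = config.stage_sizes.get(stage, 0)
        males = min(males, n)
        block = ["M"] * males + ["F"] * (n - males)
        sexes.extend(block)
    meta["sex"] = sexes[: len(meta)]
    meta["moca_score"] = rng.integers(26, 31, len(meta))
    updrs = np.full(len(meta), np.nan)
    for stage, (low, high) in _UPDRS_RANGES.items():
        mask = (meta["stage"] == stage).to_numpy()
        updrs[mask] = np.round(rng.uniform(low, high, int(mask.sum())), 1)
    meta["updrs_percent"] = updrs

    # Ct values (vectorized per gene)
    is_pd = (meta["group"] == "PD").to_numpy()
    n_samples = len(meta)
    n_reps = config.n_replicates
    genes = list(_BASELINE_CT)
    markers = set(config.marker_shifts)
    frames = []
    for gene in genes:
        shift = config.marker_shifts.get(gene, 0.0)
        bio = (rng.normal(0.0, config.biological_sd, n_samples)
               if gene in markers and config.biological_sd > 0
               else np.zeros(n_samples))
        base = _BASELINE_CT[gene] + shift * is_pd + bio
        tech = (rng.normal(0.0, config.technical_sd, (n_samples, n_reps))
                if config.technical_sd > 0 else np.zeros((n_samples, n_reps)))
        ct = np.round(base[:, None] + tech, 4)
        frames.append(pd.DataFrame({
            "sample_id": np.repeat(meta["sample_id"].to_numpy(), n_reps),
            "gene_id": gene,
            "replicate": np.tile(np.arange(1, n_reps + 1), n_samples),
            "ct": ct.ravel(),
        }))
    ct_long = pd.concat(frames, ignore_index=True)

    manifest = GroundTruthManifest(
        marker_shifts=dict(config.marker_shifts),
        group_sizes={"control": config.n_control, **dict(config.stage_sizes)},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ct_long.to_csv(out_dir / "ct_long.tsv", sep="\t", index=False)
        meta.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
        manifest.write(out_dir / "manifest.json")
    return ct_long, meta, manifest


# ---------------------------------------------------------------------------
# reporter plate
# ---------------------------------------------------------------------------

def generate_reporter_plate(
    config: SynthConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Dual-luciferase plate with planted per-condition inhibition.

    Condition ratios are the negative-control ratio scaled by
    ``1 − inhibition``, with multiplicative lognormal well noise at the
    configured CV (unit mean, so CV = 0 recovers the planted inhibition
    exactly).  Blank wells carry background-level counts in both channels.
    """
    rng = np.random.default_rng(config.seed)
    base_firefly = 10_000.0
    base_ratio = 0.8
    cv = config.reporter_cv
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0

    def noise(n: int) -> np.ndarray:
        if sigma == 0:
            return np.ones(n)
        return np.exp(rng.normal(-sigma**2 / 2.0, sigma, n))

    rows = []
    conditions = ["NC"] + [c for c in config.inhibition if c != "NC"]
    for condition in conditions:
        inhibition = config.inhibition.get(condition, 0.0)
        firefly = base_firefly * noise(config.n_wells)
        ratio = base_ratio * (1.0 - inhibition) * noise(config.n_wells)
        renilla = firefly * ratio
        for rep in range(config.n_wells):
            rows.append({"condition": condition, "replicate": rep + 1,
                         "renilla": round(float(renilla[rep]), 2),
                         "firefly": round(float(firefly[rep]), 2)})
    for rep in range(2):  # background wells
        rows.append({"condition": "blank", "replicate": rep + 1,
                     "renilla": round(float(rng.uniform(20, 80)), 2),
                     "firefly": round(float(rng.uniform(20, 80)), 2)})
    plate = pd.DataFrame(rows)
    manifest = GroundTruthManifest(inhibition=dict(config.inhibition))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        plate.to_csv(out_dir / "plate.csv", index=False)
        manifest.write(out_dir / "manifest.json")
    return plate, manifest


# ---------------------------------------------------------------------------
# WT/MT sequence pair
# ---------------------------------------------------------------------------

def _site_insert(mirna: str, site_class: str) -> str:
    """Target-strand sequence (5'→3') realizing the requested site class."""
    seed7 = reverse_complement(mirna[1:8])   # m8 base + core
    core = seed7[1:]
    return {
        "8mer": seed7 + "A",
        "7mer-m8": seed7,
        "7mer-A1": core + "A",
        "6mer": core,
    }[site_class]


def generate_sequences(
    config: SynthConfig, out_dir: str | Path | None = None
) -> tuple[str, str, str, GroundTruthManifest]:
    """(wt, mt, mirna) sequence triple with one implanted seed site.

    The background avoids any spurious site of class >= 6mer for the chosen
    miRNA; the implanted site sits at a recorded position with the requested
    class; the mutant shuffles the site window until no site of any class
    remains there.  Returns RNA-alphabet strings and the manifest; with
    ``out_dir`` writes ``wt.fa``, ``mt.fa``, ``mirna.fa``.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list("ACGU"))
    length = config.target_length

    def random_seq(n: int) -> str:
        return "".join(rng.choice(alphabet, size=n))

    mirna = None
    wt = None
    site_start = site_end = None
    for _ in range(200):
        candidate_mirna = random_seq(config.mirna_length)
        insert = _site_insert(candidate_mirna, config.site_class)
        background = random_seq(length)
        if find_seed_sites(candidate_mirna, background):
            continue
        pos = int(rng.integers(1, length - len(insert) - 1))
        candidate = background[:pos] + insert + background[pos + len(insert):]
        sites = find_seed_sites(candidate_mirna, candidate)
        if len(sites) == 1 and sites[0].site_class == config.site_class:
            mirna, wt = candidate_mirna, candidate
            site_start, site_end = sites[0].start, sites[0].end
            break
    if wt is None:
        raise RuntimeError(
            "could not build a clean background after bounded retries; "
            "increase target_length"
        )

    window = list(wt[site_start:site_end])
    mt = None
    for _ in range(200):
        rng.shuffle(window)
        candidate = wt[:site_start] + "".join(window) + wt[site_end:]
        clash = [
            s for s in find_seed_sites(mirna, candidate)
            if s.start < site_end and site_start < s.end
        ]
        if not clash:
            mt = candidate
            break
    if mt is None:
        raise RuntimeError(
            "could not disrupt the implanted site by shuffling; "
            "try a different seed or longer sequence"
        )

    manifest = GroundTruthManifest(
        site_start=site_start, site_end=site_end,
        site_class=config.site_class, mirna_sequence=mirna,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "wt.fa").write_text(f">target_wt\n{wt}\n", encoding="utf-8")
        (out_dir / "mt.fa").write_text(f">target_mt\n{mt}\n", encoding="utf-8")
        (out_dir / "mirna.fa").write_text(
            f">synthetic_mirna\n{mirna}\n", encoding="utf-8"
        )
        manifest.write(out_dir / "manifest.json")
    return wt, mt, mirna, manifest
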