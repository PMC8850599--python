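"""Typed model and TSV I/O for the annotation/interaction tables the screening
cascade consumes, plus genomic-interval arithmetic.

The knowledge base bundles seven tables: validated miRNA records,
miRNA–lncRNA interaction scores (immunoprecipitation-backed, 0–1 scale),
miRNA–gene target predictions (0–100 scale), lncRNA–gene interaction
predictions, gene loci in BED-like coordinates, tissue-expression
annotations, and disease associations.  Every numeric threshold the
screening cascade applies lives in :class:`ScreenConfig`; the cascade code
itself contains no literal thresholds.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "MirnaRecord",
    "MirnaLncrnaInteraction",
    "MirnaGeneInteraction",
    "LncrnaGeneInteraction",
    "GeneLocus",
    "TissueExpressionRecord",
    "DiseaseAssociation",
    "ScreenConfig",
    "KnowledgeBase",
    "ValidationReport",
    "KnowledgeBaseError",
    "load_knowledge_base",
    "write_knowledge_base",
    "validate_knowledge_base",
    "genomic_gap",
    "load_screen_config",
]


class KnowledgeBaseError(ValueError):
    """Raised for missing tables, malformed fields, or duplicate keys."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MirnaRecord:
    """A miRNA with its experimental-validation evidence and disease flag."""

    mirna_id: str
    evidence_methods: frozenset[str] = frozenset()
    pd_related: bool = False

    def __post_init__(self) -> None:
        if not self.mirna_id:
            raise KnowledgeBaseError("mirna_id must be non-empty")


@dataclass(frozen=True)
class MirnaLncrnaInteraction:
    """An experimentally supported miRNA–lncRNA interaction with a 0–1 score."""

    mirna_id: str
    lncrna_id: str
    score: float
    assay: str = "immunoprecipitation"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise KnowledgeBaseError(
                f"interaction score must lie in [0, 1]: "
                f"({self.mirna_id}, {self.lncrna_id}) has {self.score}"
            )


@dataclass(frozen=True)
class MirnaGeneInteraction:
    """A predicted miRNA–mRNA target interaction on the 0–100 score scale."""

    mirna_id: str
    gene_id: str
    prediction_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prediction_score <= 100.0:
            raise KnowledgeBaseError(
                f"prediction score must lie in [0, 100]: "
                f"({self.mirna_id}, {self.gene_id}) has {self.prediction_score}"
            )


@dataclass(frozen=True)
class LncrnaGeneInteraction:
    """A predicted lncRNA–gene RNA:RNA interaction count."""

    lncrna_id: str
    gene_id: str
    n_predicted_interactions: int

    def __post_init__(self) -> None:
        if self.n_predicted_interactions < 0:
            raise KnowledgeBaseError("n_predicted_interactions must be >= 0")


@dataclass(frozen=True)
class GeneLocus:
    """Genomic interval of the gene producing an entity.

    Coordinates are 0-based half-open on a single shared assembly.
    """

    entity_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise KnowledgeBaseError(
                f"invalid interval for {self.entity_id}: [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "unknown"}:
            raise KnowledgeBaseError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class TissueExpressionRecord:
    entity_id: str
    tissues: frozenset[str] = frozenset()


@dataclass(frozen=True)
class DiseaseAssociation:
    entity_id: str
    disease: str
    source: str = "database"

    def __post_init__(self) -> None:
        if not self.disease:
            raise KnowledgeBaseError("disease label must be non-empty")


@dataclass
class ScreenConfig:
    """All tunable thresholds of the candidate-selection cascade.

    Defaults follow standard database conventions: interaction scores above
    0.7 on the 0–1 immunoprecipitation scale, target-prediction scores above
    80 on the 0–100 scale, expression required in both blood and brain, at
    least two sponged miRNAs per lncRNA, and cis pairing within 50 kb.
    Score gates are strict inequalities; boundary values fail.
    """

    min_lncbase_score: float = 0.7
    required_tissues: frozenset[str] = frozenset({"blood", "brain"})
    min_mirna_degree: int = 2
    min_gene_prediction_score: float = 80.0
    max_cis_gap_bp: int = 50_000
    strong_evidence_methods: frozenset[str] = frozenset(
        {"reporter-assay", "western-blot", "qPCR"}
    )
    excluded_disease_labels: frozenset[str] = frozenset()
    pd_gene_set: frozenset[str] = frozenset()
    pd_disease_label: str = "Parkinson disease"
    # stage switches: the score gates may be disabled to mimic post-hoc use
    apply_lncbase_score_gate: bool = True
    apply_gene_score_gate: bool = True

    def __post_init__(self) -> None:
        self.required_tissues = frozenset(self.required_tissues)
        self.strong_evidence_methods = frozenset(self.strong_evidence_methods)
        self.excluded_disease_labels = frozenset(self.excluded_disease_labels)
        self.pd_gene_set = frozenset(self.pd_gene_set)
        if not 0.0 <= self.min_lncbase_score <= 1.0:
            raise KnowledgeBaseError("min_lncbase_score must lie in [0, 1]")
        if not 0.0 <= self.min_gene_prediction_score <= 100.0:
            raise KnowledgeBaseError("min_gene_prediction_score must lie in [0, 100]")
        if self.max_cis_gap_bp <= 0:
            raise KnowledgeBaseError("max_cis_gap_bp must be positive")
        if self.min_mirna_degree < 0:
            raise KnowledgeBaseError("min_mirna_degree must be >= 0")


@dataclass
class KnowledgeBase:
    """The seven tables plus provenance (paths, checksums, row counts)."""

    mirnas: list[MirnaRecord] = field(default_factory=list)
    mirna_lncrna: list[MirnaLncrnaInteraction] = field(default_factory=list)
    mirna_gene: list[MirnaGeneInteraction] = field(default_factory=list)
    lncrna_gene: list[LncrnaGeneInteraction] = field(default_factory=list)
    loci: list[GeneLocus] = field(default_factory=list)
    tissues: list[TissueExpressionRecord] = field(default_factory=list)
    diseases: list[DiseaseAssociation] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def locus_of(self, entity_id: str) -> GeneLocus | None:
        for locus in self.loci:
            if locus.entity_id == entity_id:
                return locus
        return None

    def tissues_of(self, entity_id: str) -> frozenset[str]:
        # missing record means "expressed nowhere": the tissue filter is a
        # positive selection, so absence fails it
        for rec in self.tissues:
            if rec.entity_id == entity_id:
                return rec.tissues
        return frozenset()

    def diseases_of(self, entity_id: str) -> set[str]:
        return {d.disease for d in self.diseases if d.entity_id == entity_id}

    def __eq__(self, other: object) -> bool:  # provenance excluded on purpose
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            sorted(self.mirnas, key=lambda r: r.mirna_id)
            == sorted(other.mirnas, key=lambda r: r.mirna_id)
            and set(self.mirna_lncrna) == set(other.mirna_lncrna)
            and set(self.mirna_gene) == set(other.mirna_gene)
            and set(self.lncrna_gene) == set(other.lncrna_gene)
            and set(self.loci) == set(other.loci)
            and set(self.tissues) == set(other.tissues)
            and set(self.diseases) == set(other.diseases)
        )


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def genomic_gap(locus_a: GeneLocus, locus_b: GeneLocus) -> float:
    """Bases strictly between two loci; 0 if they overlap or abut,
    ``math.inf`` if on different chromosomes.

    Symmetric and strand-agnostic, on 0-based half-open coordinates.
    """
    if locus_a.chromosome != locus_b.chromosome:
        return math.inf
    gap = max(locus_a.start, locus_b.start) - min(locus_a.end, locus_b.end)
    return float(max(0, gap))


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------
# Dialect: UTF-8, header row, tab separator, no quoting; set-valued fields
# are comma-joined tokens, empty string for the empty set.

TABLE_FILES = {
    "mirnas": "mirnas.tsv",
    "mirna_lncrna": "mirna_lncrna.tsv",
    "mirna_gene": "mirna_gene.tsv",
    "lncrna_gene": "lncrna_gene.tsv",
    "loci": "loci.tsv",
    "tissues": "tissues.tsv",
    "diseases": "diseases.tsv",
}


def _join_set(values: Iterable[str]) -> str:
    return ",".join(sorted(values))


def _split_set(text: object) -> frozenset[str]:
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return frozenset()
    text = str(text).strip()
    if not text:
        return frozenset()
    return frozenset(tok.strip() for tok in text.split(",") if tok.strip())


def _read_tsv(path: Path, table: str) -> pd.DataFrame:
    if not path.is_file():
        raise KnowledgeBaseError(f"missing table {table!r}: expected file {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _numeric(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    try:
        return pd.to_numeric(df[column])
    except (ValueError, TypeError) as exc:
        bad = df[pd.to_numeric(df[column], errors="coerce").isna()]
        line = int(bad.index[0]) + 2 if len(bad) else "?"
        raise KnowledgeBaseError(
            f"malformed numeric field in {path.name}, line {line}, column {column!r}"
        ) from exc


def _check_unique(keys: pd.Series | pd.DataFrame, path: Path) -> None:
    if isinstance(keys, pd.DataFrame):
        dup = keys[keys.duplicated()].astype(str).agg("/".join, axis=1)
    else:
        dup = keys[keys.duplicated()]
    if len(dup):
        raise KnowledgeBaseError(
            f"duplicate primary key(s) in {path.name}: {sorted(set(dup))}"
        )


def load_knowledge_base(directory: str | Path,
                        config: ScreenConfig | None = None) -> KnowledgeBase:
    """Parse the seven TSV tables in *directory* into a typed knowledge base.

    Row counts and SHA-256 checksums are recorded in the provenance block.
    Missing files, malformed numeric fields and duplicate primary keys raise
    :class:`KnowledgeBaseError` naming the offending table/row.
    """
    directory = Path(directory)
    kb = KnowledgeBase()
    prov: dict[str, dict] = {}

    for table, fname in TABLE_FILES.items():
        path = directory / fname
        df = _read_tsv(path, table)
        prov[table] = {
            "path": str(path),
            "rows": int(len(df)),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
        if table == "mirnas":
            _check_unique(df["mirna_id"], path)
            kb.mirnas = [
                MirnaRecord(
                    mirna_id=row["mirna_id"],
                    evidence_methods=_split_set(row["evidence_methods"]),
                    pd_related=str(row["pd_related"]).strip().lower()
                    in {"1", "true", "yes"},
                )
                for row in df.to_dict("records")
            ]
        elif table == "mirna_lncrna":
            _check_unique(df[["mirna_id", "lncrna_id"]], path)
            scores = _numeric(df, "score", path)
            for i, row in enumerate(df.to_dict("records")):
                if not 0.0 <= scores.iloc[i] <= 1.0:
                    raise KnowledgeBaseError(
                        f"score out of [0, 1] in {path.name}, line {i + 2}: "
                        f"({row['mirna_id']}, {row['lncrna_id']}) = {scores.iloc[i]}"
                    )
            kb.mirna_lncrna = [
                MirnaLncrnaInteraction(
                    row["mirna_id"], row["lncrna_id"],
                    float(scores.iloc[i]), row.get("assay", ""),
                )
                for i, row in enumerate(df.to_dict("records"))
            ]
        elif table == "mirna_gene":
            _check_unique(df[["mirna_id", "gene_id"]], path)
            scores = _numeric(df, "prediction_score", path)
            for i, row in enumerate(df.to_dict("records")):
                if not 0.0 <= scores.iloc[i] <= 100.0:
                    raise KnowledgeBaseError(
                        f"prediction_score out of [0, 100] in {path.name}, "
                        f"line {i + 2}: ({row['mirna_id']}, {row['gene_id']})"
                    )
            kb.mirna_gene = [
                MirnaGeneInteraction(row["mirna_id"], row["gene_id"],
                                     float(scores.iloc[i]))
                for i, row in enumerate(df.to_dict("records"))
            ]
        elif table == "lncrna_gene":
            _check_unique(df[["lncrna_id", "gene_id"]], path)
            counts = _numeric(df, "n_predicted_interactions", path)
            kb.lncrna_gene = [
                LncrnaGeneInteraction(row["lncrna_id"], row["gene_id"],
                                      int(counts.iloc[i]))
                for i, row in enumerate(df.to_dict("records"))
            ]
        elif table == "loci":
            _check_unique(df["name"], path)
            starts = _numeric(df, "start", path)
            ends = _numeric(df, "end", path)
            kb.loci = [
                GeneLocus(entity_id=row["name"], chromosome=row["chrom"],
                          start=int(starts.iloc[i]), end=int(ends.iloc[i]),
                          strand=row.get("strand") or "unknown")
                for i, row in enumerate(df.to_dict("records"))
            ]
        elif table == "tissues":
            _check_unique(df["entity_id"], path)
            kb.tissues = [
                TissueExpressionRecord(row["entity_id"], _split_set(row["tissues"]))
                for row in df.to_dict("records")
            ]
        elif table == "diseases":
            kb.diseases = [
                DiseaseAssociation(row["entity_id"], row["disease"],
                                   row.get("source", "database"))
                for row in df.to_dict("records")
            ]
    kb.provenance = prov
    return kb


def write_knowledge_base(kb: KnowledgeBase, directory: str | Path) -> Path:
    """Serialize a knowledge base to the seven-table TSV layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "evidence_methods": _join_set(r.evidence_methods),
                "pd_related": str(r.pd_related).lower(),
            }
            for r in sorted(kb.mirnas, key=lambda r: r.mirna_id)
        ],
        columns=["mirna_id", "evidence_methods", "pd_related"],
    ).to_csv(directory / TABLE_FILES["mirnas"], sep="\t", index=False)

    pd.DataFrame(
        [
            {"mirna_id": r.mirna_id, "lncrna_id": r.lncrna_id,
             "score": r.score, "assay": r.assay}
            for r in sorted(kb.mirna_lncrna, key=lambda r: (r.mirna_id, r.lncrna_id))
        ],
        columns=["mirna_id", "lncrna_id", "score", "assay"],
    ).to_csv(directory / TABLE_FILES["mirna_lncrna"], sep="\t", index=False)

    pd.DataFrame(
        [
            {"mirna_id": r.mirna_id, "gene_id": r.gene_id,
             "prediction_score": r.prediction_score}
            for r in sorted(kb.mirna_gene, key=lambda r: (r.mirna_id, r.gene_id))
        ],
        columns=["mirna_id", "gene_id", "prediction_score"],
    ).to_csv(directory / TABLE_FILES["mirna_gene"], sep="\t", index=False)

    pd.DataFrame(
        [
            {"lncrna_id": r.lncrna_id, "gene_id": r.gene_id,
             "n_predicted_interactions": r.n_predicted_interactions}
            for r in sorted(kb.lncrna_gene, key=lambda r: (r.lncrna_id, r.gene_id))
        ],
        columns=["lncrna_id", "gene_id", "n_predicted_interactions"],
    ).to_csv(directory / TABLE_FILES["lncrna_gene"], sep="\t", index=False)

    # BED-compatible column order; unused BED score column is kept at 0
    pd.DataFrame(
        [
            {"chrom": l.chromosome, "start": l.start, "end": l.end,
             "name": l.entity_id, "score": 0, "strand": l.strand}
            for l in sorted(kb.loci, key=lambda l: l.entity_id)
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    ).to_csv(directory / TABLE_FILES["loci"], sep="\t", index=False)

    pd.DataFrame(
        [
            {"entity_id": r.entity_id, "tissues": _join_set(r.tissues)}
            for r in sorted(kb.tissues, key=lambda r: r.entity_id)
        ],
        columns=["entity_id", "tissues"],
    ).to_csv(directory / TABLE_FILES["tissues"], sep="\t", index=False)

    pd.DataFrame(
        [
            {"entity_id": r.entity_id, "disease": r.disease, "source": r.source}
            for r in sorted(kb.diseases, key=lambda r: (r.entity_id, r.disease))
        ],
        columns=["entity_id", "disease", "source"],
    ).to_csv(directory / TABLE_FILES["diseases"], sep="\t", index=False)

    return directory


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Referential-integrity findings. Gaps are reported, never fatal."""

    missing_locus: list[str] = field(default_factory=list)
    dangling_references: list[str] = field(default_factory=list)
    duplicate_associations: list[str] = field(default_factory=list)

    def is_clean(self) -> bool:
        return not (self.missing_locus or self.dangling_references
                    or self.duplicate_associations)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        if self.is_clean():
            return "knowledge base is consistent\n"
        lines = []
        for label, entries in (
            ("missing locus", self.missing_locus),
            ("dangling reference", self.dangling_references),
            ("duplicate association", self.duplicate_associations),
        ):
            lines.extend(f"{label}: {e}" for e in entries)
        return "\n".join(lines) + "\n"


def validate_knowledge_base(kb: KnowledgeBase) -> ValidationReport:
    """Report dangling cross-references, entities without loci, and duplicated
    disease associations."""
    report = ValidationReport()
    known_mirnas = {r.mirna_id for r in kb.mirnas}
    loci_ids = {l.entity_id for l in kb.loci}

    interacting_entities: set[str] = set()
    for inter in kb.mirna_lncrna:
        interacting_entities.add(inter.lncrna_id)
        if inter.mirna_id not in known_mirnas:
            report.dangling_references.append(
                f"mirna_lncrna names unknown miRNA {inter.mirna_id}"
            )
    for inter in kb.mirna_gene:
        interacting_entities.add(inter.gene_id)
        if inter.mirna_id not in known_mirnas:
            report.dangling_references.append(
                f"mirna_gene names unknown miRNA {inter.mirna_id}"
            )
    for entity in sorted(interacting_entities - loci_ids):
        report.missing_locus.append(entity)

    seen: set[tuple[str, str, str]] = set()
    for assoc in kb.diseases:
        key = (assoc.entity_id, assoc.disease, assoc.source)
        if key in seen:
            report.duplicate_associations.append(
                f"{assoc.entity_id} / {assoc.disease} ({assoc.source})"
            )
        seen.add(key)
    return report


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

def load_screen_config(path: str | Path) -> ScreenConfig:
    """Read a ScreenConfig from a YAML file mirroring its field names."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("required_tissues", "strong_evidence_methods",
                "excluded_disease_labels", "pd_gene_set"):
        if key in raw and raw[key] is not None:
            raw[key] = frozenset(raw[key])
    return ScreenConfig(**raw)
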