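import numpy as np
import pytest

from triadscreen.demo import demo_knowledge_base, demo_screen_config
from triadscreen.simulate import SynthConfig, generate_knowledge_base


@pytest.fixture
def demo_kb():
    return demo_knowledge_base()


@pytest.fixture
def demo_config():
    return demo_screen_config()


@pytest.fixture
def planted_kb():
    """Synthetic knowledge base: 2 planted triads + 7 single-defect decoys."""
    return generate_knowledge_base(SynthConfig(seed=11))


def random_kb(seed: int):
    """A small random knowledge base for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    cfg = SynthConfig(
        seed=seed,
        n_planted_triads=int(rng.integers(0, 3)),
        include_decoys=bool(rng.random() < 0.5),
        n_random_mirnas=int(rng.integers(3, 10)),
        n_random_lncrnas=int(rng.integers(3, 12)),
        n_random_genes=int(rng.integers(2, 8)),
    )
    return generate_knowledge_base(cfg)


def brute_force_triads(kb, cfg):
    """Single-pass conjunction of every stage predicate over all (L, m, G)
    combinations — the independent oracle for the cascade."""
    strong = {
        r.mirna_id for r in kb.mirnas
        if r.pd_related and r.evidence_methods & cfg.strong_evidence_methods
    }
    score = {(i.mirna_id, i.lncrna_id): i.score for i in kb.mirna_lncrna}
    tissues = {t.entity_id: t.tissues for t in kb.tissues}
    diseases: dict[str, set[str]] = {}
    for d in kb.diseases:
        diseases.setdefault(d.entity_id, set()).add(d.disease)
    loci = {l.entity_id: l for l in kb.loci}
    lncrnas = {i.lncrna_id for i in kb.mirna_lncrna}
    degree = {
        L: sum(
            1 for m in strong if score.get((m, L), -1.0) > cfg.min_lncbase_score
        )
        for L in lncrnas
    }
    out = set()
    for L in lncrnas:
        if not cfg.required_tissues <= tissues.get(L, frozenset()):
            continue
        if cfg.pd_disease_label in diseases.get(L, set()):
            continue
        if degree[L] < cfg.min_mirna_degree:
            continue
        if diseases.get(L, set()) & cfg.excluded_disease_labels:
            continue
        for m in strong:
            if not score.get((m, L), -1.0) > cfg.min_lncbase_score:
                continue
            for g in kb.mirna_gene:
                if g.mirna_id != m or g.gene_id not in cfg.pd_gene_set:
                    continue
                if not g.prediction_score > cfg.min_gene_prediction_score:
                    continue
                la, lb = loci.get(L), loci.get(g.gene_id)
                if la is None or lb is None:
                    continue
                if la.chromosome != lb.chromosome:
                    continue
                gap = max(0, max(la.start, lb.start) - min(la.end, lb.end))
                if gap < cfg.max_cis_gap_bp:
                    out.add((L, m, g.gene_id))
    return out
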