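import random

import pytest

from feastkit.models import ExperimentQuant, FEAResult, RunConfig, Term


def mk_term(term_id, genes, database="GO", description="", padj=None, score=None):
    return Term(term_id=term_id, description=description or f"term {term_id}",
                database=database, goi_set=frozenset(genes), padj=padj, score=score)


def random_gene_sets(rng, n_pairs, universe_size=30, max_size=12):
    universe = [f"g{i}" for i in range(universe_size)]
    pairs = []
    for _ in range(n_pairs):
        a = set(rng.sample(universe, rng.randint(1, max_size)))
        b = set(rng.sample(universe, rng.randint(1, max_size)))
        pairs.append((a, b))
    return pairs


@pytest.fixture
def rng():
    return random.Random(20240915)


def make_structured_fea():
    """Hand-built FEA with one meta-community, one lone community and two
    unclustered terms, under OC, threshold 0.5, weak threshold 0.25.

    Block X and block Y each form a community (within-overlap 0.8); the two
    blocks share three bridge genes (cross-overlap 0.3, a weak residual
    link), so their communities merge into one meta-community.  Block Z is a
    strongly overlapping pair with no outside overlap (a lone community),
    and two fully disjoint singleton terms stay unclustered.
    """
    bridge = [f"s{i}" for i in range(3)]

    def block(tag, n_terms, core_n=5, unique_n=2, bridged=False):
        core = [f"{tag}c{i}" for i in range(core_n)] + (bridge if bridged else [])
        terms = []
        for t in range(n_terms):
            unique = [f"{tag}u{t}_{i}" for i in range(unique_n)]
            terms.append(mk_term(f"{tag}{t}", core + unique, padj=1e-6))
        return terms

    terms = []
    terms += block("X", 3, bridged=True)   # size 10, within OC 8/10
    terms += block("Y", 3, bridged=True)
    terms += block("Z", 2, core_n=5, unique_n=1, bridged=False)  # within OC 5/6
    terms.append(mk_term("L0", ["q0", "q1", "q2"], padj=1e-4))
    terms.append(mk_term("L1", ["r0", "r1", "r2"], padj=1e-4))

    universe = sorted({g for t in terms for g in t.goi_set})
    r = random.Random(7)
    e1 = {g: r.uniform(-3, 3) for g in universe}
    e2 = {g: r.uniform(-3, 3) for g in universe if r.random() < 0.8}
    fea = FEAResult(
        fea_id="FX",
        terms=terms,
        experiments=[
            ExperimentQuant("E1", values=e1, membership=set(e1)),
            ExperimentQuant("E2", values=e2, membership=set(e2)),
        ],
    )
    fea.validate()
    return fea


@pytest.fixture
def structured_fea():
    return make_structured_fea()


@pytest.fixture
def structured_config(tmp_path):
    return RunConfig(metric="OC", threshold=0.5, weak_threshold=0.25,
                     max_community_size=10, output_dir=tmp_path / "report")
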