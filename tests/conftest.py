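import random

import pytest
from hypothesis import HealthCheck, settings

from taxopep import (
    CandidateSet,
    CommunitySpec,
    GraphParams,
    RunConfig,
    ScoredPeptide,
    TaxonomyTable,
    assemble,
    generate_community,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_taxonomy() -> TaxonomyTable:
    """root(1) -> bacteria(2)/eukaryota(3); two genera; species and strains."""
    rows = {
        1: (1, "no rank", "root"),
        2: (1, "superkingdom", "Bacteria"),
        3: (1, "superkingdom", "Eukaryota"),
        10: (2, "genus", "Genus A"),
        11: (2, "genus", "Genus B"),
        30: (3, "genus", "Genus E"),
        101: (10, "species", "A one"),
        102: (10, "species", "A two"),
        111: (11, "species", "B one"),
        301: (30, "species", "E one"),
        1011: (101, "strain", "A one str1"),
        1012: (101, "strain", "A one str2"),
    }
    return TaxonomyTable(
        parent={t: v[0] for t, v in rows.items()},
        rank={t: v[1] for t, v in rows.items()},
        name={t: v[2] for t, v in rows.items()},
    )


@pytest.fixture(scope="session")
def default_community():
    return generate_community(CommunitySpec())


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return RunConfig()


def make_graph(taxa, edges, scores, params: GraphParams):
    """Assemble a factor graph straight from explicit structure.

    ``edges`` maps peptide sequence -> iterable of parent taxids;
    ``scores`` maps sequence -> detection score.
    """
    cs = CandidateSet(
        taxa=[(t, 1.0) for t in sorted(taxa)],
        peptide_edges={s: frozenset(p) for s, p in edges.items()},
        unique_counts={t: 0 for t in taxa},
    )
    peptides = [ScoredPeptide(s, scores[s]) for s in sorted(edges)]
    return assemble(cs, peptides, params)


def sample_bipartite_graph(rng: random.Random, acyclic: bool, max_vars: int = 12):
    """Random peptide-taxon graph with <= max_vars binary variables.

    Peptide degeneracy is skewed toward 1-2 parents, the typical shape of
    rank-aggregated mappings.  ``acyclic=True`` builds a forest (tracked by
    union-find over taxa); ``acyclic=False`` guarantees at least one cycle.
    """
    n_taxa = rng.randint(3 if acyclic else 2, 8)
    n_pep = max_vars - n_taxa
    taxa = list(range(1, n_taxa + 1))

    while True:
        comp = {t: t for t in taxa}

        def find(x):
            while comp[x] != x:
                comp[x] = comp[comp[x]]
                x = comp[x]
            return x

        edges, has_cycle = {}, False
        for i in range(n_pep):
            k = min(1 + (rng.random() < 0.45) + (rng.random() < 0.2), n_taxa)
            parents = rng.sample(taxa, k)
            roots = {find(t) for t in parents}
            if len(roots) < len(parents):
                has_cycle = True
                if acyclic:
                    parents = parents[:1]  # degrade to a safe single edge
                    roots = {find(parents[0])}
            first, *rest = roots
            for r in rest:
                comp[r] = first
            edges[f"P{i}"] = frozenset(parents)
        if acyclic or has_cycle:
            break

    scores = {s: rng.uniform(0.02, 0.98) for s in edges}
    params = GraphParams(
        alpha=rng.choice([0.85, 0.9, 0.99]),
        beta=rng.choice([0.5, 0.6, 0.7]),
        gamma=rng.choice([0.1, 0.3, 0.5]),
        regularized=rng.random() < 0.5,
    )
    return make_graph(taxa, edges, scores, params)
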