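"""Noisy-OR factor graph over peptides and candidate taxa.

Binary taxon variables (present/absent, prior gamma) connect to binary
peptide variables (detected/not) through one count factor per peptide: the
factor couples the peptide to the number n of its parent taxa that are
present, with the leaky noisy-OR conditional

    P(detected | n) = 1 - (1 - beta) * (1 - alpha)^n

alpha being the per-parent emission probability and beta the leak (random
or spurious detection).  An optional regularization reweights the implicit
count prior by 1/n for n >= 1, encoding that far fewer taxa are present
than are included in the graph.  Each peptide also carries an observation
factor (s, 1-s) from its detection score.

Count distributions are computed exactly as sums of independent Bernoulli
indicators via convolution trees, so no factor ever materializes a 2^k
table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .candidates import CandidateSet
from .io import ScoredPeptide

__all__ = [
    "GraphParams",
    "PeptideFactor",
    "FactorGraph",
    "noisyor_table",
    "regularize_count_prior",
    "convolution_count",
    "leave_one_out_counts",
    "assemble",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GraphParams:
    """Noisy-OR model parameters.

    alpha: probability of observing a peptide given a present parent taxon.
    beta:  probability of a random / spurious peptide observation (leak).
    gamma: prior probability that a taxon is present.
    """

    alpha: float
    beta: float
    gamma: float
    regularized: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")

    def key(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


def noisyor_table(params: GraphParams, max_parents: int) -> np.ndarray:
    """Conditional table of shape (max_parents+1, 2).

    Row n holds (P(not detected | n present parents), P(detected | n));
    rows sum to one and P(detected | n) is monotone nondecreasing in n,
    alpha and beta, with P(detected | 0) = beta (leak only).
    """
    if max_parents < 0:
        raise ValueError("max_parents must be >= 0")
    n = np.arange(max_parents + 1)
    p_det = 1.0 - (1.0 - params.beta) * (1.0 - params.alpha) ** n
    return np.column_stack([1.0 - p_det, p_det])


def regularize_count_prior(count_distribution, regularized: bool = True) -> np.ndarray:
    """Reweight a parent-count distribution by 1/n for n >= 1.

    The n = 0 entry keeps weight 1 so the empty-parent state stays
    well-defined; the vector is renormalized to sum to one.  With
    ``regularized=False`` the (normalized) input is returned unchanged.
    """
    dist = np.asarray(count_distribution, dtype=float)
    total = dist.sum()
    if total <= 0.0:
        raise ValueError("count distribution sums to zero")
    dist = dist / total
    if not regularized:
        return dist
    weights = np.ones(len(dist))
    if len(dist) > 1:
        weights[1:] = 1.0 / np.arange(1, len(dist))
    out = dist * weights
    return out / out.sum()


def count_reg_weights(n_parents: int, regularized: bool) -> np.ndarray:
    """Multiplicative factor-table weights r(n), n = 0..n_parents."""
    w = np.ones(n_parents + 1)
    if regularized and n_parents >= 1:
        w[1:] = 1.0 / np.arange(1, n_parents + 1)
    return w


# ---------------------------------------------------------------------------
# convolution trees
# ---------------------------------------------------------------------------


def _convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.convolve(a, b)


def convolution_count(probs) -> np.ndarray:
    """Exact distribution of the number of present parents.

    ``probs`` are independent Bernoulli presence probabilities; pairwise
    convolutions are arranged as a balanced binary tree, which keeps the
    intermediate supports short and the floating-point error flat.
    """
    if len(probs) == 0:
        raise ValueError("empty parent list")
    layer = [np.array([1.0 - p, p]) for p in probs]
    while len(layer) > 1:
        nxt = [
            _convolve(layer[i], layer[i + 1]) if i + 1 < len(layer) else layer[i]
            for i in range(0, len(layer), 2)
        ]
        layer = nxt
    return layer[0]


def leave_one_out_counts(probs) -> list[np.ndarray]:
    """Per-parent distribution over the count of the *other* parents.

    This is the downward pass of the convolution tree, computed with
    prefix/suffix convolutions (numerically safer than deconvolution).
    Element j has support 0..k-1 where k = len(probs).
    """
    k = len(probs)
    if k == 0:
        raise ValueError("empty parent list")
    bern = [np.array([1.0 - p, p]) for p in probs]
    prefix = [np.array([1.0])]
    for b in bern[:-1]:
        prefix.append(_convolve(prefix[-1], b))
    suffix = [np.array([1.0])]
    for b in reversed(bern[1:]):
        suffix.append(_convolve(suffix[-1], b))
    suffix.reverse()
    return [_convolve(prefix[j], suffix[j]) for j in range(k)]


# ---------------------------------------------------------------------------
# graph assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeptideFactor:
    """Per-peptide coupling: parent taxa, detection score, and the
    noisy-OR column P(detected | n) with regularization weights r(n)."""

    sequence: str
    parents: tuple[int, ...]
    score: float
    p_det: np.ndarray  # length len(parents)+1
    reg: np.ndarray  # length len(parents)+1

    @property
    def n_parents(self) -> int:
        return len(self.parents)


@dataclass
class FactorGraph:
    """Assembled bipartite factor graph ready for message passing."""

    params: GraphParams
    taxa: tuple[int, ...]
    factors: dict[str, PeptideFactor]

    @property
    def n_variables(self) -> int:
        return len(self.taxa) + len(self.factors)

    @property
    def n_factor_nodes(self) -> int:
        # one prior per taxon, one count/noisy-OR factor and one
        # observation factor per peptide
        return len(self.taxa) + 2 * len(self.factors)

    @property
    def n_nodes(self) -> int:
        return self.n_variables + self.n_factor_nodes

    @property
    def n_edges(self) -> int:
        deg = sum(f.n_parents for f in self.factors.values())
        return len(self.taxa) + deg + 2 * len(self.factors)

    def taxon_peptides(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {t: [] for t in self.taxa}
        for seq in sorted(self.factors):
            for t in self.factors[seq].parents:
                out[t].append(seq)
        return out

    def dump_json(self, path) -> None:
        """Debugging dump: node list, edge list and factor tables."""
        obj = {
            "params": {
                "alpha": self.params.alpha,
                "beta": self.params.beta,
                "gamma": self.params.gamma,
                "regularized": self.params.regularized,
            },
            "taxa": list(self.taxa),
            "peptides": [
                {
                    "sequence": f.sequence,
                    "parents": list(f.parents),
                    "score": f.score,
                    "p_detected_given_n": f.p_det.tolist(),
                    "count_regularization": f.reg.tolist(),
                }
                for f in self.factors.values()
            ],
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def assemble(
    candidates: CandidateSet,
    peptides: list[ScoredPeptide],
    params: GraphParams,
) -> FactorGraph:
    """Build the factor graph for one parameter combination.

    Structure depends only on the candidate set (it is invariant to the
    order peptides are supplied in); peptides without a candidate parent
    are skipped with a warning.
    """
    if not candidates.taxa:
        raise ValueError("empty candidate set")
    scores: dict[str, float] = {}
    for p in peptides:
        if p.sequence in scores:
            raise ValueError(f"duplicate peptide sequence: {p.sequence}")
        scores[p.sequence] = p.score

    factors: dict[str, PeptideFactor] = {}
    n_skipped = 0
    for seq in sorted(candidates.peptide_edges):
        parents = tuple(sorted(candidates.peptide_edges[seq]))
        if not parents:
            n_skipped += 1
            continue
        if seq not in scores:
            raise ValueError(f"peptide {seq} in candidate set but not scored")
        table = noisyor_table(params, len(parents))
        factors[seq] = PeptideFactor(
            sequence=seq,
            parents=parents,
            score=scores[seq],
            p_det=table[:, 1].copy(),
            reg=count_reg_weights(len(parents), params.regularized),
        )
    if n_skipped:
        logger.warning("assemble: skipped %d peptides with no candidate parent", n_skipped)
    graph = FactorGraph(params=params, taxa=tuple(sorted(candidates.taxids)), factors=factors)
    logger.info("assembled graph: %d nodes, %d edges", graph.n_nodes, graph.n_edges)
    return graph
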