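"""Grid-search parameter selection.

The weighted candidate list L_W (clustered so that near-identical taxa are
represented by a single head) is compared to each posterior-ranked list
L_S with rank-biased overlap (RBO), and the agreement is traded off
against the Shannon entropy S of the normalized marginal vector through

    M = RBO * S^(-2)

The (alpha, beta, gamma) combination maximizing M aligns the posterior
ranking with the PSM-weight evidence while concentrating the probability
mass on few taxa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .candidates import CandidateSet
from .graph import GraphParams
from .inference import PosteriorResult
from .io import RunConfig

__all__ = [
    "ClusteredList",
    "SelectionScore",
    "taxon_similarity",
    "cluster_taxa",
    "rank_biased_overlap",
    "posterior_entropy",
    "select_parameters",
    "ENTROPY_FLOOR",
]

logger = logging.getLogger(__name__)

ENTROPY_FLOOR = 1e-3  # keeps M = RBO / S^2 finite for degenerate posteriors


@dataclass
class ClusteredList:
    """Clusters of taxa with near-identical detected peptide sets.

    ``heads`` are ordered by descending weight (ties by taxid ascending);
    ``members`` maps each head to its full cluster, forming a partition of
    the candidate taxa.
    """

    heads: list[int]
    members: dict[int, set[int]]


@dataclass
class SelectionScore:
    """Per-parameter-set evaluation: RBO, entropy and the metric M."""

    params: GraphParams
    rbo: float
    entropy: float
    metric: float
    winner: bool = False
    low_confidence: bool = False


def taxon_similarity(detected_a: set[str], detected_b: set[str]) -> float:
    """Overlap coefficient |A & B| / min(|A|, |B|) of detected peptide sets.

    Min-normalization lets a taxon whose few detected peptides are all
    shared with a better-covered relative cluster with it.
    """
    if not detected_a and not detected_b:
        raise ValueError("both peptide sets are empty")
    if not detected_a or not detected_b:
        return 0.0
    return len(detected_a & detected_b) / min(len(detected_a), len(detected_b))


def cluster_taxa(
    candidates: CandidateSet,
    detected: dict[int, set[str]] | None = None,
    threshold: float = 0.9,
) -> ClusteredList:
    """Greedy single-pass clustering of candidate taxa.

    Taxa are visited by detected-peptide count descending (ties by taxid
    ascending); each joins the first existing head with similarity >=
    ``threshold``, else founds a new cluster.  Visiting order guarantees
    each head has the most detected peptides within its cluster.  Heads are
    finally ordered by their candidate weight descending.
    """
    if not candidates.taxa:
        raise ValueError("empty candidate set")
    if detected is None:
        detected = candidates.detected_peptides()
    order = sorted(detected, key=lambda t: (-len(detected[t]), t))
    heads: list[int] = []
    members: dict[int, set[int]] = {}
    for t in order:
        if not detected[t]:
            # no detected peptides: cannot be similar to anything, own cluster
            heads.append(t)
            members[t] = {t}
            continue
        for h in heads:
            if detected[h] and taxon_similarity(detected[t], detected[h]) >= threshold:
                members[h].add(t)
                break
        else:
            heads.append(t)
            members[t] = {t}
    weights = candidates.weights
    heads.sort(key=lambda t: (-weights.get(t, 0.0), t))
    return ClusteredList(heads=heads, members=members)


def rank_biased_overlap(list_a, list_b, p: float = 0.9) -> float:
    """Extrapolated rank-biased overlap of two ranked lists.

    RBO_ext = (A_d / d) p^d + ((1-p)/p) * sum_{k=1..d} (A_k / k) p^k,
    where A_k is the overlap of the two top-k prefixes and d the length of
    the shorter list.  Handles nonconjoint lists; top ranks dominate, with
    persistence p controlling how quickly weight decays with depth.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0,1)")
    a, b = list(list_a), list(list_b)
    if not a or not b:
        raise ValueError("empty ranked list")
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValueError("ranked lists must contain distinct items")
    d = min(len(a), len(b))
    seen_a: set = set()
    seen_b: set = set()
    overlap = 0
    tail = 0.0
    for k in range(1, d + 1):
        x, y = a[k - 1], b[k - 1]
        if x == y:
            overlap += 1
        else:
            overlap += (x in seen_b) + (y in seen_a)
        seen_a.add(x)
        seen_b.add(y)
        tail += (overlap / k) * p**k
    return (overlap / d) * p**d + (1.0 - p) / p * tail


def posterior_entropy(marginals: dict[int, float]) -> float:
    """Shannon entropy (nats) of the normalized marginal vector, floored.

    The marginal vector is normalized to a distribution q over taxa;
    S = -sum q ln q, floored at ENTROPY_FLOOR so the selection metric
    RBO / S^2 stays finite for near-point-mass posteriors.
    """
    total = sum(marginals.values())
    if total <= 0.0:
        raise ValueError("all marginals are zero")
    s = 0.0
    for m in marginals.values():
        if m > 0.0:
            q = m / total
            s -= q * math.log(q)
    return max(s, ENTROPY_FLOOR)


def _score_one(
    result: PosteriorResult, clustered: ClusteredList, rbo_p: float
) -> SelectionScore:
    l_s = result.ranked_taxa()
    rbo = rank_biased_overlap(clustered.heads, l_s, rbo_p)
    entropy = posterior_entropy(result.marginals)
    return SelectionScore(
        params=result.params, rbo=rbo, entropy=entropy, metric=rbo / entropy**2
    )


def select_parameters(
    results: list[PosteriorResult],
    clustered: ClusteredList,
    config: RunConfig,
) -> tuple[SelectionScore, list[SelectionScore]]:
    """Score every parameter combination and pick the winner.

    The winner maximizes M = RBO * S^(-2); exact ties prefer lower beta,
    then higher alpha, then lower gamma.  If every RBO is zero the winner
    is decided by the tie rule alone and flagged low-confidence.
    """
    if not results:
        raise ValueError("no posterior results to select from")
    scores = [_score_one(r, clustered, config.rbo_p) for r in results]

    def sort_key(s: SelectionScore):
        return (-s.metric, s.params.beta, -s.params.alpha, s.params.gamma)

    winner = min(scores, key=sort_key)
    winner.winner = True
    if all(s.rbo == 0.0 for s in scores):
        winner.low_confidence = True
        logger.warning("all parameter sets have zero rank-biased overlap")
    return winner, scores


def performance_frame(scores: list[SelectionScore]) -> pd.DataFrame:
    """Parameter-performance table (one row per combination)."""
    return pd.DataFrame(
        {
            "alpha": [s.params.alpha for s in scores],
            "beta": [s.params.beta for s in scores],
            "gamma": [s.params.gamma for s in scores],
            "rbo": [s.rbo for s in scores],
            "entropy": [s.entropy for s in scores],
            "metric": [s.metric for s in scores],
            "winner": [s.winner for s in scores],
        }
    )
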