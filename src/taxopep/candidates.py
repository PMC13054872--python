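"""Candidate taxon selection.

Peptides mapping to very many proteins are discarded, mappings are
aggregated to the target taxonomic rank, and each taxon receives a weight

    W_T = sum over peptides i mapped to T of  #PSM_i / Deg_i

where Deg_i (the degeneracy) is the number of distinct taxa peptide i maps
to at the target rank.  Each peptide thus distributes exactly its PSM mass
across its taxa, so unique peptides contribute full weight while widely
shared peptides are discounted.  The graph admits the top-``taxa_limit``
taxa by weight, plus every taxon that is the sole mapping of some peptide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import RunConfig, ScoredPeptide, TaxonMapping
from .taxonomy import TaxonomyTable, TaxonomyError

__all__ = [
    "RankedMapping",
    "CandidateSet",
    "filter_peptides",
    "aggregate_to_rank",
    "taxon_weights",
    "select_candidates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedMapping:
    """A peptide's taxa after aggregation to the target rank."""

    sequence: str
    taxa_at_rank: frozenset[int]

    def __post_init__(self) -> None:
        if not self.taxa_at_rank:
            raise ValueError(f"peptide {self.sequence}: empty rank-aggregated taxa")

    @property
    def degeneracy(self) -> int:
        return len(self.taxa_at_rank)


@dataclass
class CandidateSet:
    """Taxa admitted to the graphical model.

    ``taxa`` is ordered by weight descending (ties by taxid ascending);
    ``peptide_edges`` maps each retained peptide to its candidate parents;
    ``unique_counts`` counts, per candidate, the peptides unique to it
    *within the candidate set* (shared peptides whose other parents were
    not admitted become unique in the graph).
    """

    taxa: list[tuple[int, float]]
    peptide_edges: dict[str, frozenset[int]]
    unique_counts: dict[int, int]

    @property
    def taxids(self) -> list[int]:
        return [t for t, _ in self.taxa]

    @property
    def weights(self) -> dict[int, float]:
        return dict(self.taxa)

    def detected_peptides(self) -> dict[int, set[str]]:
        """Per-candidate set of detected peptides mapping to it."""
        out: dict[int, set[str]] = {t: set() for t, _ in self.taxa}
        for seq, parents in self.peptide_edges.items():
            for t in parents:
                out[t].add(seq)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxid": self.taxids,
                "weight": [w for _, w in self.taxa],
                "unique_peptides": [self.unique_counts[t] for t in self.taxids],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def filter_peptides(
    mappings: list[TaxonMapping],
    taxonomy: TaxonomyTable,
    config: RunConfig,
) -> list[TaxonMapping]:
    """Drop unmapped peptides, peptides matching more proteins than the
    cutoff (strictly more), and — when a restriction taxid is set — peptides
    with no taxa inside that clade."""
    if config.restrict_taxid is not None and config.restrict_taxid not in taxonomy:
        raise TaxonomyError(f"restrict_taxid {config.restrict_taxid} not in taxonomy")
    allowed = (
        taxonomy.descendants(config.restrict_taxid)
        if config.restrict_taxid is not None
        else None
    )
    kept: list[TaxonMapping] = []
    n_unmapped = n_promiscuous = n_restricted = 0
    for m in mappings:
        if not m.is_mapped:
            n_unmapped += 1
            continue
        if m.protein_count > config.protein_count_cutoff:
            n_promiscuous += 1
            continue
        taxa = m.taxa if allowed is None else m.taxa & allowed
        if not taxa:
            n_restricted += 1
            continue
        kept.append(m if taxa == m.taxa else TaxonMapping(m.sequence, frozenset(taxa), m.protein_count))
    logger.info(
        "filter_peptides: kept %d / %d (unmapped %d, >%d proteins %d, outside restriction %d)",
        len(kept), len(mappings), n_unmapped, config.protein_count_cutoff,
        n_promiscuous, n_restricted,
    )
    return kept


def aggregate_to_rank(
    mappings: list[TaxonMapping],
    taxonomy: TaxonomyTable,
    target_rank: str,
) -> list[RankedMapping]:
    """Replace each mapped taxon by its ancestor at ``target_rank``.

    Taxa lacking an ancestor at that rank are dropped from the peptide's
    set; peptides whose set becomes empty are dropped entirely (logged).
    Duplicate ancestors merge, so degeneracy is recomputed at the target
    rank.
    """
    ranked: list[RankedMapping] = []
    n_dropped_taxa = n_dropped_peps = 0
    cache: dict[int, int | None] = {}
    for m in mappings:
        at_rank: set[int] = set()
        for t in m.taxa:
            if t not in cache:
                cache[t] = taxonomy.ancestor_at_rank(t, target_rank)
            anc = cache[t]
            if anc is None:
                n_dropped_taxa += 1
            else:
                at_rank.add(anc)
        if at_rank:
            ranked.append(RankedMapping(m.sequence, frozenset(at_rank)))
        else:
            n_dropped_peps += 1
    if n_dropped_taxa or n_dropped_peps:
        logger.warning(
            "aggregate_to_rank(%s): dropped %d taxon assignments without an "
            "ancestor at rank; %d peptides left unmapped",
            target_rank, n_dropped_taxa, n_dropped_peps,
        )
    return ranked


def taxon_weights(
    peptides: list[ScoredPeptide],
    ranked: list[RankedMapping],
) -> dict[int, float]:
    """PSM-mass weights W_T = sum_i psm_count_i / degeneracy_i."""
    psm = {p.sequence: p.psm_count for p in peptides}
    missing = [r.sequence for r in ranked if r.sequence not in psm]
    if missing:
        raise ValueError(f"peptides without score records: {sorted(missing)[:5]}")
    weights: dict[int, float] = {}
    for r in ranked:
        share = psm[r.sequence] / r.degeneracy
        for t in r.taxa_at_rank:
            weights[t] = weights.get(t, 0.0) + share
    return weights


def select_candidates(
    weights: dict[int, float],
    ranked: list[RankedMapping],
    config: RunConfig,
) -> CandidateSet:
    """Admit the top-``taxa_limit`` taxa by weight plus every taxon that is
    the sole mapping of some peptide; restrict peptide edges to candidates."""
    by_weight = sorted(weights, key=lambda t: (-weights[t], t))
    selected = set(by_weight[: config.taxa_limit])
    # A taxon carrying a globally unique peptide is always admitted.
    for r in ranked:
        if r.degeneracy == 1:
            selected.update(r.taxa_at_rank)

    peptide_edges: dict[str, frozenset[int]] = {}
    n_orphaned = 0
    for r in ranked:
        parents = r.taxa_at_rank & selected
        if parents:
            peptide_edges[r.sequence] = frozenset(parents)
        else:
            n_orphaned += 1
    if n_orphaned:
        logger.info("select_candidates: %d peptides have no candidate parent", n_orphaned)

    unique_counts = {t: 0 for t in selected}
    for parents in peptide_edges.values():
        if len(parents) == 1:
            (t,) = parents
            unique_counts[t] += 1

    ordered = sorted(selected, key=lambda t: (-weights.get(t, 0.0), t))
    return CandidateSet(
        taxa=[(t, weights.get(t, 0.0)) for t in ordered],
        peptide_edges=peptide_edges,
        unique_counts=unique_counts,
    )
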