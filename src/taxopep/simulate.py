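"""Synthetic mock communities with planted ground truth.

Emulates the lab-assembled benchmark mixtures used to validate taxonomic
profilers: a root -> genus -> species taxonomy, per-species proteomes made
of synthetic peptide tokens with controlled within-genus and cross-taxon
sharing, a planted set of truly present species, noisy per-peptide
detection, and score distributions mimicking rescored search output (true
peptides high-scoring, noise uniform).  The generator emits exactly the
three input files the pipeline reads, plus the ground truth needed for
precision/recall evaluation.

Peptide tokens are arbitrary strings, not realistic tryptic sequences —
the model consumes only the mapping structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PosteriorResult
from .io import ScoredPeptide, TaxonMapping, write_mapping
from .taxonomy import TaxonomyTable

__all__ = ["CommunitySpec", "GroundTruth", "SyntheticCommunity", "generate_community", "evaluate", "optimal_threshold"]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVW"))  # 19 letters, no ambiguous codes


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a simulated community.

    Defaults describe a small lab-assembled-style mixture: 16 species in 4
    genera, 60-peptide proteomes with 30% genus-level and 5% cross-taxon
    sharing, 6 planted species whose peptides are each detected with
    probability 0.5, and 30 spurious detections.
    """

    n_genera: int = 4
    species_per_genus: int = 4
    peptides_per_species: int = 60
    within_genus_share: float = 0.3
    cross_share: float = 0.05
    n_planted: int = 6
    planted: tuple[int, ...] | None = None  # explicit species taxids, optional
    detect_prob: float = 0.5
    noise_peptides: int = 30
    true_score_beta: tuple[float, float] = (8.0, 2.0)
    psm_rate: float = 0.5  # psm_count ~ 1 + Poisson(psm_rate)
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("within_genus_share", "cross_share", "detect_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_genera < 1 or self.species_per_genus < 1:
            raise ValueError("community must contain at least one species")


@dataclass
class GroundTruth:
    """Planted species and per-detected-peptide origin labels."""

    present: set[int]
    peptide_origin: dict[str, str]  # sequence -> "true" | "noise"


@dataclass
class SyntheticCommunity:
    """In-memory community: pipeline inputs plus ground truth."""

    taxonomy: TaxonomyTable
    mappings: list[TaxonMapping]
    peptides: list[ScoredPeptide]
    truth: GroundTruth
    spec: CommunitySpec
    species: list[int] = field(default_factory=list)
    proteomes: dict[int, set[str]] = field(default_factory=dict)

    def write(self, outdir) -> dict[str, Path]:
        """Write the three pipeline input files; returns their paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "taxonomy": outdir / "taxonomy.tsv",
            "mapping": outdir / "mapping.jsonl",
            "peptides": outdir / "peptides.tsv",
        }
        self.taxonomy.to_tsv(paths["taxonomy"])
        write_mapping(self.mappings, paths["mapping"])
        pd.DataFrame(
            {
                "peptide": [p.sequence for p in self.peptides],
                "score": [p.score for p in self.peptides],
                "psms": [p.psm_count for p in self.peptides],
            }
        ).to_csv(paths["peptides"], sep="\t", index=False)
        return paths


def _token(rng: np.random.Generator, length: int = 12) -> str:
    return "".join(rng.choice(_AA, size=length))


def generate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Build a community with planted present taxa, fully seed-reproducible."""
    rng = np.random.default_rng(spec.seed)

    # taxonomy: root(1) -> genera -> species
    parent = {1: 1}
    rank = {1: "no rank"}
    name = {1: "root"}
    species: list[int] = []
    species_of_genus: dict[int, list[int]] = {}
    next_id = 2
    for g in range(spec.n_genera):
        genus_id = next_id
        next_id += 1
        parent[genus_id] = 1
        rank[genus_id] = "genus"
        name[genus_id] = f"Genus_{g + 1}"
        species_of_genus[genus_id] = []
        for s in range(spec.species_per_genus):
            sp = next_id
            next_id += 1
            parent[sp] = genus_id
            rank[sp] = "species"
            name[sp] = f"Genus_{g + 1} species_{s + 1}"
            species.append(sp)
            species_of_genus[genus_id].append(sp)
    taxonomy = TaxonomyTable(parent=parent, rank=rank, name=name)

    # planted species
    if spec.planted is not None:
        planted = set(int(t) for t in spec.planted)
        outside = planted - set(species)
        if outside:
            raise ValueError(f"planted taxa outside the generated tree: {sorted(outside)}")
    else:
        n = min(spec.n_planted, len(species))
        planted = set(rng.choice(species, size=n, replace=False).tolist())

    # proteomes: unique + genus-shared + cross-shared tokens
    n_within = round(spec.within_genus_share * spec.peptides_per_species)
    n_cross = round(spec.cross_share * spec.peptides_per_species)
    n_unique = spec.peptides_per_species - n_within - n_cross
    proteome: dict[int, set[str]] = {sp: set() for sp in species}

    for genus_id, sibs in species_of_genus.items():
        # one shared pool per genus: every sibling carries all of it, so
        # within_genus_share is the exact shared fraction of each proteome
        pool = [_token(rng) for _ in range(n_within)]
        for sp in sibs:
            proteome[sp].update(pool)
            while len(proteome[sp]) < n_within + n_unique:
                proteome[sp].add(_token(rng))

    for sp in species:
        for _ in range(n_cross):
            other = int(rng.choice([s for s in species if s != sp]))
            tok = _token(rng)
            proteome[sp].add(tok)
            proteome[other].add(tok)

    # peptide -> taxa mapping derived from proteomes
    taxa_of: dict[str, set[int]] = {}
    for sp in species:
        for tok in proteome[sp]:
            taxa_of.setdefault(tok, set()).add(sp)

    # detections from planted species
    a, b = spec.true_score_beta
    detected: dict[str, ScoredPeptide] = {}
    origin: dict[str, str] = {}
    for sp in sorted(planted):
        for tok in sorted(proteome[sp]):
            if tok in detected:
                continue
            if rng.random() < spec.detect_prob:
                score = float(np.clip(rng.beta(a, b), 0.0, 1.0))
                psm = 1 + int(rng.poisson(spec.psm_rate))
                detected[tok] = ScoredPeptide(tok, score, psm)
                origin[tok] = "true"

    # spurious detections drawn from non-planted proteomes
    noise_candidates = sorted(
        tok for tok, taxa in taxa_of.items() if tok not in detected and not (taxa & planted)
    )
    n_noise = min(spec.noise_peptides, len(noise_candidates))
    if n_noise:
        for idx in rng.choice(len(noise_candidates), size=n_noise, replace=False):
            tok = noise_candidates[idx]
            detected[tok] = ScoredPeptide(tok, float(rng.random()), 1)
            origin[tok] = "noise"

    peptides = [detected[tok] for tok in sorted(detected)]
    mappings = [
        TaxonMapping(tok, frozenset(taxa_of[tok]), protein_count=len(taxa_of[tok]))
        for tok in sorted(detected)
    ]
    return SyntheticCommunity(
        taxonomy=taxonomy,
        mappings=mappings,
        peptides=peptides,
        truth=GroundTruth(present=planted, peptide_origin=origin),
        spec=spec,
        species=species,
        proteomes=proteome,
    )


def noiseless_variant(spec: CommunitySpec) -> CommunitySpec:
    """Same community design with perfect detection and no spurious hits."""
    return replace(spec, detect_prob=1.0, noise_peptides=0)


def evaluate(
    posteriors: PosteriorResult,
    truth: GroundTruth,
    thresholds,
    unique_counts: dict[int, int] | None = None,
    require_unique: bool = False,
) -> pd.DataFrame:
    """Precision / recall / F1 of ``marginal > threshold`` calls.

    With ``require_unique`` a taxon must additionally have at least one
    unique peptide (within the candidate set) to be called present.  An
    empty prediction set yields precision 0 with ``no_predictions`` set.
    """
    if not truth.present:
        raise ValueError("empty ground truth")
    rows = []
    for thr in thresholds:
        predicted = {t for t, m in posteriors.marginals.items() if m > thr}
        if require_unique and unique_counts is not None:
            predicted = {t for t in predicted if unique_counts.get(t, 0) >= 1}
        tp = len(predicted & truth.present)
        precision = tp / len(predicted) if predicted else 0.0
        recall = tp / len(truth.present)
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        rows.append(
            {
                "threshold": float(thr),
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "n_predicted": len(predicted),
                "no_predictions": not predicted,
            }
        )
    return pd.DataFrame(rows)


def optimal_threshold(table: pd.DataFrame) -> float:
    """Largest threshold attaining the maximal F1.

    The most stringent cutoff that retains peak F1: raising the threshold
    beyond it would start costing recall.
    """
    best = table["f1"].max()
    if not math.isfinite(best):
        raise ValueError("no finite F1 values")
    return float(table.loc[table["f1"] >= best - 1e-12, "threshold"].max())
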