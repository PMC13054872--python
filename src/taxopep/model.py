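"""Model/Results facade over the full profiling pipeline.

:class:`TaxonInferenceModel` is built from the three inputs (scored
peptides, peptide-taxon mapping, taxonomy) plus a :class:`RunConfig`;
``fit()`` runs filtering, rank aggregation, weighting, candidate selection,
the (alpha, beta, gamma) grid search with belief propagation, clustering
and parameter selection, and returns a :class:`TaxonInferenceResults`
carrying the winning posteriors, all per-combination selection scores, and
run diagnostics.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .candidates import (
    CandidateSet,
    aggregate_to_rank,
    filter_peptides,
    select_candidates,
    taxon_weights,
)
from .inference import PosteriorResult, grid_search
from .io import (
    RunConfig,
    ScoredPeptide,
    TaxonMapping,
    read_mapping,
    read_scored_peptides,
    write_results,
)
from .selection import (
    ClusteredList,
    SelectionScore,
    cluster_taxa,
    performance_frame,
    select_parameters,
)
from .taxonomy import TaxonomyTable

__all__ = ["TaxonInferenceModel", "TaxonInferenceResults"]


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class TaxonInferenceModel:
    """Taxonomic profiling model for one metaproteomic sample."""

    def __init__(
        self,
        peptides: list[ScoredPeptide],
        mappings: list[TaxonMapping],
        taxonomy: TaxonomyTable,
        config: RunConfig | None = None,
    ):
        self.peptides = list(peptides)
        self.mappings = list(mappings)
        self.taxonomy = taxonomy
        self.config = config or RunConfig()
        self.input_digests: dict[str, str] = {}

    @classmethod
    def from_files(
        cls,
        peptides_path,
        mapping_path,
        taxonomy_path,
        config: RunConfig | None = None,
    ) -> "TaxonInferenceModel":
        config = config or RunConfig()
        taxonomy = TaxonomyTable.from_tsv(taxonomy_path)
        model = cls(
            peptides=read_scored_peptides(peptides_path, config),
            mappings=read_mapping(mapping_path, taxonomy),
            taxonomy=taxonomy,
            config=config,
        )
        model.input_digests = {
            "peptides": _digest(peptides_path),
            "mapping": _digest(mapping_path),
            "taxonomy": _digest(taxonomy_path),
        }
        return model

    def build_candidates(self) -> CandidateSet:
        """Filtering, rank aggregation, Eq.-style PSM weighting, selection."""
        filtered = filter_peptides(self.mappings, self.taxonomy, self.config)
        ranked = aggregate_to_rank(filtered, self.taxonomy, self.config.target_rank)
        kept = {r.sequence for r in ranked}
        self._scored_kept = [p for p in self.peptides if p.sequence in kept]
        weights = taxon_weights(self._scored_kept, ranked)
        self._n_filtered = len(filtered)
        self._n_ranked = len(ranked)
        return select_candidates(weights, ranked, self.config)

    def fit(self) -> "TaxonInferenceResults":
        t0 = time.time()
        candidates = self.build_candidates()
        if not candidates.taxa:
            raise ValueError("no candidate taxa: nothing to infer")
        results = grid_search(candidates, self._scored_kept, self.config)
        clustered = cluster_taxa(
            candidates, threshold=self.config.cluster_threshold
        )
        winner, scores = select_parameters(results, clustered, self.config)
        best = next(r for r in results if r.params is winner.params)
        return TaxonInferenceResults(
            model=self,
            candidates=candidates,
            clustered=clustered,
            all_results=results,
            scores=scores,
            winner=winner,
            best=best,
            elapsed=time.time() - t0,
        )


@dataclass
class TaxonInferenceResults:
    """Fitted posteriors plus grid-search diagnostics."""

    model: TaxonInferenceModel
    candidates: CandidateSet
    clustered: ClusteredList
    all_results: list[PosteriorResult]
    scores: list[SelectionScore]
    winner: SelectionScore
    best: PosteriorResult
    elapsed: float = 0.0
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def marginals(self) -> dict[int, float]:
        return self.best.marginals

    @property
    def params(self):
        return self.winner.params

    def results_frame(self) -> pd.DataFrame:
        tax = self.model.taxonomy
        order = self.best.ranked_taxa()
        return pd.DataFrame(
            {
                "taxid": order,
                "name": [tax.name.get(t, "") for t in order],
                "rank": [tax.rank.get(t, "") for t in order],
                "posterior": [self.marginals[t] for t in order],
                "unique_peptides": [self.candidates.unique_counts.get(t, 0) for t in order],
                "weight": [self.candidates.weights.get(t, 0.0) for t in order],
            }
        )

    def performance_frame(self) -> pd.DataFrame:
        return performance_frame(self.scores)

    def to_csv(self, path) -> pd.DataFrame:
        return write_results(
            self.marginals,
            self.model.taxonomy,
            path,
            unique_counts=self.candidates.unique_counts,
            weights=self.candidates.weights,
        )

    def manifest(self) -> dict:
        """Reproducibility record: config, input digests, per-stage counts."""
        m = self.model
        return {
            "version": __version__,
            "config": m.config.to_dict(),
            "input_digests": m.input_digests,
            "winning_params": {
                "alpha": self.params.alpha,
                "beta": self.params.beta,
                "gamma": self.params.gamma,
                "regularized": self.params.regularized,
            },
            "counts": {
                "peptides_read": len(m.peptides),
                "mappings_read": len(m.mappings),
                "peptides_after_filter": getattr(m, "_n_filtered", None),
                "peptides_rank_mapped": getattr(m, "_n_ranked", None),
                "candidate_taxa": len(self.candidates.taxa),
                "cluster_heads": len(self.clustered.heads),
                "parameter_combinations": len(self.all_results),
                "bp_iterations_winner": self.best.iterations,
                "bp_converged_all": all(r.converged for r in self.all_results),
            },
            "elapsed_seconds": round(self.elapsed, 3),
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1, sort_keys=True)

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary, statsmodels-style."""
        p = self.params
        lines = [
            "Taxon inference results",
            "=" * 64,
            f"candidate taxa: {len(self.candidates.taxa)}"
            f"   peptides in graph: {len(self.best.peptide_marginals)}",
            f"grid combinations: {len(self.all_results)}"
            f"   winning (alpha, beta, gamma): ({p.alpha}, {p.beta}, {p.gamma})",
            f"RBO: {self.winner.rbo:.4f}   entropy: {self.winner.entropy:.4f}"
            f"   metric M: {self.winner.metric:.4g}",
            f"converged: {self.best.converged} ({self.best.iterations} sweeps)",
            "-" * 64,
            f"{'taxid':>8} {'posterior':>10} {'unique':>7}  name",
        ]
        for t in self.best.ranked_taxa()[:top]:
            lines.append(
                f"{t:>8} {self.marginals[t]:>10.4f} "
                f"{self.candidates.unique_counts.get(t, 0):>7}  "
                f"{self.model.taxonomy.name.get(t, '')}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def save_all(self, outdir) -> dict[str, Path]:
        """Write results CSV, performance CSV and manifest JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "results": outdir / "results.csv",
            "performance": outdir / "parameter_performance.csv",
            "manifest": outdir / "manifest.json",
        }
        self.to_csv(paths["results"])
        self.performance_frame().to_csv(paths["performance"], index=False)
        self.save_manifest(paths["manifest"])
        return paths
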