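"""Input/output layer: scored peptide lists, peptide-taxon mappings,
taxonomy tables, run configuration, and result CSVs.

File formats
------------
* scored peptides: CSV or TSV with a header naming a ``peptide`` and a
  ``score`` column (an optional ``psms`` column carries explicit
  spectrum-match counts).  Duplicate sequences are collapsed to a single
  record keeping the highest score; without an explicit count column the
  number of duplicate rows becomes the PSM count.
* peptide-taxon mapping: JSON lines, one object per peptide of the form
  ``{"peptide": str, "taxa": [int, ...], "protein_count": int}`` —
  a stable offline stand-in for a taxonomic annotation service response.
* taxonomy: 4-column TSV, see :mod:`taxopep.taxonomy`.
* results: CSV sorted by posterior descending, ties by taxid ascending.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

from .taxonomy import TaxonomyTable

__all__ = [
    "ScoredPeptide",
    "TaxonMapping",
    "RunConfig",
    "InputFormatError",
    "read_scored_peptides",
    "read_mapping",
    "write_mapping",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

# Standard 20 amino acids; search engines occasionally emit B/J/O/U/X/Z,
# which we accept with a warning rather than an error.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class InputFormatError(ValueError):
    """Raised for malformed input tables."""


@dataclass(frozen=True)
class ScoredPeptide:
    """A peptide sequence with a detection score and PSM multiplicity.

    ``score`` is the probability that the peptide is truly present in the
    sample (e.g. a rescored search-engine posterior); ``psm_count`` is the
    number of spectra matched to the sequence.
    """

    sequence: str
    score: float
    psm_count: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score outside [0,1]: {self.score!r} for {self.sequence}")
        if self.psm_count < 1:
            raise ValueError(f"psm_count must be >= 1, got {self.psm_count}")


@dataclass(frozen=True)
class TaxonMapping:
    """The set of taxa whose proteomes contain a peptide.

    ``protein_count`` is the number of proteins the peptide matched in the
    reference; peptides hitting very many proteins are typically conserved
    housekeeping sequence and carry little taxonomic signal.
    """

    sequence: str
    taxa: frozenset[int]
    protein_count: int = 0

    def __post_init__(self) -> None:
        if self.protein_count < 0:
            raise ValueError("protein_count must be non-negative")
        if self.protein_count > 0 and not self.taxa:
            raise ValueError(f"peptide {self.sequence}: proteins matched but no taxa")

    @property
    def is_mapped(self) -> bool:
        return bool(self.taxa)


@dataclass
class RunConfig:
    """Tunable knobs of the full pipeline with field-standard defaults.

    The candidate limit of 150 taxa, the 10,000-protein exclusion cutoff,
    the 27-combination (alpha, beta, gamma) grid and the 0.9 clustering
    threshold are the recommended defaults for metaproteomic samples.
    """

    taxa_limit: int = 150
    protein_count_cutoff: int = 10_000
    restrict_taxid: int | None = None
    target_rank: str = "species"
    regularized: bool = False
    alpha_grid: tuple[float, ...] = (0.85, 0.9, 0.99)
    beta_grid: tuple[float, ...] = (0.5, 0.6, 0.7)
    gamma_grid: tuple[float, ...] = (0.1, 0.3, 0.5)
    rbo_p: float = 0.9
    cluster_threshold: float = 0.9
    bp_tolerance: float = 1e-6
    bp_max_iters: int = 5000
    damping: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.taxa_limit < 1:
            raise ValueError("taxa_limit must be >= 1")
        if not 0.5 < self.cluster_threshold <= 1.0:
            raise ValueError("cluster_threshold must be in (0.5, 1]")
        if not 0.0 < self.rbo_p < 1.0:
            raise ValueError("rbo_p must be in (0,1)")
        for grid_name in ("alpha_grid", "beta_grid", "gamma_grid"):
            grid = tuple(getattr(self, grid_name))
            if not grid:
                raise ValueError(f"{grid_name} is empty")
            if any(not 0.0 < v < 1.0 for v in grid):
                raise ValueError(f"{grid_name} values must lie in (0,1)")
            object.__setattr__(self, grid_name, grid)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        out = {}
        for key, value in self.__dict__.items():
            out[key] = list(value) if isinstance(value, tuple) else value
        return out

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


# ---------------------------------------------------------------------------
# scored peptides
# ---------------------------------------------------------------------------

_PEPTIDE_ALIASES = ("peptide", "sequence", "peptides", "pep")
_SCORE_ALIASES = ("score", "probability", "prob")
_PSM_ALIASES = ("psms", "psm", "psm_count", "n_psms")


def _find_column(columns, aliases, what, path):
    lowered = {str(c).strip().lower(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    raise InputFormatError(f"{path}: no {what} column (looked for {', '.join(aliases)})")


def read_scored_peptides(path, config: RunConfig | None = None) -> list[ScoredPeptide]:
    """Read a scored peptide table, collapsing duplicate sequences.

    For a sequence occurring on several rows the highest score is kept and,
    unless an explicit PSM column is present, the row multiplicity becomes
    the PSM count.  Scores outside [0,1] are rejected.
    """
    # dtype=str + python float(): exact round-trip of written scores
    # (pandas' fast float parser can be off by one ulp)
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
    pep_col = _find_column(frame.columns, _PEPTIDE_ALIASES, "peptide", path)
    score_col = _find_column(frame.columns, _SCORE_ALIASES, "score", path)
    try:
        psm_col = _find_column(frame.columns, _PSM_ALIASES, "psm", path)
    except InputFormatError:
        psm_col = None

    scores = []
    for i, raw in enumerate(frame[score_col]):
        try:
            scores.append(float(raw))
        except (TypeError, ValueError):
            raise InputFormatError(
                f"{path}: non-numeric score at row {i + 2}"  # header + 1-based
            ) from None

    records: dict[str, dict] = {}
    nonstandard: set[str] = set()
    for i, raw_seq in enumerate(frame[pep_col]):
        seq = str(raw_seq).strip().upper()
        extra = set(seq) - STANDARD_RESIDUES
        if extra:
            nonstandard.add(seq)
        score = scores[i]
        psm = int(frame[psm_col].iloc[i]) if psm_col is not None else 1
        rec = records.get(seq)
        if rec is None:
            records[seq] = {"score": score, "psm": psm}
        else:
            rec["score"] = max(rec["score"], score)
            rec["psm"] = max(rec["psm"], psm) if psm_col is not None else rec["psm"] + 1
    if nonstandard:
        warnings.warn(
            f"{len(nonstandard)} peptide(s) contain non-standard residues "
            f"(e.g. {sorted(nonstandard)[0]})",
            stacklevel=2,
        )
    return [
        ScoredPeptide(seq, rec["score"], rec["psm"]) for seq, rec in records.items()
    ]


# ---------------------------------------------------------------------------
# peptide-taxon mapping (JSON lines)
# ---------------------------------------------------------------------------


def read_mapping(path, taxonomy: TaxonomyTable) -> list[TaxonMapping]:
    """Read a JSON-lines peptide-taxon mapping, validating taxon ids.

    Unmapped peptides (empty taxa, zero protein count) are retained so the
    caller can report them; every referenced taxid must exist in the
    taxonomy.
    """
    mappings: list[TaxonMapping] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise InputFormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            seq = str(obj["peptide"]).upper()
            if seq in seen:
                raise InputFormatError(f"{path}:{lineno}: duplicate peptide {seq}")
            seen.add(seq)
            taxa = frozenset(int(t) for t in obj.get("taxa", []))
            taxonomy.validate_taxids(taxa)
            mappings.append(
                TaxonMapping(seq, taxa, int(obj.get("protein_count", len(taxa))))
            )
    return mappings


def write_mapping(mappings, path) -> None:
    with open(path, "w") as fh:
        for m in mappings:
            fh.write(
                json.dumps(
                    {
                        "peptide": m.sequence,
                        "taxa": sorted(m.taxa),
                        "protein_count": m.protein_count,
                    }
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["taxid", "name", "rank", "posterior", "unique_peptides", "weight"]


def write_results(
    marginals: dict[int, float],
    taxonomy: TaxonomyTable,
    path,
    unique_counts: dict[int, int] | None = None,
    weights: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Write the per-taxon posterior table, sorted by posterior descending
    (ties broken by taxid ascending). Returns the frame written."""
    unique_counts = unique_counts or {}
    weights = weights or {}
    order = sorted(marginals, key=lambda t: (-marginals[t], t))
    frame = pd.DataFrame(
        {
            "taxid": order,
            "name": [taxonomy.name.get(t, "") for t in order],
            "rank": [taxonomy.rank.get(t, "") for t in order],
            "posterior": [marginals[t] for t in order],
            "unique_peptides": [unique_counts.get(t, 0) for t in order],
            "weight": [weights.get(t, 0.0) for t in order],
        },
        columns=RESULT_COLUMNS,
    )
    frame.to_csv(path, index=False)
    return frame


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
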