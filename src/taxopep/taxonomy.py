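"""Minimal NCBI-style taxonomy table.

A taxonomy is a rooted tree of integer taxon identifiers, each carrying a
rank label and a name.  Only the operations the profiling pipeline needs are
provided: ancestor lookup at a target rank, descendant sets for taxid
restriction, and validation of externally supplied taxon ids.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["TaxonomyTable", "TaxonomyError"]


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy tables or unknown taxon ids."""


@dataclass
class TaxonomyTable:
    """Rooted taxonomy with parent links, ranks and names.

    The root is the unique node whose parent is itself (NCBI convention,
    taxid 1) or a non-positive sentinel.
    """

    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str]
    root: int = field(init=False)

    def __post_init__(self) -> None:
        roots = [t for t, p in self.parent.items() if p == t or p <= 0]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children: dict[int, list[int]] = {t: [] for t in self.parent}
        for t, p in self.parent.items():
            if t == self.root:
                continue
            if p not in self.parent:
                raise TaxonomyError(f"taxid {t} has unknown parent {p}")
            self._children[p].append(t)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen: set[int] = set()
        for start in self.parent:
            path = []
            t = start
            while t not in seen and t != self.root:
                path.append(t)
                seen.add(t)
                t = self.parent[t]
                if t in path:
                    raise TaxonomyError(f"cycle in parent links at taxid {t}")
            seen.update(path)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TaxonomyTable":
        """Build from a DataFrame with columns taxid, parent, rank, name."""
        required = {"taxid", "parent", "rank", "name"}
        missing = required - set(frame.columns)
        if missing:
            raise TaxonomyError(f"taxonomy table missing columns: {sorted(missing)}")
        taxids = frame["taxid"].astype(int)
        if taxids.duplicated().any():
            dupes = sorted(taxids[taxids.duplicated()].unique().tolist())
            raise TaxonomyError(f"duplicate taxids: {dupes}")
        return cls(
            parent=dict(zip(taxids, frame["parent"].astype(int))),
            rank=dict(zip(taxids, frame["rank"].astype(str))),
            name=dict(zip(taxids, frame["name"].astype(str))),
        )

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        """Read a 4-column TSV (taxid, parent, rank, name) with header."""
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        rows = sorted(self.parent)
        pd.DataFrame(
            {
                "taxid": rows,
                "parent": [self.parent[t] for t in rows],
                "rank": [self.rank[t] for t in rows],
                "name": [self.name[t] for t in rows],
            }
        ).to_csv(path, sep="\t", index=False)

    # -- queries -----------------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def validate_taxids(self, taxids) -> None:
        unknown = sorted(t for t in set(taxids) if t not in self.parent)
        if unknown:
            raise TaxonomyError(f"unknown taxids: {unknown}")

    def lineage(self, taxid: int) -> list[int]:
        """Path from ``taxid`` up to and including the root."""
        if taxid not in self.parent:
            raise TaxonomyError(f"unknown taxid: {taxid}")
        out = [taxid]
        while out[-1] != self.root:
            out.append(self.parent[out[-1]])
        return out

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Nearest ancestor (or self) with the given rank, else None."""
        for t in self.lineage(taxid):
            if self.rank[t] == rank:
                return t
        return None

    def descendants(self, taxid: int) -> set[int]:
        """All taxa in the subtree rooted at ``taxid``, including itself."""
        if taxid not in self.parent:
            raise TaxonomyError(f"unknown taxid: {taxid}")
        out = {taxid}
        queue = deque([taxid])
        while queue:
            for child in self._children[queue.popleft()]:
                out.add(child)
                queue.append(child)
        return out
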