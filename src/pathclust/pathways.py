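"""Pathway databases and pathway-protein matrices at the three q-value cutoffs.

A pathway database maps named pathways to protein accession sets (standard
GMT format).  For each cancer subtype, proteins passing each of the three
significance cutoffs (q < 0.2, q < 0.1, q < 0.05) are crossed with pathway
membership to form integer matrices Q1, Q2, Q3: entry (i, j) of Q_k is k if
protein j belongs to pathway i *and* passed cutoff k, else 0.  The merged
matrix takes the elementwise maximum, so each entry records the index of
the strictest cutoff the protein passes — the screens are nested, so a 3
implies 1 and 2.  A pathway profile is the per-pathway count of significant
member proteins at one cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayDB",
    "read_gmt",
    "write_gmt",
    "build_cutoff_matrix",
    "merge_matrices",
    "PathwayProteinMatrix",
    "build_pathway_protein_matrix",
    "pathway_profile",
]


@dataclass(frozen=True)
class PathwayDB:
    """Ordered collection of named pathways with protein-accession members."""

    pathways: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.pathways)

    def proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.pathways.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.pathways[name]


def read_gmt(path) -> PathwayDB:
    """Parse a GMT file (name TAB description TAB member...).

    Duplicate members within a pathway are deduplicated; a duplicated
    pathway name or a line with fewer than three fields is an error.
    """
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            if name in pathways:
                raise ValueError(f"{path}: line {lineno}: duplicate pathway {name!r}")
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: line {lineno}: pathway {name!r} is empty")
            pathways[name] = frozenset(members)
            descriptions[name] = desc
    if not pathways:
        raise ValueError(f"{path}: no pathways found")
    return PathwayDB(pathways=pathways, descriptions=descriptions)


def write_gmt(db: PathwayDB, path) -> None:
    """Write a pathway database in GMT format (members sorted for determinism)."""
    with open(path, "w") as fh:
        for name in db.names:
            desc = db.descriptions.get(name, "na")
            members = "\t".join(sorted(db[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def build_cutoff_matrix(
    significant: Iterable[str],
    db: PathwayDB,
    k: int,
    pathways: Sequence[str] | None = None,
    proteins: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Integer pathway x protein matrix for one cutoff.

    Entry is *k* where the protein is both a pathway member and in the
    cutoff-k significant set, else 0.  Row/column indices default to the
    full database and the significant set but may be fixed to a common
    (union) index so matrices are comparable across subtypes.
    """
    if k not in (1, 2, 3):
        raise ValueError("cutoff index must be 1, 2 or 3")
    sig = set(significant)
    if pathways is None:
        pathways = db.names
    if proteins is None:
        proteins = sorted(sig)
    if sig and not (sig & set(db.proteins())):
        logger.warning("no overlap between significant proteins and pathway database")
    mat = np.zeros((len(pathways), len(proteins)), dtype=int)
    col_of = {p: j for j, p in enumerate(proteins)}
    for i, pw in enumerate(pathways):
        for p in db[pw] & sig:
            if p in col_of:
                mat[i, col_of[p]] = k
    return pd.DataFrame(mat, index=list(pathways), columns=list(proteins))


def _align_pad(frames: Sequence[pd.DataFrame]) -> list[pd.DataFrame]:
    rows = sorted(set().union(*[f.index for f in frames]))
    cols = sorted(set().union(*[f.columns for f in frames]))
    return [f.reindex(index=rows, columns=cols, fill_value=0) for f in frames]


def merge_matrices(
    q1: pd.DataFrame, q2: pd.DataFrame, q3: pd.DataFrame
) -> pd.DataFrame:
    """Elementwise maximum of the three cutoff matrices on the union index."""
    a, b, c = _align_pad([q1, q2, q3])
    merged = np.maximum(np.maximum(a.to_numpy(), b.to_numpy()), c.to_numpy())
    if merged.size and (merged.min() < 0 or merged.max() > 3):
        raise ValueError("merged entries must lie in {0, 1, 2, 3}")
    return pd.DataFrame(merged, index=a.index, columns=a.columns)


@dataclass
class PathwayProteinMatrix:
    """Merged pathway x protein matrix for one subtype.

    ``values`` holds entries in {0,1,2,3} (strictest cutoff passed);
    ``direction`` mirrors it with "up"/"down"/"" annotations that do not
    enter any distance arithmetic.
    """

    values: pd.DataFrame
    direction: pd.DataFrame | None = None
    subtype: str = ""

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.size and (v.min() < 0 or v.max() > 3):
            raise ValueError("entries must lie in {0, 1, 2, 3}")

    def changed_counts(self) -> pd.Series:
        """Per-pathway number of changed (nonzero-entry) proteins."""
        return (self.values > 0).sum(axis=1)

    def profile(self, cutoff: int = 1) -> pd.Series:
        """Per-pathway count of proteins passing at least *cutoff*."""
        return (self.values >= cutoff).sum(axis=1)


def build_pathway_protein_matrix(
    significant_sets: Mapping[int, Iterable[str]],
    db: PathwayDB,
    pathways: Sequence[str] | None = None,
    proteins: Sequence[str] | None = None,
    directions: Mapping[str, str] | None = None,
    subtype: str = "",
) -> PathwayProteinMatrix:
    """Cross nested significant sets {1: ..., 2: ..., 3: ...} with the DB and merge."""
    mats = []
    if proteins is None:
        union: set[str] = set()
        for s in significant_sets.values():
            union |= set(s)
        proteins = sorted(union)
    if pathways is None:
        pathways = db.names
    for k in (1, 2, 3):
        mats.append(
            build_cutoff_matrix(
                significant_sets.get(k, ()), db, k, pathways=pathways, proteins=proteins
            )
        )
    merged = merge_matrices(*mats)
    direction = None
    if directions is not None:
        arrow = pd.DataFrame("", index=merged.index, columns=merged.columns)
        for p in merged.columns:
            if p in directions:
                hit = merged[p] > 0
                arrow.loc[hit, p] = directions[p]
        direction = arrow
    return PathwayProteinMatrix(values=merged, direction=direction, subtype=subtype)


def pathway_profile(
    significant: Iterable[str] | PathwayProteinMatrix,
    db: PathwayDB | None = None,
    cutoff: int = 1,
    pathways: Sequence[str] | None = None,
) -> pd.Series:
    """Per-pathway count of significant proteins.

    Accepts either a significant protein set plus a database, or a merged
    :class:`PathwayProteinMatrix` (counting entries >= *cutoff* per row).
    """
    if isinstance(significant, PathwayProteinMatrix):
        return significant.profile(cutoff)
    if db is None:
        raise ValueError("a pathway database is required with a protein set")
    sig = set(significant)
    if pathways is None:
        pathways = db.names
    return pd.Series(
        {pw: len(db[pw] & sig) for pw in pathways}, name="n_significant"
    ).reindex(pathways)
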