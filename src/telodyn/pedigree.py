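"""Pedigree handling and kinship-matrix computation.

The additive-genetic covariance among relatives is parameterized by the
kinship coefficient phi(i, j): the probability that an allele sampled at
random from individual i and one sampled from j are identical by descent.
For a non-inbred individual phi(i, i) = 0.5, a parent-offspring or
full-sib pair has phi = 0.25, half sibs 0.125, and 2*phi scales the
additive-genetic covariance between phenotypes.

Kinship is computed by the standard tabular recursion evaluated in
topological (parents-before-offspring) order:

    phi(i, i) = 0.5 * (1 + phi(f_i, m_i))
    phi(i, j) = 0.5 * (phi(f_i, j) + phi(m_i, j))    for j already placed

with founders assumed non-inbred and mutually unrelated, and a missing
single parent treated as a unique phantom founder (contributing zero
co-ancestry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "Pedigree",
    "KinshipMatrix",
    "read_pedigree",
    "write_pedigree",
    "compute_kinship",
    "mean_pairwise_kinship",
]

#: Sentinel used for an unknown parent in the on-disk format.
MISSING_PARENT = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree: cycle, dangling parent, or a
    sex/parent-role conflict."""


@dataclass(frozen=True)
class Pedigree:
    """An immutable pedigree: individuals with optional sire/dam links.

    Parameters
    ----------
    table:
        DataFrame with columns ``id``, ``sire``, ``dam``, ``sex``, ``age``.
        ``sire``/``dam`` are ``None`` for founders; ``sex`` is ``"F"``,
        ``"M"`` or ``""`` (unknown); ``age`` is in years (NaN allowed).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["id", "sire", "dam", "sex", "age"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {missing}")
        ids = t["id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise PedigreeError(f"duplicate individual id: {dup!r}")
        known = set(ids)
        for role in ("sire", "dam"):
            parents = t[role].dropna()
            unknown = set(parents.astype(str)) - known
            if unknown:
                raise PedigreeError(
                    f"{role} ids not present in pedigree: {sorted(unknown)[:5]}"
                )
        sex_of = dict(zip(ids, t["sex"]))
        for role, want in (("sire", "M"), ("dam", "F")):
            for p in t[role].dropna().astype(str):
                if sex_of.get(p) not in (want, "", None):
                    raise PedigreeError(
                        f"{role} {p!r} has recorded sex {sex_of[p]!r}"
                    )
        # acyclicity check doubles as construction of the topological order
        object.__setattr__(self, "_topo_order", _topological_order(t))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"].astype(str))

    @property
    def topological_order(self) -> list[str]:
        """Ids ordered so that every parent precedes its offspring."""
        return list(self._topo_order)

    def founders(self) -> list[str]:
        t = self.table
        mask = t["sire"].isna() & t["dam"].isna()
        return list(t.loc[mask, "id"].astype(str))

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        row = self.table.set_index(self.table["id"].astype(str)).loc[individual]
        sire = None if pd.isna(row["sire"]) else str(row["sire"])
        dam = None if pd.isna(row["dam"]) else str(row["dam"])
        return sire, dam


def _topological_order(table: pd.DataFrame) -> list[str]:
    """Kahn's algorithm over parent->child edges; raises on a cycle."""
    ids = list(table["id"].astype(str))
    index = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i, (s, d) in enumerate(zip(table["sire"], table["dam"])):
        for p in (s, d):
            if pd.notna(p):
                children[index[str(p)]].append(i)
                indeg[i] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    order: list[str] = []
    while queue:
        i = queue.pop()
        order.append(ids[i])
        for j in children[i]:
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    if len(order) != n:
        raise PedigreeError("pedigree contains a cycle")
    return order


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric matrix of kinship coefficients for an ordered id list."""

    ids: list[str]
    phi: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        if phi.shape != (len(self.ids), len(self.ids)):
            raise ValueError("phi shape does not match id list")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(
            self, "_index", {v: k for k, v in enumerate(self.ids)}
        )

    def submatrix(self, subset: list[str]) -> "KinshipMatrix":
        idx = [self._index[s] for s in subset]
        return KinshipMatrix(list(subset), self.phi[np.ix_(idx, idx)])

    def additive_relationship(self) -> np.ndarray:
        """The numerator relationship matrix A = 2*phi."""
        return 2.0 * self.phi

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


def read_pedigree(path) -> Pedigree:
    """Read a tab-delimited pedigree file.

    Expected columns: ``id``, ``sire``, ``dam``, ``sex``, ``age`` with
    ``0`` denoting an unknown parent.  Row order is immaterial.
    """
    t = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    for role in ("sire", "dam"):
        t[role] = t[role].where(t[role] != MISSING_PARENT, other=pd.NA)
    t["sex"] = t["sex"].fillna("").astype(str)
    t["age"] = pd.to_numeric(t.get("age"), errors="coerce")
    return Pedigree(t.reset_index(drop=True))


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the tab-delimited pedigree format (unknown parent = 0)."""
    t = ped.table.copy()
    for role in ("sire", "dam"):
        t[role] = t[role].fillna(MISSING_PARENT)
    t.to_csv(path, sep="\t", index=False)


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship coefficients for every pair in the pedigree.

    Runs the tabular recursion in topological order; output row/column
    order follows the pedigree table, not the topological order.
    """
    ids = ped.ids
    index = {v: k for k, v in enumerate(ids)}
    t = ped.table
    sire = [None if pd.isna(s) else index[str(s)] for s in t["sire"]]
    dam = [None if pd.isna(d) else index[str(d)] for d in t["dam"]]

    n = len(ids)
    phi = np.zeros((n, n))
    placed: list[int] = []
    placed_mask = np.zeros(n, dtype=bool)
    for label in ped.topological_order:
        i = index[label]
        f, m = sire[i], dam[i]
        row = np.zeros(n)
        if f is not None:
            row += phi[f]
        if m is not None:
            row += phi[m]
        row *= 0.5
        sel = placed_mask.copy()
        phi[i, sel] = row[sel]
        phi[sel, i] = row[sel]
        inbreeding = phi[f, m] if (f is not None and m is not None) else 0.0
        phi[i, i] = 0.5 * (1.0 + inbreeding)
        placed.append(i)
        placed_mask[i] = True
    return KinshipMatrix(ids, phi)


def mean_pairwise_kinship(km: KinshipMatrix, subset: list[str] | None = None) -> float:
    """Mean kinship over unordered distinct pairs (diagonal excluded)."""
    if subset is None:
        subset = km.ids
    if len(subset) < 2:
        raise ValueError("mean pairwise kinship needs at least 2 individuals")
    sub = km.submatrix(list(subset)).phi
    n = sub.shape[0]
    off_sum = sub.sum() - np.trace(sub)
    return float(off_sum / (n * (n - 1)))
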