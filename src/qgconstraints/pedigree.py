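"""Pedigree handling and the additive relationship matrix.

A pedigree is a set of (individual, sire, dam) records. The additive
relationship matrix A gives the expected additive-genetic relatedness
between every pair of individuals; its diagonal is 1 + F (inbreeding
coefficient). A is built with the tabular method, processing individuals
in topological order (parents before offspring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = ""
DEFAULT_UNKNOWN_CODES = frozenset({"", "NA", "0", "*"})


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (cycles, duplicates)."""


@dataclass
class Pedigree:
    """Validated pedigree in topological order (founders first).

    ``ids[i]``'s parents are ``ids[sire[i]]`` / ``ids[dam[i]]``;
    a parent index of -1 means unknown.
    """

    ids: list[str]
    sire: np.ndarray  # int64 indices into ids, -1 for unknown
    dam: np.ndarray
    n_inserted_founders: int = 0

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise PedigreeError("duplicate individual ids")
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise PedigreeError("parent index arrays must match id count")
        # topological order: every parent index precedes its offspring
        idx = np.arange(n)
        for par in (self.sire, self.dam):
            known = par >= 0
            if np.any(par[known] >= idx[known]):
                raise PedigreeError("records are not in topological order")
        self._index = {iid: i for i, iid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.ids, dtype=object)
        sire = np.where(self.sire >= 0, ids[np.maximum(self.sire, 0)], UNKNOWN)
        dam = np.where(self.dam >= 0, ids[np.maximum(self.dam, 0)], UNKNOWN)
        return pd.DataFrame({"id": ids, "sire": sire, "dam": dam})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RelatednessMatrix:
    """Dense additive relationship matrix with its id ordering."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    def __getitem__(self, pair) -> float:
        i, j = pair
        if isinstance(i, str):
            i = self.ids.index(i)
        if isinstance(j, str):
            j = self.ids.index(j)
        return float(self.values[i, j])

    @property
    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0

    def write_csv(self, path, dense: bool = False) -> None:
        if dense:
            pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)
            return
        iu = np.triu_indices(len(self.ids))
        vals = self.values[iu]
        keep = vals != 0.0
        pd.DataFrame(
            {"i": np.asarray(self.ids, dtype=object)[iu[0][keep]],
             "j": np.asarray(self.ids, dtype=object)[iu[1][keep]],
             "value": vals[keep]}
        ).to_csv(path, index=False)


def _toposort(records: list[tuple[str, str, str]]) -> Pedigree:
    """Order records founders-first; auto-insert missing parents as founders."""
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        raise PedigreeError(f"duplicate individual id: {dup.index[0]!r}")
    known = set(ids)
    parents = {r[0]: (r[1], r[2]) for r in records}
    inserted = []
    for _, s, d in records:
        for p in (s, d):
            if p != UNKNOWN and p not in known:
                known.add(p)
                inserted.append(p)
                parents[p] = (UNKNOWN, UNKNOWN)
    if inserted:
        warnings.warn(
            f"{len(inserted)} parent id(s) absent from the id column; inserted as founders",
            stacklevel=3,
        )
    # Kahn's algorithm on parent -> offspring edges
    all_ids = inserted + ids
    n_unresolved = {
        iid: sum(1 for p in parents[iid] if p != UNKNOWN) for iid in all_ids
    }
    children: dict[str, list[str]] = {iid: [] for iid in all_ids}
    for iid in all_ids:
        for p in parents[iid]:
            if p != UNKNOWN:
                children[p].append(iid)
    order = [iid for iid in all_ids if n_unresolved[iid] == 0]
    head = 0
    while head < len(order):
        cur = order[head]
        head += 1
        for ch in children[cur]:
            n_unresolved[ch] -= 1
            if n_unresolved[ch] == 0:
                order.append(ch)
    if len(order) != len(all_ids):
        stuck = next(iid for iid in all_ids if n_unresolved[iid] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving {stuck!r}")
    pos = {iid: i for i, iid in enumerate(order)}
    sire = np.array([pos[parents[iid][0]] if parents[iid][0] != UNKNOWN else -1 for iid in order])
    dam = np.array([pos[parents[iid][1]] if parents[iid][1] != UNKNOWN else -1 for iid in order])
    return Pedigree(order, sire, dam, n_inserted_founders=len(inserted))


def read_pedigree(path, unknown_codes=DEFAULT_UNKNOWN_CODES) -> Pedigree:
    """Read a pedigree CSV with columns id, sire, dam.

    Unknown parents may be encoded by any value in ``unknown_codes``
    (missing cells always count as unknown). Records may appear in any
    order; the result is topologically sorted.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree file must have columns {sorted(required)}")
    codes = set(unknown_codes) | {""}

    def norm(v: str) -> str:
        v = v.strip()
        return UNKNOWN if v in codes else v

    records = [
        (row.id.strip(), norm(row.sire), norm(row.dam))
        for row in df.itertuples(index=False)
    ]
    return _toposort(records)


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    """Build a Pedigree from a DataFrame with id/sire/dam columns (strings, '' = unknown)."""
    records = [(str(r.id), str(r.sire), str(r.dam)) for r in df.itertuples(index=False)]
    return _toposort(records)


def prune_informative(ped: Pedigree, phenotyped: set[str]) -> Pedigree:
    """Keep phenotyped individuals plus the ancestors linking them.

    Retains the union of the phenotyped set and every ancestor of a
    phenotyped individual; unphenotyped individuals with no phenotyped
    descendant contribute no likelihood information and are dropped.
    Idempotent.
    """
    if not phenotyped:
        raise ValueError("phenotyped set is empty")
    present = set(ped.ids) & set(phenotyped)
    missing = set(phenotyped) - present
    if missing:
        warnings.warn(f"{len(missing)} phenotyped id(s) not in pedigree; ignored", stacklevel=2)
    if not present:
        raise ValueError("no phenotyped individual found in the pedigree")
    n = len(ped)
    keep = np.zeros(n, dtype=bool)
    for iid in present:
        keep[ped.index_of(iid)] = True
    # sweep from offspring to founders: parents of kept individuals are kept
    for i in range(n - 1, -1, -1):
        if keep[i]:
            if ped.sire[i] >= 0:
                keep[ped.sire[i]] = True
            if ped.dam[i] >= 0:
                keep[ped.dam[i]] = True
    idx = np.flatnonzero(keep)
    remap = {old: new for new, old in enumerate(idx)}
    sire = np.array([remap[s] if s >= 0 and keep[s] else -1 for s in ped.sire[idx]])
    dam = np.array([remap[d] if d >= 0 and keep[d] else -1 for d in ped.dam[idx]])
    return Pedigree([ped.ids[i] for i in idx], sire, dam)


def additive_relationship(ped: Pedigree) -> RelatednessMatrix:
    """Tabular-method additive relationship matrix with inbreeding.

    a_ii = 1 + 0.5 * a(sire_i, dam_i); a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))
    for j earlier in the topological order; unknown parents contribute 0.
    """
    n = len(ped)
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
            row = 0.5 * (A[:i, s] + A[:i, d])
        elif s >= 0:
            A[i, i] = 1.0
            row = 0.5 * A[:i, s]
        elif d >= 0:
            A[i, i] = 1.0
            row = 0.5 * A[:i, d]
        else:
            A[i, i] = 1.0
            row = np.zeros(i)
        A[i, :i] = row
        A[:i, i] = row
    return RelatednessMatrix(list(ped.ids), A)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-individual inbreeding coefficient F = 0.5 * a(sire, dam).

    Runs the tabular recursion keeping the full matrix; intended for
    pedigrees small enough for a dense A (n <= ~10,000).
    """
    return additive_relationship(ped).inbreeding


def a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules, with inbreeding.

    A^-1 = sum over individuals of (1/m_i) * w_i w_i' where w_i has 1 at i,
    -1/2 at each known parent, and m_i is the Mendelian-segregation
    variance coefficient: 0.5 - 0.25 (F_s + F_d) with both parents known,
    0.75 - 0.25 F_p with one, 1 with none.
    """
    n = len(ped)
    F = inbreeding_coefficients(ped)
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        parents = [p for p in (s, d) if p >= 0]
        m = 1.0 - 0.25 * sum(1.0 + F[p] for p in parents)
        inv_m = 1.0 / m
        entries = [(i, 1.0)] + [(p, -0.5) for p in parents]
        for a, va in entries:
            for b, vb in entries:
                rows.append(a)
                cols.append(b)
                vals.append(inv_m * va * vb)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


RELATEDNESS_BIN_WIDTH = 0.05


def relatedness_summary(ped: Pedigree) -> pd.DataFrame:
    """Histogram of pairwise (off-diagonal) relatedness values.

    Fixed bins of width 0.05 from 0 up to the maximum observed value
    (at least [0, 1)); counts sum to n*(n-1)/2.
    """
    A = additive_relationship(ped).values
    n = A.shape[0]
    pairs = A[np.triu_indices(n, k=1)]
    top = max(1.0, float(pairs.max()) + 1e-12 if pairs.size else 1.0)
    n_bins = int(np.ceil(round(top / RELATEDNESS_BIN_WIDTH, 9)))
    edges = np.arange(n_bins + 1) * RELATEDNESS_BIN_WIDTH
    counts, _ = np.histogram(pairs, bins=edges)
    # np.histogram closes the last bin; keep half-open semantics by construction
    return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})
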