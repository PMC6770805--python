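"""Pedigree construction, inbreeding and the numerator relationship matrix.

The additive (numerator) relationship matrix ``A`` carries the expected
proportion of alleles identical by descent between every pair of animals in
a pedigree; its diagonal is ``1 + F`` with ``F`` the inbreeding coefficient.
The animal-model evaluation never forms ``A`` itself for a large herdbook:
it needs only the sparse inverse ``A^-1``, which Henderson's rules assemble
directly from the parent pointers and the per-animal Mendelian-sampling
variances.  Inbreeding coefficients are obtained with the Meuwissen & Luo
recursion, which scales to herdbook-size pedigrees.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = ""
#: tokens accepted in input files as "parent unknown"
_UNKNOWN_TOKENS = {"", "0", "NA", "na", "nan", "None", None, 0}

BUCK = "buck"
DOE = "doe"


class PedigreeError(ValueError):
    """Structural defect in a pedigree (cycle, duplicate, sex conflict)."""


@dataclass
class Pedigree:
    """A validated, topologically sorted pedigree.

    Attributes
    ----------
    ids : list of str
        Animal identifiers, ancestors before descendants.
    sire, dam : ndarray of int
        Positional parent indices, ``-1`` for unknown.
    sex : ndarray of object
        ``"buck"`` or ``"doe"`` per animal.
    birth_year : ndarray of int
        Year of birth (0 where unrecorded, e.g. inserted parents).
    inbreeding : ndarray of float
        Wright's F per animal; founders are 0.
    generation_depth : ndarray of int
        1 for founders, ``1 + max(parent depths)`` otherwise.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    birth_year: np.ndarray
    inbreeding: np.ndarray = field(default=None, repr=False)
    generation_depth: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.generation_depth is None:
            depth = np.ones(len(self.ids), dtype=int)
            for i in range(len(self.ids)):
                pd_ = [depth[p] for p in (self.sire[i], self.dam[i]) if p >= 0]
                if pd_:
                    depth[i] = 1 + max(pd_)
            self.generation_depth = depth
        if self.inbreeding is None and len(self.ids):
            self.inbreeding = inbreeding_coefficients(self)
        elif self.inbreeding is None:
            self.inbreeding = np.zeros(0)
        self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self):
        return len(self.ids)

    @property
    def index(self) -> dict:
        """Mapping animal_id -> position in topological order."""
        return self._index

    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def offspring_counts(self) -> np.ndarray:
        counts = np.zeros(len(self), dtype=int)
        for p in self.sire:
            if p >= 0:
                counts[p] += 1
        for p in self.dam:
            if p >= 0:
                counts[p] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        sid = [self.ids[s] if s >= 0 else UNKNOWN for s in self.sire]
        did = [self.ids[d] if d >= 0 else UNKNOWN for d in self.dam]
        return pd.DataFrame(
            {
                "animal_id": self.ids,
                "sire_id": sid,
                "dam_id": did,
                "sex": self.sex,
                "birth_year": self.birth_year,
                "inbreeding": self.inbreeding,
                "generation_depth": self.generation_depth,
            }
        )


@dataclass
class RelationshipSummary:
    n_animals: int
    mean_inbreeding: float
    relatedness_range: tuple
    offspring_range: tuple
    depth_range: tuple


def _norm_parent(tok):
    if isinstance(tok, float) and np.isnan(tok):
        return UNKNOWN
    if tok in _UNKNOWN_TOKENS:
        return UNKNOWN
    return str(tok)


def validate_pedigree(raw_records) -> Pedigree:
    """Validate raw parentage rows and return a topologically sorted Pedigree.

    Parameters
    ----------
    raw_records : DataFrame or iterable of tuples
        Columns/fields ``animal_id, sire_id, dam_id[, sex[, birth_year]]``.
        Parents referenced but not listed are inserted as founders with the
        sex their parental role implies.

    Raises
    ------
    PedigreeError
        On duplicate ids, an animal used as both sire and dam, a listed
        animal whose declared sex conflicts with its parental role, or a
        parentage cycle (the error names one animal on the cycle).
    """
    if isinstance(raw_records, pd.DataFrame):
        rows = raw_records.to_dict("records")
    else:
        rows = []
        for r in raw_records:
            if isinstance(r, dict):
                rows.append(dict(r))
            else:
                r = tuple(r)
                keys = ("animal_id", "sire_id", "dam_id", "sex", "birth_year")
                rows.append(dict(zip(keys, r)))

    seen = set()
    declared_sex = {}
    birth_year = {}
    parents = {}
    for r in rows:
        aid = str(r["animal_id"])
        if aid in seen:
            raise PedigreeError(f"duplicate animal_id {aid!r}")
        seen.add(aid)
        s = _norm_parent(r.get("sire_id", UNKNOWN))
        d = _norm_parent(r.get("dam_id", UNKNOWN))
        if s != UNKNOWN and s == d:
            raise PedigreeError(f"animal {s!r} used as both sire and dam of {aid!r}")
        parents[aid] = (s, d)
        sx = r.get("sex")
        if sx in (BUCK, DOE):
            declared_sex[aid] = sx
        by = r.get("birth_year")
        if by is not None and not (isinstance(by, float) and np.isnan(by)):
            birth_year[aid] = int(by)

    used_as_sire, used_as_dam = set(), set()
    for s, d in parents.values():
        if s != UNKNOWN:
            used_as_sire.add(s)
        if d != UNKNOWN:
            used_as_dam.add(d)
    both = used_as_sire & used_as_dam
    if both:
        raise PedigreeError(f"animal {sorted(both)[0]!r} used as both sire and dam")
    for a in used_as_sire:
        if declared_sex.get(a, BUCK) != BUCK:
            raise PedigreeError(f"sire {a!r} declared {declared_sex[a]!r}")
    for a in used_as_dam:
        if declared_sex.get(a, DOE) != DOE:
            raise PedigreeError(f"dam {a!r} declared {declared_sex[a]!r}")

    # insert referenced-only parents as founders
    for a in used_as_sire | used_as_dam:
        if a not in parents:
            parents[a] = (UNKNOWN, UNKNOWN)
            declared_sex.setdefault(a, BUCK if a in used_as_sire else DOE)

    # Kahn toposort, deterministic by input-then-id order
    order_hint = {a: i for i, a in enumerate(parents)}
    children = {a: [] for a in parents}
    indeg = {a: 0 for a in parents}
    for a, (s, d) in parents.items():
        for p in (s, d):
            if p != UNKNOWN:
                children[p].append(a)
                indeg[a] += 1
    ready = sorted((a for a, k in indeg.items() if k == 0), key=order_hint.get)
    heap = [(order_hint[a], a) for a in ready]
    heapq.heapify(heap)
    topo = []
    while heap:
        _, a = heapq.heappop(heap)
        topo.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, (order_hint[c], c))
    if len(topo) != len(parents):
        on_cycle = next(a for a, k in indeg.items() if k > 0)
        raise PedigreeError(f"pedigree cycle detected involving animal {on_cycle!r}")

    idx = {a: i for i, a in enumerate(topo)}
    n = len(topo)
    sire = np.full(n, -1, dtype=int)
    dam = np.full(n, -1, dtype=int)
    sex = np.empty(n, dtype=object)
    year = np.zeros(n, dtype=int)
    for a, i in idx.items():
        s, d = parents[a]
        sire[i] = idx[s] if s != UNKNOWN else -1
        dam[i] = idx[d] if d != UNKNOWN else -1
        sex[i] = declared_sex.get(a, DOE)
        year[i] = birth_year.get(a, 0)
    return Pedigree(topo, sire, dam, sex, year)


def read_pedigree_csv(path) -> Pedigree:
    """Read the pedigree CSV dialect (animal_id, sire_id, dam_id, sex, birth_year)."""
    df = pd.read_csv(path, dtype={"animal_id": str, "sire_id": str, "dam_id": str})
    return validate_pedigree(df)


def mendelian_sampling_variances(ped: Pedigree) -> np.ndarray:
    """Per-animal within-family (Mendelian sampling) variance scalars d_i.

    d_i = 0.5 - 0.25 (F_s + F_d) with both parents known, 0.75 - 0.25 F_p
    with one, and 1 for founders.  These are the diagonal of the D matrix of
    the A = T D T' decomposition, so log|A| = sum(log d).
    """
    F = ped.inbreeding
    d = np.ones(len(ped))
    for i in range(len(ped)):
        s, m = ped.sire[i], ped.dam[i]
        if s >= 0 and m >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[m])
        elif s >= 0 or m >= 0:
            d[i] = 0.75 - 0.25 * F[max(s, m)]
    return d


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo recursion.

    For each animal the algorithm accumulates the coefficients L_ij of its
    ancestors (processing youngest-first with a max-heap) and evaluates
    a_ii = sum_j L_ij^2 d_j, whence F_i = a_ii - 1.  O(total ancestor count),
    no dense matrix.
    """
    n = len(ped.ids)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    d = np.ones(n)  # Mendelian sampling variances, filled as we go
    for i in range(n):
        s, m = sire[i], dam[i]
        if s >= 0 and m >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[m])
        elif s >= 0 or m >= 0:
            d[i] = 0.75 - 0.25 * F[max(s, m)]
        if s < 0 or m < 0:
            F[i] = 0.0  # at least one unknown parent -> founder contribution
            continue
        coef = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            c = coef.pop(j, None)
            if c is None:
                continue
            aii += c * c * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p in coef:
                        coef[p] += 0.5 * c
                    else:
                        coef[p] = 0.5 * c
                        heapq.heappush(heap, -p)
        F[i] = aii - 1.0
    return F


def additive_relationship(ped: Pedigree, subset=None) -> np.ndarray:
    """Dense numerator relationship submatrix by the tabular method.

    Builds A over the requested animals plus all their ancestors (so entries
    are exact) and returns the rows/columns for `subset` in the order given.
    Intended for subsets up to a couple of thousand animals.
    """
    if subset is None:
        keep = list(range(len(ped)))
    else:
        try:
            keep = [ped.index[a] for a in subset]
        except KeyError as e:
            raise KeyError(f"unknown animal id {e.args[0]!r}") from None
    needed = set(keep)
    stack = list(keep)
    while stack:
        i = stack.pop()
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0 and p not in needed:
                needed.add(p)
                stack.append(p)
    order = sorted(needed)  # topological (positions are topologically sorted)
    pos = {g: k for k, g in enumerate(order)}
    m = len(order)
    A = np.zeros((m, m))
    for k, g in enumerate(order):
        s, d = ped.sire[g], ped.dam[g]
        ks = pos.get(s, -1) if s >= 0 else -1
        kd = pos.get(d, -1) if d >= 0 else -1
        for j in range(k):
            a = 0.0
            if ks >= 0:
                a += 0.5 * A[ks, j]
            if kd >= 0:
                a += 0.5 * A[kd, j]
            A[k, j] = A[j, k] = a
        aii = 1.0
        if ks >= 0 and kd >= 0:
            aii += 0.5 * A[ks, kd]
        A[k, k] = aii
    sel = [pos[g] for g in keep]
    return A[np.ix_(sel, sel)]


def a_inverse_sparse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of the numerator relationship matrix (Henderson's rules).

    Accommodates inbreeding through the Mendelian-sampling variances: each
    animal contributes 1/d_i to the block over (itself, sire, dam) with the
    usual (1, -1/2, -1/2) pattern.
    """
    n = len(ped)
    d = mendelian_sampling_variances(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        alpha = 1.0 / d[i]
        s, m = ped.sire[i], ped.dam[i]
        add(i, i, alpha)
        for p in (s, m):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
                add(p, p, 0.25 * alpha)
        if s >= 0 and m >= 0:
            add(s, m, 0.25 * alpha)
            add(m, s, 0.25 * alpha)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def write_a_inverse_triplets(ainv: sparse.spmatrix, path) -> None:
    """Export A^-1 as 1-based coordinate triplets (i, j, value)."""
    coo = ainv.tocoo()
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1}\t{j + 1}\t{v:.12g}\n")


def _pairwise_relationship(ped: Pedigree, i: int, j: int, cache: dict) -> float:
    """Recursive additive relationship a(i, j) with memoisation."""
    if i < 0 or j < 0:
        return 0.0
    if j > i:
        i, j = j, i
    key = (i, j)
    if key in cache:
        return cache[key]
    if i == j:
        v = 1.0 + ped.inbreeding[i]
    else:
        v = 0.5 * (
            _pairwise_relationship(ped, ped.sire[i], j, cache)
            + _pairwise_relationship(ped, ped.dam[i], j, cache)
        )
    cache[key] = v
    return v


def pedigree_summary(
    ped: Pedigree, max_dense: int = 2000, n_pair_sample: int = 100_000, seed: int = 0
) -> RelationshipSummary:
    """Mean inbreeding, relatedness range, offspring and depth ranges.

    For pedigrees above `max_dense` animals the per-animal mean relatedness
    is estimated from a seeded random sample of `n_pair_sample` pairs rather
    than the full O(n^2) matrix.
    """
    n = len(ped)
    if n == 0:
        return RelationshipSummary(0, 0.0, (0.0, 0.0), (0, 0), (0, 0))
    counts = ped.offspring_counts()
    if n <= max_dense:
        A = additive_relationship(ped)
        if n > 1:
            off = A - np.diag(np.diag(A))
            per_animal = off.sum(axis=1) / (n - 1)
        else:
            per_animal = np.zeros(1)
        rel_range = (float(per_animal.min()), float(per_animal.max()))
    else:
        rng = np.random.default_rng(seed)
        cache = {}
        sums = np.zeros(n)
        npair = np.zeros(n)
        ii = rng.integers(0, n, size=n_pair_sample)
        jj = rng.integers(0, n, size=n_pair_sample)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            a = _pairwise_relationship(ped, int(i), int(j), cache)
            sums[i] += a
            sums[j] += a
            npair[i] += 1
            npair[j] += 1
        ok = npair > 0
        per_animal = sums[ok] / npair[ok]
        rel_range = (float(per_animal.min()), float(per_animal.max()))
    return RelationshipSummary(
        n_animals=n,
        mean_inbreeding=float(ped.inbreeding.mean()),
        relatedness_range=rel_range,
        offspring_range=(int(counts.min()), int(counts.max())),
        depth_range=(int(ped.generation_depth.min()), int(ped.generation_depth.max())),
    )
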