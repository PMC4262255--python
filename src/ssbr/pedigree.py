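"""Pedigrees and the additive (numerator) relationship matrix.

A pedigree is a list of (individual, sire, dam) records. Individuals are
re-indexed so that parents always precede offspring; all matrices produced
here are indexed by that internal position, with id <-> position maps carried
on every result. The population is partitioned into set 1 (non-genotyped) and
set 2 (genotyped) individuals, the partition that drives single-step
imputation and the mixed-model equations downstream.

The additive relationship matrix A is built two ways: densely by the tabular
method (for small pedigrees and as an oracle), and as a sparse inverse built
directly from Henderson's rules with inbreeding handled by the
Meuwissen-Luo/Quaas recursion for Mendelian-sampling variances.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "RelationshipSystem",
    "PedigreeError",
    "read_pedigree",
    "build_A",
    "build_A_inverse",
]

#: sentinel for an unknown parent after normalization
MISSING = None

_MISSING_TOKENS = {"0", "", ".", "na", "nan", "none"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, bad parents)."""


def _normalize_parent(tok) -> str | None:
    if tok is None:
        return MISSING
    s = str(tok).strip()
    if s.lower() in _MISSING_TOKENS:
        return MISSING
    return s


@dataclass
class Pedigree:
    """Topologically ordered pedigree with a genotyped/non-genotyped split.

    Attributes
    ----------
    records : list of (id, sire-or-None, dam-or-None), in topological order.
    order : dict mapping external id -> internal position.
    genotyped_flag : boolean array over internal positions; True = set 2.
    """

    records: list[tuple[str, str | None, str | None]]
    order: dict[str, int] = field(init=False)
    genotyped_flag: np.ndarray = field(init=False)

    def __post_init__(self):
        self.order = {rec[0]: i for i, rec in enumerate(self.records)}
        if len(self.order) != len(self.records):
            dupes = pd.Series([r[0] for r in self.records])
            raise PedigreeError(
                f"duplicate individual ids: {sorted(dupes[dupes.duplicated()])}"
            )
        for ind, sire, dam in self.records:
            for par in (sire, dam):
                if par is not None:
                    if par not in self.order:
                        raise PedigreeError(f"parent {par!r} of {ind!r} is not a record")
                    if self.order[par] >= self.order[ind]:
                        raise PedigreeError(
                            f"parent {par!r} does not precede offspring {ind!r}"
                        )
        self.genotyped_flag = np.zeros(len(self.records), dtype=bool)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records,
        genotyped_ids=(),
        genotyped_order: list[str] | None = None,
    ) -> "Pedigree":
        """Build from unordered (id, sire, dam) triples.

        Unknown parents may be None, "0" or "". Parents that are named but
        never listed as individuals are auto-added as founders (with a
        warning). Records are re-ordered parents-before-offspring; a cycle is
        a hard error naming the individuals involved.

        ``genotyped_order`` optionally fixes the ordering of set 2 (normally
        the genotype-file row order, so genotype rows align without a join).
        """
        raw = [(str(i).strip(), _normalize_parent(s), _normalize_parent(d))
               for i, s, d in records]
        ids = {r[0] for r in raw}
        parents = {p for r in raw for p in r[1:] if p is not None}
        orphans = sorted(parents - ids)
        if orphans:
            warnings.warn(
                f"parents not listed as individuals, added as founders: {orphans}",
                stacklevel=2,
            )
            raw = [(p, MISSING, MISSING) for p in orphans] + raw

        # Kahn topological sort, stable in input order
        by_id = {r[0]: r for r in raw}
        n_parents_placed: dict[str, int] = {}
        children: dict[str, list[str]] = {i: [] for i in by_id}
        for ind, sire, dam in raw:
            deps = [p for p in (sire, dam) if p is not None]
            n_parents_placed[ind] = len(deps)
            for p in deps:
                children[p].append(ind)
        ready = [r[0] for r in raw if n_parents_placed[r[0]] == 0]
        ordered: list[str] = []
        seen = set()
        while ready:
            nxt: list[str] = []
            for ind in ready:
                ordered.append(ind)
                seen.add(ind)
                for ch in children[ind]:
                    n_parents_placed[ch] -= 1
                    if n_parents_placed[ch] == 0:
                        nxt.append(ch)
            ready = nxt
        if len(ordered) != len(raw):
            cyc = sorted(set(by_id) - seen)
            raise PedigreeError(f"pedigree contains a cycle involving: {cyc}")

        ped = cls([by_id[i] for i in ordered])
        ped.set_genotyped(genotyped_ids, genotyped_order)
        return ped

    def set_genotyped(self, genotyped_ids, genotyped_order=None) -> None:
        genotyped_ids = {str(g).strip() for g in genotyped_ids}
        unknown = genotyped_ids - set(self.order)
        if unknown:
            raise PedigreeError(f"genotyped ids not in pedigree: {sorted(unknown)}")
        self.genotyped_flag = np.array(
            [rec[0] in genotyped_ids for rec in self.records], dtype=bool
        )
        if genotyped_order is not None:
            got = [str(g).strip() for g in genotyped_order]
            if set(got) != genotyped_ids:
                raise PedigreeError("genotyped_order does not match genotyped_ids")
            self._set2_ids = got
        else:
            self._set2_ids = [r[0] for r, f in zip(self.records, self.genotyped_flag) if f]

    # -- views ------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def set1_ids(self) -> list[str]:
        """Non-genotyped ids, in topological order."""
        return [r[0] for r, f in zip(self.records, self.genotyped_flag) if not f]

    @property
    def set2_ids(self) -> list[str]:
        """Genotyped ids; ordering follows the genotype file when given."""
        return list(self._set2_ids)

    @property
    def set1_positions(self) -> np.ndarray:
        return np.flatnonzero(~self.genotyped_flag)

    @property
    def set2_positions(self) -> np.ndarray:
        return np.array([self.order[i] for i in self._set2_ids], dtype=np.int64)

    def parent_positions(self) -> np.ndarray:
        """(n, 2) array of sire/dam internal positions, -1 for unknown."""
        out = np.full((self.n, 2), -1, dtype=np.int64)
        for i, (_, s, d) in enumerate(self.records):
            if s is not None:
                out[i, 0] = self.order[s]
            if d is not None:
                out[i, 1] = self.order[d]
        return out


@dataclass
class RelationshipSystem:
    """Sparse A-inverse with its set-1/set-2 partition blocks.

    ``A11``, ``A12``, ``A21``, ``A22`` are blocks of the *inverse* matrix
    (superscript blocks A^{ij}), indexed by set-1 and set-2 positions. A^{11}
    is, up to 1/sigma^2_eps, the precision matrix of the imputation residual.
    """

    pedigree: Pedigree
    A_inv: sp.csr_matrix
    inbreeding: np.ndarray

    def __post_init__(self):
        p1 = self.pedigree.set1_positions
        p2 = self.pedigree.set2_positions
        Ai = self.A_inv.tocsr()
        self.A11 = Ai[np.ix_(p1, p1)].tocsc()
        self.A12 = Ai[np.ix_(p1, p2)].tocsc()
        self.A21 = Ai[np.ix_(p2, p1)].tocsc()
        self.A22 = Ai[np.ix_(p2, p2)].tocsc()
        self._A11_solve = None

    @property
    def n1(self) -> int:
        return self.A11.shape[0]

    @property
    def n2(self) -> int:
        return self.A22.shape[0]

    def solve_A11(self, b: np.ndarray) -> np.ndarray:
        """Solve A^{11} x = b, factorizing A^{11} once and reusing it."""
        if self.n1 == 0:
            return np.zeros_like(b)
        if self._A11_solve is None:
            if self.n1 == 1:
                d = self.A11[0, 0]
                if d <= 0:
                    raise np.linalg.LinAlgError("A^{11} is not positive definite")
                self._A11_solve = lambda v: v / d
            else:
                lu = sp.linalg.splu(self.A11.tocsc())
                self._A11_solve = lu.solve
        return self._A11_solve(np.asarray(b, dtype=float))


def read_pedigree(path, genotyped_ids=(), genotyped_order=None) -> Pedigree:
    """Read a 3-column pedigree file (header id,sire,dam; comma or whitespace
    delimited; missing parent 0 or empty) and flag the genotyped set."""
    if isinstance(path, io.IOBase):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise PedigreeError("empty pedigree file")
    sep = "," if "," in lines[0] else None
    rows = []
    for ln in lines:
        parts = [p.strip() for p in (ln.split(sep) if sep else ln.split())]
        rows.append(parts)
    if rows and rows[0][0].lower() in {"id", "individual", "animal"}:
        rows = rows[1:]
    records = []
    for parts in rows:
        if len(parts) < 3:
            parts = parts + [""] * (3 - len(parts))
        records.append((parts[0], parts[1], parts[2]))
    return Pedigree.from_records(records, genotyped_ids, genotyped_order)


def build_A(ped: Pedigree) -> np.ndarray:
    """Dense additive relationship matrix by the tabular method.

    Founders get diagonal 1 and zero off-diagonals among themselves;
    a_ij = (a_{i,s(j)} + a_{i,d(j)}) / 2 for i < j, and the diagonal is
    1 + a_{sd}/2 (inbreeding). O(n^2): intended for small-to-moderate
    pedigrees and as the oracle for the sparse inverse.
    """
    n = ped.n
    par = ped.parent_positions()
    A = np.zeros((n, n))
    for j in range(n):
        s, d = par[j]
        for i in range(j):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[i, s]
            if d >= 0:
                a += 0.5 * A[i, d]
            A[i, j] = A[j, i] = a
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def _inbreeding(par: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients F_i = a_{sd}/2 by memoized tabular recursion.

    Pairwise relationships are resolved lazily (Quaas-style recursion on the
    younger member of each pair), so no dense A is formed; the memo is shared
    across the whole pedigree.
    """
    n = par.shape[0]
    memo: dict[tuple[int, int], float] = {}

    def a(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            s, d = par[i]
            val = 1.0 + 0.5 * a(s, d)
        else:
            s, d = par[j]  # recurse through the younger individual's parents
            val = 0.5 * (a(i, s) + a(i, d))
        memo[key] = val
        return val

    F = np.zeros(n)
    for i in range(n):
        s, d = par[i]
        if s >= 0 and d >= 0:
            F[i] = 0.5 * a(s, d)
    return F


def build_A_inverse(ped: Pedigree) -> RelationshipSystem:
    """Sparse A-inverse by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of individual i is
    d_i = 0.5 - 0.25 (F_s + F_d) with both parents known,
    d_i = 0.75 - 0.25 F_p with one known parent, and 1 for founders; the
    inverse is the sum over individuals of the usual rank-one contributions
    scaled by 1/d_i. Raises for a degenerate (non-positive) d_i.
    """
    n = ped.n
    par = ped.parent_positions()
    F = _inbreeding(par)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = par[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * F[p]
        else:
            di = 1.0
        if di <= 1e-12:
            raise np.linalg.LinAlgError(
                f"singular Mendelian-sampling variance for {ped.records[i][0]!r}"
            )
        b = 1.0 / di
        add(i, i, b)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * b)
                add(p, i, -0.5 * b)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * b)
    A_inv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A_inv.sum_duplicates()
    return RelationshipSystem(ped, A_inv, F)
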