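"""Pedigree container and pedigree-based relationship machinery.

Implements the numerator relationship matrix A by the tabular method,
per-animal inbreeding coefficients by the Meuwissen–Luo ancestor-tracing
recursion, and the sparse inverse A⁻¹ assembled from Mendelian-sampling
variances (Henderson's rules, accounting for inbreeding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = "0"


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Parameters
    ----------
    ids : sequence of str
        Animal identifiers, unique, in an order where every parent precedes
        its offspring (enforced / re-established at construction).
    sire, dam : int arrays
        Parent indices into ``ids``; -1 marks an unknown parent.
    generation : int array, optional
        Generation label per animal (founders = 0). Derived from pedigree
        depth when not supplied.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None
    sex: np.ndarray | None = None  # 'M'/'F', optional
    _index: dict[str, int] = field(init=False, repr=False)
    _F: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        if len(set(self.ids)) != len(self.ids):
            raise PedigreeError("duplicate animal ids")
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        for par in (self.sire, self.dam):
            if par.shape != (n,):
                raise PedigreeError("parent array length mismatch")
            if np.any(par >= np.arange(n)):
                raise PedigreeError("pedigree not topologically ordered")
        self._index = {a: k for k, a in enumerate(self.ids)}
        if self.generation is None:
            gen = np.zeros(n, dtype=np.int64)
            for i in range(n):
                g = 0
                if self.sire[i] >= 0:
                    g = gen[self.sire[i]] + 1
                if self.dam[i] >= 0:
                    g = max(g, gen[self.dam[i]] + 1)
                gen[i] = g
            self.generation = gen
        else:
            self.generation = np.asarray(self.generation, dtype=np.int64)

    # ------------------------------------------------------------------
    @classmethod
    def from_parent_map(
        cls,
        records: Iterable[tuple[str, str, str]],
        generation: Sequence[int] | None = None,
    ) -> "Pedigree":
        """Build from (animal, sire, dam) string triples; "0"/""/NA = unknown.

        Records may arrive in any order; a topological sort (Kahn) is applied.
        Parents that never appear as animals are added as founders.
        """
        recs = [(str(a), str(s), str(d)) for a, s, d in records]
        missing = {"", UNKNOWN, "NA", "nan", "None"}
        known = {a for a, _, _ in recs}
        extra = []
        for _, s, d in recs:
            for p in (s, d):
                if p not in missing and p not in known:
                    known.add(p)
                    extra.append((p, UNKNOWN, UNKNOWN))
        recs = extra + recs
        parents = {a: (s if s not in missing else None, d if d not in missing else None) for a, s, d in recs}
        # Kahn topological sort
        order: list[str] = []
        placed: set[str] = set()
        pending = list(parents)
        guard = 0
        while pending:
            rest = []
            progressed = False
            for a in pending:
                s, d = parents[a]
                if (s is None or s in placed) and (d is None or d in placed):
                    order.append(a)
                    placed.add(a)
                    progressed = True
                else:
                    rest.append(a)
            if not progressed:
                raise PedigreeError(f"cyclic pedigree involving: {rest[:5]}")
            pending = rest
            guard += 1
            if guard > len(parents) + 1:  # pragma: no cover
                raise PedigreeError("topological sort failed")
        idx = {a: k for k, a in enumerate(order)}
        sire = np.array([idx[parents[a][0]] if parents[a][0] else -1 for a in order])
        dam = np.array([idx[parents[a][1]] if parents[a][1] else -1 for a in order])
        gen = None
        if generation is not None:
            gmap = dict(zip((str(a) for a, _, _ in recs[len(extra):]), generation))
            gen = np.array([gmap.get(a, 0) for a in order])
        return cls(order, sire, dam, gen)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str).fillna(UNKNOWN)
        cols = list(df.columns[:3])
        return cls.from_parent_map(df[cols].itertuples(index=False, name=None))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [self.ids[s] if s >= 0 else UNKNOWN for s in self.sire],
                "dam": [self.ids[d] if d >= 0 else UNKNOWN for d in self.dam],
            }
        ).to_csv(path, index=False)

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[str(a)] for a in ids], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message clarity
            raise PedigreeError(f"unknown animal id {e.args[0]!r}") from None

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    # ------------------------------------------------------------------
    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F by the Meuwissen–Luo recursion.

        For each animal the row of L (from A = LDL') is traced over its
        ancestors; a_ii = Σ_j L_ij² d_j and F_i = a_ii − 1. Mendelian
        sampling variances d_j use F of j's parents, with an unknown parent
        contributing as F = −1 (i.e. d = 0.75 − 0.25·F_known for one known
        parent, d = 1 for none).
        """
        if self._F is not None:
            return self._F
        n = len(self)
        F = np.zeros(n)
        sire, dam = self.sire, self.dam
        d = np.empty(n)
        for i in range(n):
            Fs = F[sire[i]] if sire[i] >= 0 else -1.0
            Fd = F[dam[i]] if dam[i] >= 0 else -1.0
            d[i] = 0.5 - 0.25 * (Fs + Fd)
            if sire[i] < 0 and dam[i] < 0:
                F[i] = 0.0
                continue
            # trace L-row of i over ancestors, descending index order
            v: dict[int, float] = {i: 1.0}
            a_ii = 0.0
            todo = {i}
            while todo:
                j = max(todo)
                todo.discard(j)
                vj = v[j]
                a_ii += vj * vj * d[j]
                for p in (sire[j], dam[j]):
                    if p >= 0:
                        v[p] = v.get(p, 0.0) + 0.5 * vj
                        todo.add(p)
            F[i] = a_ii - 1.0
        self._F = F
        return F

    def mendelian_variance(self) -> np.ndarray:
        """Within-family (Mendelian sampling) variance d_i in units of σ²a."""
        F = self.inbreeding()
        Fs = np.where(self.sire >= 0, F[np.maximum(self.sire, 0)], -1.0)
        Fd = np.where(self.dam >= 0, F[np.maximum(self.dam, 0)], -1.0)
        return 0.5 - 0.25 * (Fs + Fd)

    # ------------------------------------------------------------------
    def relationship_matrix(self, subset: Sequence[str] | None = None) -> "RelationshipMatrix":
        """Numerator relationship matrix A by the tabular method.

        a_ii = 1 + a_sd/2 and a_ij = (a_js + a_jd)/2, with terms involving an
        unknown parent set to zero. ``subset`` extracts the rows/columns of
        the listed ids from the full-pedigree A (used for A11/A12/A22).
        """
        n = len(self)
        A = np.zeros((n, n))
        sire, dam = self.sire, self.dam
        for i in range(n):
            s, d = sire[i], dam[i]
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
            A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        if subset is None:
            return RelationshipMatrix("A", A, list(self.ids))
        k = self.index_of(subset)
        return RelationshipMatrix("A", A[np.ix_(k, k)], [str(a) for a in subset])

    def a_inverse(self) -> "RelationshipMatrix":
        """Sparse A⁻¹ from per-animal Mendelian-sampling variances.

        Contribution rules for animal i with parents s, d and α_i = 1/d_i:
        add α to (i,i); −α/2 to (i,s),(i,d) and transposes; α/4 to the
        parent block — terms with unknown parents dropped.
        """
        n = len(self)
        dvec = self.mendelian_variance()
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        ar = np.arange(n)
        alpha = 1.0 / dvec
        def add(r, c, v):
            rows.append(np.asarray(r)); cols.append(np.asarray(c)); vals.append(np.asarray(v))
        add(ar, ar, alpha)
        for par in ("s", "d"):
            p = self.sire if par == "s" else self.dam
            m = p >= 0
            add(ar[m], p[m], -0.5 * alpha[m])
            add(p[m], ar[m], -0.5 * alpha[m])
        for p1 in (self.sire, self.dam):
            for p2 in (self.sire, self.dam):
                m = (p1 >= 0) & (p2 >= 0)
                add(p1[m], p2[m], 0.25 * alpha[m])
        Ainv = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
        ).tocsr()
        return RelationshipMatrix("Ainv", Ainv, list(self.ids))


@dataclass
class RelationshipMatrix:
    """Symmetric kinship-type matrix tagged by kind, with an id↔index map.

    kind ∈ {A, Ainv, A22, G, Gstar, Ginv, H, Hinv}. Inverse kinds are held
    sparse (CSR); the rest dense.
    """

    kind: str
    values: np.ndarray | sp.spmatrix
    ids: list[str]

    KINDS = ("A", "Ainv", "A22", "G", "Gstar", "Ginv", "H", "Hinv")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown relationship kind {self.kind!r}")
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape inconsistent with id list")
        self._index = {a: k for k, a in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self._index[str(a)] for a in ids], dtype=np.int64)

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def submatrix(self, ids: Sequence[str], kind: str | None = None) -> "RelationshipMatrix":
        k = self.index_of(ids)
        v = self.dense()[np.ix_(k, k)]
        return RelationshipMatrix(kind or self.kind, v, [str(a) for a in ids])

    def to_triplets(self, path, tol: float = 0.0) -> None:
        """Write as 3-column triplet text: id_i, id_j, value (upper triangle)."""
        v = self.values.tocoo() if sp.issparse(self.values) else sp.coo_matrix(self.values)
        with open(path, "w") as fh:
            fh.write("id_i\tid_j\tvalue\n")
            for i, j, x in zip(v.row, v.col, v.data):
                if i <= j and abs(x) > tol:
                    fh.write(f"{self.ids[i]}\t{self.ids[j]}\t{x:.10g}\n")

    @classmethod
    def from_triplets(cls, path, kind: str, ids: Sequence[str]) -> "RelationshipMatrix":
        ids = [str(a) for a in ids]
        idx = {a: k for k, a in enumerate(ids)}
        df = pd.read_csv(path, sep="\t", dtype={"id_i": str, "id_j": str})
        n = len(ids)
        M = np.zeros((n, n))
        for i, j, x in df.itertuples(index=False):
            a, b = idx[i], idx[j]
            M[a, b] = x
            M[b, a] = x
        if kind in ("Ainv", "Hinv", "Ginv"):
            return cls(kind, sp.csr_matrix(M), ids)
        return cls(kind, M, ids)
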