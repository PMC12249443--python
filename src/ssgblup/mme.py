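"""Henderson's mixed-model equations for single-trait animal models.

Assembles the coefficient matrix and right-hand side for
y = Xb + Z1 a + Z2 pe + Z3 m + e with a (and m) ~ N(0, K σ²) for K = A or
H, pe ~ N(0, I σ²pe). The system is held in the variance-ratio form
(multiplied through by σ²e): C = W'W + blockdiag(0, λa K⁻¹, λpe I, λm K⁻¹)
so that C⁻¹ σ²e gives prediction error (co)variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import Pedigree, RelationshipMatrix
from .screening import TraitModelSpec


class MMEError(ValueError):
    pass


def fixed_design(data: pd.DataFrame, factors: dict[str, list[str]]) -> tuple[np.ndarray, list[str]]:
    """Full-rank fixed-effect design: intercept + treatment-coded dummies.

    The first observed level of each factor is the reference. Declared but
    unobserved levels are dropped from the design (they are non-estimable);
    an observed level absent from the declaration raises.
    """
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    for f, declared in factors.items():
        obs = [str(v) for v in data[f].astype(str)]
        levels = [l for l in (declared or sorted(set(obs))) if l in set(obs)]
        if not levels:
            raise MMEError(f"factor {f!r}: no declared level observed")
        unknown = set(obs) - set(levels)
        if unknown:
            raise MMEError(f"factor {f!r}: undeclared levels {sorted(unknown)[:4]}")
        for lev in levels[1:]:
            cols.append(np.array([1.0 if v == lev else 0.0 for v in obs]))
            names.append(f"{f}:{lev}")
    return np.column_stack(cols), names


@dataclass
class MMESystem:
    """Assembled single-trait MME in variance-ratio form."""

    spec: TraitModelSpec
    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    Z: dict[str, sp.csr_matrix]          # term -> records × levels incidence
    term_ids: dict[str, list[str]]       # term -> level ids (animal ids)
    kinv: RelationshipMatrix
    ratios: dict[str, float]             # term -> σ²e / σ²term
    _C: sp.csr_matrix | None = field(default=None, repr=False)
    _rhs: np.ndarray | None = field(default=None, repr=False)
    _slices: dict[str, slice] = field(default_factory=dict, repr=False)

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_equations(self) -> int:
        return self.X.shape[1] + sum(Z.shape[1] for Z in self.Z.values())

    def coefficient_matrix(self) -> tuple[sp.csr_matrix, np.ndarray, dict[str, slice]]:
        if self._C is not None:
            return self._C, self._rhs, self._slices
        terms = list(self.Z)
        W = sp.hstack([sp.csr_matrix(self.X)] + [self.Z[t] for t in terms]).tocsr()
        C = (W.T @ W).tocsr()
        rhs = W.T @ self.y
        p = self.X.shape[1]
        offs = {}
        start = p
        blocks = [sp.csr_matrix((p, p))]
        Kv = self.kinv.values
        Kv = Kv if sp.issparse(Kv) else sp.csr_matrix(Kv)
        for t in terms:
            q = self.Z[t].shape[1]
            offs[t] = slice(start, start + q)
            start += q
            lam = self.ratios[t]
            blocks.append(lam * Kv if t in ("additive", "maternal") else lam * sp.eye(q))
        self._slices = {"fixed": slice(0, p), **offs}
        self._C = (C + sp.block_diag(blocks)).tocsr()
        self._rhs = rhs
        return self._C, self._rhs, self._slices


def assemble_mme(
    spec: TraitModelSpec,
    data: pd.DataFrame,
    kinv: RelationshipMatrix,
    ratios: dict[str, float],
    pedigree: Pedigree | None = None,
) -> MMESystem:
    """Build the MME for one trait's records.

    kinv must be an Ainv or Hinv covering every animal in the data (animals
    without records still receive additive equations through K⁻¹). For
    maternal models a pedigree is required to map each record to its dam.
    """
    if kinv.kind not in ("Ainv", "Hinv"):
        raise MMEError("kinv must be of kind Ainv or Hinv")
    d = data.loc[data["trait"] == spec.trait] if "trait" in data.columns else data
    if d.empty:
        raise MMEError(f"no records for trait {spec.trait!r}")
    d = d.reset_index(drop=True)
    missing = set(map(str, d["animal"])) - set(kinv.ids)
    if missing:
        raise MMEError(f"animals absent from the relationship inverse: {sorted(missing)[:5]}")
    y = d["value"].to_numpy(dtype=float)
    X, names = fixed_design(d, spec.fixed_factors)
    nrec = len(d)
    Z: dict[str, sp.csr_matrix] = {}
    term_ids: dict[str, list[str]] = {}
    a_idx = kinv.index_of(d["animal"])
    nk = kinv.n
    Z["additive"] = sp.coo_matrix(
        (np.ones(nrec), (np.arange(nrec), a_idx)), shape=(nrec, nk)
    ).tocsr()
    term_ids["additive"] = list(kinv.ids)
    if "permanent_env" in spec.random_terms:
        pe_ids = sorted(set(map(str, d["animal"])), key=lambda a: kinv.index_of([a])[0])
        pmap = {a: k for k, a in enumerate(pe_ids)}
        pe_idx = np.array([pmap[str(a)] for a in d["animal"]])
        Z["permanent_env"] = sp.coo_matrix(
            (np.ones(nrec), (np.arange(nrec), pe_idx)), shape=(nrec, len(pe_ids))
        ).tocsr()
        term_ids["permanent_env"] = pe_ids
    if "maternal" in spec.random_terms:
        if pedigree is None:
            raise MMEError("maternal model requires the pedigree to map records to dams")
        an_idx = pedigree.index_of(d["animal"])
        dams = pedigree.dam[an_idx]
        if np.any(dams < 0):
            bad = [d["animal"].iloc[i] for i in np.flatnonzero(dams < 0)[:5]]
            raise MMEError(f"maternal model: records with unknown dam ({bad})")
        dam_ids = [pedigree.ids[j] for j in dams]
        dm_idx = kinv.index_of(dam_ids)
        Z["maternal"] = sp.coo_matrix(
            (np.ones(nrec), (np.arange(nrec), dm_idx)), shape=(nrec, nk)
        ).tocsr()
        term_ids["maternal"] = list(kinv.ids)
    for t in Z:
        if t not in ratios or ratios[t] <= 0:
            raise MMEError(f"missing/invalid variance ratio for term {t!r}")
    return MMESystem(spec, y, X, names, Z, term_ids, kinv, dict(ratios))


def solve_mme(system: MMESystem, dense_cap: int = 8000):
    """Solve C u = rhs; returns (solutions, slices, pev_fn).

    pev_fn(sigma2_e) returns the additive-block diagonal of C⁻¹·σ²e, i.e.
    per-animal prediction error variances. Uses a dense Cholesky inverse
    below ``dense_cap`` equations and sparse per-column solves above it.
    """
    C, rhs, slices = system.coefficient_matrix()
    n = C.shape[0]
    a = slices["additive"]
    if n <= dense_cap:
        Cd = C.toarray()
        try:
            cho = la.cho_factor(Cd)
        except la.LinAlgError as e:
            raise MMEError("singular coefficient matrix after constraints") from e
        sol = la.cho_solve(cho, rhs)
        Cinv = la.cho_solve(cho, np.eye(n))
        diag_aa = np.diag(Cinv)[a]
        def pev(sigma2_e: float) -> np.ndarray:
            return diag_aa * sigma2_e
    else:
        lu = spla.splu(C.tocsc())
        sol = lu.solve(rhs)
        def pev(sigma2_e: float) -> np.ndarray:
            out = np.empty(a.stop - a.start)
            e = np.zeros(n)
            for k, i in enumerate(range(a.start, a.stop)):
                e[i] = 1.0
                out[k] = lu.solve(e)[i]
                e[i] = 0.0
            return out * sigma2_e
    return sol, slices, pev
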