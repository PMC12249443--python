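"""REML variance-component estimation for single- and two-trait animal models.

Two estimation paths are used:

* a spectral path for models with a single genetic term and residual
  (y = Xb + Za + e): the additive covariance ZKZ' is eigendecomposed once
  and the restricted likelihood is profiled down to the single variance
  ratio λ = σ²a/σ²e, maximized by bounded scalar search. Component
  covariances come from the exact expected (Fisher) information.
* a dense average-information (AI) path for models with additional random
  terms (permanent environment, maternal): Newton steps on the AI matrix
  with EM-REML fallback whenever a proposal leaves the parameter space,
  and components pinned (and flagged) at a small positive floor.

The two-trait model (shared additive structure, trait-specific fixed
effects, no pe/maternal terms) is estimated by direct maximization of the
restricted likelihood over log-Cholesky-parametrized genetic and residual
(co)variance matrices — spectrally when both traits are single-record on a
common animal set, densely otherwise. Asymptotic covariances come from the
numerically differentiated observed information in component space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.optimize as opt
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import Pedigree, RelationshipMatrix
from .screening import TraitModelSpec


class REMLError(RuntimeError):
    pass


# ----------------------------------------------------------------------
@dataclass
class VarianceComponents:
    """REML estimates for one trait.

    components: ordered name → estimate, residual last. cov is the
    asymptotic covariance of the estimates in the same order.
    """

    components: dict[str, float]
    cov: np.ndarray
    loglik: float
    converged: bool
    iterations: int
    n_records: int
    pinned: tuple[str, ...] = ()
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.components)

    @property
    def sigma2_a(self) -> float:
        return self.components["additive"]

    @property
    def sigma2_e(self) -> float:
        return self.components["residual"]

    @property
    def sigma2_p(self) -> float:
        return float(sum(self.components.values()))

    def ratio(self, term: str) -> float:
        """σ²e/σ²term for the MME; a component estimated at the zero
        boundary enters at a small positive floor so the system stays
        finite (its block then shrinks essentially to the prior mean)."""
        return self.sigma2_e / max(self.components[term], 1e-6 * self.sigma2_p)

    def to_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.clip(np.diag(self.cov), 0, None))
        return pd.DataFrame(
            {"component": self.names,
             "estimate": [self.components[k] for k in self.names],
             "se": se}
        )


def heritability(vc: VarianceComponents) -> tuple[float, float]:
    """h² = σ²a/σ²p with its delta-method standard error.

    σ²p is the full component sum; Var(σ²p) and Cov(σ²a, σ²p) follow from
    the component covariance matrix by the linear map σ²p = Σ_i θ_i.
    """
    sp2 = vc.sigma2_p
    if sp2 <= 0:
        raise REMLError("zero phenotypic variance")
    sa = vc.sigma2_a
    h2 = sa / sp2
    k = len(vc.names)
    ia = vc.names.index("additive")
    # gradient of sa/sp wrt each component
    g = np.full(k, -sa / sp2**2)
    g[ia] += 1.0 / sp2
    var = float(g @ vc.cov @ g)
    return h2, float(np.sqrt(max(var, 0.0)))


# ----------------------------------------------------------------------
@dataclass
class AdditiveStructure:
    """Reusable eigendecomposition of the additive relationship among a
    fixed set of animals; lets replicated fits on one pedigree skip the
    O(n³) decomposition."""

    ids: tuple[str, ...]
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


def additive_structure(kinv: RelationshipMatrix, ids: Sequence[str]) -> AdditiveStructure:
    K = _relationship_submatrix(kinv, ids)
    w, U = la.eigh(K)
    return AdditiveStructure(tuple(str(a) for a in ids), np.clip(w, 0.0, None), U)


def _relationship_submatrix(kinv: RelationshipMatrix, ids: Sequence[str]) -> np.ndarray:
    """Dense K (A or H) among the listed animals, from K or its inverse."""
    if kinv.kind in ("A", "H", "A22", "G", "Gstar"):
        return kinv.submatrix(ids).dense()
    idx = kinv.index_of(ids)
    Kv = kinv.values.tocsc() if sp.issparse(kinv.values) else sp.csc_matrix(kinv.values)
    lu = spla.splu(Kv)
    rhs = np.zeros((Kv.shape[0], len(idx)))
    rhs[idx, np.arange(len(idx))] = 1.0
    cols = lu.solve(rhs)
    K = cols[idx, :]
    return 0.5 * (K + K.T)


def _extract(spec: TraitModelSpec, data: pd.DataFrame, pedigree: Pedigree | None):
    from .mme import fixed_design

    d = data.loc[data["trait"] == spec.trait] if "trait" in data.columns else data
    if d.empty:
        raise REMLError(f"no records for trait {spec.trait!r}")
    d = d.reset_index(drop=True)
    y = d["value"].to_numpy(dtype=float)
    X, _ = fixed_design(d, spec.fixed_factors)
    animals = [str(a) for a in d["animal"]]
    dams = None
    if "maternal" in spec.random_terms:
        if pedigree is None:
            raise REMLError("maternal model requires the pedigree")
        ai = pedigree.index_of(animals)
        if np.any(pedigree.dam[ai] < 0):
            raise REMLError("maternal model: records with unknown dam")
        dams = [pedigree.ids[j] for j in pedigree.dam[ai]]
    return d, y, X, animals, dams


def reml_estimate(
    spec: TraitModelSpec,
    data: pd.DataFrame,
    kinv: RelationshipMatrix,
    start: Optional[dict[str, float]] = None,
    algorithm: str = "ai",
    tol: float = 1e-8,
    max_iter: int = 200,
    pedigree: Pedigree | None = None,
    structure: AdditiveStructure | None = None,
) -> VarianceComponents:
    """REML estimates of the variance components of a single-trait model."""
    d, y, X, animals, dams = _extract(spec, data, pedigree)
    terms = [t for t in ("additive", "permanent_env", "maternal") if t in spec.random_terms]
    if (structure is not None and terms == ["additive"] and algorithm != "em"
            and tuple(animals) == structure.ids):
        return _spectral_univariate(y, X, None, tol=tol,
                                    eig=(structure.eigenvalues, structure.eigenvectors))
    uniq = list(dict.fromkeys(animals + (dams or [])))
    K = _relationship_submatrix(kinv, uniq)
    pos = {a: i for i, a in enumerate(uniq)}
    ra = np.array([pos[a] for a in animals])
    if terms == ["additive"] and algorithm != "em":
        M = K[np.ix_(ra, ra)]
        return _spectral_univariate(y, X, M, tol=tol)
    # dense multi-component path
    Vs: list[np.ndarray] = []
    qs: list[int] = []
    for t in terms:
        if t == "additive":
            Vs.append(K[np.ix_(ra, ra)])
            qs.append(len(set(animals)))
        elif t == "permanent_env":
            same = (ra[:, None] == ra[None, :]).astype(float)
            Vs.append(same)
            qs.append(len(set(animals)))
        else:  # maternal
            rm = np.array([pos[a] for a in dams])
            Vs.append(K[np.ix_(rm, rm)])
            qs.append(len(set(dams)))
    start_vec = None
    if start:
        start_vec = np.array([start[t] for t in terms] + [start["residual"]])
    vc = _ai_reml(y, X, Vs, qs, names=terms, start=start_vec,
                  algorithm=algorithm, tol=tol, max_iter=max_iter)
    vc = VarianceComponents(
        components={**{t: vc.components[t] for t in terms}, "residual": vc.components["residual"]},
        cov=vc.cov, loglik=vc.loglik, converged=vc.converged, iterations=vc.iterations,
        n_records=len(y), pinned=vc.pinned, loglik_trace=vc.loglik_trace,
    )
    return vc


# ----------------------------------------------------------------------
def _spectral_univariate(y, X, M, tol: float = 1e-8, eig=None) -> VarianceComponents:
    """Profiled REML for V = σ²a M + σ²e I via one eigendecomposition."""
    n, p = X.shape
    if n <= p:
        raise REMLError("more fixed-effect parameters than records")
    if eig is not None:
        w, U = eig
    else:
        w, U = la.eigh(M)
        w = np.clip(w, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    nfev = 0

    def neg2remll(loglam: float) -> float:
        lam = np.exp(loglam)
        dvec = lam * w + 1.0
        Xd = Xt / dvec[:, None]
        XtDX = Xt.T @ Xd
        cho = la.cho_factor(XtDX)
        b = la.cho_solve(cho, Xd.T @ yt)
        rss = float(yt @ (yt / dvec) - (Xd.T @ yt) @ b)
        s2e = rss / (n - p)
        return ((n - p) * np.log(s2e) + np.sum(np.log(dvec))
                + 2.0 * np.sum(np.log(np.diag(cho[0]))) + (n - p))

    res = opt.minimize_scalar(neg2remll, bounds=(-14.0, 10.0), method="bounded",
                              options={"xatol": 1e-10})
    loglam = float(res.x)
    pinned: tuple[str, ...] = ()
    if loglam < -13.0:
        loglam, pinned = -np.inf, ("additive",)
    lam = np.exp(loglam) if np.isfinite(loglam) else 0.0
    dvec = lam * w + 1.0
    Xd = Xt / dvec[:, None]
    XtDX = Xt.T @ Xd
    cho = la.cho_factor(XtDX)
    b = la.cho_solve(cho, Xd.T @ yt)
    rss = float(yt @ (yt / dvec) - (Xd.T @ yt) @ b)
    s2e = rss / (n - p)
    s2a = lam * s2e
    v = s2a * w + s2e
    # expected information in (σ²a, σ²e); P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹
    Xv = Xt / v[:, None]
    Lc = la.cholesky(la.inv(Xt.T @ Xv), lower=True)
    B = Xv @ Lc                                    # n × p, BB' completes P
    BtWB = {1: B.T @ (B * w[:, None]), 0: B.T @ B}
    dB = np.einsum("ij,ij->i", B, B)

    def tr_PP(wa, wb, key_a, key_b):
        t1 = float(np.sum(wa * wb / v**2))
        t2 = float(np.sum(wa * wb * dB / v))
        t3 = float(np.trace(BtWB[key_a] @ BtWB[key_b]))
        return t1 - 2.0 * t2 + t3

    ones = np.ones_like(w)
    I = 0.5 * np.array(
        [[tr_PP(w, w, 1, 1), tr_PP(w, ones, 1, 0)],
         [tr_PP(w, ones, 1, 0), tr_PP(ones, ones, 0, 0)]]
    )
    try:
        cov = la.inv(I)
    except la.LinAlgError:
        cov = np.full((2, 2), np.nan)
    ll = -0.5 * (np.sum(np.log(v)) + 2.0 * np.sum(np.log(np.diag(la.cholesky(Xt.T @ Xv))))
                 + rss / s2e)
    return VarianceComponents(
        components={"additive": s2a, "residual": s2e},
        cov=cov, loglik=float(ll), converged=bool(res.success), iterations=int(res.nfev),
        n_records=n, pinned=pinned, loglik_trace=[float(ll)],
    )


# ----------------------------------------------------------------------
def _ai_reml(y, X, Vs, qs, names, start=None, algorithm="ai", tol=1e-8, max_iter=200):
    """Dense AI-REML with EM fallback over components (θ_1..θ_k, σ²e)."""
    n, p = X.shape
    k = len(Vs)
    vary = float(np.var(y))
    floor = 1e-8 * vary
    if start is None:
        theta = np.array([0.5 * vary / k] * k + [0.5 * vary])
    else:
        theta = np.asarray(start, dtype=float).copy()
    qvec = np.array(list(qs) + [n], dtype=float)
    names_all = list(names) + ["residual"]
    trace: list[float] = []
    pinned: set[str] = set()
    converged = False
    it = 0

    def common(theta):
        V = theta[-1] * np.eye(n)
        for j in range(k):
            V += theta[j] * Vs[j]
        cho = la.cho_factor(V)
        Vinv = la.cho_solve(cho, np.eye(n))
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        choX = la.cho_factor(XtVinvX)
        Py = Vinv @ y - VinvX @ la.cho_solve(choX, VinvX.T @ y)
        ll = -0.5 * (2.0 * np.sum(np.log(np.diag(cho[0])))
                     + 2.0 * np.sum(np.log(np.diag(choX[0])))
                     + float(y @ Py))
        return Vinv, VinvX, choX, Py, ll

    def score_ai(theta, Vinv, VinvX, choX, Py):
        mats = Vs + [np.eye(n)]
        tP = np.empty(k + 1)
        yPVPy = np.empty(k + 1)
        ts = []
        for j, Vj in enumerate(mats):
            tr1 = float(np.sum(Vinv * Vj))
            S = VinvX.T @ Vj @ VinvX
            tr2 = float(np.trace(la.cho_solve(choX, S)))
            tP[j] = tr1 - tr2
            t = Vj @ Py
            ts.append(t)
            yPVPy[j] = float(Py @ t)
        score = -0.5 * (tP - yPVPy)
        AI = np.empty((k + 1, k + 1))
        for i_ in range(k + 1):
            Pti = Vinv @ ts[i_] - VinvX @ la.cho_solve(choX, VinvX.T @ ts[i_])
            for j_ in range(i_, k + 1):
                AI[i_, j_] = AI[j_, i_] = 0.5 * float(ts[j_] @ Pti)
        return score, AI, tP, yPVPy

    Vinv, VinvX, choX, Py, ll = common(theta)
    trace.append(ll)
    for it in range(1, max_iter + 1):
        score, AI, tP, yPVPy = score_ai(theta, Vinv, VinvX, choX, Py)
        if np.linalg.norm(score) < 1e-6 * max(1.0, 1.0 / vary):
            converged = True
            break
        use_em = algorithm == "em"
        if not use_em:
            try:
                delta = la.solve(AI, score, assume_a="sym")
            except la.LinAlgError:
                use_em = True
            else:
                prop = theta + delta
                if np.any(prop < floor):
                    use_em = True
        if use_em:
            prop = theta + theta**2 * (yPVPy - tP) / qvec
        prop = np.maximum(prop, floor)
        for j, t in enumerate(names_all):
            if t in pinned:
                prop[j] = floor
        # step halving if likelihood drops materially
        new = None
        step = prop - theta
        for _ in range(6):
            cand = theta + step
            cand = np.maximum(cand, floor)
            try:
                new = common(cand)
            except la.LinAlgError:
                step *= 0.5
                continue
            if new[4] >= ll - 1e-6 * abs(ll) - 1e-8 or algorithm == "em":
                break
            step *= 0.5
        if new is None:
            raise REMLError("variance update failed: non-PD covariance at every step size")
        rel = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), floor))
        newly = {names_all[j] for j in range(k + 1) if cand[j] <= floor * 1.001}
        pinned |= newly
        theta = cand
        Vinv, VinvX, choX, Py, ll = new
        trace.append(ll)
        if rel < tol:
            converged = True
            break
    score, AI, _, _ = score_ai(theta, Vinv, VinvX, choX, Py)
    try:
        cov = la.inv(AI)
    except la.LinAlgError:
        cov = np.full((k + 1, k + 1), np.nan)
    return VarianceComponents(
        components=dict(zip(names_all, theta)),
        cov=cov, loglik=float(ll), converged=converged, iterations=it,
        n_records=n, pinned=tuple(sorted(pinned)), loglik_trace=trace,
    )


# ----------------------------------------------------------------------
@dataclass
class BivariateComponents:
    """Two-trait REML estimates: 2×2 genetic and residual (co)variances.

    cov is the asymptotic covariance of (g11, g12, g22, r11, r12, r22).
    """

    traits: tuple[str, str]
    G0: np.ndarray
    R0: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_animals: int
    bent: bool = False

    @property
    def P0(self) -> np.ndarray:
        return self.G0 + self.R0


def correlations(bc: BivariateComponents) -> tuple[float, float]:
    """Genetic and phenotypic correlations from the (co)variance matrices.

    rA = Cov(a_i, a_j)/√(σ²ai σ²aj); the phenotypic covariance is the sum
    of genetic and residual covariances.
    """
    g, p = bc.G0, bc.P0
    if g[0, 0] <= 0 or g[1, 1] <= 0 or p[0, 0] <= 0 or p[1, 1] <= 0:
        raise REMLError("zero variance: correlations undefined")
    ra = g[0, 1] / np.sqrt(g[0, 0] * g[1, 1])
    rp = p[0, 1] / np.sqrt(p[0, 0] * p[1, 1])
    return float(ra), float(rp)


def _chol_from_params(v: np.ndarray) -> np.ndarray:
    # clamped so boundary cases (perfectly correlated traits) saturate
    # instead of overflowing
    v = np.clip(v, -15.0, 15.0)
    L = np.array([[np.exp(v[0]), 0.0], [v[1], np.exp(v[2])]])
    return L @ L.T


def _nearest_psd(S: np.ndarray) -> np.ndarray:
    w, Q = la.eigh(S)
    return (Q * np.maximum(w, 1e-10)) @ Q.T


def bivariate_reml(
    spec_i: TraitModelSpec,
    spec_j: TraitModelSpec,
    data: pd.DataFrame,
    kinv: RelationshipMatrix,
    tol: float = 1e-8,
    pedigree: Pedigree | None = None,
    structure: AdditiveStructure | None = None,
) -> BivariateComponents:
    """Two-trait REML (additive + residual per trait, shared relationship).

    Repeated records are reduced to each animal's first record — the
    two-trait model carries no permanent-environmental term. When both
    traits are observed on the same animal set, the restricted likelihood
    is evaluated spectrally; otherwise a dense stacked-system likelihood is
    used. Non-PD (co)variance proposals are handled by the log-Cholesky
    parametrization; a final bending to the nearest PSD matrix is applied
    (and flagged) only if numerical asymmetry remains.
    """
    frames = []
    for spec in (spec_i, spec_j):
        d = data.loc[data["trait"] == spec.trait].drop_duplicates("animal")
        if d.empty:
            raise REMLError(f"no records for trait {spec.trait!r}")
        frames.append(d.reset_index(drop=True))
    d1, d2 = frames
    a1 = [str(a) for a in d1["animal"]]
    a2 = [str(a) for a in d2["animal"]]
    from .mme import fixed_design

    X1, _ = fixed_design(d1, spec_i.fixed_factors)
    X2, _ = fixed_design(d2, spec_j.fixed_factors)
    y1 = d1["value"].to_numpy(dtype=float)
    y2 = d2["value"].to_numpy(dtype=float)
    balanced = a1 == a2
    uniq = list(dict.fromkeys(a1 + a2))

    if balanced:
        if structure is not None and structure.ids == tuple(a1):
            w, U = structure.eigenvalues, structure.eigenvectors
        else:
            K = _relationship_submatrix(kinv, uniq)
            w, U = la.eigh(K)
            w = np.clip(w, 0.0, None)
        ys = (U.T @ y1, U.T @ y2)
        Xs = (U.T @ X1, U.T @ X2)
        n1 = n2 = len(a1)
        p1, p2 = X1.shape[1], X2.shape[1]

        def neg2ll_mats(G0, R0):
            av = G0[0, 0] * w + R0[0, 0]
            bv = G0[0, 1] * w + R0[0, 1]
            cv = G0[1, 1] * w + R0[1, 1]
            det = av * cv - bv * bv
            if np.any(det <= 0) or np.any(av <= 0):
                return np.inf
            ia, ib, ic = cv / det, -bv / det, av / det
            X1t, X2t = Xs
            y1t, y2t = ys
            M11 = X1t.T @ (X1t * ia[:, None])
            M12 = X1t.T @ (X2t * ib[:, None])
            M22 = X2t.T @ (X2t * ic[:, None])
            M = np.block([[M11, M12], [M12.T, M22]])
            r = np.concatenate([X1t.T @ (ia * y1t + ib * y2t), X2t.T @ (ib * y1t + ic * y2t)])
            try:
                choM = la.cho_factor(M)
            except la.LinAlgError:
                return np.inf
            beta = la.cho_solve(choM, r)
            quad = float(np.sum(ia * y1t**2 + 2 * ib * y1t * y2t + ic * y2t**2) - r @ beta)
            return (float(np.sum(np.log(det)))
                    + 2.0 * float(np.sum(np.log(np.diag(choM[0])))) + quad)
    else:
        K = _relationship_submatrix(kinv, uniq)
        i1 = np.array([uniq.index(a) for a in a1])
        i2 = np.array([uniq.index(a) for a in a2])
        K11 = K[np.ix_(i1, i1)]
        K12 = K[np.ix_(i1, i2)]
        K22 = K[np.ix_(i2, i2)]
        S12 = (np.array(a1)[:, None] == np.array(a2)[None, :]).astype(float)
        n1, n2 = len(a1), len(a2)
        X = la.block_diag(X1, X2)
        yy = np.concatenate([y1, y2])

        def neg2ll_mats(G0, R0):
            V = np.block(
                [[G0[0, 0] * K11 + R0[0, 0] * np.eye(n1), G0[0, 1] * K12 + R0[0, 1] * S12],
                 [(G0[0, 1] * K12 + R0[0, 1] * S12).T, G0[1, 1] * K22 + R0[1, 1] * np.eye(n2)]]
            )
            try:
                cho = la.cho_factor(V)
            except la.LinAlgError:
                return np.inf
            VinvX = la.cho_solve(cho, X)
            XtVinvX = X.T @ VinvX
            try:
                choX = la.cho_factor(XtVinvX)
            except la.LinAlgError:
                return np.inf
            Viy = la.cho_solve(cho, yy)
            b = la.cho_solve(choX, X.T @ Viy)
            quad = float(yy @ Viy - (X.T @ Viy) @ b)
            return (2.0 * float(np.sum(np.log(np.diag(cho[0]))))
                    + 2.0 * float(np.sum(np.log(np.diag(choX[0])))) + quad)

    v1, v2 = float(np.var(y1)), float(np.var(y2))

    def unpack(v):
        return _chol_from_params(v[:3]), _chol_from_params(v[3:])

    def objective(v):
        G0, R0 = unpack(v)
        return neg2ll_mats(G0, R0)

    x0 = np.array([0.5 * np.log(0.3 * v1), 0.0, 0.5 * np.log(0.3 * v2),
                   0.5 * np.log(0.6 * v1), 0.0, 0.5 * np.log(0.6 * v2)])
    res = opt.minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    res2 = opt.minimize(objective, res.x, method="BFGS",
                        options={"gtol": 1e-6, "maxiter": 200})
    best = res2 if np.isfinite(res2.fun) and res2.fun <= res.fun else res
    G0, R0 = unpack(best.x)
    bent = False
    for S in (G0, R0):
        if la.eigvalsh(S)[0] < 0:
            bent = True
    if bent:
        G0, R0 = _nearest_psd(G0), _nearest_psd(R0)

    # observed information in component space by central differences
    def nll_components(c):
        G = np.array([[c[0], c[1]], [c[1], c[2]]])
        R = np.array([[c[3], c[4]], [c[4], c[5]]])
        return 0.5 * neg2ll_mats(G, R)

    c0 = np.array([G0[0, 0], G0[0, 1], G0[1, 1], R0[0, 0], R0[0, 1], R0[1, 1]])
    H = _numeric_hessian(nll_components, c0)
    try:
        cov = la.inv(H)
    except la.LinAlgError:
        cov = np.full((6, 6), np.nan)
    return BivariateComponents(
        traits=(spec_i.trait, spec_j.trait), G0=G0, R0=R0, cov=cov,
        loglik=-0.5 * float(best.fun), converged=bool(best.success or res.success),
        n_animals=len(uniq), bent=bent,
    )


def _numeric_hessian(f, x0, rel_step=1e-4):
    k = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1e-3 * np.max(np.abs(x0)) + 1e-12)
    H = np.empty((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                val = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                val = (f(x0 + ei + ej) - f(x0 + ei - ej)
                       - f(x0 - ei + ej) + f(x0 - ei - ej)) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return H
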