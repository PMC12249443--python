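"""Independent reference implementations used as oracles in the tests.

Everything here is deliberately written from first principles (cell-by-cell
recursions, dense linear algebra on the marginal model), not by calling the
package's own code paths.
"""

from __future__ import annotations

import numpy as np

from ssgblup.pedigree import Pedigree


def tabular_A(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Numerator relationship matrix by the cell-by-cell tabular recursion."""
    n = len(sire)
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        for i in range(j):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[i, s]
            if d >= 0:
                v += 0.5 * A[i, d]
            A[i, j] = A[j, i] = v
        A[j, j] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def random_pedigree(rng: np.random.Generator, n: int, p_founder: float = 0.25) -> Pedigree:
    """Random topologically ordered pedigree with inbreeding loops.

    Parents are drawn uniformly from earlier animals (possibly close
    relatives), with occasional single-known-parent records.
    """
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i in range(1, n):
        if rng.random() < p_founder:
            continue
        s = int(rng.integers(0, i))
        d = int(rng.integers(0, i))
        if s == d:
            d = -1
        if rng.random() < 0.1:
            s = -1
        sire[i], dam[i] = s, d
    return Pedigree([f"P{k}" for k in range(n)], sire, dam)


def dense_blup(y, X, Z, K, s2a, s2e):
    """GLS/BLUP on the marginal model: b̂ = (X'V⁻¹X)⁻¹X'V⁻¹y and
    â = σ²a K Z' V⁻¹ (y − Xb̂); PEV = diag(σ²a K − σ²a² K Z' P Z K)."""
    V = s2a * Z @ K @ Z.T + s2e * np.eye(len(y))
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    b = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    resid = y - X @ b
    a = s2a * K @ Z.T @ Vinv @ resid
    P = Vinv - Vinv @ X @ np.linalg.solve(XtVinvX, X.T @ Vinv)
    pev = np.diag(s2a * K - s2a**2 * K @ Z.T @ P @ Z @ K)
    return b, a, pev


def oneway_F(groups: list[np.ndarray]) -> float:
    """Textbook one-way ANOVA F = MSB/MSW."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


def halfsib_sire_variance(y: np.ndarray, sire_of: np.ndarray) -> float:
    """ANOVA estimator of the sire variance in a balanced paternal
    half-sib design; σ²a ≈ 4 σ²s."""
    sires = np.unique(sire_of)
    k = len(sires)
    per = len(y) // k
    means = np.array([y[sire_of == s].mean() for s in sires])
    grand = y.mean()
    msb = per * ((means - grand) ** 2).sum() / (k - 1)
    msw = sum(((y[sire_of == s] - y[sire_of == s].mean()) ** 2).sum() for s in sires) / (len(y) - k)
    return (msb - msw) / per
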