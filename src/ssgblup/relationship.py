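"""Genomic and single-step relationship matrices.

G follows the VanRaden form G = WW′ / (2 Σ_k p_k(1−p_k)) with W the
genotype matrix column-centered by twice the counted-allele frequency.
G* is the blended (and optionally rescaled) invertible version
wG + (1−w)A22, and H / H⁻¹ are the single-step matrices combining the
pedigree relationships of non-genotyped animals with G* on the genotyped
block.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

from .genotypes import GenotypeMatrix
from .pedigree import RelationshipMatrix


def build_genomic_matrix(
    genotypes: GenotypeMatrix,
    freq_policy: str = "observed",
    freqs: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Genomic relationship matrix from a complete (QC'd, imputed) panel.

    freq_policy: "observed" uses frequencies counted in the genotyped set;
    "supplied" uses ``freqs``; "0.5" fixes every p_j at 0.5. Centering uses
    the counted allele's frequency (codes 0/1/2 map to −2p, 1−2p, 2−2p).
    """
    codes = np.asarray(genotypes.codes, dtype=float)
    if np.any(codes < 0):
        raise ValueError("genotype matrix contains missing codes; run QC/imputation first")
    if freq_policy == "observed":
        p = codes.mean(axis=0) / 2.0
    elif freq_policy == "supplied":
        if freqs is None:
            raise ValueError("freq_policy='supplied' requires freqs")
        p = np.asarray(freqs, dtype=float)
    elif freq_policy == "0.5":
        p = np.full(genotypes.n_snps, 0.5)
    else:
        raise ValueError(f"unknown freq_policy {freq_policy!r}")
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("zero denominator: all SNPs monomorphic under the chosen frequencies")
    W = codes - 2.0 * p
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix("G", G, list(genotypes.ids))


def blend_and_tune_G(
    G: RelationshipMatrix,
    A22: RelationshipMatrix,
    blend_weight: float = 0.95,
    tune: bool = False,
) -> RelationshipMatrix:
    """G* = wG + (1−w)A22, optionally after rescaling G to A22's means.

    Tuning is the two-parameter adjustment G ← a + bG chosen so the mean
    diagonal and mean off-diagonal of G match those of A22 (aligns the two
    matrices' base populations). Blending guarantees invertibility whenever
    A22 is positive definite and w < 1.
    """
    if G.ids != A22.ids:
        raise ValueError("G and A22 must share the same id map")
    if not 0 < blend_weight <= 1:
        raise ValueError("blend weight must lie in (0, 1]")
    Gv = G.dense().copy()
    Av = A22.dense()
    n = G.n
    if tune and n > 1:
        dg, da = np.mean(np.diag(Gv)), np.mean(np.diag(Av))
        off = ~np.eye(n, dtype=bool)
        og, oa = np.mean(Gv[off]), np.mean(Av[off])
        if abs(dg - og) < 1e-12:
            raise ValueError("cannot tune G: diagonal and off-diagonal means coincide")
        b = (da - oa) / (dg - og)
        a = oa - b * og
        Gv = a + b * Gv
    Gs = blend_weight * Gv + (1.0 - blend_weight) * Av
    # must be invertible for the single-step H⁻¹
    lam_min = la.eigvalsh(Gs, subset_by_index=[0, 0])[0] if n > 1 else Gs[0, 0]
    if lam_min <= 1e-10:
        raise ValueError(
            f"blended G* numerically singular (min eigenvalue {lam_min:.3e}); "
            "increase A22 weight or check for duplicated genotypes"
        )
    return RelationshipMatrix("Gstar", Gs, list(G.ids))


def build_H_matrix(
    A: RelationshipMatrix, Gstar: RelationshipMatrix, genotyped_ids: list[str]
) -> RelationshipMatrix:
    """Single-step relationship matrix H.

    Non-genotyped block: A11 + A12 A22⁻¹ (G* − A22) A22⁻¹ A21;
    off-diagonal: A12 A22⁻¹ G*; genotyped block: G*. Returned in the id
    order of A.
    """
    genotyped_ids = [str(g) for g in genotyped_ids]
    if Gstar is not None and list(Gstar.ids) != genotyped_ids:
        raise ValueError("Gstar must be indexed by genotyped_ids")
    Av = A.dense()
    if not genotyped_ids:
        return RelationshipMatrix("H", Av.copy(), list(A.ids))
    gi = A.index_of(genotyped_ids)
    ng = np.setdiff1d(np.arange(A.n), gi)
    A11 = Av[np.ix_(ng, ng)]
    A12 = Av[np.ix_(ng, gi)]
    A22 = Av[np.ix_(gi, gi)]
    Gs = Gstar.dense()
    # T = A12 A22⁻¹ via symmetric solve
    cho = la.cho_factor(A22)
    T = la.cho_solve(cho, A12.T).T
    H = np.empty_like(Av)
    H[np.ix_(ng, ng)] = A11 + T @ (Gs - A22) @ T.T
    H12 = T @ Gs
    H[np.ix_(ng, gi)] = H12
    H[np.ix_(gi, ng)] = H12.T
    H[np.ix_(gi, gi)] = Gs
    H = 0.5 * (H + H.T)
    return RelationshipMatrix("H", H, list(A.ids))


def build_H_inverse(
    Ainv: RelationshipMatrix,
    Gstar: RelationshipMatrix | None,
    A22: RelationshipMatrix | None,
    genotyped_ids: list[str],
) -> RelationshipMatrix:
    """Sparse single-step inverse H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A22⁻¹].

    The correction (G*⁻¹ − A22⁻¹) is dense on the genotyped block only and
    is scattered onto the genotyped rows/columns of the sparse A⁻¹.
    """
    genotyped_ids = [str(g) for g in genotyped_ids]
    Av = Ainv.values if sp.issparse(Ainv.values) else sp.csr_matrix(Ainv.values)
    if not genotyped_ids:
        return RelationshipMatrix("Hinv", Av.copy(), list(Ainv.ids))
    if Gstar is None or A22 is None:
        raise ValueError("Gstar and A22 required when genotyped_ids is non-empty")
    if list(Gstar.ids) != genotyped_ids or list(A22.ids) != genotyped_ids:
        raise ValueError("Gstar/A22 id maps must equal genotyped_ids")
    gi = Ainv.index_of(genotyped_ids)
    Gs = Gstar.dense()
    try:
        Ginv = la.cho_solve(la.cho_factor(Gs), np.eye(len(gi)))
    except la.LinAlgError as e:
        raise ValueError("singular G*: blend with A22 before inverting") from e
    A22inv = la.cho_solve(la.cho_factor(A22.dense()), np.eye(len(gi)))
    corr = Ginv - A22inv
    rows = np.repeat(gi, len(gi))
    cols = np.tile(gi, len(gi))
    C = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=Av.shape)
    return RelationshipMatrix("Hinv", (Av + C.tocsr()), list(Ainv.ids))
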