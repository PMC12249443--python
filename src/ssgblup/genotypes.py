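"""SNP genotype container, quality control, and text-format IO.

Genotypes are additive codes 0/1/2 (count of the counted allele) with -1
marking a missing call. QC applies the four panel filters in a fixed order:
individual call rate, SNP call rate, Hardy–Weinberg equilibrium (1-df
Pearson chi-square on the three genotype counts), and minor allele
frequency; surviving missing codes are imputed to the SNP mean 2p_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Animals × SNPs additive-code matrix.

    codes: int8 array with entries in {0, 1, 2, MISSING}, or a float array
    after mean-imputation.
    """

    ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.codes = np.asarray(self.codes)
        if self.codes.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError("genotype matrix shape inconsistent with id lists")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Observed counted-allele frequency p_j per SNP (missing excluded)."""
        c = self.codes
        obs = c != MISSING
        with np.errstate(invalid="ignore"):
            p = np.where(obs, c, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))
        return p

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeMatrix":
        a = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        s = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            [self.ids[i] for i in a], [self.snp_ids[j] for j in s], self.codes[np.ix_(a, s)]
        )

    # -- PLINK-RAW-style whitespace table: header of SNP names, rows id + codes
    def to_raw(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("IID " + " ".join(self.snp_ids) + "\n")
            for i, a in enumerate(self.ids):
                row = " ".join("NA" if c == MISSING else str(int(c)) for c in self.codes[i])
                fh.write(f"{a} {row}\n")

    @classmethod
    def from_raw(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        ids = df.iloc[:, 0].astype(str).tolist()
        snps = list(df.columns[1:])
        codes = df.iloc[:, 1:].to_numpy(dtype=float)
        codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
        return cls(ids, snps, codes)


@dataclass
class QCThresholds:
    """Panel QC thresholds; defaults follow standard 100K-array practice."""

    min_ind_call_rate: float = 0.90
    min_snp_call_rate: float = 0.90
    hwe_p_floor: float = 1e-6
    maf_floor: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_ind_call_rate", "min_snp_call_rate", "maf_floor"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 < self.hwe_p_floor < 1:
            raise ValueError("hwe_p_floor must lie in (0, 1)")


@dataclass
class QCReport:
    n_animals_in: int
    n_snps_in: int
    animals_removed_call_rate: int = 0
    snps_removed_call_rate: int = 0
    snps_removed_hwe: int = 0
    snps_removed_maf: int = 0
    n_animals_out: int = 0
    n_snps_out: int = 0
    removed_animal_ids: list[str] = field(default_factory=list)
    removed_snp_ids: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("animals_in", self.n_animals_in),
            ("snps_in", self.n_snps_in),
            ("animals_removed_call_rate", self.animals_removed_call_rate),
            ("snps_removed_call_rate", self.snps_removed_call_rate),
            ("snps_removed_hwe", self.snps_removed_hwe),
            ("snps_removed_maf", self.snps_removed_maf),
            ("animals_out", self.n_animals_out),
            ("snps_out", self.n_snps_out),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])


def hwe_chisq_p(codes: np.ndarray) -> np.ndarray:
    """1-df Pearson chi-square HWE p-value per SNP column (missing excluded)."""
    obs = codes != MISSING
    n = obs.sum(axis=0).astype(float)
    n0 = ((codes == 0) & obs).sum(axis=0)
    n1 = ((codes == 1) & obs).sum(axis=0)
    n2 = ((codes == 2) & obs).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n1 + 2 * n2) / (2 * n)
        q = 1 - p
        e0, e1, e2 = n * q * q, 2 * n * p * q, n * p * p
        chi2 = np.zeros_like(p)
        for o, e in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
            chi2 = chi2 + term
    pval = stats.chi2.sf(chi2, df=1)
    # monomorphic SNPs carry no HWE evidence
    pval = np.where((p <= 0) | (p >= 1), 1.0, pval)
    return pval


def qc_filter_genotypes(
    raw: GenotypeMatrix, thresholds: QCThresholds | None = None, impute: bool = True
) -> tuple[GenotypeMatrix, QCReport]:
    """Sequential panel QC: individual call rate → SNP call rate → HWE → MAF.

    Each filter is applied to the matrix surviving the previous step, so
    e.g. SNP call rates are computed after low-call-rate animals are gone.
    Remaining missing codes are imputed to the SNP mean 2p_j so the genomic
    relationship formula applies to a complete matrix.
    """
    thr = thresholds or QCThresholds()
    rep = QCReport(raw.n_animals, raw.n_snps)
    g = raw

    obs = g.codes != MISSING
    ind_cr = obs.mean(axis=1)
    keep_a = ind_cr >= thr.min_ind_call_rate
    rep.animals_removed_call_rate = int((~keep_a).sum())
    rep.removed_animal_ids = [g.ids[i] for i in np.flatnonzero(~keep_a)]
    g = g.subset(animal_idx=np.flatnonzero(keep_a))
    if g.n_animals == 0:
        raise ValueError("no animals survive individual call-rate filtering")

    obs = g.codes != MISSING
    snp_cr = obs.mean(axis=0)
    keep_s = snp_cr >= thr.min_snp_call_rate
    rep.snps_removed_call_rate = int((~keep_s).sum())
    rep.removed_snp_ids["call_rate"] = [g.snp_ids[j] for j in np.flatnonzero(~keep_s)]
    g = g.subset(snp_idx=np.flatnonzero(keep_s))

    if g.n_snps:
        pvals = hwe_chisq_p(g.codes)
        keep_s = pvals >= thr.hwe_p_floor
        rep.snps_removed_hwe = int((~keep_s).sum())
        rep.removed_snp_ids["hwe"] = [g.snp_ids[j] for j in np.flatnonzero(~keep_s)]
        g = g.subset(snp_idx=np.flatnonzero(keep_s))

    if g.n_snps:
        p = g.allele_frequencies()
        maf = np.minimum(p, 1 - p)
        keep_s = maf >= thr.maf_floor
        rep.snps_removed_maf = int((~keep_s).sum())
        rep.removed_snp_ids["maf"] = [g.snp_ids[j] for j in np.flatnonzero(~keep_s)]
        g = g.subset(snp_idx=np.flatnonzero(keep_s))

    if g.n_snps == 0:
        raise ValueError("no SNPs survive quality control")

    if impute and np.any(g.codes == MISSING):
        p = g.allele_frequencies()
        codes = g.codes.astype(float)
        miss = codes == MISSING
        codes[miss] = np.broadcast_to(2.0 * p, codes.shape)[miss]
        g = GenotypeMatrix(g.ids, g.snp_ids, codes)

    rep.n_animals_out, rep.n_snps_out = g.n_animals, g.n_snps
    return g, rep
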