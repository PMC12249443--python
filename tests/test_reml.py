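"""MME assembly and REML estimation: closed forms, method-of-moments
oracles, parameter recovery, and the correlation arithmetic."""

import numpy as np
import pandas as pd
import pytest

import ssgblup as s
from ssgblup.mme import MMEError, assemble_mme
from ssgblup.pedigree import Pedigree
from ssgblup.reml import (REMLError, BivariateComponents, VarianceComponents,
                          bivariate_reml, correlations, heritability,
                          reml_estimate)
from ssgblup.screening import TraitModelSpec
from ssgblup.simulate import SimulationConfig, SyntheticTraitDefinition
from oracles import halfsib_sire_variance


def herd(seed=1, founders=200, gens=2, dps=3, opd=2, **trait_kw):
    cfg = SimulationConfig(n_founders=founders, n_generations=gens,
                           dams_per_sire=dps, offspring_per_dam=opd,
                           n_snps=60, seed=seed)
    ped = s.simulate_pedigree(cfg)
    tr = SyntheticTraitDefinition("t", mean=5.0, residual_sd=1.0, **trait_kw)
    ph = s.simulate_phenotypes(ped, None, [tr], config=cfg)
    return ped, tr, ph


class TestMMEAssembly:
    def test_single_animal_hand_system(self):
        ped = Pedigree(["X"], np.array([-1]), np.array([-1]))
        data = pd.DataFrame({"animal": ["X"], "trait": ["t"], "value": [3.0]})
        sys_ = assemble_mme(TraitModelSpec("t"), data, ped.a_inverse(),
                            {"additive": 2.0})
        C, rhs, slices = sys_.coefficient_matrix()
        assert np.allclose(C.toarray(), [[1.0, 1.0], [1.0, 3.0]])
        assert np.allclose(rhs, [3.0, 3.0])

    def test_no_pe_block_without_pe_term(self, small_herd):
        ped = small_herd["pedigree"]
        sys_ = assemble_mme(TraitModelSpec("gain"), small_herd["phenotypes"],
                            ped.a_inverse(), {"additive": 2.0})
        assert set(sys_.Z) == {"additive"}

    def test_maternal_incidence_maps_to_dam(self, small_herd):
        ped = small_herd["pedigree"]
        d = small_herd["phenotypes"]
        d = d.loc[(d["trait"] == "gain")]
        known_dam = d["animal"].map(
            lambda a: ped.dam[ped.index_of([a])[0]] >= 0)
        d = d.loc[known_dam].reset_index(drop=True)
        spec = TraitModelSpec("gain", random_terms=("additive", "maternal"))
        sys_ = assemble_mme(spec, d, ped.a_inverse(),
                            {"additive": 2.0, "maternal": 4.0}, pedigree=ped)
        Z3 = sys_.Z["maternal"].toarray()
        for r in range(min(20, len(d))):
            ai = ped.index_of([d["animal"].iloc[r]])[0]
            assert Z3[r, ped.dam[ai]] == 1.0
            assert Z3[r].sum() == 1.0

    def test_animal_missing_from_kinv_rejected(self):
        ped = Pedigree(["X"], np.array([-1]), np.array([-1]))
        data = pd.DataFrame({"animal": ["Y"], "trait": ["t"], "value": [1.0]})
        with pytest.raises(MMEError, match="absent"):
            assemble_mme(TraitModelSpec("t"), data, ped.a_inverse(), {"additive": 2.0})


class TestHeritabilityArithmetic:
    def vc(self, comps, cov=None):
        k = len(comps)
        return VarianceComponents(comps, cov if cov is not None else np.zeros((k, k)),
                                  0.0, True, 1, 100)

    def test_plain_ratio(self):
        h2, _ = heritability(self.vc({"additive": 30.0, "residual": 70.0}))
        assert h2 == pytest.approx(0.30)

    def test_repeatability_model_sums_all_components(self):
        h2, _ = heritability(self.vc({"additive": 20.0, "permanent_env": 10.0,
                                      "residual": 70.0}))
        assert h2 == pytest.approx(0.20)

    def test_zero_phenotypic_variance_rejected(self):
        with pytest.raises(REMLError):
            heritability(self.vc({"additive": 0.0, "residual": 0.0}))

    def test_se_matches_finite_difference_delta_oracle(self):
        cov = np.array([[4.0, 1.2], [1.2, 2.5]])
        vc = self.vc({"additive": 30.0, "residual": 70.0}, cov)
        _, se = heritability(vc)
        # oracle: numerical gradient of h2(sa, se) propagated through cov
        f = lambda v: v[0] / (v[0] + v[1])
        x0 = np.array([30.0, 70.0])
        g = np.empty(2)
        for i in range(2):
            e = np.zeros(2); e[i] = 1e-6
            g[i] = (f(x0 + e) - f(x0 - e)) / 2e-6
        assert se == pytest.approx(float(np.sqrt(g @ cov @ g)), abs=1e-6)


class TestUnivariateREML:
    def test_pure_noise_estimates_near_zero_h2(self):
        ped, tr, ph = herd(seed=21, founders=400, h2_true=0.0)
        ph["value"] += np.random.default_rng(0).normal(0, 1e-12, len(ph))
        vc = reml_estimate(TraitModelSpec("t"), ph, ped.a_inverse())
        h2, _ = heritability(vc)
        assert h2 < 0.05

    def test_halfsib_anova_oracle(self):
        # balanced paternal half-sib families: REML σ²a ≈ 4 × sire variance
        n_sires, n_prog = 60, 12
        ids = [f"S{i}" for i in range(n_sires)] + [f"D{i}" for i in range(n_sires * n_prog)]
        sire = [-1] * n_sires + [-1] * (n_sires * n_prog)
        dam = [-1] * len(ids)
        prog_ids, prog_sire = [], []
        k = len(ids)
        for si in range(n_sires):
            for j in range(n_prog):
                prog_ids.append(f"P{si}_{j}")
                prog_sire.append(si)
        ped = Pedigree(ids + prog_ids,
                       np.array(sire + prog_sire),
                       np.array(dam + [n_sires + i for i in range(len(prog_ids))]))
        cfg = SimulationConfig(seed=77)
        tr = SyntheticTraitDefinition("t", mean=0.0, h2_true=0.3, residual_sd=1.0)
        ph = s.simulate_phenotypes(ped, None, [tr], config=cfg)
        ph = ph[ph["animal"].str.startswith("P")].reset_index(drop=True)
        vc = reml_estimate(TraitModelSpec("t"), ph, ped.a_inverse())
        sire_of = ph["animal"].str.split("_").str[0].to_numpy()
        s2s = halfsib_sire_variance(ph["value"].to_numpy(), sire_of)
        assert vc.sigma2_a == pytest.approx(4 * s2s, abs=0.15)

    def test_spectral_and_em_paths_agree(self):
        ped, tr, ph = herd(seed=31, founders=120, h2_true=0.35)
        ainv = ped.a_inverse()
        fast = reml_estimate(TraitModelSpec("t"), ph, ainv)
        em = reml_estimate(TraitModelSpec("t"), ph, ainv, algorithm="em",
                           tol=1e-10, max_iter=2000)
        assert em.sigma2_a == pytest.approx(fast.sigma2_a, rel=5e-3, abs=5e-3)

    def test_em_likelihood_monotone(self):
        ped, tr, ph = herd(seed=32, founders=100, h2_true=0.3)
        em = reml_estimate(TraitModelSpec("t"), ph, ped.a_inverse(),
                           algorithm="em", tol=1e-10, max_iter=60)
        ll = np.array(em.loglik_trace)
        assert np.all(np.diff(ll) > -1e-6)

    def test_invariant_to_relabeling_and_record_order(self):
        ped, tr, ph = herd(seed=33, founders=100, h2_true=0.3)
        ainv = ped.a_inverse()
        base = reml_estimate(TraitModelSpec("t"), ph, ainv)
        shuffled = ph.sample(frac=1.0, random_state=5).reset_index(drop=True)
        perm = reml_estimate(TraitModelSpec("t"), shuffled, ainv)
        assert perm.sigma2_a == pytest.approx(base.sigma2_a, rel=1e-6)

    def test_repeatability_model_recovery(self):
        ests = []
        for seed in range(8):
            ped, tr, ph = herd(seed=200 + seed, founders=150, gens=2,
                               h2_true=0.3, repeatability=0.5, records_per_animal=2)
            vc = reml_estimate(TraitModelSpec("t", random_terms=("additive", "permanent_env")),
                               ph, ped.a_inverse())
            ests.append([vc.components["additive"], vc.components["permanent_env"],
                         vc.components["residual"]])
        m, sd = np.mean(ests, axis=0), np.std(ests, axis=0, ddof=1) / np.sqrt(8)
        true = np.array([tr.sigma2_a, tr.sigma2_pe, tr.sigma2_e])
        assert np.all(np.abs(m - true) < 2.5 * np.maximum(sd, 0.02))

    def test_maternal_model_recovery(self):
        ests = []
        for seed in range(8):
            cfg = SimulationConfig(n_founders=120, n_generations=2, dams_per_sire=5,
                                   offspring_per_dam=4, n_snps=40, seed=300 + seed)
            ped = s.simulate_pedigree(cfg)
            tr = SyntheticTraitDefinition("t", mean=0.0, h2_true=0.3,
                                          maternal_h2=0.15, residual_sd=1.0)
            ph = s.simulate_phenotypes(ped, None, [tr], config=cfg)
            vc = reml_estimate(TraitModelSpec("t", random_terms=("additive", "maternal")),
                               ph, ped.a_inverse(), pedigree=ped)
            ests.append([vc.components["additive"], vc.components["maternal"],
                         vc.components["residual"]])
        m, sd = np.mean(ests, axis=0), np.std(ests, axis=0, ddof=1) / np.sqrt(8)
        true = np.array([tr.sigma2_a, tr.sigma2_m, tr.sigma2_e])
        assert np.all(np.abs(m - true) < 2.5 * np.maximum(sd, 0.03))


class TestCorrelationArithmetic:
    def bc(self, G0, R0):
        return BivariateComponents(("a", "b"), np.asarray(G0, float),
                                   np.asarray(R0, float), np.zeros((6, 6)),
                                   0.0, True, 100)

    def test_zero_genetic_covariance(self):
        ra, _ = correlations(self.bc([[2, 0], [0, 3]], [[1, 0.5], [0.5, 1]]))
        assert ra == 0.0

    def test_cauchy_schwarz_boundary(self):
        ra, _ = correlations(self.bc([[4, 6], [6, 9]], [[1, 0], [0, 1]]))
        assert ra == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        ra, rp = correlations(self.bc([[4, 3], [3, 9]], [[2, -1], [-1, 3]]))
        assert ra == pytest.approx(0.5)
        assert rp == pytest.approx((3 - 1) / np.sqrt(6 * 12))

    def test_zero_variance_rejected(self):
        with pytest.raises(REMLError):
            correlations(self.bc([[0, 0], [0, 1]], [[1, 0], [0, 1]]))


class TestBivariateREML:
    def pair(self, seed, ra, founders=250):
        cfg = SimulationConfig(n_founders=founders, n_generations=2, dams_per_sire=3,
                               offspring_per_dam=2, n_snps=60, seed=seed)
        ped = s.simulate_pedigree(cfg)
        t1 = SyntheticTraitDefinition("x", 0.0, 0.35, 1.0,
                                      genetic_correlation_partner=("z", ra))
        t2 = SyntheticTraitDefinition("z", 0.0, 0.40, 1.0)
        ph = s.simulate_phenotypes(ped, None, [t1, t2], config=cfg)
        return ped, ph

    def test_independent_traits_near_zero_rA(self):
        vals = []
        for seed in (51, 52, 53):
            ped, ph = self.pair(seed, 0.0)
            bc = bivariate_reml(TraitModelSpec("x"), TraitModelSpec("z"),
                                ph, ped.a_inverse())
            vals.append(correlations(bc)[0])
        assert abs(np.mean(vals)) < 0.12

    def test_positive_rA_recovery(self):
        vals = []
        for seed in (61, 62, 63):
            ped, ph = self.pair(seed, 0.5)
            bc = bivariate_reml(TraitModelSpec("x"), TraitModelSpec("z"),
                                ph, ped.a_inverse())
            vals.append(correlations(bc)[0])
        assert np.mean(vals) == pytest.approx(0.5, abs=0.12)

    def test_duplicated_trait_gives_unit_genetic_correlation(self):
        # the partner shares the trait's breeding values exactly (fresh
        # residuals), so the true genetic correlation is 1
        ped, ph = self.pair(71, 0.0, founders=150)
        x = ph[ph["trait"] == "x"].reset_index(drop=True)
        dup = x.copy()
        dup["trait"] = "xcopy"
        dup["value"] = dup["tbv"] + np.random.default_rng(4).normal(0, 1.0, len(dup))
        bc = bivariate_reml(TraitModelSpec("x"), TraitModelSpec("xcopy"),
                            pd.concat([x, dup]), ped.a_inverse())
        ra, _ = correlations(bc)
        assert ra == pytest.approx(1.0, abs=0.05)

    def test_unbalanced_records_supported(self):
        ped, ph = self.pair(81, 0.5, founders=150)
        # drop a third of one trait's records: dense unbalanced path
        xz = ph[ph["trait"] == "x"]
        keep = xz.sample(frac=0.67, random_state=3)
        d = pd.concat([keep, ph[ph["trait"] == "z"]]).reset_index(drop=True)
        bc = bivariate_reml(TraitModelSpec("x"), TraitModelSpec("z"), d,
                            ped.a_inverse())
        ra, _ = correlations(bc)
        assert -0.2 < ra <= 1.0 and bc.converged
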