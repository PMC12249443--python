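"""BLUP solutions, PEV-based and validation reliabilities, subsets,
and the PBLUP-vs-ssGBLUP comparison."""

import numpy as np
import pandas as pd
import pytest

import ssgblup as s
from ssgblup.evaluate import (EvaluationError, adjusted_phenotypes,
                              compare_methods, define_subsets,
                              reliability_from_pev, solve_blup,
                              validation_reliability)
from ssgblup.mme import assemble_mme
from ssgblup.pedigree import Pedigree
from ssgblup.screening import TraitModelSpec
from ssgblup.simulate import SimulationConfig, SyntheticTraitDefinition
from oracles import dense_blup, random_pedigree


def evaluate_plain(ped, ph, s2a, s2e, kinv=None, method="PBLUP", trait="t"):
    kinv = kinv if kinv is not None else ped.a_inverse()
    sys_ = assemble_mme(TraitModelSpec(trait), ph, kinv, {"additive": s2e / s2a})
    return solve_blup(sys_, s2a, s2e, method=method)


class TestSolveBlup:
    def test_recordless_unrelated_animal_has_prior_mean_ebv(self):
        ped = Pedigree(["X", "L"], np.array([-1, -1]), np.array([-1, -1]))
        ph = pd.DataFrame({"animal": ["X"], "trait": "t", "value": [4.0]})
        res = evaluate_plain(ped, ph, 0.3, 0.7)
        assert res.ebv_of(["L"])[0] == pytest.approx(0.0)
        assert res.reliability_of(["L"])[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_record_known_mean_shrinks_by_h2(self):
        # no fixed effects at all: â = h²·y from the 1×1 animal equation
        ped = Pedigree(["X"], np.array([-1]), np.array([-1]))
        ph = pd.DataFrame({"animal": ["X"], "trait": "t", "value": [2.0]})
        sys_ = assemble_mme(TraitModelSpec("t"), ph, ped.a_inverse(),
                            {"additive": 0.7 / 0.3})
        sys_.X = np.zeros((1, 0))
        sys_.fixed_names = []
        res = solve_blup(sys_, 0.3, 0.7)
        assert res.ebv[0] == pytest.approx(0.3 * 2.0)
        assert res.reliability[0] == pytest.approx(0.3)

    def test_matches_dense_gls_oracle(self, rng):
        ped = random_pedigree(rng, 80)
        cfg = SimulationConfig(seed=5)
        tr = SyntheticTraitDefinition("t", mean=3.0, h2_true=0.4, residual_sd=1.0)
        ph = s.simulate_phenotypes(ped, None, [tr], config=cfg)
        ph = ph.sample(n=60, random_state=1).reset_index(drop=True)  # some recordless
        s2a, s2e = tr.sigma2_a, tr.sigma2_e
        res = evaluate_plain(ped, ph, s2a, s2e)
        K = ped.relationship_matrix().dense()
        Z = np.zeros((len(ph), len(ped)))
        Z[np.arange(len(ph)), ped.index_of(ph["animal"])] = 1.0
        X = np.ones((len(ph), 1))
        b, a, pev = dense_blup(ph["value"].to_numpy(), X, Z, K, s2a, s2e)
        assert np.abs(res.ebv - a).max() < 1e-6
        assert np.abs(res.pev - pev).max() < 1e-8
        assert res.fixed_effects["intercept"] == pytest.approx(b[0])


class TestReliability:
    def test_no_information_gives_zero(self):
        r = reliability_from_pev(np.array([0.3]), 0.3)
        assert r[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_record_no_relatives_equals_h2(self):
        ped = Pedigree(["X"], np.array([-1]), np.array([-1]))
        ph = pd.DataFrame({"animal": ["X"], "trait": "t", "value": [1.0]})
        sys_ = assemble_mme(TraitModelSpec("t"), ph, ped.a_inverse(),
                            {"additive": 0.75 / 0.25})
        sys_.X = np.zeros((1, 0))  # fixed effects known
        res = solve_blup(sys_, 0.25, 0.75)
        assert res.reliability[0] == pytest.approx(0.25, abs=1e-10)

    def test_inbreeding_denominator(self):
        r = reliability_from_pev(np.array([0.25]), 0.5, inbreeding=np.array([0.25]))
        assert r[0] == pytest.approx(1 - 0.25 / (0.5 * 1.25))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(EvaluationError):
            reliability_from_pev(np.array([0.1]), 0.0)

    def test_own_record_increases_reliability(self):
        # same animal with vs without its own record, all else fixed
        ped = Pedigree(["S", "D", "O1", "O2"], np.array([-1, -1, 0, 0]),
                       np.array([-1, -1, 1, 1]))
        base = pd.DataFrame({"animal": ["S", "D", "O1"], "trait": "t",
                             "value": [1.0, 2.0, 1.5]})
        more = pd.concat([base, pd.DataFrame({"animal": ["O2"], "trait": "t",
                                              "value": [2.5]})])
        r0 = evaluate_plain(ped, base, 0.4, 0.6).reliability_of(["O2"])[0]
        r1 = evaluate_plain(ped, more, 0.4, 0.6).reliability_of(["O2"])[0]
        assert r1 > r0


class TestValidationReliability:
    def setup_method(self):
        cfg = SimulationConfig(n_founders=300, n_generations=2, dams_per_sire=3,
                               offspring_per_dam=2, n_snps=50, seed=17)
        self.ped = s.simulate_pedigree(cfg)
        tr = SyntheticTraitDefinition("t", mean=0.0, h2_true=0.4, residual_sd=1.0)
        self.ph = s.simulate_phenotypes(self.ped, None, [tr], config=cfg)
        self.tr = tr

    def result_with_ebv(self, ebv):
        return s.EvaluationResult("PBLUP", "t", list(self.ped.ids), ebv,
                                  np.zeros(len(self.ped)), np.zeros(len(self.ped)),
                                  {}, 1.0, 1.0)

    def test_perfect_prediction_gives_one(self):
        truth = self.ph.drop_duplicates("animal")[["animal", "tbv"]]
        tb = truth.set_index("animal")["tbv"]
        res = self.result_with_ebv(np.array([tb.get(a, 0.0) for a in self.ped.ids]))
        r = validation_reliability(res, truth, mode="truth", ids=list(truth["animal"]))
        assert r == pytest.approx(1.0)

    def test_independent_prediction_near_zero(self):
        truth = self.ph.drop_duplicates("animal")[["animal", "tbv"]]
        rng = np.random.default_rng(0)
        res = self.result_with_ebv(rng.normal(size=len(self.ped)))
        r = validation_reliability(res, truth, mode="truth", ids=list(truth["animal"]))
        assert r < 0.01

    def test_phenotype_and_truth_modes_agree_in_forward_validation(self):
        young = self.ped.generation == self.ped.generation.max()
        vids = [self.ped.ids[i] for i in np.flatnonzero(young)]
        train = self.ph[~self.ph["animal"].isin(vids)]
        vc_ratio = self.tr.sigma2_e / self.tr.sigma2_a
        sys_ = assemble_mme(TraitModelSpec("t"), train, self.ped.a_inverse(),
                            {"additive": vc_ratio})
        res = solve_blup(sys_, self.tr.sigma2_a, self.tr.sigma2_e)
        truth = self.ph.drop_duplicates("animal")[["animal", "tbv"]]
        r_truth = validation_reliability(res, truth, mode="truth", ids=vids)
        adj = adjusted_phenotypes(self.ph[self.ph["animal"].isin(vids)], res,
                                  TraitModelSpec("t"))
        r_pheno = validation_reliability(res, adj, h2=0.4, mode="phenotype", ids=vids)
        assert r_pheno == pytest.approx(r_truth, abs=0.15)

    def test_too_few_validation_animals_rejected(self):
        truth = self.ph.drop_duplicates("animal")[["animal", "tbv"]].head(5)
        res = self.result_with_ebv(np.zeros(len(self.ped)))
        with pytest.raises(EvaluationError, match="fewer than 10"):
            validation_reliability(res, truth, mode="truth", ids=list(truth["animal"]))


class TestSubsets:
    def test_empty_genotyped_set(self):
        ped = Pedigree(["a", "b"], np.array([-1, -1]), np.array([-1, -1]))
        sub = define_subsets(ped, [])
        assert sub.genotyped == [] and sub.genotyped_and_relatives == []
        assert sub.whole == ["a", "b"]

    def test_all_genotyped_saturates(self):
        ped = Pedigree(["a", "b", "c"], np.array([-1, -1, 0]), np.array([-1, -1, 1]))
        sub = define_subsets(ped, ped.ids)
        assert set(sub.genotyped_and_relatives) == set(ped.ids)

    def test_trio_offspring_genotyped_marks_parents(self):
        ped = Pedigree(["s", "d", "o", "x"], np.array([-1, -1, 0, -1]),
                       np.array([-1, -1, 1, -1]))
        sub = define_subsets(ped, ["o"])
        assert set(sub.genotyped_and_relatives) == {"s", "d", "o"}

    def test_nesting_invariant(self, small_herd):
        sub = define_subsets(small_herd["pedigree"], small_herd["genotyped_ids"])
        assert set(sub.genotyped) <= set(sub.genotyped_and_relatives) <= set(sub.whole)


class TestCompareMethods:
    def make_result(self, ids, rel, ebv, method):
        n = len(ids)
        return s.EvaluationResult(method, "t", ids, np.asarray(ebv, float),
                                  np.zeros(n), np.asarray(rel, float), {}, 1.0, 1.0)

    def test_self_comparison_is_null(self):
        ped = Pedigree(["a", "b", "c"], np.array([-1] * 3), np.array([-1] * 3))
        r = self.make_result(ped.ids, [0.2, 0.3, 0.4], [1.0, 2.0, 3.0], "ssGBLUP")
        rp = self.make_result(ped.ids, [0.2, 0.3, 0.4], [1.0, 2.0, 3.0], "PBLUP")
        ct = compare_methods(rp, r, define_subsets(ped, ped.ids))
        whole = ct.table[ct.table["subset"] == "whole"].iloc[0]
        assert whole["delta_rel_pct"] == 0.0
        assert whole["corr_ebv_gebv"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        ped = Pedigree(["a", "b", "c"], np.array([-1] * 3), np.array([-1] * 3))
        rp = self.make_result(ped.ids, [0.2, 0.3, 0.4], [1.0, 2.0, 3.0], "PBLUP")
        rs = self.make_result(ped.ids, [0.3, 0.4, 0.5], [2.0, 4.0, 6.0], "ssGBLUP")
        ct = compare_methods(rp, rs, define_subsets(ped, ped.ids))
        whole = ct.table[ct.table["subset"] == "whole"].iloc[0]
        assert whole["delta_rel_pct"] == pytest.approx(10.0)
        assert whole["corr_ebv_gebv"] == pytest.approx(1.0)

    def test_uninformative_genomics_reproduces_pblup(self, small_herd):
        # G* numerically equal to A22 → identical EBVs from both systems
        ped = small_herd["pedigree"]
        gids = small_herd["genotyped_ids"]
        ph = small_herd["phenotypes"]
        A22 = ped.relationship_matrix(subset=gids)
        A22.kind = "A22"
        Gs = s.RelationshipMatrix("Gstar", A22.dense().copy(), gids)
        ainv = ped.a_inverse()
        hinv = s.build_H_inverse(ainv, Gs, A22, gids)
        d = ph[ph["trait"] == "gain"]
        p = evaluate_plain(ped, d, 0.4, 0.6, kinv=ainv, trait="gain")
        h = evaluate_plain(ped, d, 0.4, 0.6, kinv=hinv, method="ssGBLUP", trait="gain")
        assert np.abs(p.ebv - h.ebv).max() < 1e-8
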