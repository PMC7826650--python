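import numpy as np
import pytest

from oracles import bf_spearman
from radrep.comparison import compare_iccs, fisher_z, volume_confounding
from radrep.gaussianisation import boxcox_transform
from radrep.repeatability import IccResult, icc_1_1
from radrep.synthetic import RandomEffectsSpec, simulate_multifeature_table


def _icc_result(icc, n=50):
    return IccResult(icc=icc, ci_low=np.nan, ci_high=np.nan, n_subjects=n, k=2)


def _simulated_icc(rng, sigma_b, n=50):
    b = rng.normal(0, sigma_b, n)
    return icc_1_1(b[:, None] + rng.normal(0, 1, (n, 2)))


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    @pytest.mark.parametrize("r", [0.3, 0.75, 0.99])
    def test_round_trip_and_antisymmetry(self, r):
        assert np.tanh(fisher_z(r)) == pytest.approx(r, abs=1e-12)
        assert fisher_z(-r) == -fisher_z(r)

    def test_boundary_flagged(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestCompare:
    def test_equal_inputs_give_null_result(self):
        a = _icc_result(0.8)
        c = compare_iccs(a, a)
        assert c.z_diff == 0.0
        assert c.p == pytest.approx(1.0)
        assert not c.significant

    def test_antisymmetric_in_arguments(self):
        a, b = _icc_result(0.9, 60), _icc_result(0.7, 40)
        ab = compare_iccs(a, b)
        ba = compare_iccs(b, a)
        assert ba.z_diff == -ab.z_diff
        assert ba.p == ab.p
        assert ba.significant == ab.significant

    def test_ci_contains_z_diff_and_respects_bonferroni_gate(self):
        a, b = _icc_result(0.95, 50), _icc_result(0.5, 50)
        c = compare_iccs(a, b, alpha=0.05, n_features=105)
        assert c.ci_low <= c.z_diff <= c.ci_high
        assert c.significant == (c.p < 0.05 / 105)

    def test_se_variants_ordered(self):
        a, b = _icc_result(0.9), _icc_result(0.7)
        assert compare_iccs(a, b, se_variant="intraclass").se > 0
        assert (
            compare_iccs(a, b, se_variant="classic").se
            > compare_iccs(a, b, se_variant="intraclass").se
        )

    def test_type_i_error_near_nominal_under_null(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 600
        for _ in range(n_rep):
            a = _simulated_icc(rng, np.sqrt(3))
            b = _simulated_icc(rng, np.sqrt(3))
            if compare_iccs(a, b, n_features=1).p < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 0.025  # 3 binomial SEs ~ 0.027

    def test_power_increases_with_icc_separation(self):
        rng = np.random.default_rng(7)

        def power(sb_a, sb_b, n_rep=300):
            hits = 0
            for _ in range(n_rep):
                a = _simulated_icc(rng, sb_a)
                b = _simulated_icc(rng, sb_b)
                if compare_iccs(a, b, n_features=1).p < 0.05:
                    hits += 1
            return hits / n_rep

        # true ICCs: 0.6 vs 0.9 (wide) and 0.7 vs 0.8 (narrow)
        wide = power(np.sqrt(0.6 / 0.4), np.sqrt(0.9 / 0.1))
        narrow = power(np.sqrt(0.7 / 0.3), np.sqrt(0.8 / 0.2))
        assert wide > narrow

    def test_family_wise_error_controlled_by_bonferroni(self):
        rng = np.random.default_rng(11)
        m = 10
        fwer_hits = 0
        n_rep = 200
        for _ in range(n_rep):
            any_sig = False
            for _f in range(m):
                a = _simulated_icc(rng, np.sqrt(3), n=30)
                b = _simulated_icc(rng, np.sqrt(3), n=30)
                if compare_iccs(a, b, alpha=0.05, n_features=m).significant:
                    any_sig = True
            fwer_hits += any_sig
        assert fwer_hits / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_small_cohorts_rejected(self):
        with pytest.raises(ValueError):
            compare_iccs(_icc_result(0.5, 3), _icc_result(0.5, 50))


class TestVolumeConfounding:
    def _table(self):
        specs = [
            RandomEffectsSpec(mu=10, sigma_b=2, sigma_w=0.5, n_lesions=60, seed=i, name=n)
            for i, n in enumerate(["shape_mesh_volume", "independent_feature"])
        ]
        return simulate_multifeature_table(specs)

    def test_reference_correlates_perfectly_with_itself(self):
        table = self._table()
        rho = volume_confounding(table, "shape_mesh_volume")
        assert rho["shape_mesh_volume"] == 1.0

    def test_independent_feature_near_zero(self):
        rho = volume_confounding(self._table(), "shape_mesh_volume")
        assert rho["independent_feature"] < 0.3

    def test_derived_feature_strongly_correlated(self):
        table = self._table()
        vol = table.data["shape_mesh_volume"]
        table = table.with_values("independent_feature", (vol**2).to_numpy())
        rho = volume_confounding(table, "shape_mesh_volume")
        assert rho["independent_feature"] == pytest.approx(1.0)

    def test_matches_brute_force_rank_oracle(self, rng):
        table = self._table()
        x = table.data["independent_feature"].to_numpy()
        ref = table.data["shape_mesh_volume"].to_numpy()
        rho = volume_confounding(table, "shape_mesh_volume")
        assert rho["independent_feature"] == pytest.approx(abs(bf_spearman(x, ref)), abs=1e-12)

    def test_invariant_under_boxcox_of_either_variable(self):
        table = self._table()
        rho0 = volume_confounding(table, "shape_mesh_volume")["independent_feature"]
        vals = table.data["independent_feature"].to_numpy()
        vals = vals - vals.min() + 0.5
        table2 = table.with_values("independent_feature", boxcox_transform(vals, 0.0))
        rho1 = volume_confounding(table2, "shape_mesh_volume")["independent_feature"]
        assert rho1 == pytest.approx(rho0, abs=1e-12)

    def test_constant_feature_flagged_nan(self):
        table = self._table().with_values("independent_feature", np.full(120, 1.0))
        rho = volume_confounding(table, "shape_mesh_volume")
        assert np.isnan(rho["independent_feature"])

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            volume_confounding(self._table(), "nope")
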