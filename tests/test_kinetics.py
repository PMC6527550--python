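import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exopath.kinetics import (REFERENCE_AFFINITIES, AffinityResult,
                              KineticParams, competitive_rate, delta_g,
                              fit_competitive_ki, fit_spr_kd, fold_ratio,
                              table1_report)
from exopath.synthetic import make_kinetic_dataset, make_spr_dataset


class TestCompetitiveRate:
    def test_half_saturation_without_inhibitor(self):
        p = KineticParams(Vmax=1.0, KM=2.0, Ki=1.0)
        assert competitive_rate(2.0, 0.0, p) == pytest.approx(0.5)

    def test_inhibitor_at_ki_with_s_at_km(self):
        p = KineticParams(Vmax=1.0, KM=2.0, Ki=0.7)
        assert competitive_rate(2.0, 0.7, p) == pytest.approx(1.0 / 3.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_matches_direct_formula(self, seed):
        r = np.random.default_rng(seed)
        vmax, km, ki = r.uniform(0.1, 10, 3)
        S, I = r.uniform(0.01, 20, 2)
        p = KineticParams(vmax, km, ki)
        assert competitive_rate(S, I, p) == pytest.approx(
            vmax * S / (km * (1 + I / ki) + S), rel=1e-12)

    def test_monotone_decreasing_in_inhibitor(self):
        p = KineticParams(1.0, 2.0, 1.5)
        I = np.linspace(0, 10, 50)
        v = competitive_rate(np.full_like(I, 3.0), I, p)
        assert np.all(np.diff(v) < 0)

    def test_invalid_inputs(self):
        p = KineticParams(1.0, 2.0, 1.5)
        with pytest.raises(ValueError):
            competitive_rate(-1.0, 0.0, p)
        with pytest.raises(ValueError):
            KineticParams(1.0, -2.0, 1.5)


class TestKiFit:
    def test_noise_free_identifiability(self):
        data = make_kinetic_dataset(Vmax=1.0, KM=2.0, Ki=2.55, noise_cv=0.0,
                                    seed=0)
        params, se, dixon = fit_competitive_ki(data)
        assert params.Ki == pytest.approx(2.55, rel=1e-6)
        assert params.KM == pytest.approx(2.0, rel=1e-6)
        assert params.Vmax == pytest.approx(1.0, rel=1e-6)

    def test_dixon_intersection_is_minus_ki_noise_free(self):
        data = make_kinetic_dataset(Ki=2.55, noise_cv=0.0, seed=0)
        _, _, dixon = fit_competitive_ki(data)
        assert dixon == pytest.approx(-2.55, rel=1e-6)

    def test_noisy_recovery_within_ten_percent_median(self):
        errs = []
        for seed in range(100):
            data = make_kinetic_dataset(Ki=2.55, noise_cv=0.05, seed=seed)
            params, _, _ = fit_competitive_ki(data)
            errs.append(abs(params.Ki - 2.55) / 2.55)
        assert np.median(errs) < 0.10

    def test_single_substrate_level_is_non_identifiable(self):
        data = make_kinetic_dataset(S_grid=np.array([2.0]), noise_cv=0.0,
                                    seed=0)
        with pytest.raises(ValueError):
            fit_competitive_ki(data)


class TestSPRFit:
    def test_noise_free_round_trip(self):
        data = make_spr_dataset(KD=0.16e-3, Rmax=100.0, noise_cv=0.0, seed=0)
        kd, rmax, _ = fit_spr_kd(data)
        assert kd == pytest.approx(0.16e-3, rel=1e-6)
        assert rmax == pytest.approx(100.0, rel=1e-6)

    def test_half_maximal_response_at_kd(self):
        # an odd-length geometric series contains C = KD as its mid-point
        data = make_spr_dataset(KD=1e-4, Rmax=80.0, n_conc=9, noise_cv=0.0,
                                seed=0)
        df = data.records
        at_kd = df.loc[np.isclose(df["C"], 1e-4), "Req"]
        assert len(at_kd) >= 1
        assert at_kd.iloc[0] == pytest.approx(40.0, rel=1e-6)

    def test_series_spans_tenth_to_tenfold_kd(self):
        data = make_spr_dataset(KD=2e-4, noise_cv=0.0, seed=0)
        c = data.records["C"]
        assert c.min() == pytest.approx(0.1 * 2e-4, rel=1e-9)
        assert c.max() == pytest.approx(10 * 2e-4, rel=1e-9)
        # one concentration injected in duplicate
        assert c.duplicated().sum() == 1

    def test_noisy_recovery_within_five_percent_median(self):
        errs = []
        for seed in range(100):
            data = make_spr_dataset(KD=0.16e-3, noise_cv=0.02, seed=seed)
            kd, _, _ = fit_spr_kd(data)
            errs.append(abs(kd - 0.16e-3) / 0.16e-3)
        assert np.median(errs) < 0.05

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError):
            make_spr_dataset(n_conc=3)


class TestDeltaG:
    @pytest.mark.parametrize("K,T,expected", [
        (0.16e-3, 298.15, -21.7),
        (2.55e-3, 303.15, -15.1),
    ])
    def test_published_reference_points(self, K, T, expected):
        assert delta_g(K, T) == pytest.approx(expected, abs=0.05)

    def test_unit_standard_state(self):
        assert delta_g(1.0, 298.15) == 0.0

    def test_monotone_and_antisymmetric(self):
        assert delta_g(1e-4, 300.0) < delta_g(1e-3, 300.0)
        assert delta_g(2.0, 300.0) + delta_g(0.5, 300.0) == \
            pytest.approx(0.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            delta_g(-1.0, 300.0)
        with pytest.raises(ValueError):
            delta_g(1e-3, 0.0)


class TestTable:
    def test_full_panel_delta_g(self):
        printed = {"Glc": -21.7, "G6SG-OMe": -29.1, "3dGlc": -11.7,
                   "4dGlc": -11.8, "octyl-O-Glc": -22.6,
                   "octyl-S-Glc": -17.2, "G2SG-OMe": -15.1}
        table = table1_report()
        for _, row in table.iterrows():
            assert row["delta_G_kJ_mol"] == pytest.approx(
                printed[row["ligand"]], abs=0.05)

    def test_fold_ratio_g2sg_over_g6sg(self):
        assert fold_ratio(REFERENCE_AFFINITIES, "G2SG-OMe", "G6SG-OMe") == 320

    def test_unknown_source_tag_rejected(self):
        with pytest.raises(ValueError):
            table1_report([("X", 1e-3, "telepathy")])

    def test_affinity_result_invariant(self):
        dg = delta_g(1e-3, 298.15)
        AffinityResult(1e-3, 298.15, dg, "SPR")
        with pytest.raises(ValueError):
            AffinityResult(1e-3, 298.15, dg + 1.0, "SPR")


class TestCoverage:
    def test_nominal_ki_inside_95_interval_most_of_the_time(self):
        hits = 0
        for seed in range(100):
            data = make_kinetic_dataset(Ki=2.55, noise_cv=0.05, seed=seed)
            params, se, _ = fit_competitive_ki(data)
            lo = params.Ki - 1.96 * se["Ki"]
            hi = params.Ki + 1.96 * se["Ki"]
            hits += lo <= 2.55 <= hi
        assert hits >= 90
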