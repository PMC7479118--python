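"""Force-extension laws, step-size predictions and the Δφ integral."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtweez import (
    ConstructState,
    Environment,
    FoldedDomainParams,
    HandleParams,
    PeptideParams,
    conformational_free_energy,
    folded_extension,
    handle_extension,
    kBT_at_temperature,
    peptide_extension,
    state_extension,
    step_size_curve,
    wlc_relative_extension,
)
from mtweez.constructs import looping_states
from mtweez.polymer import _marko_siggia


class TestThermalEnergy:
    @pytest.mark.parametrize("temp, expected", [(23.0, 4.089), (37.0, 4.282)])
    def test_kBT_values(self, temp, expected):
        assert kBT_at_temperature(temp) == pytest.approx(expected, abs=5e-4)

    def test_absolute_zero_rejected(self):
        with pytest.raises(ValueError):
            kBT_at_temperature(-273.15)

    def test_environment_exposes_kBT(self):
        assert Environment(23.0).kBT == kBT_at_temperature(23.0)


class TestWormLikeChain:
    def test_zero_force_zero_extension(self):
        assert wlc_relative_extension(0.0) == 0.0

    def test_contour_length_asymptote(self):
        assert wlc_relative_extension(1e6) == pytest.approx(1.0, abs=1e-3)

    def test_inversion_matches_bisection_oracle(self):
        # frozen: bisection on f = x + 1/(4(1-x)^2) - 1/4 to 1e-9
        assert wlc_relative_extension(0.654) == pytest.approx(0.336359080, abs=1e-8)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            wlc_relative_extension(-0.1)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=1e-6, max_value=1e3))
    def test_exact_inverse_of_marko_siggia(self, f_hat):
        x_hat = wlc_relative_extension(f_hat)
        assert 0.0 < x_hat < 1.0
        assert _marko_siggia(x_hat) == pytest.approx(f_hat, rel=1e-8)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.0, max_value=100.0),
           st.floats(min_value=1e-3, max_value=10.0))
    def test_strictly_increasing(self, f_hat, df):
        assert wlc_relative_extension(f_hat + df) > wlc_relative_extension(f_hat)


class TestPeptideExtension:
    def test_zero_force(self, i27_peptide, env37):
        assert peptide_extension(0.0, i27_peptide, env37) == 0.0

    def test_i27_at_3p5pN(self, i27_peptide, env37):
        # frozen from the numeric WLC inversion at F*Lp/kBT = 0.6539
        ext = peptide_extension(3.5, i27_peptide, env37)
        assert ext == pytest.approx(11.374, abs=0.01)

    def test_monotone_and_bounded(self, i27_peptide, env23):
        forces = np.linspace(0.1, 60, 40)
        exts = [peptide_extension(f, i27_peptide, env23) for f in forces]
        assert np.all(np.diff(exts) > 0)
        assert exts[-1] < i27_peptide.contour_length

    def test_negative_force_rejected(self, i27_peptide, env23):
        with pytest.raises(ValueError):
            peptide_extension(-1.0, i27_peptide, env23)


class TestFoldedExtension:
    def test_zero_force_limit(self, i27_rod, env37):
        assert folded_extension(0.0, i27_rod, env37) == 0.0

    def test_full_alignment_limit(self, i27_rod, env37):
        assert folded_extension(1e6, i27_rod, env37) == pytest.approx(4.4, rel=1e-4)

    def test_langevin_value(self, i27_rod, env37):
        # d*(coth(a) - 1/a), a = 3.5*4.4/4.28209
        assert folded_extension(3.5, i27_rod, env37) == pytest.approx(3.183, abs=0.005)

    def test_small_force_series_continuous(self, i27_rod, env23):
        # the series branch must join the coth branch smoothly
        f = 1e-4 * env23.kBT / i27_rod.rod_length
        lo = folded_extension(f * 0.999, i27_rod, env23)
        hi = folded_extension(f * 1.001, i27_rod, env23)
        assert lo == pytest.approx(hi, rel=1e-2)


class TestHandleExtension:
    def test_relative_extension_at_10pN(self, handle, env23):
        # frozen: 1 - 0.5*sqrt(kBT/(F Lp)) + F/S at the default parameters
        rel = handle_extension(10.0, handle, env23) / handle.contour_length
        assert rel == pytest.approx(0.9607, abs=1e-3)

    def test_increasing_in_force(self, handle, env23):
        forces = np.linspace(0.6, 50, 30)
        exts = [handle_extension(f, handle, env23) for f in forces]
        assert np.all(np.diff(exts) > 0)

    def test_below_validity_floor_rejected(self, handle, env23):
        with pytest.raises(ValueError):
            handle_extension(0.4, handle, env23)


class TestStateExtension:
    def test_empty_state(self, env23):
        assert state_extension(ConstructState([], "empty"), 5.0, env23) == 0.0

    def test_single_element(self, i27_peptide, env23):
        state = ConstructState([("peptide", i27_peptide)])
        assert state_extension(state, 5.0, env23) == peptide_extension(
            5.0, i27_peptide, env23)

    def test_additivity(self, i27_peptide, i27_rod, handle, env23):
        state = ConstructState([("handle", handle), ("peptide", i27_peptide),
                                ("folded_domain", i27_rod)])
        total = (handle_extension(8.0, handle, env23)
                 + peptide_extension(8.0, i27_peptide, env23)
                 + folded_extension(8.0, i27_rod, env23))
        assert state_extension(state, 8.0, env23) == pytest.approx(total)

    def test_loop_release_gap_near_70nm(self, env23):
        looped, unlooped = looping_states()
        gap = (state_extension(unlooped, 9.6, env23)
               - state_extension(looped, 9.6, env23))
        assert gap == pytest.approx(70.0, abs=10.0)


class TestStepSizeCurve:
    def test_identical_states_zero(self, i27_peptide, env23):
        s = ConstructState([("peptide", i27_peptide)])
        assert np.all(step_size_curve(s, s, [1, 5, 10], env23) == 0.0)

    def test_i27_unfolding_step_at_8pN(self, i27_peptide, i27_rod, env23):
        before = ConstructState([("folded_domain", i27_rod)])
        after = ConstructState([("peptide", i27_peptide)])
        step = step_size_curve(before, after, [8.0], env23)[0]
        assert step == pytest.approx(14.9, abs=1.5)

    def test_sr4_unfolding_step(self, sr4_peptide, sr4_rod, env23):
        # ~17.9 +/- 1 nm steps reported for the six-repeat traces at ~7.9 pN
        before = ConstructState([("folded_domain", sr4_rod)])
        after = ConstructState([("peptide", sr4_peptide)])
        step = step_size_curve(before, after, [7.9], env23)[0]
        assert step == pytest.approx(17.9, abs=2.0)

    def test_step_grows_with_force(self, i27_peptide, i27_rod, env23):
        before = ConstructState([("folded_domain", i27_rod)])
        after = ConstructState([("peptide", i27_peptide)])
        steps = step_size_curve(before, after, np.linspace(2, 20, 10), env23)
        assert np.all(np.diff(steps) > 0)


class TestConformationalFreeEnergy:
    def test_zero_force(self, i27_peptide, i27_rod, env37):
        assert conformational_free_energy(0.0, i27_peptide, i27_rod, env37) == 0.0

    def test_i27_value_within_printed_band(self, i27_peptide, i27_rod, env37):
        dphi = conformational_free_energy(3.5, i27_peptide, i27_rod, env37)
        assert dphi == pytest.approx(3.95, abs=0.7)

    def test_matches_dense_trapezoid_oracle(self, rng):
        env = Environment(25.0)
        for _ in range(20):
            pep = PeptideParams(n_residues=int(rng.integers(30, 200)),
                                persistence_length=rng.uniform(0.5, 1.5))
            rod = FoldedDomainParams(rod_length=rng.uniform(2.0, 6.0))
            force = rng.uniform(1.0, 10.0)
            fgrid = np.linspace(0, force, 10_001)
            gap = np.array([peptide_extension(f, pep, env)
                            - folded_extension(f, rod, env) for f in fgrid])
            oracle = np.trapezoid(gap, fgrid) / env.kBT
            val = conformational_free_energy(force, pep, rod, env)
            assert val == pytest.approx(oracle, abs=1e-3)

    def test_additive_over_force_intervals(self, i27_peptide, i27_rod, env37):
        a = conformational_free_energy(2.0, i27_peptide, i27_rod, env37)
        b = conformational_free_energy(5.0, i27_peptide, i27_rod, env37,
                                       f_low=2.0)
        total = conformational_free_energy(5.0, i27_peptide, i27_rod, env37)
        assert a + b == pytest.approx(total, abs=1e-6)

    def test_monotone_when_unfolded_longer(self, i27_peptide, i27_rod, env37):
        vals = [conformational_free_energy(f, i27_peptide, i27_rod, env37)
                for f in np.linspace(0, 8, 9)]
        assert np.all(np.diff(vals) >= 0)


class TestParameterValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_residues": -1},
        {"n_residues": 10, "contour_per_residue": 0.0},
        {"n_residues": 10, "persistence_length": -0.8},
    ])
    def test_bad_peptide_params(self, kwargs):
        with pytest.raises(ValueError):
            PeptideParams(**kwargs)

    def test_bad_rod_and_handle(self):
        with pytest.raises(ValueError):
            FoldedDomainParams(rod_length=-1.0)
        with pytest.raises(ValueError):
            HandleParams(n_bp=0)
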