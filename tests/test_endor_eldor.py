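"""Single- and multi-quantum line positions, synthesis, fitting, DQ edges."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import find_peaks

from sodepr.endor_eldor import (
    SpectralComponent,
    dq_edges,
    fit_components,
    mq_frequencies,
    offset_to_aeff,
    sq_frequencies,
    synthesize_spectrum,
)
from sodepr.orientation_select import EulerAngles, QuadrupoleTensor
from sodepr.spin_core import SpinModelError
from sodepr.synthetic_data import add_noise

Z = np.array([0.0, 0.0, 1.0])


class TestSQFrequencies:
    def test_matrix_line_at_zero_offset(self):
        lines = sq_frequencies(0.0, "1H", -2.5)
        assert len(lines) == 1 and lines[0].offset_mhz == 0.0

    def test_resolved_features_at_8_and_16_mhz(self):
        assert sq_frequencies(5.3, "1H", -1.5)[0].offset_mhz == pytest.approx(7.95)
        assert sq_frequencies(6.4, "1H", -2.5)[0].offset_mhz == pytest.approx(16.0)

    def test_both_branches_present(self):
        offsets = sorted(l.offset_mhz for l in sq_frequencies(4.0, "1H", -2.5))
        assert offsets == [-10.0, 10.0]

    def test_quadrupole_splitting_and_limit(self):
        quad = QuadrupoleTensor((-0.4, -0.4, 0.8), EulerAngles())
        lines = sq_frequencies(4.0, "14N", -2.5, quad=quad, direction=Z)
        pos = sorted(l.offset_mhz for l in lines if l.offset_mhz > 0)
        assert pos == pytest.approx([10.0 - 1.2, 10.0 + 1.2])
        zero_quad = QuadrupoleTensor((0.0, 0.0, 0.0), EulerAngles())
        lines0 = sq_frequencies(4.0, "14N", -2.5, quad=zero_quad, direction=Z)
        assert sorted({round(l.offset_mhz, 9) for l in lines0}) == [-10.0, 10.0]

    def test_quadrupole_for_spin_half_rejected(self):
        quad = QuadrupoleTensor((-0.4, -0.4, 0.8), EulerAngles())
        with pytest.raises(SpinModelError):
            sq_frequencies(4.0, "1H", -2.5, quad=quad, direction=Z)


class TestMQFrequencies:
    def test_n14_dq_doublet_20_and_12(self):
        assert mq_frequencies([(4.0, "14N", 2)], -2.5)[0].offset_mhz == 20.0
        assert mq_frequencies([(4.0, "14N", 2)], -1.5)[0].offset_mhz == 12.0

    def test_two_proton_dq_combination(self):
        lines = mq_frequencies([(6.4, "1H", 1), (5.3, "1H", 1)], -2.5)
        assert lines[0].offset_mhz == pytest.approx(29.25)

    def test_zero_coupling_participant_contributes_nothing(self):
        with_zero = mq_frequencies([(6.4, "1H", 1), (0.0, "1H", 1)], -2.5)
        assert with_zero[0].offset_mhz == pytest.approx(16.0)

    def test_flip_exceeding_2i_rejected(self):
        with pytest.raises(SpinModelError):
            mq_frequencies([(4.0, "1H", 2)], -2.5)

    def test_single_quantum_not_a_multiquantum(self):
        with pytest.raises(SpinModelError):
            mq_frequencies([(4.0, "1H", 1)], -2.5)


class TestOffsetToAeff:
    def test_printed_sq_edge_inverts_to_minus_4p8(self):
        assert offset_to_aeff(-12.0, -2.5, 1) == pytest.approx(-4.8)

    def test_dq_doublet_inverts_consistently(self):
        assert offset_to_aeff(20.0, -2.5, 2) == pytest.approx(4.0)
        assert offset_to_aeff(12.0, -1.5, 2) == pytest.approx(4.0)

    def test_degenerate_inversion_rejected(self):
        with pytest.raises(SpinModelError):
            offset_to_aeff(5.0, -2.5, 0)

    @given(
        a=st.floats(-8, 8),
        ms=st.sampled_from([-2.5, -1.5, -0.5, 0.5, 1.5]),
        q=st.integers(1, 3),
    )
    @settings(derandomize=True, max_examples=200)
    def test_forward_inverse_identity(self, a, ms, q):
        offset = -ms * q * a
        assert offset_to_aeff(offset, ms, q) == pytest.approx(a, abs=1e-9)


class TestSynthesize:
    def test_single_component_single_manifold_gaussian(self):
        axis = np.arange(5.0, 25.0, 0.02)
        spec = synthesize_spectrum(
            [SpectralComponent(6.0, 2.0, manifolds=(-2.5,))], axis, "eldor_sq"
        )
        peak = axis[np.argmax(spec.amplitude)]
        assert peak == pytest.approx(15.0, abs=0.05)
        half = axis[spec.amplitude > spec.amplitude.max() / 2]
        assert half[-1] - half[0] == pytest.approx(2.0, abs=0.1)

    def test_two_components_give_8_and_16_features(self):
        axis = np.arange(-5.0, 25.0, 0.02)
        spec = synthesize_spectrum(
            [SpectralComponent(5.3, 2.2), SpectralComponent(6.4, 2.2)],
            axis, "eldor_sq",
        )
        pk, _ = find_peaks(spec.amplitude, prominence=0.05 * spec.amplitude.max())
        peaks = axis[pk]
        assert np.min(np.abs(peaks - 8.0)) < 1.0
        assert np.min(np.abs(peaks - 16.0)) < 0.5

    def test_amplitudes_scale_linearly(self):
        axis = np.arange(-5.0, 25.0, 0.05)
        c1 = [SpectralComponent(5.0, 2.0, amplitude=1.0)]
        c2 = [SpectralComponent(5.0, 2.0, amplitude=3.0)]
        s1 = synthesize_spectrum(c1, axis).amplitude
        s2 = synthesize_spectrum(c2, axis).amplitude
        assert np.allclose(s2, 3 * s1)

    def test_endor_kind_places_both_branches(self):
        axis = np.arange(-20.0, 20.0, 0.05)
        spec = synthesize_spectrum(
            [SpectralComponent(6.0, 0.5, manifolds=(-1.5,))], axis, "endor"
        )
        assert spec.amplitude[np.argmin(np.abs(axis - 9.0))] > 0.5
        assert spec.amplitude[np.argmin(np.abs(axis + 9.0))] > 0.5


class TestFitComponents:
    def test_noise_free_two_component_recovery(self):
        axis = np.arange(-6.0, 25.0, 0.05)
        spec = synthesize_spectrum(
            [SpectralComponent(5.3, 2.2), SpectralComponent(6.4, 2.2),
             SpectralComponent(0.0, 2.2)],
            axis, "eldor_sq",
        )
        fit = fit_components(spec, 2)
        a = sorted(c.a_eff_mhz for c in fit.components)
        assert a[0] == pytest.approx(5.3, abs=0.05)
        assert a[1] == pytest.approx(6.4, abs=0.05)

    def test_third_weak_component_recovered(self):
        axis = np.arange(-6.0, 25.0, 0.05)
        spec = synthesize_spectrum(
            [SpectralComponent(5.3, 2.2), SpectralComponent(6.4, 2.2),
             SpectralComponent(2.6, 2.2, amplitude=0.6),
             SpectralComponent(0.0, 2.2)],
            axis, "eldor_sq",
        )
        fit = fit_components(spec, 3)
        a = sorted(c.a_eff_mhz for c in fit.components)
        assert a[0] == pytest.approx(2.6, abs=0.1)

    def test_seeded_noise_shifts_below_0p2_mhz(self):
        axis = np.arange(-6.0, 25.0, 0.05)
        spec = synthesize_spectrum(
            [SpectralComponent(5.3, 2.2), SpectralComponent(6.4, 2.2),
             SpectralComponent(0.0, 2.2)],
            axis, "eldor_sq",
        )
        for seed in range(20):
            fit = fit_components(add_noise(spec, 20, seed=seed), 2)
            a = sorted(c.a_eff_mhz for c in fit.components)
            assert abs(a[0] - 5.3) < 0.2 and abs(a[1] - 6.4) < 0.2

    def test_all_zero_spectrum_rejected(self):
        from sodepr.fieldsweep import Spectrum

        spec = Spectrum(np.arange(0.0, 10.0, 0.1), np.zeros(100), "eldor_sq")
        with pytest.raises(SpinModelError):
            fit_components(spec, 1)


class TestDQEdges:
    def test_high_edge_from_measured_components(self):
        lo, hi = dq_edges([6.4, 5.3], -2.5)
        assert hi == pytest.approx(29.25)

    def test_identical_pair_reading(self):
        lo, hi = dq_edges([6.4], -2.5)
        assert hi == pytest.approx(32.0)

    def test_all_zero_components(self):
        assert dq_edges([0.0, 0.0], -2.5) == (0.0, 0.0)

    @given(
        st.lists(st.floats(-8, 8), min_size=2, max_size=5),
        st.sampled_from([-2.5, -1.5]),
    )
    @settings(derandomize=True, max_examples=100)
    def test_high_edge_equals_sum_of_two_largest_sq_offsets(self, a_values, ms):
        """Exact identity of the line-position algebra."""
        _, hi = dq_edges(a_values, ms)
        sq = sorted(-ms * a for a in a_values)
        assert hi == pytest.approx(sq[-1] + sq[-2], abs=1e-9)


class TestDQQuadrupoleInvariance:
    def test_single_nucleus_dq_ignores_quadrupole(self, rng):
        """DQ positions are pure hyperfine; SQ positions shift with the EFG."""
        direction = np.array([0.0, 0.0, 1.0])
        dq_ref = mq_frequencies([(4.0, "14N", 2)], -2.5)[0].offset_mhz
        sq_positions = set()
        for _ in range(100):
            p = rng.uniform(0.2, 1.5)
            frame = EulerAngles(rng.uniform(0, 2 * np.pi),
                                rng.uniform(0, np.pi),
                                rng.uniform(0, 2 * np.pi))
            quad = QuadrupoleTensor((-p / 2, -p / 2, p), frame)
            dq = mq_frequencies([(4.0, "14N", 2)], -2.5)[0].offset_mhz
            assert dq == dq_ref
            sq = sq_frequencies(4.0, "14N", -2.5, quad=quad, direction=direction)
            sq_positions.add(round(max(l.offset_mhz for l in sq), 6))
        assert len(sq_positions) > 10  # the SQ lines really do move
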