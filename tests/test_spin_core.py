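"""First-order S=5/2 arithmetic: shifts, turning points, read-off inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sodepr.spin_core import (
    CANONICAL_ORIENTATIONS,
    MS_LOWER,
    Orientation,
    SpectrometerSettings,
    SpinModelError,
    ZFSParameters,
    boltzmann_weight,
    boltzmann_weights,
    canonical_positions,
    canonicalize_zfs,
    exact_transition_ghz,
    firstorder_shift,
    invert_turning_points,
    resonance_field,
)

MAGIC = math.acos(math.sqrt(1.0 / 3.0))


class TestFirstOrderShift:
    def test_vanishes_at_magic_angle_for_axial_tensor(self):
        zfs = ZFSParameters(-7.3, 0.0)
        for ms in MS_LOWER:
            assert firstorder_shift(zfs, Orientation(MAGIC, 0.3), ms) == pytest.approx(
                0.0, abs=1e-12
            )

    @pytest.mark.parametrize(
        "orient, expected",
        [
            (Orientation(0.0, 0.0), 42.40),  # (-2) * 2D along D_zz
            (Orientation(math.pi / 2, math.pi / 2), -17.42),  # (-2) * (-D - 3E)
        ],
    )
    def test_mn_mn_sod_canonical_shifts(self, orient, expected):
        zfs = ZFSParameters(-10.60, 0.63)
        assert firstorder_shift(zfs, orient, -2.5) == pytest.approx(expected, abs=1e-10)

    def test_equatorial_sweep_spans_minus_d_plus_minus_3e(self):
        zfs = ZFSParameters(-10.60, 0.63)
        phis = np.linspace(0, 2 * math.pi, 721)
        vals = np.array(
            [
                firstorder_shift(zfs, Orientation(math.pi / 2, p), -1.5)
                for p in phis
            ]
        )
        # the equatorial bracket spans -D -/+ 3E; the (ms + 1/2) = -1 factor
        # at ms = -3/2 maps it onto [D - 3E, D + 3E]
        assert vals.max() == pytest.approx(zfs.d_ghz + 3 * zfs.e_ghz, abs=1e-9)
        assert vals.min() == pytest.approx(zfs.d_ghz - 3 * zfs.e_ghz, abs=1e-9)

    def test_invalid_manifold_rejected(self):
        with pytest.raises(SpinModelError):
            firstorder_shift(ZFSParameters(-10.0), Orientation(0.0), 2.5)


class TestResonanceField:
    def test_isotropic_limit_gives_center_field(self, w_band):
        zfs = ZFSParameters(1e-30, 0.0, allow_noncanonical=True)
        b = resonance_field(w_band, zfs, Orientation(0.3, 0.1), -0.5)
        assert b == pytest.approx(3354.2, abs=1.0)  # nu_obs*h/(g*beta) at 94 GHz

    def test_mn_mn_zz_edge_sits_1513_mt_below_center(self, w_band):
        zfs = ZFSParameters(-10.60, 0.63)
        b = resonance_field(w_band, zfs, Orientation(0.0), -2.5)
        assert w_band.center_field_mt - b == pytest.approx(1513.0, abs=1.0)

    def test_opposite_shifts_mirror_about_center(self, w_band):
        # (ms + 1/2) is -2 for ms=-5/2 and +2 for ms=+3/2: equal and
        # opposite shifts at any single orientation
        zfs = ZFSParameters(-9.1, 1.7)
        o = Orientation(0.77, 2.1)
        b1 = resonance_field(w_band, zfs, o, -2.5)
        b2 = resonance_field(w_band, zfs, o, 1.5)
        assert b1 + b2 == pytest.approx(2 * w_band.center_field_mt, rel=1e-12)

    def test_unphysical_combination_rejected(self):
        settings_low = SpectrometerSettings(nu_obs_ghz=9.5, temperature_k=6.0)
        with pytest.raises(SpinModelError):
            resonance_field(settings_low, ZFSParameters(-10.6, 0.6), Orientation(0.0), -2.5)


class TestCanonicalPositionsAndInversion:
    def test_zero_zfs_collapses_to_center(self, w_band):
        zfs = ZFSParameters(1e-30, 0.0, allow_noncanonical=True)
        tp = canonical_positions(w_band, zfs)
        for b in tp.positions.values():
            assert b == pytest.approx(tp.center_mt, abs=1e-6)

    def test_mn_fe_sign_pattern_for_negative_d(self, w_band):
        tp = canonical_positions(w_band, ZFSParameters(-10.46, 0.33))
        assert tp[("zz", -2.5)] < tp.center_mt
        assert tp[("xx", -2.5)] > tp.center_mt
        assert tp[("yy", -2.5)] > tp.center_mt
        assert len(set(np.round(list(tp.positions.values()), 3))) == 6

    def test_zz_offsets_scale_with_manifold_factor(self, w_band):
        tp = canonical_positions(w_band, ZFSParameters(-10.60, 0.63))
        assert tp.offset(("zz", -2.5)) == pytest.approx(
            2 * tp.offset(("zz", -1.5)), rel=1e-12
        )

    @pytest.mark.parametrize("d, e", [(-10.60, 0.63), (-10.46, 0.33)])
    def test_readoff_roundtrip_is_exact(self, w_band, d, e):
        recovered = invert_turning_points(
            canonical_positions(w_band, ZFSParameters(d, e)), w_band
        )
        assert recovered.d_ghz == pytest.approx(d, abs=1e-9)
        assert recovered.e_ghz == pytest.approx(e, abs=1e-9)

    def test_rigid_field_shift_cancels(self, w_band):
        tp = canonical_positions(w_band, ZFSParameters(-10.60, 0.63))
        tp.positions = {k: v + 1.0 for k, v in tp.positions.items()}
        rec = invert_turning_points(tp, w_band)
        assert rec.d_ghz == pytest.approx(-10.60, abs=1e-9)
        assert rec.e_ghz == pytest.approx(0.63, abs=1e-9)

    def test_roundtrip_over_random_zfs(self, w_band, rng):
        for _ in range(1000):
            d = rng.uniform(1, 15) * rng.choice([-1, 1])
            e = rng.uniform(0, abs(d) / 3)
            rec = invert_turning_points(
                canonical_positions(w_band, ZFSParameters(d, e)), w_band
            )
            assert abs(rec.d_ghz - d) < 1e-9 and abs(rec.e_ghz - e) < 1e-9

    def test_missing_labels_raise(self, w_band):
        tp = canonical_positions(w_band, ZFSParameters(-10.0, 0.5))
        del tp.positions[("yy", -2.5)]
        with pytest.raises(SpinModelError):
            invert_turning_points(tp, w_band)

    def test_noncanonical_recovery_warns_but_returns(self, w_band):
        tp = canonical_positions(w_band, ZFSParameters(-10.0, 0.5))
        # swap xx and yy: E comes out negative
        tp.positions[("xx", -2.5)], tp.positions[("yy", -2.5)] = (
            tp.positions[("yy", -2.5)],
            tp.positions[("xx", -2.5)],
        )
        with pytest.warns(UserWarning):
            rec = invert_turning_points(tp, w_band)
        assert rec.e_ghz < 0


class TestZFSValidation:
    def test_rhombicity_convention_enforced(self):
        with pytest.raises(SpinModelError):
            ZFSParameters(-10.0, 5.0)
        with pytest.raises(SpinModelError):
            ZFSParameters(0.0, 0.0)

    @given(
        d=st.floats(-15, 15).filter(lambda x: abs(x) > 0.5),
        e=st.floats(-10, 10),
    )
    @settings(derandomize=True, max_examples=200)
    def test_canonicalize_preserves_tensor_and_lands_in_convention(self, d, e):
        z = canonicalize_zfs(d, e)
        assert 0 <= z.e_ghz <= abs(z.d_ghz) / 3 + 1e-9
        lam_in = sorted([-d / 3 + e, -d / 3 - e, 2 * d / 3])
        lam_out = sorted(
            [-z.d_ghz / 3 + z.e_ghz, -z.d_ghz / 3 - z.e_ghz, 2 * z.d_ghz / 3]
        )
        assert np.allclose(lam_in, lam_out, atol=1e-9)


class TestBoltzmann:
    def test_infinite_temperature_limit(self):
        s = SpectrometerSettings(temperature_k=1e9)
        for ms in (-2.5, 0.5, 2.5):
            assert boltzmann_weight(s, 3355.0, ms) == pytest.approx(1 / 6, abs=1e-6)

    def test_low_temperature_population_ordering(self, w_band):
        w = boltzmann_weights(w_band, 3355.0)
        ordered = [w[m] for m in (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)]
        assert all(a > b for a, b in zip(ordered, ordered[1:]))

    def test_normalization(self, w_band):
        assert sum(boltzmann_weights(w_band, 2000.0).values()) == pytest.approx(1.0)


class TestExactDiagonalizationOracle:
    def test_firstorder_within_second_order_bound_at_turning_points(
        self, w_band, rng
    ):
        """At the canonical orientations the read-off relies on, the
        closed-form shift tracks the exact 6x6 eigenvalue differences to
        within 5*D^2/nu_obs."""
        b0 = w_band.center_field_mt
        for _ in range(60):
            d = rng.uniform(8, 12) * rng.choice([-1, 1])
            bound = 5 * d**2 / w_band.nu_obs_ghz
            zfs = ZFSParameters(d, rng.uniform(0, abs(d) / 3))
            for orient in CANONICAL_ORIENTATIONS.values():
                for ms in MS_LOWER:
                    approx_freq = w_band.ghz_per_mt * b0 + firstorder_shift(
                        zfs, orient, ms
                    )
                    exact = exact_transition_ghz(w_band, zfs, orient, b0, ms)
                    assert abs(exact - approx_freq) < bound

    def test_general_orientation_error_stays_second_order(self, w_band, rng):
        """Away from the canonical orientations the second-order error grows
        but remains bounded by an empirical 14*D^2/nu_obs envelope."""
        b0 = w_band.center_field_mt
        for _ in range(60):
            d = rng.uniform(8, 12) * rng.choice([-1, 1])
            zfs = ZFSParameters(d, rng.uniform(0, abs(d) / 3))
            orient = Orientation(rng.uniform(0, math.pi), rng.uniform(0, 2 * math.pi))
            ms = rng.choice(MS_LOWER)
            approx_freq = w_band.ghz_per_mt * b0 + firstorder_shift(zfs, orient, ms)
            exact = exact_transition_ghz(w_band, zfs, orient, b0, ms)
            assert abs(exact - approx_freq) < 14 * d**2 / w_band.nu_obs_ghz
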