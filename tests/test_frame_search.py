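"""Tensor conditioning and the brute-force Euler frame search."""

import math

import numpy as np
import pytest

from sodepr.frame_search import (
    ENDOR_WINDOW_MHZ,
    SearchTargets,
    TensorSet,
    adjust_aiso,
    euler_grid_search,
    frame_distance_deg,
    predict_constraints,
    symmetrize_tensor,
    symmetry_orbit,
)
from sodepr.orientation_select import EulerAngles, HyperfineTensor, effective_coupling

Z = np.array([0.0, 0.0, 1.0])


class TestSymmetrize:
    def test_axial_tensor_unchanged(self):
        hft = HyperfineTensor("1H", 0.2, (-2.0, -2.0, 4.0))
        out = symmetrize_tensor(hft)
        assert tuple(out.t_principal_mhz) == (-2.0, -2.0, 4.0)

    def test_rhombic_tensor_averaged(self):
        hft = HyperfineTensor("1H", 0.0, (-1.0, -3.0, 4.0))
        out = symmetrize_tensor(hft)
        assert tuple(out.t_principal_mhz) == (-2.0, -2.0, 4.0)
        assert out.t_principal_mhz.sum() == pytest.approx(0.0, abs=1e-12)
        assert out.a_iso_mhz == hft.a_iso_mhz


class TestAdjustAiso:
    def _set(self, a_iso=0.0):
        return TensorSet({"H": HyperfineTensor("1H", a_iso, (-3.2, -3.2, 6.4))})

    def test_matching_prediction_needs_no_shift(self):
        ts = self._set()
        predicted = effective_coupling(ts.hyperfine["H"], Z, -2.5).a_eff_mhz
        _, shifts = adjust_aiso(ts, {"H": predicted}, Z)
        assert shifts["H"] == pytest.approx(0.0, abs=1e-12)

    def test_known_offset_recovered(self):
        ts = self._set(a_iso=0.0)
        predicted = effective_coupling(ts.hyperfine["H"], Z, -2.5).a_eff_mhz
        adjusted, shifts = adjust_aiso(ts, {"H": predicted + 0.4}, Z)
        assert shifts["H"] == pytest.approx(0.4, abs=1e-9)
        assert adjusted.hyperfine["H"].a_iso_mhz == pytest.approx(0.4)

    def test_large_shift_clamped_with_warning(self):
        ts = self._set()
        predicted = effective_coupling(ts.hyperfine["H"], Z, -2.5).a_eff_mhz
        with pytest.warns(UserWarning, match="clamp"):
            _, shifts = adjust_aiso(ts, {"H": predicted + 2.0}, Z, max_shift_mhz=0.5)
        assert shifts["H"] == pytest.approx(0.5)


class TestPredictConstraints:
    def test_identity_frame_reproduces_direct_projection(self, toy_tensors):
        coup, spec = predict_constraints(toy_tensors, EulerAngles())
        for name, hft in toy_tensors.hyperfine.items():
            direct = effective_coupling(hft, Z, -2.5).a_eff_mhz
            assert coup[name] == pytest.approx(direct, abs=1e-9)
        assert spec.axis[0] <= ENDOR_WINDOW_MHZ[0]
        assert spec.axis[-1] >= ENDOR_WINDOW_MHZ[1]

    def test_water_protons_dominate_along_pseudo_symmetry_axis(self, toy_tensors):
        coup, _ = predict_constraints(toy_tensors, EulerAngles())
        protons = {k: v for k, v in coup.items() if k.startswith("H")}
        top_two = sorted(protons, key=lambda k: -protons[k])[:2]
        assert set(top_two) == {"H_w_prime", "H_w"}

    def test_y_rotation_swaps_zz_and_xx_roles(self, toy_tensors):
        rot = EulerAngles(0.0, math.pi / 2, 0.0)  # 90 degrees about y
        coup_rot, _ = predict_constraints(toy_tensors, rot)
        x = np.array([1.0, 0.0, 0.0])
        for name, hft in toy_tensors.hyperfine.items():
            # candidate D_zz now lies along -molecular x
            direct = effective_coupling(hft, x, -2.5).a_eff_mhz
            assert coup_rot[name] == pytest.approx(direct, abs=1e-9)

    def test_missing_nucleus_raises(self, toy_tensors):
        from sodepr.spin_core import SpinModelError

        with pytest.raises(SpinModelError):
            predict_constraints(toy_tensors, EulerAngles(), names=["nope"])


class TestEulerSearch:
    TARGET_NUCLEI = ("H_w_prime", "H_w", "N_eps_His26")

    def _targets(self, tensors, euler):
        coup, spec = predict_constraints(tensors, euler, window=(-12.0, 12.0))
        return SearchTargets(
            aeff_mhz={k: coup[k] for k in self.TARGET_NUCLEI}, endor=spec
        )

    def test_known_frame_recovered_within_grid_step(self, toy_tensors):
        true = EulerAngles.from_degrees(40.0, 55.0, 110.0)
        res = euler_grid_search(toy_tensors, self._targets(toy_tensors, true),
                                grid_step_deg=5.0)
        assert frame_distance_deg(res.best, true) <= 5.0

    def test_symmetry_orbit_members_share_the_score(self, toy_tensors):
        true = EulerAngles.from_degrees(25.0, 70.0, 200.0)
        targets = self._targets(toy_tensors, true)
        res = euler_grid_search(toy_tensors, targets, grid_step_deg=10.0,
                                refine=False)
        from sodepr.frame_search import _Scorer

        scorer = _Scorer(toy_tensors, targets, (1.0, 1.0))
        scores = [
            scorer(np.array([[e.alpha, e.beta, e.gamma]]))[0, 0]
            for e in symmetry_orbit(res.best)
        ]
        assert max(scores) - min(scores) < 1e-5
        assert len(res.symmetry_orbit) == 4

    def test_heavier_coupling_weight_cannot_worsen_coupling_fit(self, toy_tensors):
        true = EulerAngles.from_degrees(70.0, 40.0, 10.0)
        targets = self._targets(toy_tensors, true)
        r1 = euler_grid_search(toy_tensors, targets, grid_step_deg=10.0,
                               weights=(1.0, 1.0), refine=False)
        r2 = euler_grid_search(toy_tensors, targets, grid_step_deg=10.0,
                               weights=(2.0, 1.0), refine=False)
        assert r2.aeff_rms_mhz <= r1.aeff_rms_mhz + 1e-9

    def test_invalid_grid_step_rejected(self, toy_tensors):
        targets = self._targets(toy_tensors, EulerAngles())
        with pytest.raises(ValueError):
            euler_grid_search(toy_tensors, targets, grid_step_deg=7.0)


class TestFrameDistance:
    def test_orbit_members_have_zero_distance(self):
        e = EulerAngles.from_degrees(33.0, 61.0, 140.0)
        for member in symmetry_orbit(e):
            assert frame_distance_deg(e, member) == pytest.approx(0.0, abs=1e-6)

    def test_known_rotation_angle(self):
        a = EulerAngles()
        b = EulerAngles.from_degrees(0.0, 20.0, 0.0)
        assert frame_distance_deg(a, b) == pytest.approx(20.0, abs=1e-6)
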