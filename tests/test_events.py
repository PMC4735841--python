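"""Selection cuts, three-interaction energy determination and cone building."""

import numpy as np
import pandas as pd
import pytest

from comptel.events import (ConeEvent, TripleEvent, cone_from_triple,
                            cones_from_listmode, geometric_cos_angle,
                            incident_energy_from_triple, listmode_to_triples,
                            read_cones, select_events, write_cones)
from comptel.physics import scattered_energy


def _triples_frame(rows):
    return pd.DataFrame(rows, columns=["event_id", "e1", "e2", "e3"]).assign(
        total_energy=lambda d: d.e1 + d.e2 + d.e3)


class TestSelection:
    def test_sum_window_inclusive(self):
        tr = _triples_frame([(0, 300.0, 500.0, 475.0),   # 1275 -> kept
                             (1, 100.0, 200.0, 211.0),   # 511  -> rejected
                             (2, 100.0, 300.0, 400.0)])  # 800 boundary -> kept
        out = select_events(tr, (800.0, 1400.0))
        assert list(out.event_id) == [0, 2]

    def test_idempotent(self):
        tr = _triples_frame([(0, 300.0, 500.0, 475.0), (1, 50.0, 60.0, 70.0)])
        once = select_events(tr, (800, 1400))
        twice = select_events(once, (800, 1400))
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_input(self):
        out = select_events(_triples_frame([]), (800, 1400))
        assert out.empty


class TestGeometricAngle:
    def test_collinear_right_angle_reversal(self):
        r1 = np.array([0.0, 0.0, 0.0])
        r2 = np.array([0.0, 0.0, 10.0])
        assert geometric_cos_angle(r1, r2, [0, 0, 20.0]) == pytest.approx(1.0)
        assert geometric_cos_angle(r1, r2, [10.0, 0, 10.0]) == pytest.approx(
            0.0, abs=1e-12)
        assert geometric_cos_angle(r1, r2, r1) == pytest.approx(-1.0)

    def test_coincident_points_degenerate(self):
        with pytest.raises(ValueError):
            geometric_cos_angle([0, 0, 0.0], [0, 0, 0.0], [1, 1, 1.0])


class TestIncidentEnergy:
    def test_forward_constructed_two_scatter(self):
        """A 611 keV photon deposits 100, leaving 511 keV, which at 90 deg
        deposits exactly 255.5 keV."""
        e0 = incident_energy_from_triple(100.0, 255.5, 0.0)
        assert e0 == pytest.approx(611.0, abs=1e-9)

    def test_random_forward_kinematics_inverts(self, rng):
        """The estimator inverts forward Compton kinematics exactly."""
        for _ in range(200):
            e_in = rng.uniform(600, 2000)
            c1 = rng.uniform(-0.9, 0.95)
            e_after1 = scattered_energy(e_in, c1)
            e1 = e_in - e_after1
            c2 = rng.uniform(-0.9, 0.95)
            e2 = e_after1 - scattered_energy(e_after1, c2)
            if min(e1, e2) < 1.0:
                continue
            e0 = incident_energy_from_triple(e1, e2, c2)
            assert e0 == pytest.approx(e_in, rel=1e-9)

    def test_degenerate_forward_scatter(self):
        with pytest.raises(ValueError):
            incident_energy_from_triple(100.0, 200.0, 1.0)

    def test_exceeds_deposits(self):
        e0 = incident_energy_from_triple(120.0, 310.0, -0.3)
        assert e0 > 120.0 + 310.0


class TestConeFromTriple:
    def test_axis_normalized_and_fields(self, geometry):
        ev = TripleEvent(e1=200.0, e2=400.0, e3=300.0,
                         r1=np.array([1.0, 0.0, 2.5]),
                         r2=np.array([-2.0, 3.0, 67.5]),
                         r3=np.array([4.0, -1.0, 140.0]))
        cone = cone_from_triple(ev, geometry)
        assert np.linalg.norm(cone.axis) == pytest.approx(1.0, abs=1e-12)
        assert 0 < cone.half_angle < np.pi
        assert cone.half_angle_sigma > 0
        assert cone.e0_estimate > 600
        # axis points from layer 2 back through layer 1
        assert cone.axis[2] < 0

    def test_inconsistent_triple_rejected(self, geometry):
        # backscatter geometry with e2 = 60 keV fixes E0 - e1 = 157.4 keV;
        # e1 = 600 keV then implies cos(theta1) = -1.57: unphysical
        ev = TripleEvent(e1=600.0, e2=60.0, e3=30.0,
                         r1=np.array([0.0, 0.0, 2.5]),
                         r2=np.array([0.0, 1.0, 67.5]),
                         r3=np.array([0.0, 0.0, 2.5]))
        with pytest.raises(ValueError):
            cone_from_triple(ev, geometry)


class TestNoiseFreeOracle:
    def test_exact_incident_energy_recovery(self, geometry, noise_free_triples):
        """Noise-free ordered 1275 keV triples reconstruct E0 = 1275 exactly."""
        tr = noise_free_triples
        r1 = tr[["x1", "y1", "z1"]].to_numpy()
        r2 = tr[["x2", "y2", "z2"]].to_numpy()
        r3 = tr[["x3", "y3", "z3"]].to_numpy()
        c2 = geometric_cos_angle(r1, r2, r3)
        ok = c2 < 1 - 1e-6
        e0 = incident_energy_from_triple(tr.e1.to_numpy()[ok],
                                         tr.e2.to_numpy()[ok], c2[ok])
        assert np.max(np.abs(e0 - 1275.0) / 1275.0) < 1e-9

    def test_source_lies_on_every_cone(self, geometry, noise_free_triples):
        """For ideal ordered triples the source direction lies on the cone."""
        cones = cones_from_listmode(
            _listmode_from_triples(noise_free_triples), geometry,
            sum_window=None)
        assert len(cones) >= 10
        apex = cones[["apex_x_mm", "apex_y_mm", "apex_z_mm"]].to_numpy()
        axis = cones[["axis_x", "axis_y", "axis_z"]].to_numpy()
        src = np.array([0.0, 0.0, -35.0])
        to_src = src[None, :] - apex
        to_src /= np.linalg.norm(to_src, axis=1, keepdims=True)
        ang = np.arccos(np.clip(np.sum(to_src * axis, axis=1), -1, 1))
        resid = np.abs(ang - cones.half_angle_rad.to_numpy())
        assert np.max(resid) < 1e-6


def _listmode_from_triples(tr):
    rows = []
    for _, r in tr.iterrows():
        for li in (1, 2, 3):
            rows.append({"event_id": int(r.event_id), "layer": li,
                         "x_mm": r[f"x{li}"], "y_mm": r[f"y{li}"],
                         "z_mm": r[f"z{li}"], "e_kev": r[f"e{li}"],
                         "t_ns": 0.0})
    return pd.DataFrame(rows)


class TestListmodePlumbing:
    def test_pivot_round_trip(self):
        tr = pd.DataFrame({
            "event_id": [3], "e1": [200.0], "e2": [300.0], "e3": [400.0],
            "x1": [0.1], "y1": [0.2], "z1": [2.5],
            "x2": [1.0], "y2": [2.0], "z2": [67.5],
            "x3": [3.0], "y3": [4.0], "z3": [140.0]})
        lm = _listmode_from_triples(tr)
        back = listmode_to_triples(lm)
        assert back.e1.iloc[0] == 200.0
        assert back.total_energy.iloc[0] == pytest.approx(900.0)

    def test_cone_file_round_trip(self, geometry, noise_free_triples, tmp_path):
        cones = cones_from_listmode(
            _listmode_from_triples(noise_free_triples.head(20)), geometry,
            sum_window=None)
        write_cones(cones, tmp_path / "c.csv")
        back = read_cones(tmp_path / "c.csv")
        np.testing.assert_allclose(back.half_angle_rad, cones.half_angle_rad,
                                   rtol=1e-8)
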