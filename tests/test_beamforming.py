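"""Sphere forward model and LCMV inverse: analytic properties and round trips."""

import numpy as np
import pytest

import entropyscope as es
from entropyscope.beamforming import MU0_4PI


def primary_dipole_radial_field(loc, q, head):
    """Independent oracle: in a spherical conductor the volume currents add
    nothing to the radial field component, so radial sensors must see exactly
    the Biot-Savart field of the primary current dipole alone."""
    r = head.sensor_positions - head.sphere_center
    r0 = np.asarray(loc) - head.sphere_center
    d = r - r0
    B = MU0_4PI * np.cross(q, d) / np.linalg.norm(d, axis=1, keepdims=True) ** 3
    rhat = r / np.linalg.norm(r, axis=1, keepdims=True)
    return np.einsum("ij,ij->i", B, rhat)


class TestSarvasLeadfield:
    def test_radial_dipole_produces_no_field(self, head):
        loc = np.array([0.0, 0.0, 0.05])
        radial = np.array([0.0, 0.0, 1.0])
        lf = es.sarvas_leadfield(loc, radial, head)
        tangential = es.sarvas_leadfield(loc, np.array([1.0, 0.0, 0.0]), head)
        assert np.abs(lf).max() < 1e-10 * np.abs(tangential).max()

    def test_linearity_in_moment(self, head):
        loc = np.array([0.02, 0.01, 0.04])
        q1 = np.array([0.3, -0.5, 0.1])
        q2 = np.array([-0.1, 0.2, 0.7])
        l1 = es.sarvas_leadfield(loc, q1, head)
        l2 = es.sarvas_leadfield(loc, q2, head)
        l12 = es.sarvas_leadfield(loc, 2 * q1 + 3 * q2, head)
        np.testing.assert_allclose(l12, 2 * l1 + 3 * l2, rtol=1e-12)

    def test_radial_projection_matches_primary_dipole_oracle(self, head):
        """Radial sensors: full sphere solution == primary Biot-Savart term."""
        loc = np.array([0.025, -0.015, 0.035])
        q = np.array([0.2, 0.6, -0.3])
        got = es.sarvas_leadfield(loc, q, head)  # fixture sensors are radial
        want = primary_dipole_radial_field(loc, q, head)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_reflection_symmetry(self):
        """Mirroring dipole, moment and sensors through the x-z plane mirrors
        the (pseudovector) field pattern."""
        pos, ori = es.spherical_sensor_array(30)
        head = es.HeadModel(np.zeros(3), 0.09, pos, ori)
        mirror = np.diag([1.0, -1.0, 1.0])
        head_m = es.HeadModel(np.zeros(3), 0.09, pos @ mirror, ori @ mirror)
        loc = np.array([0.02, 0.03, 0.04])
        q = np.array([0.1, 0.5, -0.2])
        lf = es.sarvas_leadfield(loc, q, head)
        # B is a pseudovector: mirrored source with mirrored moment gives a
        # field whose mirrored-radial projection flips sign
        lf_m = es.sarvas_leadfield(mirror @ loc, mirror @ q, head_m)
        np.testing.assert_allclose(lf_m, -lf, rtol=1e-10)

    def test_geometry_errors(self, head):
        with pytest.raises(ValueError):
            es.sarvas_leadfield(np.array([0.0, 0.0, 0.2]), np.ones(3), head)
        with pytest.raises(ValueError):
            es.sarvas_leadfield(np.zeros(3), np.ones(3), head)


class TestCovariance:
    def test_white_noise_gives_scaled_identity(self, head, rng):
        data = rng.standard_normal((48, 60000))
        rec = es.SensorRecording(data, 600.0, head.sensor_positions,
                                 head.sensor_orientations)
        C, eta2 = es.estimate_covariance(rec, band=(1, 150))
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 0.1 * np.diag(C).mean()
        assert np.allclose(np.diag(C), np.diag(C).mean(), rtol=0.2)
        assert eta2 > 0

    def test_duplicate_channels_floor_eta2(self, head, rng):
        row = rng.standard_normal(5000)
        data = np.tile(row, (48, 1))
        rec = es.SensorRecording(data, 600.0, head.sensor_positions,
                                 head.sensor_orientations)
        C, eta2 = es.estimate_covariance(rec)
        assert eta2 >= np.finfo(float).eps * np.trace(C)
        assert eta2 < 1e-10 * np.trace(C)

    def test_rank_deficiency_warns(self, head, rng):
        rec = es.SensorRecording(rng.standard_normal((48, 40)), 600.0,
                                 head.sensor_positions, head.sensor_orientations)
        with pytest.warns(UserWarning):
            es.estimate_covariance(rec)


@pytest.fixture(scope="module")
def dipole_scene(head):
    rng = np.random.default_rng(42)
    # place the source exactly on a grid point so localisation and the
    # round-trip correlation are evaluated at the matched voxel
    grid = es.make_grid(head, spacing=0.008)
    loc = grid[np.argmin(np.linalg.norm(grid - [0.03, 0.0, 0.04], axis=1))]
    u = loc / np.linalg.norm(loc)
    ori = np.cross(u, [0.0, 0.0, 1.0])
    ori /= np.linalg.norm(ori)
    h = es.sarvas_leadfield(loc, ori, head)
    q = rng.standard_normal(15000)
    signal = np.outer(h, q)
    noise_amp = np.linalg.norm(signal) / (np.sqrt(10) * np.sqrt(signal.size))
    data = signal + noise_amp * rng.standard_normal(signal.shape)
    rec = es.SensorRecording(data, 600.0, head.sensor_positions,
                             head.sensor_orientations)
    C, eta2 = es.estimate_covariance(rec)
    return {"grid": grid, "loc": loc, "q": q, "rec": rec, "C": C,
            "eta2": eta2, "h": h, "ori": ori}


class TestWeights:
    def test_unit_gain_everywhere(self, head, dipole_scene):
        sub = dipole_scene["grid"][::29]
        model = es.compute_weights(dipole_scene["C"], head, sub,
                                   mu=4.0, eta2=dipole_scene["eta2"])
        gains = np.einsum("ij,ij->i", model.weights, model.leadfields)
        np.testing.assert_allclose(gains, 1.0, rtol=1e-8)

    def test_localisation_and_round_trip(self, head, dipole_scene):
        model = es.compute_weights(dipole_scene["C"], head, dipole_scene["grid"],
                                   mu=4.0, eta2=dipole_scene["eta2"])
        peak = int(np.argmax(model.pseudo_z))
        err = np.linalg.norm(model.grid[peak] - dipole_scene["loc"])
        assert err <= 0.008  # within one grid step
        vol = es.project_sources(dipole_scene["rec"], model)
        r = np.corrcoef(vol.timecourses[peak], dipole_scene["q"])[0, 1]
        assert abs(r) > 0.95

    def test_high_mu_limit_is_matched_filter(self, head, dipole_scene):
        """As mu -> infinity the weight direction tends to the lead field."""
        loc = dipole_scene["loc"][None, :]
        model = es.compute_weights(dipole_scene["C"], head, loc, mu=1e12,
                                   eta2=dipole_scene["eta2"])
        w = model.weights[0]
        h = model.leadfields[0]
        cos = abs(w @ h) / (np.linalg.norm(w) * np.linalg.norm(h))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_scale_equivariance(self, head, dipole_scene):
        model = es.compute_weights(dipole_scene["C"], head,
                                   dipole_scene["loc"][None, :],
                                   mu=4.0, eta2=dipole_scene["eta2"])
        rec = dipole_scene["rec"]
        scaled = es.SensorRecording(3.5 * rec.data, rec.sampling_rate,
                                    rec.channel_positions, rec.channel_orientations)
        v1 = es.project_sources(rec, model).timecourses
        v2 = es.project_sources(scaled, model).timecourses
        np.testing.assert_allclose(v2, 3.5 * v1, rtol=1e-12)

    def test_noise_free_unit_gain_projection(self, head, dipole_scene):
        """m(t) = h q(t) with the matching fixed orientation recovers q(t)
        exactly at the source voxel: the unit-gain constraint wT h = 1."""
        h, q, ori = dipole_scene["h"], dipole_scene["q"], dipole_scene["ori"]
        rec = es.SensorRecording(np.outer(h, q), 600.0, head.sensor_positions,
                                 head.sensor_orientations)
        C, eta2 = es.estimate_covariance(rec)
        model = es.compute_weights(C, head, dipole_scene["loc"][None, :],
                                   mu=4.0, eta2=eta2,
                                   fixed_orientations=ori[None, :])
        out = es.project_sources(rec, model).timecourses[0]
        np.testing.assert_allclose(out, q, atol=1e-8 * np.abs(q).max())

    def test_zero_input_zero_output(self, head, dipole_scene):
        model = es.compute_weights(dipole_scene["C"], head,
                                   dipole_scene["loc"][None, :],
                                   mu=4.0, eta2=dipole_scene["eta2"])
        rec = es.SensorRecording(np.zeros((48, 100)), 600.0,
                                 head.sensor_positions, head.sensor_orientations)
        assert not es.project_sources(rec, model).timecourses.any()

    def test_channel_mismatch_rejected(self, head, dipole_scene):
        model = es.compute_weights(dipole_scene["C"], head,
                                   dipole_scene["loc"][None, :])
        bad = es.SensorRecording(np.zeros((10, 100)), 600.0,
                                 head.sensor_positions[:10],
                                 head.sensor_orientations[:10])
        with pytest.raises(ValueError):
            es.project_sources(bad, model)

    def test_grid_outside_sphere_rejected(self, head, dipole_scene):
        with pytest.raises(ValueError):
            es.compute_weights(dipole_scene["C"], head,
                               np.array([[0.0, 0.0, 0.2]]))
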