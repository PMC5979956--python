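"""Forward models and cohort structure of the synthetic phantom."""

import numpy as np
import pytest

from gratiomap.mtsat import (
    FlashTriplet,
    compute_aapp,
    compute_delta_app,
    compute_r1app,
)
from gratiomap.noddi import DiffusionScheme
from gratiomap.phantom import (
    CohortSpec,
    PhantomConfig,
    TRACT_NAMES,
    add_rician_noise,
    flash_mt_forward,
    generate_cohort,
    generate_phantom,
    noddi_forward,
    two_shell_scheme,
)

from conftest import small_config


class TestFlashForward:
    def test_mtsat_roundtrip_recovers_delta(self):
        # forward-simulate the triplet, invert with the mapping equations
        pd, r1, delta = 1000.0, 1.0, 0.02
        deg = np.pi / 180
        s_pd = flash_mt_forward(pd, r1, 0.0, 5 * deg, 0.024)
        s_t1 = flash_mt_forward(pd, r1, 0.0, 13 * deg, 0.010)
        s_mt = flash_mt_forward(pd, r1, delta, 5 * deg, 0.024)
        trip = FlashTriplet(s_pd=np.array([s_pd]), s_t1=np.array([s_t1]),
                            s_mt=np.array([s_mt]))
        a_app = compute_aapp(trip)
        r1app = compute_r1app(trip)
        d = compute_delta_app(trip.s_mt, 5.0, 0.024, a_app, r1app)
        assert abs(d[0] - 0.02) <= 1e-6

    def test_zero_delta_is_plain_flash(self):
        s = flash_mt_forward(1000.0, 1.0, 0.0, 0.1, 0.024)
        expected = 1000.0 * 0.1 * 1.0 * 0.024 / (0.024 + 0.005)
        assert s == pytest.approx(expected, rel=1e-12)

    def test_linear_in_amplitude(self):
        s1 = flash_mt_forward(500.0, 1.0, 0.02, 0.1, 0.024)
        s2 = flash_mt_forward(1000.0, 1.0, 0.02, 0.1, 0.024)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_monotone_decreasing_in_delta(self):
        deltas = np.linspace(0.0, 0.1, 20)
        s = flash_mt_forward(1000.0, 1.0, deltas, 0.1, 0.024)
        assert np.all(np.diff(s) < 0)

    def test_nonpositive_tr_rejected(self):
        with pytest.raises(ValueError):
            flash_mt_forward(1000.0, 1.0, 0.02, 0.1, 0.0)


class TestNoddiForward:
    def test_free_water_is_monoexponential(self, scheme):
        sig = noddi_forward(0.5, 1.0, 16.0, [0, 0, 1], scheme)
        b1000 = scheme.bvals == 1000
        assert np.allclose(sig[b1000], np.exp(-3.0), atol=1e-4)

    def test_b0_is_exactly_one(self, scheme):
        sig = noddi_forward(0.6, 0.1, 16.0, [0, 0, 1], scheme)
        assert sig[scheme.b0_indices[0]] == 1.0

    def test_signal_in_unit_interval(self, scheme):
        for vic, viso, kappa in [(0.2, 0.0, 0.5), (0.9, 0.3, 64.0), (0.0, 0.0, 1.0)]:
            sig = noddi_forward(vic, viso, kappa, [0, 0, 1], scheme)
            assert np.all(sig >= 0) and np.all(sig <= 1 + 1e-12)

    def test_invalid_fractions_rejected(self, scheme):
        with pytest.raises(ValueError):
            noddi_forward(1.2, 0.0, 1.0, [0, 0, 1], scheme)


class TestRicianNoise:
    def test_zero_sigma_is_identity(self):
        x = np.linspace(0, 10, 100)
        assert np.array_equal(add_rician_noise(x, 0.0, 1), x)

    def test_zero_signal_gives_rayleigh_mean(self):
        # |complex N(0, 1)| has mean sqrt(pi/2)
        noisy = add_rician_noise(np.zeros(200_000), 1.0, 3)
        assert noisy.mean() == pytest.approx(np.sqrt(np.pi / 2), abs=0.02)

    def test_seed_reproducibility(self):
        x = np.ones(50)
        assert np.array_equal(
            add_rician_noise(x, 0.5, 11), add_rician_noise(x, 0.5, 11)
        )

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), -1.0, 0)


class TestPhantom:
    def test_two_shell_scheme_has_41_volumes(self, scheme):
        assert scheme.n_volumes == 41
        assert scheme.b0_indices.size == 1
        assert np.count_nonzero(scheme.bvals == 1000) == 20
        assert np.count_nonzero(scheme.bvals == 2000) == 20

    def test_same_seed_identical_output(self):
        cfg = small_config(snr=30.0)
        a = generate_phantom(cfg, 5)
        b = generate_phantom(cfg, 5)
        assert np.array_equal(a.dwi_series, b.dwi_series)
        assert np.array_equal(a.flash_mt, b.flash_mt)

    def test_truth_invariants(self, noisefree_phantom):
        t = noisefree_phantom.truth
        avf = (1 - t.mvf_true) * (1 - t.viso_true) * t.vic_true
        assert np.all(t.mvf_true + avf <= 1 + 1e-9)
        has_fibers = t.vic_true > 0
        norms = np.linalg.norm(t.fiber_dir[has_fibers], axis=-1)
        assert np.allclose(norms, 1.0)

    def test_atlas_sides_disjoint(self, noisefree_phantom):
        atlas = noisefree_phantom.atlas
        for tract in TRACT_NAMES:
            left = atlas.probability(tract, "left") >= 0.5
            right = atlas.probability(tract, "right") >= 0.5
            assert not np.any(left & right)

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(shape=(10, 10, 4), canal_radius=7.5, cord_radius=5.0)


class TestCohort:
    def test_paper_structure_counts(self):
        spec = CohortSpec(
            n_patients=4,
            n_controls=2,
            laterality=("left", "right", "bilateral", "left"),
            snr=None,
            phantom=small_config(),
            seed=0,
        )
        subs = generate_cohort(spec)
        assert len(subs) == 6
        controls = [s for s in subs if s.group == "control"]
        assert len(controls) == 2  # two normal sides each -> 4 control sides

    def test_laterality_length_validated(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=3, n_controls=1, laterality=("left",))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=0, n_controls=0, laterality=())

    def test_null_effect_matches_controls(self):
        spec = CohortSpec(
            n_patients=1,
            n_controls=1,
            laterality=("left",),
            affected_avf_reduction=0.0,
            subject_jitter=0.0,
            snr=None,
            phantom=small_config(snr=None, heterogeneity=0.0),
            seed=1,
        )
        subs = generate_cohort(spec)
        pat, ctl = subs[0], subs[1]
        assert np.array_equal(pat.data.truth.vic_true, ctl.data.truth.vic_true)
        assert np.array_equal(pat.data.truth.mvf_true, ctl.data.truth.mvf_true)

    def test_affected_vic_reduction_readback(self):
        spec = CohortSpec(
            n_patients=1,
            n_controls=1,
            laterality=("left",),
            affected_avf_reduction=0.2,
            subject_jitter=0.0,
            snr=None,
            phantom=small_config(snr=None, heterogeneity=0.0),
            seed=2,
        )
        subs = generate_cohort(spec)
        pat, ctl = subs[0], subs[1]
        lcst = pat.data.atlas.probability("lcst", "left") >= 0.5
        mean_pat = pat.data.truth.vic_true[lcst].mean()
        mean_ctl = ctl.data.truth.vic_true[lcst].mean()
        assert mean_pat == pytest.approx(0.8 * mean_ctl, rel=1e-6)
        # myelin preserved by default
        assert np.allclose(
            pat.data.truth.mvf_true[lcst], ctl.data.truth.mvf_true[lcst]
        )

    def test_cohort_determinism(self):
        spec = CohortSpec(
            n_patients=1, n_controls=1, laterality=("left",), snr=20.0,
            phantom=small_config(), seed=9,
        )
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        assert np.array_equal(a[0].data.dwi_series, b[0].data.dwi_series)
        assert a[0].mjoa == b[0].mjoa
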