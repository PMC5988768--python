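"""Jones forward model: retarder algebra, Berek experiment, A-scan simulation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from psoct.errors import DomainError, RangeError
from psoct.optics import (
    AcquisitionParams,
    RetarderElement,
    berek_measure,
    fold_quarter,
    qwp,
    retarder_matrix,
    simulate_ascan,
    simulate_bscan,
    simulate_volume,
)
from psoct.tissue import dn_for_brc


class TestRetarderAlgebra:
    def test_zero_retardance_is_identity(self):
        for axis in (0.0, 0.4, 1.2):
            np.testing.assert_allclose(
                retarder_matrix(RetarderElement(0.0, axis)), np.eye(2), atol=1e-15
            )

    def test_two_quarter_waves_compose_to_half_wave(self):
        axis = 0.7
        q = retarder_matrix(RetarderElement(math.pi / 2, axis))
        h = retarder_matrix(RetarderElement(math.pi, axis))
        np.testing.assert_allclose(q @ q, h, atol=1e-12)

    @given(
        st.floats(0.0, 2 * math.pi, exclude_max=True),
        st.floats(0.0, math.pi, exclude_max=True),
    )
    def test_unitarity(self, retardance, axis):
        j = retarder_matrix(RetarderElement(retardance, axis))
        assert abs(abs(np.linalg.det(j)) - 1.0) < 1e-12
        np.testing.assert_allclose(j @ j.conj().T, np.eye(2), atol=1e-12)

    def test_out_of_range_element_rejected(self):
        with pytest.raises(DomainError):
            RetarderElement(-0.1, 0.0)
        with pytest.raises(DomainError):
            RetarderElement(0.5, 4.0)


class TestBerekExperiment:
    def test_noiseless_sweep_is_identity_with_fold(self):
        # retardation 0..180 deg in 10 deg steps, axes 0..180: measured equals
        # the set retardation folded at 90 deg, at every grid point
        for set_ret in range(0, 181, 10):
            expected = set_ret if set_ret <= 90 else 180 - set_ret
            for axis in range(0, 181, 10):
                assert berek_measure(set_ret, axis) == pytest.approx(
                    expected, abs=1e-9
                )

    def test_axis_independence_at_45_degrees(self):
        values = [berek_measure(45.0, a) for a in range(0, 181, 10)]
        assert max(values) - min(values) < 1e-9
        assert values[0] == pytest.approx(45.0, abs=1e-9)

    def test_quarter_wave_at_oblique_axis(self):
        assert berek_measure(90.0, 20.0) == pytest.approx(90.0, abs=1e-9)

    def test_zero_retardation(self):
        assert berek_measure(0.0, 137.0) == pytest.approx(0.0, abs=1e-9)

    def test_noise_is_seeded_and_folded(self):
        a = berek_measure(88.0, 10.0, noise_sd=5.0, seed=3)
        b = berek_measure(88.0, 10.0, noise_sd=5.0, seed=3)
        assert a == b
        assert 0.0 <= a <= 90.0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            berek_measure(200.0, 0.0)
        with pytest.raises(DomainError):
            berek_measure(10.0, -5.0)


class TestFold:
    @given(st.floats(-20.0, 20.0))
    def test_fold_range_and_period(self, x):
        f = fold_quarter(x)
        assert 0.0 <= f <= math.pi / 2 + 1e-12
        assert fold_quarter(x + math.pi) == pytest.approx(f, abs=1e-9)


class TestAScanSimulation:
    def test_isotropic_tissue_reads_quarter_pi(self, make_slab, noiseless_params):
        tissue = make_slab(0.0)
        av, ah = simulate_ascan(tissue, 5.0, noiseless_params, seed=None)
        inside = av + ah > 0
        delta = np.arctan2(av[inside], ah[inside])
        np.testing.assert_allclose(delta, math.pi / 4, atol=1e-12)

    def test_homogeneous_slab_is_folded_ramp(self, make_slab, noiseless_params):
        # closed form: delta(z) = fold(pi/4 + 2*pi*2*dn/lambda0 * z)
        truth = 4.0
        tissue = make_slab(truth)
        av, ah = simulate_ascan(tissue, 5.0, noiseless_params, seed=None)
        inside = np.nonzero(av + ah > 0)[0]
        delta = np.arctan2(av[inside], ah[inside])
        pix_tissue_mm = noiseless_params.axial_pixel_air_mm / tissue.refractive_index
        z = (np.arange(inside.size) + 1) * pix_tissue_mm
        expected = fold_quarter(math.pi / 4 + truth * z)
        np.testing.assert_allclose(delta, expected, atol=1e-10)

    def test_energy_independent_of_retarder_settings(self, make_slab, noiseless_params):
        # unitarity: Av^2 + Ah^2 equals the scatter profile squared whatever
        # the birefringence above the pixel
        t0, t1 = make_slab(0.0), make_slab(5.0)
        av0, ah0 = simulate_ascan(t0, 5.0, noiseless_params, seed=None)
        av1, ah1 = simulate_ascan(t1, 5.0, noiseless_params, seed=None)
        np.testing.assert_allclose(av0**2 + ah0**2, av1**2 + ah1**2, atol=1e-12)

    def test_measurement_independent_of_optic_axis_map(self, make_slab, noiseless_params):
        tissue = make_slab(3.0)
        av_ref, ah_ref = simulate_ascan(tissue, 5.0, noiseless_params, seed=None)
        tissue.axis_map = np.full_like(tissue.axis_map, 1.234)
        av, ah = simulate_ascan(tissue, 5.0, noiseless_params, seed=None)
        np.testing.assert_allclose(av, av_ref, atol=1e-12)
        np.testing.assert_allclose(ah, ah_ref, atol=1e-12)

    def test_closed_form_matches_explicit_jones_chain(self):
        # the vectorised amplitudes equal |projections| of
        # QWP(45) . J(pi/2 + 2 psi, theta) . QWP(45) . E_V computed matrix-wise
        from psoct.optics import _sandwich_amplitudes, _SOURCE_STATE

        rng = np.random.default_rng(0)
        for _ in range(50):
            psi = rng.uniform(0, 6.0)
            theta = rng.uniform(0, math.pi)
            ret = math.fmod(math.pi / 2 + 2 * psi, 2 * math.pi)
            chain = (
                qwp(math.pi / 4)
                @ retarder_matrix(RetarderElement(ret, theta))
                @ qwp(math.pi / 4)
                @ _SOURCE_STATE
            )
            av, ah = _sandwich_amplitudes(math.pi / 2 + 2 * psi, theta)
            assert abs(chain[1]) == pytest.approx(float(av), abs=1e-12)
            assert abs(chain[0]) == pytest.approx(float(ah), abs=1e-12)

    def test_determinism_same_seed(self, make_slab, default_params):
        tissue = make_slab(3.0)
        a = simulate_ascan(tissue, 5.0, default_params, seed=11)
        b = simulate_ascan(tissue, 5.0, default_params, seed=11)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_lateral_position_outside_block_rejected(self, make_slab, default_params):
        with pytest.raises(RangeError):
            simulate_ascan(make_slab(1.0), 99.0, default_params, seed=0)

    def test_speckle_mean_converges_to_noiseless(self, make_slab, default_params):
        # multiplicative noise has unit mean: averaging N noisy A-scans
        # approaches the noiseless A-scan at the 1/sqrt(N) rate
        tissue = make_slab(2.0)
        clean_av, clean_ah = simulate_ascan(tissue, 5.0, default_params, seed=None)
        n = 400
        acc = np.zeros_like(clean_av)
        for s in range(n):
            av, _ = simulate_ascan(tissue, 5.0, default_params, seed=s)
            acc += av
        acc /= n
        inside = clean_av > 0.05
        rel = np.abs(acc[inside] - clean_av[inside]) / clean_av[inside]
        # per-pixel SD ~ noise_sigma*0.52/sqrt(N) ~ 0.0016; allow 5 sigma
        assert np.median(rel) < 5 * default_params.noise_sigma * 0.53 / math.sqrt(n)


class TestVolume:
    def test_default_volume_shapes(self, make_slab, default_params):
        vol = simulate_volume(make_slab(2.0), default_params, 5, seed=0)
        assert len(vol) == 5
        assert len({pair.shape for pair in vol}) == 1
        assert all(pair.truth is not None for pair in vol)

    def test_single_bscan_volume(self, make_slab, default_params):
        assert len(simulate_volume(make_slab(2.0), default_params, 1, seed=0)) == 1

    def test_adjacent_bscans_differ_only_by_noise(self, make_slab, default_params):
        tissue = make_slab(2.0)
        clean = simulate_bscan(tissue, default_params, seed=None)
        vol = simulate_volume(tissue, default_params, 2, seed=4)
        for pair in vol:
            inside = clean.Av > 0
            rel = np.abs(pair.Av[inside] - clean.Av[inside]) / clean.Av[inside]
            assert np.median(rel) < 4 * default_params.noise_sigma
        assert not np.array_equal(vol[0].Av, vol[1].Av)

    def test_bad_parameters_rejected(self):
        with pytest.raises(Exception):
            AcquisitionParams(wavelength=-1.0)
        with pytest.raises(Exception):
            AcquisitionParams(n_ascans=0)
        with pytest.raises(DomainError):
            simulate_volume(None, AcquisitionParams(), 0, seed=0)
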