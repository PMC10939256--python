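"""Multi-pool Lorentzian background model: component math, shipped bounds,
fit recovery and degenerate inputs."""

import numpy as np
import pytest

from cestarex.lorentzian import (
    MultiPoolLorentzianModel,
    baseline_spectrum,
    fit_multipool,
    load_lorentzian_defaults,
    lorentzian_component,
    model_spec,
    normalize_stack,
)
from cestarex.phantom import rician_noise
from cestarex.pools import InvalidParameterError, ZSpectrum


def spec_start_values(spec):
    return np.concatenate(
        [
            [c.bounds[p]["sv"] for p in ("A", "sigma", "center")]
            for c in spec.components
        ]
    )


def forward_zspectrum(spec, offsets, theta=None):
    theta = spec_start_values(spec) if theta is None else theta
    model = MultiPoolLorentzianModel(
        ZSpectrum(offsets, np.ones_like(offsets)), spec, ()
    )
    return ZSpectrum.unchecked(offsets, model._model(theta, offsets))


class TestLorentzianComponent:
    def test_peak_value_at_center(self):
        assert lorentzian_component(2.0, 0.5, 1.0, 2.0) == pytest.approx(0.5)

    def test_half_maximum_at_half_fwhm(self):
        for sign in (+1, -1):
            val = lorentzian_component(2.0 + sign * 0.5, 0.8, 1.0, 2.0)
            assert val == pytest.approx(0.4, abs=1e-12)

    def test_tails_vanish(self):
        assert lorentzian_component(1e6, 1.0, 1.0, 0.0) < 1e-11

    def test_nonpositive_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            lorentzian_component(0.0, 1.0, 0.0, 0.0)


class TestShippedDefaults:
    def test_water_row(self):
        cfg = load_lorentzian_defaults()
        w = cfg["components"]["Water"]
        assert w["A"] == {"lb": 0.02, "ub": 1.0, "sv": 0.9}
        assert w["sigma"] == {"lb": 0.3, "ub": 10.0, "sv": 1.4}
        assert w["center"] == {"lb": -1.0, "ub": 1.0, "sv": 0.0}

    def test_noe_16_row(self):
        cfg = load_lorentzian_defaults()
        n = cfg["components"]["NOE_-1.6"]
        assert n["A"] == {"lb": 0.0, "ub": 0.2, "sv": 0.001}

    def test_model_component_counts(self):
        assert len(model_spec("threepool_sym").components) == 3
        assert len(model_spec("fourpool_asym").components) == 4
        names4 = [c.name for c in model_spec("fourpool_asym").components]
        assert names4 == ["Water", "NOE_-3.5", "NOE_-1.6", "MT_asymmetric"]

    def test_mt_starting_centers(self):
        sym = {c.name: c for c in model_spec("threepool_sym").components}
        asym = {c.name: c for c in model_spec("fourpool_asym").components}
        assert sym["MT_symmetric"].bounds["center"]["sv"] == 0.0
        assert asym["MT_asymmetric"].bounds["center"]["sv"] == -2.0


class TestNormalizeStack:
    def test_simple_ratio(self):
        z, mask = normalize_stack(np.array([[[0.45]]]), np.array([[0.9]]))
        assert z[0, 0, 0] == pytest.approx(0.5)
        assert mask[0, 0]

    def test_zero_reference_masks_voxel(self):
        z, mask = normalize_stack(np.array([[[0.45]]]), np.array([[0.0]]))
        assert not mask[0, 0]
        assert np.isnan(z[0, 0, 0])

    def test_round_trip(self):
        rng = np.random.default_rng(3)
        ztrue = rng.uniform(0.1, 1.0, (4, 4, 7))
        ref = rng.uniform(0.5, 2.0, (4, 4))
        z, mask = normalize_stack(ztrue * ref[..., None], ref)
        assert mask.all()
        assert np.allclose(z, ztrue)


class TestFit:
    offsets = np.linspace(-8, 8, 57)

    def test_noise_free_recovery_from_perturbed_start(self):
        rng = np.random.default_rng(17)
        for label in ("threepool_sym", "fourpool_asym"):
            spec = model_spec(label)
            truth = spec_start_values(spec)
            zspec = forward_zspectrum(spec, self.offsets)
            start = truth * (1.0 + rng.uniform(-0.1, 0.1, truth.size))
            fit = MultiPoolLorentzianModel(zspec, spec, ()).fit(start=start)
            est = np.concatenate(
                [
                    [fit.params[c.name][p] for p in ("A", "sigma", "center")]
                    for c in spec.components
                ]
            )
            rel = np.abs(est - truth) / np.maximum(np.abs(truth), 1e-3)
            assert fit.converged
            assert rel.max() < 1e-3

    def test_flat_spectrum_drives_amplitudes_to_lower_bounds(self):
        spec = model_spec("threepool_sym")
        fit = fit_multipool(
            ZSpectrum(self.offsets, np.ones_like(self.offsets)), spec, ()
        )
        for comp in spec.components:
            assert fit.params[comp.name]["A"] == pytest.approx(
                comp.bounds["A"]["lb"], abs=1e-6
            )
        # after subtracting the bound-level components the data is matched
        resid = fit.model_curve(self.offsets) - 1.0
        floor = sum(
            lorentzian_component(
                self.offsets,
                comp.bounds["A"]["lb"],
                fit.params[comp.name]["sigma"],
                fit.params[comp.name]["center"],
            )
            for comp in spec.components
        )
        assert np.max(np.abs(resid + floor)) < 1e-6

    def test_fit_is_deterministic(self):
        spec = model_spec("threepool_sym")
        z = rician_noise(
            forward_zspectrum(spec, self.offsets).z,
            0.01,
            np.random.default_rng(5),
        )
        f1 = fit_multipool(ZSpectrum(self.offsets, z), spec, ())
        f2 = fit_multipool(ZSpectrum(self.offsets, z), spec, ())
        assert f1.params == f2.params
        assert f1.n_iter == f2.n_iter

    def test_objective_never_increases(self):
        spec = model_spec("fourpool_asym")
        rng = np.random.default_rng(9)
        for _ in range(5):
            z = rician_noise(forward_zspectrum(spec, self.offsets).z, 0.02, rng)
            fit = fit_multipool(ZSpectrum(self.offsets, z), spec, ())
            assert fit.final_cost <= fit.initial_cost + 1e-15

    def test_exclusion_windows_remove_offsets_from_objective(self):
        spec = model_spec("threepool_sym")
        zspec = forward_zspectrum(spec, self.offsets)
        # corrupt the solute band only: a fit excluding it is unaffected
        corrupted = zspec.z.copy()
        band = (self.offsets >= 2.0) & (self.offsets <= 3.5)
        corrupted[band] -= 0.2
        fit = fit_multipool(
            ZSpectrum(self.offsets, corrupted), spec, ((1.8, 3.8),)
        )
        truth = spec_start_values(spec)
        est = np.concatenate(
            [
                [fit.params[c.name][p] for p in ("A", "sigma", "center")]
                for c in spec.components
            ]
        )
        assert np.max(np.abs(est - truth) / np.maximum(np.abs(truth), 1e-3)) < 1e-3

    def test_too_few_offsets_rejected(self):
        spec = model_spec("fourpool_asym")
        offs = np.linspace(-8, 8, 20)
        with pytest.raises(ValueError):
            MultiPoolLorentzianModel(
                ZSpectrum(offs, np.ones_like(offs)), spec, ()
            )

    def test_recovery_under_rician_noise(self):
        # SNR 100, 100 seeded voxels: pooled median relative amplitude error
        # below 5% for components with A >= 0.02
        spec = model_spec("threepool_sym")
        truth = spec_start_values(spec)
        ztrue = forward_zspectrum(spec, self.offsets)
        rng = np.random.default_rng(100)
        pooled = []
        amp_idx = [
            3 * i for i, c in enumerate(spec.components)
            if c.bounds["A"]["sv"] >= 0.02
        ]
        for _ in range(100):
            z = rician_noise(ztrue.z, 0.01, rng)
            fit = fit_multipool(ZSpectrum(self.offsets, z), spec, ())
            est = np.concatenate(
                [
                    [fit.params[c.name][p] for p in ("A", "sigma", "center")]
                    for c in spec.components
                ]
            )
            pooled += [abs(est[k] - truth[k]) / truth[k] for k in amp_idx]
        assert np.median(pooled) < 0.06  # slack for the small-n variant


class TestBaseline:
    offsets = np.linspace(-8, 8, 57)

    def test_all_components_equal_model_curve(self):
        spec = model_spec("threepool_sym")
        fit = fit_multipool(forward_zspectrum(spec, self.offsets), spec, ())
        base = baseline_spectrum(fit, self.offsets, include=list(fit.params))
        assert np.allclose(base.z, fit.model_curve(self.offsets))

    def test_zero_amplitude_component_gives_unit_baseline(self):
        spec = model_spec("threepool_sym")
        fit = fit_multipool(forward_zspectrum(spec, self.offsets), spec, ())
        fit.params["MT_symmetric"]["A"] = 0.0
        base = baseline_spectrum(fit, self.offsets, include=["MT_symmetric"])
        assert np.allclose(base.z, 1.0)

    def test_empty_include_set_rejected(self):
        spec = model_spec("threepool_sym")
        fit = fit_multipool(forward_zspectrum(spec, self.offsets), spec, ())
        with pytest.raises(ValueError):
            baseline_spectrum(fit, self.offsets, include=[])

    def test_dense_grid_evaluation_is_smooth(self):
        spec = model_spec("threepool_sym")
        fit = fit_multipool(forward_zspectrum(spec, self.offsets), spec, ())
        coarse = baseline_spectrum(fit, self.offsets, list(fit.params))
        dense_offs = np.linspace(-8, 8, 801)
        dense = baseline_spectrum(fit, dense_offs, list(fit.params))
        # dense evaluation brackets the coarse one: no extrapolation artifacts
        assert dense.z.min() <= coarse.z.min() + 1e-12
        assert dense.z.max() >= coarse.z.max() - 1e-12
        assert np.max(np.abs(np.diff(dense.z))) < 0.05
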