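"""Pixel-wise fitting: exact inversion, masking, MTR maps, oracle checks."""

import numpy as np
import pytest

from qmriskin import models
from qmriskin.fitting import fit_map, fit_pixel, mtr_map
from qmriskin.phantom import (PhantomSpec, TissueParameters, make_phantom,
                              simulate_series)
from qmriskin.protocols import default_protocol

from _grid_oracle import grid_argmin

TE = 5.3 * np.arange(1, 65)
TR = np.geomspace(0.1, 15.0, 12)
TSAT = np.geomspace(0.1, 4.6, 8)
BVAL = models.stejskal_tanner_b(np.linspace(0, 900, 9), 5.0, 10.25)


class TestFitPixel:
    def test_noiseless_cpmg_exact_inversion(self):
        s = models.cpmg_signal(30.0, 1.0, 0.05, TE)
        t2, a, c, rss, ok = fit_pixel(s, TE, "cpmg")
        assert ok
        assert t2 == pytest.approx(30.0, rel=1e-3)
        assert a == pytest.approx(1.0, rel=1e-3)
        assert c == pytest.approx(0.05, rel=1e-2)

    def test_noiseless_mt_exact_inversion(self):
        st = models.MTState(m0=1.0, mss=0.4, km=2.0)
        s = models.mt_signal(st, TSAT)
        km, a, c, rss, ok = fit_pixel(s, TSAT, "mt")
        assert ok
        assert km == pytest.approx(2.0, rel=1e-3)
        assert a + c == pytest.approx(1.0, rel=1e-3)   # M0
        assert c == pytest.approx(0.4, rel=1e-3)        # Mss

    def test_noiseless_satrec_and_diffusion(self):
        s = models.satrec_signal(1.2, 1.0, 0.02, TR)
        t1, *_, ok = fit_pixel(s, TR, "satrec")
        assert ok and t1 == pytest.approx(1.2, rel=1e-3)
        s = models.diffusion_signal(1e-3, 1.0, 0.01, BVAL)
        adc, *_, ok = fit_pixel(s, BVAL, "diffusion")
        assert ok and adc == pytest.approx(1e-3, rel=1e-3)

    def test_mt_with_pinned_m0(self):
        # pinning the equilibrium magnetization to its true value recovers
        # km exactly with one fewer free parameter
        st = models.MTState(m0=1.0, mss=0.4, km=2.0)
        s = models.mt_signal(st, TSAT)
        km, a, c, rss, ok = fit_pixel(s, TSAT, "mt", fix_m0=1.0)
        assert ok
        assert km == pytest.approx(2.0, rel=1e-3)
        assert c == pytest.approx(0.4, rel=1e-3)  # Mss

    def test_all_zero_pixel_flags_nonconverged(self):
        *_, ok = fit_pixel(np.zeros_like(TE), TE, "cpmg")
        assert not ok

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            fit_pixel([1.0, 0.5, 0.2], [1.0, 2.0, 3.0], "cpmg")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            fit_pixel(np.ones(8), np.arange(8.0), "flair")

    def test_idempotence(self):
        """Refitting the fitted model's own prediction returns the same fit."""
        rng = np.random.default_rng(0)
        s = models.cpmg_signal(30.0, 1.0, 0.0, TE)
        s = np.sqrt((s + rng.normal(0, 0.02, s.shape)) ** 2
                    + rng.normal(0, 0.02, s.shape) ** 2)
        t2, a, c, *_ = fit_pixel(s, TE, "cpmg")
        pred = models.cpmg_signal(t2, a, c, TE)
        t2b, ab, cb, *_ = fit_pixel(pred, TE, "cpmg")
        assert t2b == pytest.approx(t2, rel=1e-4)
        assert ab == pytest.approx(a, rel=1e-4)


def _uniform_series(kind, **tissue):
    params = dict(t1_s=1.2, t2_ms=30.0, km_per_s=2.0, adc_mm2_per_s=1e-3,
                  a=1.0, c=0.0, mss_over_m0=0.45)
    params.update(tissue)
    spec = PhantomSpec(grid_shape=(8, 12),
                       layer_extents={"dermis": (0, 8)},
                       compartments={"dermis": TissueParameters(**params)})
    _, _, truth = make_phantom(spec)
    return simulate_series(truth, default_protocol(kind)), truth


class TestFitMap:
    def test_uniform_phantom_map_is_uniform(self):
        series, _ = _uniform_series("cpmg")
        pmap = fit_map(series)
        vals = pmap.values[pmap.converged]
        assert vals.std() / vals.mean() < 1e-6

    def test_two_compartment_means_match_truth(self):
        spec = PhantomSpec(grid_shape=(16, 16))
        label_map, names, truth = make_phantom(spec)
        series = simulate_series(truth, default_protocol("cpmg"))
        pmap = fit_map(series)
        for idx, name in enumerate(names):
            sel = (label_map == idx) & pmap.converged
            expected = spec.compartments[name].t2_ms
            assert pmap.values[sel].mean() == pytest.approx(expected, rel=1e-3)

    def test_masked_fit_equals_unmasked_restricted(self):
        series, _ = _uniform_series("mt")
        full = fit_map(series)
        mask = np.zeros(series.shape, dtype=bool)
        mask[2:5, 3:9] = True
        part = fit_map(series, mask=mask)
        assert np.allclose(part.values[mask], full.values[mask])
        assert np.all(np.isnan(part.values[~mask]))
        assert not part.converged[~mask].any()

    def test_empty_mask_rejected(self):
        series, _ = _uniform_series("cpmg")
        with pytest.raises(ValueError):
            fit_map(series, mask=np.zeros(series.shape, dtype=bool))

    def test_mask_shape_mismatch_rejected(self):
        series, _ = _uniform_series("cpmg")
        with pytest.raises(ValueError):
            fit_map(series, mask=np.ones((4, 4), dtype=bool))


class TestMtrMap:
    def test_uniform_mtr(self):
        series, _ = _uniform_series("mt", mss_over_m0=0.4)
        pmap = mtr_map(series)
        vals = pmap.values[pmap.converged]
        assert vals == pytest.approx(0.6, rel=1e-3)

    def test_no_transfer_gives_zero(self):
        series, _ = _uniform_series("mt", mss_over_m0=1.0 - 1e-9)
        pmap = mtr_map(series)
        assert np.nanmax(pmap.values) == pytest.approx(0.0, abs=1e-3)

    def test_matches_definition_pixelwise(self):
        series, _ = _uniform_series("mt", mss_over_m0=0.45)
        fit = fit_map(series)
        derived = mtr_map(mt_fit=fit)
        m0 = fit.amplitude + fit.offset
        expected = models.mtr(m0[fit.converged], fit.offset[fit.converged])
        assert np.allclose(derived.values[fit.converged],
                           np.clip(expected, 0, 1))

    def test_requires_mt_input(self):
        series, _ = _uniform_series("cpmg")
        with pytest.raises(ValueError):
            mtr_map(series)


class TestGridOracle:
    """The solver's minimum agrees with an exhaustive coarse-grid search."""

    @pytest.mark.parametrize("kind,p_truth,p_lo,p_hi", [
        ("cpmg", 30.0, 5.0, 200.0),
        ("satrec", 1.2, 0.2, 10.0),
        ("mt", 2.0, 0.2, 20.0),
        ("diffusion", 1e-3, 1e-4, 1e-2),
    ])
    def test_fit_within_one_grid_cell(self, kind, p_truth, p_lo, p_hi, rng):
        x = {"cpmg": TE, "satrec": TR, "mt": TSAT, "diffusion": BVAL}[kind]
        n_pix = 64  # small crop here; the full 32x32 runs in the
        # acceptance suite
        kw = {"cpmg": dict(t2_ms=p_truth), "satrec": dict(t1_s=p_truth),
              "mt": dict(km_per_s=p_truth),
              "diffusion": dict(adc_mm2_per_s=p_truth)}[kind]
        params = dict(t1_s=1.2, t2_ms=30.0, km_per_s=2.0,
                      adc_mm2_per_s=1e-3, a=1.0, c=0.0, mss_over_m0=0.45)
        params.update(kw)
        tp = TissueParameters(**params)
        if kind == "mt":
            clean = tp.mss_over_m0 + (1 - tp.mss_over_m0) * np.exp(
                -tp.km_per_s * x)
        elif kind == "cpmg":
            clean = models.cpmg_signal(tp.t2_ms, 1.0, 0.0, x)
        elif kind == "satrec":
            clean = models.satrec_signal(tp.t1_s, 1.0, 0.0, x)
        else:
            clean = models.diffusion_signal(tp.adc_mm2_per_s, 1.0, 0.0, x)
        sig = np.sqrt((clean[None, :] + rng.normal(0, 0.02, (n_pix, x.size)))
                      ** 2 + rng.normal(0, 0.02, (n_pix, x.size)) ** 2)

        p_grid = np.geomspace(p_lo, p_hi, 40)
        if kind == "mt":  # decaying amplitude M0-Mss ~ 0.55, offset Mss ~ 0.45
            a_grid = np.linspace(0.1, 1.2, 89)
            c_grid = np.linspace(0.0, 0.8, 129)
        else:
            a_grid = np.linspace(0.5, 1.5, 21)
            c_grid = np.linspace(0.0, 0.2, 21)
        p_hat, _, _, p_idx = grid_argmin(sig, x, kind, p_grid, a_grid, c_grid)

        for i in range(n_pix):
            v, *_, ok = fit_pixel(sig[i], x, kind)
            assert ok
            lo_cell = p_grid[max(p_idx[i] - 1, 0)]
            hi_cell = p_grid[min(p_idx[i] + 1, len(p_grid) - 1)]
            assert lo_cell <= v <= hi_cell, (
                f"pixel {i}: fit {v} vs grid argmin {p_hat[i]}")
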