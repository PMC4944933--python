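"""Pixel-wise nonlinear least-squares parameter mapping.

Every contrast is fit to its monoexponential model with a constant offset
term (the offset also absorbs the Rician noise floor of magnitude data):

* cpmg:      S(TE) = A exp(-TE/T2) + C          ->  T2 map (ms)
* satrec:    S(TR) = A (1 - exp(-TR/T1)) + C    ->  T1 map (s)
* mt:        M(t)  = C + A exp(-km t)           ->  km map (s^-1),
             with M0 = A + C and Mss = C, so MTR = 1 - C/(A + C)
* diffusion: S(b)  = A exp(-b ADC) + C          ->  ADC map (mm^2/s)

Fits are ordinary (Gaussian) least squares on magnitude data, bounded
trust-region, with deterministic data-driven initialization: the offset
starts at the minimum observed signal and the rate comes from a log-linear
regression of the offset-subtracted signal (for saturation recovery, from
the half-recovery point). Pixels that fail to converge are flagged rather
than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .series import ImageSeries

__all__ = ["ParameterMap", "fit_pixel", "fit_map", "mtr_map",
           "KIND_TO_PARAM", "FIT_BOUNDS"]

log = logging.getLogger(__name__)

KIND_TO_PARAM = {"cpmg": "T2", "satrec": "T1", "mt": "km", "diffusion": "ADC"}
PARAM_UNITS = {"T2": "ms", "T1": "s", "km": "s^-1", "ADC": "mm^2/s",
               "MTR": ""}

# (lower, upper) for the rate/time parameter of each kind
FIT_BOUNDS = {
    "cpmg": (1e-6, 1e4),     # T2, ms
    "satrec": (1e-6, 20.0),  # T1, s
    "mt": (1e-6, 1e2),       # km, s^-1
    "diffusion": (1e-9, 1e-1),  # ADC, mm^2/s
}

_REL_TOL = 1e-8
_MAX_NFEV = 500


@dataclass
class ParameterMap:
    """A fitted 2-D parameter map with per-pixel diagnostics.

    ``values`` holds NaN at pixels that were masked out or failed to
    converge; ``converged`` is False there.
    """

    name: str
    values: np.ndarray
    amplitude: np.ndarray
    offset: np.ndarray
    rss: np.ndarray
    converged: np.ndarray
    units: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def summary(self) -> dict:
        ok = self.converged
        vals = self.values[ok]
        return {
            "name": self.name,
            "units": self.units,
            "n_pixels": int(self.values.size),
            "n_converged": int(ok.sum()),
            "mean": float(vals.mean()) if vals.size else None,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else None,
        }


def _model(kind, x, p, a, c):
    if kind == "cpmg":
        return a * np.exp(-x / p) + c
    if kind == "satrec":
        return a * (1.0 - np.exp(-x / p)) + c
    if kind == "mt":
        return c + a * np.exp(-p * x)
    if kind == "diffusion":
        return a * np.exp(-x * p) + c
    raise ValueError(f"unknown kind {kind!r}")


def _jacobian(kind, x, p, a, c):
    """Analytic Jacobian of the residuals w.r.t. (p, a, c)."""
    J = np.empty((x.size, 3))
    if kind == "cpmg":
        e = np.exp(-x / p)
        J[:, 0] = a * e * x / p ** 2
        J[:, 1] = e
    elif kind == "satrec":
        e = np.exp(-x / p)
        J[:, 0] = -a * e * x / p ** 2
        J[:, 1] = 1.0 - e
    else:  # mt, diffusion: a * exp(-p x) + c
        e = np.exp(-p * x)
        J[:, 0] = -a * x * e
        J[:, 1] = e
    J[:, 2] = 1.0
    return J


def _initial_guess(kind, x, s):
    """Deterministic starting point (offset from the signal minimum, rate
    from a log-linear regression; satrec uses the half-recovery point)."""
    smin, smax = float(s.min()), float(s.max())
    span = max(smax - smin, 1e-12)
    c0 = smin
    a0 = span
    if kind == "satrec":
        half = c0 + 0.5 * a0
        idx = np.argmax(s >= half)
        x_half = x[idx] if s[idx] >= half else x[len(x) // 2]
        p0 = max(x_half / np.log(2.0), 1e-6)
        return p0, a0, c0
    # decaying kinds: regress log(S - C0) on x over clearly-positive points
    d = s - c0
    use = d > 0.05 * span
    if use.sum() >= 2:
        slope, intercept = np.polyfit(x[use], np.log(d[use] + 1e-30), 1)
        rate = max(-slope, 1e-12)
        a0 = float(np.exp(intercept))
    else:
        rate = 1.0 / max(x.mean(), 1e-12)
    if kind in ("mt", "diffusion"):
        p0 = rate  # km and ADC multiply the schedule directly
    else:
        p0 = 1.0 / rate  # cpmg fits the time constant T2
    return p0, max(a0, 1e-12), c0


def fit_pixel(series_values, schedule, kind, fix_m0: float | None = None):
    """Fit one pixel's signal curve to the kind-matched model.

    Parameters
    ----------
    series_values : array_like
        Signal at each schedule point (>= 4 points: three free parameters
        plus one degree of freedom).
    schedule : array_like
        Acquisition-variable values (TE ms / TR s / t_sat s / b s/mm^2).
    kind : str
        One of ``cpmg``, ``satrec``, ``mt``, ``diffusion``.
    fix_m0 : float, optional
        For ``mt`` only: pin the equilibrium magnetization ``A + C`` to
        this value (e.g. the shortest-saturation frame) instead of
        fitting it freely.

    Returns
    -------
    (value, amplitude, offset, rss, converged)
        ``converged`` is False (and values are NaN) on failure instead of
        raising.
    """
    s = np.asarray(series_values, dtype=float)
    x = np.asarray(schedule, dtype=float)
    if kind not in KIND_TO_PARAM:
        raise ValueError(f"unknown kind {kind!r}")
    if s.shape != x.shape:
        raise ValueError("signal and schedule lengths differ")
    if s.size < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    nan = (np.nan,) * 4
    if not np.all(np.isfinite(s)) or np.all(s <= 0):
        return (*nan, False)

    lo, hi = FIT_BOUNDS[kind]
    p0, a0, c0 = _initial_guess(kind, x, s)
    p0 = float(np.clip(p0, lo * 1.01, hi * 0.99))

    if kind == "mt" and fix_m0 is not None:
        # free parameters: (km, Mss); A = M0 - Mss
        def resid(theta):
            km, mss = theta
            return mss + (fix_m0 - mss) * np.exp(-km * x) - s

        def jac(theta):
            km, mss = theta
            e = np.exp(-km * x)
            return np.column_stack([-(fix_m0 - mss) * x * e, 1.0 - e])

        res = least_squares(
            resid, x0=[p0, max(c0, 0.0)], jac=jac,
            bounds=([lo, 0.0], [hi, max(fix_m0, 1e-12)]),
            ftol=_REL_TOL, xtol=_REL_TOL, gtol=_REL_TOL, max_nfev=_MAX_NFEV)
        if not res.success:
            return (*nan, False)
        km, mss = res.x
        return km, fix_m0 - mss, mss, float(res.cost * 2), True

    def resid(theta):
        return _model(kind, x, *theta) - s

    res = least_squares(
        resid, x0=[p0, a0, max(c0, 0.0)],
        jac=lambda theta: _jacobian(kind, x, *theta),
        bounds=([lo, 0.0, 0.0], [hi, np.inf, np.inf]),
        ftol=_REL_TOL, xtol=_REL_TOL, gtol=_REL_TOL, max_nfev=_MAX_NFEV)
    if not res.success or not np.all(np.isfinite(res.x)):
        return (*nan, False)
    p, a, c = res.x
    return p, a, c, float(res.cost * 2), True


def fit_map(series: ImageSeries, mask=None, fix_m0: bool = False) -> ParameterMap:
    """Fit every (in-mask) pixel of an image series.

    Parameters
    ----------
    series : ImageSeries
    mask : ndarray of bool, optional
        Restrict fitting to these pixels; elsewhere the map is NaN and
        flagged non-converged. Must be non-empty if given.
    fix_m0 : bool
        For ``mt`` series, pin M0 to the shortest-saturation frame value
        per pixel instead of fitting it.

    Notes
    -----
    Deterministic given inputs. Non-converged pixels carry NaN.
    """
    x = series.fit_schedule
    kind = series.kind
    shape = series.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(
                f"mask shape {mask.shape} != image shape {shape}")
        if not mask.any():
            raise ValueError("mask selects no pixels")

    values = np.full(shape, np.nan)
    amp = np.full(shape, np.nan)
    off = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    frames = series.frames
    for r, c in zip(*np.nonzero(mask)):
        sig = frames[:, r, c]
        m0 = float(sig[0]) if (kind == "mt" and fix_m0) else None
        v, a, o, e, ok = fit_pixel(sig, x, kind, fix_m0=m0)
        if ok:
            values[r, c], amp[r, c], off[r, c], rss[r, c] = v, a, o, e
            conv[r, c] = True
    name = KIND_TO_PARAM[kind]
    n_fail = int(mask.sum() - conv.sum())
    if n_fail:
        log.warning("%s fit: %d/%d pixels did not converge",
                    kind, n_fail, int(mask.sum()))
    return ParameterMap(
        name=name, values=values, amplitude=amp, offset=off, rss=rss,
        converged=conv, units=PARAM_UNITS[name],
        meta={"kind": kind, "n_failed": n_fail, "fix_m0": bool(fix_m0)})


def mtr_map(mt_series: ImageSeries = None, mask=None,
            mt_fit: ParameterMap = None) -> ParameterMap:
    """Magnetization-transfer-ratio map, ``1 - Mss/M0``, from the MT fit.

    Either an MT series (fit here) or an existing km map from
    :func:`fit_map` may be supplied. Using the exponential-fit
    parameterization, ``Mss = C`` and ``M0 = A + C``, so
    ``MTR = 1 - C/(A + C)``. Values are clipped to [0, 1] (clipping is
    logged); pixels with non-positive fitted M0 are flagged.
    """
    if mt_fit is None:
        if mt_series is None:
            raise ValueError("provide an MT series or an MT fit")
        if mt_series.kind != "mt":
            raise ValueError(f"expected an 'mt' series, got {mt_series.kind!r}")
        mt_fit = fit_map(mt_series, mask=mask)
    if mt_fit.meta.get("kind", "mt") != "mt":
        raise ValueError("mtr_map requires an MT fit")
    m0 = mt_fit.amplitude + mt_fit.offset
    ok = mt_fit.converged & (m0 > 0)
    values = np.full(mt_fit.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = 1.0 - mt_fit.offset / m0
    n_clip = int(np.sum(ok & ((raw < 0) | (raw > 1))))
    if n_clip:
        log.warning("MTR map: clipped %d pixels into [0, 1]", n_clip)
    values[ok] = np.clip(raw[ok], 0.0, 1.0)
    return ParameterMap(
        name="MTR", values=values, amplitude=mt_fit.amplitude,
        offset=mt_fit.offset, rss=mt_fit.rss, converged=ok,
        units="", meta={"kind": "mt", "derived": "1 - Mss/M0",
                        "n_clipped": n_clip})
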