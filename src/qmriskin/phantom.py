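"""Layered-skin phantoms and noisy multi-contrast series simulation.

A phantom is a 2-D grid partitioned into labeled compartments — buffer bath,
epidermis, dermis, and optionally a hair follicle blob inside the dermis —
each carrying one set of tissue parameters. Layers are stacked along the
first (image-row) axis, i.e. perpendicular to the epidermal surface, as in
a punch biopsy imaged with B0 normal to the skin.

Magnitude images carry Rician noise: if the noiseless signal is S and the
per-channel Gaussian noise SD is sigma, the observed magnitude is
``sqrt((S + g1)^2 + g2^2)`` with independent g1, g2 ~ N(0, sigma^2). The
resulting noise floor is why every fit model includes a constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import models
from .protocols import AcquisitionProtocol
from .series import ImageSeries

__all__ = [
    "TissueParameters",
    "PhantomSpec",
    "make_phantom",
    "add_rician_noise",
    "simulate_series",
    "DEFAULT_COMPARTMENTS",
    "PARAM_NAMES",
]

#: the five mapped parameters, in report order
PARAM_NAMES = ("MTR", "km", "T2", "T1", "ADC")


@dataclass(frozen=True)
class TissueParameters:
    """Ground-truth MR parameters of one compartment.

    Attributes
    ----------
    t1_s : float
        Longitudinal relaxation time, s.
    t2_ms : float
        Transverse relaxation time, ms. Must satisfy T2 <= T1 once
        converted to common units.
    km_per_s : float
        Apparent magnetization transfer rate, s^-1.
    adc_mm2_per_s : float
        Apparent diffusion coefficient, mm^2/s.
    a : float
        Proton-density amplitude (equilibrium signal), arbitrary units.
    c : float
        Constant signal offset, arbitrary units.
    mss_over_m0 : float
        Steady-state over equilibrium magnetization ratio in [0, 1];
        the magnetization transfer ratio is ``1 - mss_over_m0``.
    """

    t1_s: float
    t2_ms: float
    km_per_s: float
    adc_mm2_per_s: float
    a: float = 1.0
    c: float = 0.0
    mss_over_m0: float = 0.5

    def __post_init__(self) -> None:
        for name in ("t1_s", "t2_ms", "km_per_s", "adc_mm2_per_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.mss_over_m0 <= 1.0):
            raise ValueError("mss_over_m0 must lie in [0, 1]")
        if self.t2_ms * 1e-3 > self.t1_s:
            raise ValueError("T2 must not exceed T1")
        if self.a < 0 or self.c < 0:
            raise ValueError("amplitude and offset must be non-negative")

    @property
    def mtr(self) -> float:
        return 1.0 - self.mss_over_m0

    def truth(self, name: str) -> float:
        """Ground-truth value of one of the five mapped parameters."""
        return {
            "MTR": self.mtr,
            "km": self.km_per_s,
            "T2": self.t2_ms,
            "T1": self.t1_s,
            "ADC": self.adc_mm2_per_s,
        }[name]


# Realistic ex-vivo values for skin in chilled buffer; the dermis entry is
# typically overridden per subject from a cohort draw.
DEFAULT_COMPARTMENTS = {
    "bath": TissueParameters(
        t1_s=2.5, t2_ms=800.0, km_per_s=0.1, adc_mm2_per_s=1.3e-3,
        a=1.2, c=0.0, mss_over_m0=0.98,
    ),
    "epidermis": TissueParameters(
        t1_s=1.0, t2_ms=15.0, km_per_s=2.5, adc_mm2_per_s=0.5e-3,
        a=0.9, c=0.0, mss_over_m0=0.40,
    ),
    "dermis": TissueParameters(
        t1_s=1.2, t2_ms=30.0, km_per_s=2.0, adc_mm2_per_s=1.0e-3,
        a=1.0, c=0.0, mss_over_m0=0.45,
    ),
    "follicle": TissueParameters(
        t1_s=1.5, t2_ms=45.0, km_per_s=1.0, adc_mm2_per_s=1.4e-3,
        a=1.1, c=0.0, mss_over_m0=0.60,
    ),
}


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of a layered-skin phantom.

    ``layer_extents`` maps compartment name to a half-open row interval
    ``(start, stop)``; the intervals must partition ``[0, n_rows)`` in
    order. ``follicle`` optionally places an elliptical blob (center row,
    center col, semi-axis rows, semi-axis cols) that must fall inside the
    dermis rows.
    """

    grid_shape: tuple = (128, 256)
    pixel_size_um: tuple = (19.5, 46.9)
    layer_extents: dict | None = None
    compartments: dict = field(default_factory=lambda: dict(DEFAULT_COMPARTMENTS))
    follicle: tuple | None = None
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 4 or cols < 4:
            raise ValueError("grid too small")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.layer_extents is None:
            # bath / epidermis / dermis split along rows
            b = int(round(0.30 * rows))
            e = int(round(0.45 * rows))
            self.layer_extents = {
                "bath": (0, b), "epidermis": (b, e), "dermis": (e, rows)
            }
        prev = 0
        for name, (start, stop) in self.layer_extents.items():
            if start != prev:
                raise ValueError(
                    f"layer {name!r} starts at row {start}, expected {prev} "
                    "(extents must be contiguous and non-overlapping)")
            if stop <= start:
                raise ValueError(f"layer {name!r} has empty extent")
            if name not in self.compartments:
                raise ValueError(f"no tissue parameters for layer {name!r}")
            prev = stop
        if prev != rows:
            raise ValueError("layer extents must cover the full grid height")
        if self.follicle is not None:
            r0, c0, ar, ac = self.follicle
            d0, d1 = self.layer_extents["dermis"]
            if not (d0 <= r0 - ar and r0 + ar <= d1):
                raise ValueError("follicle must lie within the dermis layer")
            if "follicle" not in self.compartments:
                raise ValueError("no tissue parameters for 'follicle'")


def make_phantom(spec: PhantomSpec):
    """Build the compartment label map and per-parameter ground-truth maps.

    Returns
    -------
    label_map : ndarray of int
        Compartment index per pixel (a partition: every pixel exactly one
        label).
    names : list of str
        Compartment name per label index.
    truth_maps : dict
        One 2-D map per entry of :data:`PARAM_NAMES` plus ``"A"``, ``"C"``
        and ``"mss_over_m0"``, piecewise-constant over compartments.
    """
    rows, cols = spec.grid_shape
    names = list(spec.layer_extents)
    label_map = np.empty((rows, cols), dtype=np.int16)
    for idx, (name, (start, stop)) in enumerate(spec.layer_extents.items()):
        label_map[start:stop, :] = idx
    if spec.follicle is not None:
        r0, c0, ar, ac = spec.follicle
        rr, cc = np.ogrid[:rows, :cols]
        inside = ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
        names.append("follicle")
        label_map[inside] = len(names) - 1

    truth_maps = {}
    fields = {
        "T1": "t1_s", "T2": "t2_ms", "km": "km_per_s", "ADC": "adc_mm2_per_s",
        "A": "a", "C": "c", "mss_over_m0": "mss_over_m0",
    }
    for key, attr in fields.items():
        m = np.empty((rows, cols), dtype=float)
        for idx, name in enumerate(names):
            m[label_map == idx] = getattr(spec.compartments[name], attr)
        truth_maps[key] = m
    truth_maps["MTR"] = 1.0 - truth_maps["mss_over_m0"]
    return label_map, names, truth_maps


def add_rician_noise(frame, sigma, rng):
    """Corrupt a non-negative magnitude frame with Rician noise.

    Each pixel S is replaced by ``sqrt((S + g1)^2 + g2^2)`` with g1, g2
    independent N(0, sigma^2). ``rng`` is a ``numpy.random.Generator`` or a
    seed. ``sigma = 0`` returns the input unchanged.
    """
    frame = np.asarray(frame, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if np.any(frame < 0):
        raise ValueError("magnitude frame must be non-negative")
    if sigma == 0:
        return frame.copy()
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    g1 = rng.normal(0.0, sigma, size=frame.shape)
    g2 = rng.normal(0.0, sigma, size=frame.shape)
    return np.sqrt((frame + g1) ** 2 + g2 ** 2)


def _forward_frames(truth_maps: dict, protocol: AcquisitionProtocol) -> np.ndarray:
    """Evaluate the kind-matched forward model at every schedule point."""
    x = protocol.fit_schedule
    a, c = truth_maps["A"], truth_maps["C"]
    kind = protocol.kind
    frames = np.empty((len(x),) + a.shape, dtype=float)
    for i, xi in enumerate(x):
        if kind == "cpmg":
            frames[i] = models.cpmg_signal(truth_maps["T2"], a, c, xi)
        elif kind == "satrec":
            frames[i] = models.satrec_signal(truth_maps["T1"], a, c, xi)
        elif kind == "mt":
            # steady-state plateau Mss = r*A is the offset of the MT decay
            r = truth_maps["mss_over_m0"]
            frames[i] = r * a + (a - r * a) * np.exp(-truth_maps["km"] * xi)
        elif kind == "diffusion":
            frames[i] = models.diffusion_signal(truth_maps["ADC"], a, c, xi)
        else:  # pragma: no cover - guarded by AcquisitionProtocol
            raise ValueError(f"unknown protocol kind {kind!r}")
    return frames


def simulate_series(truth_maps, protocol, noise_sigma=0.0, seed=None) -> ImageSeries:
    """Simulate one noisy magnitude series from ground-truth maps.

    Frame i is the kind-matched forward model evaluated pixel-wise at
    schedule value i, then Rician-noised with SD ``noise_sigma``.
    """
    frames = _forward_frames(truth_maps, protocol)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed) if not isinstance(
            seed, np.random.Generator) else seed
        frames = add_rician_noise(frames, noise_sigma, rng)
    return ImageSeries(frames=frames, protocol=protocol,
                       meta={"noise_sigma": float(noise_sigma)})
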