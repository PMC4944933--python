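"""Closed-form forward signal models for the four imaging contrasts.

All acquisitions are single-slice spin-echo magnitude images whose signal,
as a function of one acquisition variable, follows a monoexponential with a
constant offset term:

* CPMG multi-echo T2 decay:        S(TE) = A exp(-TE / T2) + C
* Saturation-recovery T1:          S(TR) = A (1 - exp(-TR / T1)) + C
* Off-resonance saturation (MT):   M(t)  = Mss + (M0 - Mss) exp(-km t)
* Stejskal-Tanner diffusion:       S(b)  = A exp(-b ADC) + C

Units follow field convention: T2 in ms (TE in ms), T1 in s (TR in s),
km in s^-1 (saturation time in s), ADC in mm^2/s (b in s/mm^2).

The magnetization-transfer ratio is MTR = 1 - Mss/M0, the fractional
steady-state signal loss under off-resonance saturation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MTState",
    "cpmg_signal",
    "satrec_signal",
    "mt_signal",
    "mtr",
    "stejskal_tanner_b",
    "diffusion_signal",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.675e8


@dataclass(frozen=True)
class MTState:
    """Two magnetization levels and the apparent transfer rate.

    Attributes
    ----------
    m0 : float
        Equilibrium magnetization (signal units).
    mss : float
        Steady-state magnetization under continued off-resonance
        saturation (signal units). Must satisfy ``0 <= mss <= m0``.
    km : float
        Apparent magnetization transfer rate, s^-1. Must be positive.
    """

    m0: float
    mss: float
    km: float

    def __post_init__(self) -> None:
        if not self.km > 0:
            raise ValueError(f"km must be positive, got {self.km}")
        if not (0.0 <= self.mss <= self.m0):
            raise ValueError(
                f"require 0 <= Mss <= M0, got Mss={self.mss}, M0={self.m0}"
            )


def cpmg_signal(t2_ms, a, c, te_ms):
    """Multi-echo T2 decay: ``A * exp(-TE/T2) + C``.

    Parameters
    ----------
    t2_ms : float or ndarray
        Transverse relaxation time, ms; must be positive.
    a, c : float or ndarray
        Decaying amplitude and constant offset, signal units.
    te_ms : array_like
        Echo times, ms.

    Returns
    -------
    ndarray
        Signal at each echo time (broadcast over parameter maps).
    """
    t2_ms = np.asarray(t2_ms, dtype=float)
    if np.any(t2_ms <= 0):
        raise ValueError("T2 must be positive")
    te_ms = np.asarray(te_ms, dtype=float)
    return a * np.exp(-te_ms / t2_ms) + c


def satrec_signal(t1_s, a, c, tr_s):
    """Saturation-recovery T1 signal: ``A * (1 - exp(-TR/T1)) + C``."""
    t1_s = np.asarray(t1_s, dtype=float)
    if np.any(t1_s <= 0):
        raise ValueError("T1 must be positive")
    tr_s = np.asarray(tr_s, dtype=float)
    return a * (1.0 - np.exp(-tr_s / t1_s)) + c


def mt_signal(state: MTState, t_sat_s):
    """Signal under off-resonance presaturation of duration ``t_sat_s``.

    ``M(t) = Mss + (M0 - Mss) * exp(-km t)`` decays monotonically from the
    equilibrium magnetization M0 toward the steady state Mss at the
    apparent transfer rate km.
    """
    t = np.asarray(t_sat_s, dtype=float)
    return state.mss + (state.m0 - state.mss) * np.exp(-state.km * t)


def mtr(m0, mss):
    """Magnetization transfer ratio, ``1 - Mss/M0``.

    Lies in [0, 1] whenever ``0 <= Mss <= M0``. M0 must be positive.
    """
    m0 = np.asarray(m0, dtype=float)
    if np.any(m0 <= 0):
        raise ValueError("M0 must be positive")
    return 1.0 - np.asarray(mss, dtype=float) / m0


def stejskal_tanner_b(g_mT_per_m, delta_ms, Delta_ms, gamma=GAMMA_PROTON, b0=0.0):
    """Diffusion weighting for rectangular Stejskal-Tanner gradients.

    ``b = (gamma * G * delta)**2 * (Delta - delta/3) + b0`` with the result
    in s/mm^2. ``b0`` carries any weighting from imaging gradients that the
    pulsed pair does not account for.

    Parameters
    ----------
    g_mT_per_m : float or ndarray
        Diffusion gradient amplitude, mT/m; non-negative.
    delta_ms : float
        Gradient lobe duration, ms.
    Delta_ms : float
        Lobe separation, ms; must exceed ``delta_ms``.
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1.
    b0 : float
        Baseline b-value, s/mm^2.
    """
    g = np.asarray(g_mT_per_m, dtype=float)
    if np.any(g < 0):
        raise ValueError("gradient amplitude must be non-negative")
    if not delta_ms < Delta_ms:
        raise ValueError(
            f"require delta < Delta, got delta={delta_ms} ms, Delta={Delta_ms} ms"
        )
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if b0 < 0:
        raise ValueError("b0 must be non-negative")
    g_T_per_m = g * 1e-3
    delta_s = delta_ms * 1e-3
    Delta_s = Delta_ms * 1e-3
    b_s_per_m2 = (gamma * g_T_per_m * delta_s) ** 2 * (Delta_s - delta_s / 3.0)
    return b_s_per_m2 * 1e-6 + b0  # s/m^2 -> s/mm^2


def diffusion_signal(adc_mm2_per_s, a, c, b_s_per_mm2):
    """Monoexponential diffusion decay: ``A * exp(-b ADC) + C``."""
    adc = np.asarray(adc_mm2_per_s, dtype=float)
    if np.any(adc <= 0):
        raise ValueError("ADC must be positive")
    b = np.asarray(b_s_per_mm2, dtype=float)
    return a * np.exp(-b * adc) + c
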