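"""Radiometric (14C) kinetics and CO2:O2 specificity.

Fixed-label assays report carboxylation as scintillation counts: CPM
divided by the specific activity (CPM per nmol) gives nmol CO2 fixed;
normalizing by assay time and by the number of active sites (quantified
by 14C-CABP binding) gives a per-site rate in s^-1. Rates across a
bicarbonate series are fit to the Michaelis-Menten law
v = kcat * S / (KM + S) by nonlinear least squares.

Dissolved CO2 follows the bicarbonate equilibrium
CO2 = HCO3- * 10^(pKa' - pH) with an apparent pKa' of 6.10, which
reproduces the assay's 4 mM -> 50 uM and 55 mM -> 700 uM correspondences
at pH 8.0.

The specificity factor S_C/O is the carboxylation:oxygenation velocity
ratio normalized to equal gas concentrations. With [1-3H]RuBP each
carboxylation yields one labeled glycerate and each oxygenation one
labeled glycolate, so vc/vo equals the glycerate:glycolate count ratio
and S_C/O = (vc/vo) * [O2]/[CO2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

PKA_APP_DEFAULT = 6.10
HENRY_CO2_M_PER_ATM = 0.0334  # 25 C
HENRY_O2_M_PER_ATM = 0.00126  # 25 C

# gas mixture used for the specificity assays (ppm)
SPECIFICITY_GAS_O2_PPM = 995_009.0
SPECIFICITY_GAS_CO2_PPM = 4_991.0


@dataclass
class RadioAssayPoint:
    """One 14C fixation measurement at a given CO2 concentration."""

    co2_uM: float
    cpm: float
    specific_activity_cpm_per_nmol: float
    active_sites_nmol: float
    assay_time_s: float = 120.0
    assay_volume_ul: float = 500.0
    bicarbonate_mM: float | None = None

    def __post_init__(self) -> None:
        for name in ("co2_uM", "cpm", "assay_time_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class MMFit:
    kcat_per_s: float
    kcat_se: float
    km_uM: float
    km_se: float
    covariance: np.ndarray
    residual_rms: float


@dataclass
class SpecificityResult:
    glycerate_cpm: float
    glycolate_cpm: float
    co2_uM: float
    o2_uM: float
    vc_over_vo: float
    s_co: float
    s_co_se: float


def co2_from_bicarbonate(hco3_mM: float, pH: float, pKa_app: float = PKA_APP_DEFAULT) -> float:
    """Dissolved CO2 (uM) in equilibrium with bicarbonate (mM) at given pH."""
    if hco3_mM < 0:
        raise ValueError("bicarbonate concentration must be >= 0")
    if not 5 < pH < 11:
        raise ValueError("pH out of the supported 5-11 range")
    return hco3_mM * 1000.0 * 10.0 ** (pKa_app - pH)


def bicarbonate_from_co2(co2_uM: float, pH: float, pKa_app: float = PKA_APP_DEFAULT) -> float:
    """Inverse of :func:`co2_from_bicarbonate` (mM)."""
    return co2_uM / 1000.0 / 10.0 ** (pKa_app - pH)


def calibrate_specific_activity(total_cpm: float, rubp_nmol: float = 5.2) -> float:
    """CPM per nmol from an exhaustive-consumption calibration assay."""
    if total_cpm <= 0 or rubp_nmol <= 0:
        raise ValueError("total_cpm and rubp_nmol must be positive")
    return total_cpm / rubp_nmol


def cpm_to_rate(point: RadioAssayPoint) -> float:
    """Per-site carboxylation rate (s^-1) from one assay point."""
    if point.specific_activity_cpm_per_nmol <= 0:
        raise ValueError("specific activity must be positive")
    if point.active_sites_nmol <= 0:
        raise ValueError("active_sites_nmol must be positive")
    if point.assay_time_s <= 0:
        raise ValueError("assay_time_s must be positive")
    nmol_fixed = point.cpm / point.specific_activity_cpm_per_nmol
    return nmol_fixed / (point.assay_time_s * point.active_sites_nmol)


def _mm(s: np.ndarray, kcat: float, km: float) -> np.ndarray:
    return kcat * s / (km + s)


def _hanes_woolf_init(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    ok = v > 0
    if ok.sum() >= 2 and len(np.unique(s[ok])) >= 2:
        fit = stats.linregress(s[ok], s[ok] / v[ok])
        if fit.slope > 0 and fit.intercept > 0:
            kcat0 = 1.0 / fit.slope
            return kcat0, fit.intercept * kcat0
    return float(v.max() * 1.5), float(np.median(s))


def fit_michaelis_menten(points: Sequence[tuple[float, float]]) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit of (S in uM, rate) points.

    Initialized from a Hanes-Woolf linearization; standard errors come
    from the local covariance. Replicate points enter individually and
    unweighted.
    """
    arr = np.asarray(points, dtype=float)
    s, v = arr[:, 0], arr[:, 1]
    if len(np.unique(s)) < 3:
        raise ValueError("need >= 3 distinct substrate concentrations")
    if np.any(v < 0):
        raise ValueError("rates must be >= 0")
    p0 = _hanes_woolf_init(s, v)
    try:
        popt, pcov = optimize.curve_fit(_mm, s, v, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Michaelis-Menten fit failed to converge; Hanes-Woolf fallback "
            f"kcat={p0[0]:.3g}, KM={p0[1]:.3g}"
        ) from exc
    kcat, km = float(popt[0]), float(popt[1])
    if kcat <= 0 or km <= 0:
        raise RuntimeError(f"non-physical fit: kcat={kcat:.3g}, KM={km:.3g}")
    ses = np.sqrt(np.clip(np.diag(pcov), 0, None))
    resid = v - _mm(s, kcat, km)
    return MMFit(
        kcat_per_s=kcat,
        kcat_se=float(ses[0]),
        km_uM=km,
        km_se=float(ses[1]),
        covariance=pcov,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def fit_michaelis_menten_points(points: Sequence[RadioAssayPoint]) -> MMFit:
    """MM fit straight from raw assay points (CPM converted per point)."""
    return fit_michaelis_menten([(p.co2_uM, cpm_to_rate(p)) for p in points])


def dissolved_gas(
    ppm: float, henry_coeff_M_per_atm: float, total_pressure_atm: float = 1.0
) -> float:
    """Dissolved concentration (uM) of a gas at a given mixing ratio.

    c = ppm * 1e-6 * pressure * K_H, expressed in uM (so numerically
    ppm * pressure * K_H).
    """
    if not 0 <= ppm <= 1e6:
        raise ValueError("ppm must be within [0, 1e6]")
    return ppm * 1e-6 * total_pressure_atm * henry_coeff_M_per_atm * 1e6


def specificity_from_peaks(
    glycerate_cpm: float, glycolate_cpm: float, co2_uM: float, o2_uM: float
) -> SpecificityResult:
    """S_C/O from labeled product peaks and dissolved gas concentrations.

    The standard error assumes independent Poisson counting of the two
    peaks.
    """
    if glycolate_cpm <= 0:
        raise ValueError("zero glycolate counts: specificity unbounded at assay sensitivity")
    if glycerate_cpm < 0:
        raise ValueError("glycerate counts must be >= 0")
    if co2_uM <= 0 or o2_uM <= 0:
        raise ValueError("gas concentrations must be positive")
    vc_vo = glycerate_cpm / glycolate_cpm
    s_co = vc_vo * (o2_uM / co2_uM)
    rel_se = (
        math.sqrt(1.0 / glycerate_cpm + 1.0 / glycolate_cpm) if glycerate_cpm > 0 else math.inf
    )
    return SpecificityResult(
        glycerate_cpm=glycerate_cpm,
        glycolate_cpm=glycolate_cpm,
        co2_uM=co2_uM,
        o2_uM=o2_uM,
        vc_over_vo=vc_vo,
        s_co=s_co,
        s_co_se=s_co * rel_se,
    )
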