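"""Spectrophotometric screen: A340 slopes, CABP titration, activity calls.

The coupled assay reports carboxylation through NADH oxidation at 340 nm:
each carboxylation yields two 3-phosphoglycerate molecules, each of which
consumes one NADH, so the NADH oxidation rate is twice the carboxylation
rate. A trace's linear A340 slope divided by the effective extinction
coefficient gives the NADH consumption rate; dividing by two converts to
carboxylation rate.

Because CABP binds active sites stoichiometrically and essentially
irreversibly, the rate declines linearly with CABP concentration:
rate(c) = kcat * ([E] - c) for c < [E]. A least-squares line through the
(CABP, rate) points yields the active-site concentration [E] as its
x-intercept and the uninhibited rate Vmax as its y-intercept; the
per-site turnover number is kcat = Vmax / [E].

The effective extinction coefficient is instrument-specific (plate path
lengths differ from 1 cm) and therefore a required configuration value
with no default.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AssayTrace:
    """One well's (time, A340) series with CABP metadata."""

    well_id: str
    variant_id: str
    cabp_nM: float
    timestamps_s: np.ndarray
    a340: np.ndarray
    batch_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if self.timestamps_s.shape != self.a340.shape:
            raise ValueError("timestamps and a340 must have equal length")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.cabp_nM < 0:
            raise ValueError("cabp_nM must be >= 0")


@dataclass(frozen=True)
class AssayConfig:
    """Assay constants for converting slopes into per-site rates.

    epsilon_eff: effective extinction coefficient, absorbance per molar
    NADH (required; path-length specific). The fit window defaults to
    30-330 s, skipping mixing dead time.
    """

    epsilon_eff: float
    enzyme_nominal_nM: float = 50.0
    cabp_series_nM: tuple[float, ...] = (0.0, 0.0, 10.0, 20.0, 30.0, 90.0)
    nadh_per_carboxylation: float = 2.0
    activity_threshold_per_s: float = 0.5
    fit_window_s: tuple[float, float] = (30.0, 330.0)
    reference_tolerance: float = 0.25

    def __post_init__(self) -> None:
        if self.epsilon_eff <= 0:
            raise ValueError("epsilon_eff must be positive")
        if self.activity_threshold_per_s <= 0:
            raise ValueError("activity threshold must be positive")


class SlopeFit(NamedTuple):
    slope: float  # absorbance per second
    stderr: float
    intercept: float
    n_points: int


@dataclass
class TitrationResult:
    variant_id: str
    vmax_nM_per_s: float | None
    active_sites_nM: float | None
    kcat_per_s: float | None
    r_squared: float | None
    active: bool
    n_points_used: int
    flags: list[str] = field(default_factory=list)


def fit_slope(trace: AssayTrace, config: AssayConfig) -> SlopeFit:
    """Ordinary least-squares A340 slope inside the configured window."""
    lo, hi = config.fit_window_s
    mask = (trace.timestamps_s >= lo) & (trace.timestamps_s <= hi)
    if mask.sum() < 10:
        raise ValueError(
            f"only {int(mask.sum())} points in fit window [{lo}, {hi}] s for "
            f"well {trace.well_id!r}; need >= 10"
        )
    t = trace.timestamps_s[mask]
    y = trace.a340[mask]
    res = stats.linregress(t, y)
    resid = y - (res.intercept + res.slope * t)
    sigma = resid.std(ddof=2)
    if sigma > 0 and np.any(np.abs(resid) > 5 * sigma):
        logger.warning("well %s: gross artifact(s) beyond 5 sigma in fit window", trace.well_id)
    return SlopeFit(float(res.slope), float(res.stderr), float(res.intercept), int(mask.sum()))


def slope_to_carbox_rate(
    slope: float, config: AssayConfig, stderr: float = 0.0
) -> float:
    """Convert an A340 slope (A/s) to carboxylation rate in nM/s.

    rate = (-slope / epsilon_eff) / nadh_per_carboxylation, in molar per
    second, scaled to nM/s. Positive slopes beyond the slope's own noise
    are warned about; negative rates are clamped to zero.
    """
    if slope > 0 and slope > 2 * stderr:
        warnings.warn(f"positive A340 slope {slope:.3g}/s beyond noise; rate clamped to 0")
        return 0.0
    rate = (-slope / config.epsilon_eff) / config.nadh_per_carboxylation * 1e9
    return max(rate, 0.0)


def titration_fit(
    rates_by_cabp: Sequence[tuple[float, float]],
    config: AssayConfig,
    variant_id: str = "",
) -> TitrationResult:
    """Fit rate vs [CABP] line; extract [E] (x-intercept) and kcat.

    Replicate rates at the same CABP concentration (notably the duplicate
    zero) are averaged first. Points at CABP beyond the estimated [E]
    with near-zero rate (saturated inhibition) are excluded once and the
    line refit, since they sit off the linear regime.
    """
    grouped: dict[float, list[float]] = {}
    for cabp, rate in rates_by_cabp:
        grouped.setdefault(float(cabp), []).append(float(rate))
    concs = np.array(sorted(grouped))
    rates = np.array([np.mean(grouped[c]) for c in concs])

    if len(concs) < 3:
        raise ValueError("need >= 3 distinct CABP concentrations")

    result = TitrationResult(
        variant_id=variant_id, vmax_nM_per_s=None, active_sites_nM=None,
        kcat_per_s=None, r_squared=None, active=False, n_points_used=len(concs),
    )

    zero_rate = rates[concs == 0].mean() if np.any(concs == 0) else rates.max()
    if zero_rate <= 0:
        result.flags.append("no-activity")
        return result

    def _line(c: np.ndarray, r: np.ndarray) -> tuple[float, float, float]:
        fit = stats.linregress(c, r)
        return float(fit.intercept), float(fit.slope), float(fit.rvalue) ** 2

    a, b, r2 = _line(concs, rates)
    if b < 0:
        e_est = -a / b
        keep = ~((concs > e_est) & (rates < 0.05 * zero_rate))
        if keep.sum() >= 3 and not keep.all():
            a, b, r2 = _line(concs[keep], rates[keep])
            result.n_points_used = int(keep.sum())
            result.flags.append("saturated-points-excluded")

    if b >= 0:
        result.flags.append("not-quantifiable: non-negative titration slope")
        return result

    active_sites = -a / b
    if not 0 < active_sites <= 2 * concs.max():
        result.flags.append(f"active-sites-implausible: {active_sites:.3g} nM")
        return result

    kcat = a / active_sites  # == -b
    result.vmax_nM_per_s = a
    result.active_sites_nM = active_sites
    result.kcat_per_s = kcat
    result.r_squared = r2
    result.active = call_active(kcat, config)
    return result


def call_active(kcat: float | None, config: AssayConfig) -> bool:
    """Activity call: kcat at or above the threshold (inclusive)."""
    return kcat is not None and math.isfinite(kcat) and kcat >= config.activity_threshold_per_s


def analyze_titration(
    traces: Sequence[AssayTrace], config: AssayConfig, variant_id: str | None = None
) -> TitrationResult:
    """Full per-variant pipeline: slopes -> rates -> titration line -> kcat."""
    if variant_id is None:
        variant_id = traces[0].variant_id
    points = []
    for trace in traces:
        sf = fit_slope(trace, config)
        points.append((trace.cabp_nM, slope_to_carbox_rate(sf.slope, config, sf.stderr)))
    return titration_fit(points, config, variant_id=variant_id)


@dataclass
class BatchQC:
    expected_kcat: float
    per_batch: dict[str, tuple[float, bool]]  # batch -> (reference kcat, passed)
    running_mean: float
    running_se: float

    @property
    def flagged_batches(self) -> list[str]:
        return [b for b, (_, ok) in self.per_batch.items() if not ok]


def batch_reference_check(
    batch_results: Mapping[str, float],
    expected_kcat: float,
    tolerance_fraction: float = 0.25,
) -> BatchQC:
    """Flag batches whose internal-reference kcat strays from expectation.

    ``batch_results`` maps batch id to the reference variant's measured
    kcat in that batch. The running mean and its standard error
    (sd/sqrt(n)) across batches are reported.
    """
    if not batch_results:
        raise ValueError("no batches supplied; reference missing")
    per_batch = {
        b: (k, abs(k - expected_kcat) / expected_kcat <= tolerance_fraction)
        for b, k in batch_results.items()
    }
    values = np.array(list(batch_results.values()), dtype=float)
    se = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else 0.0
    return BatchQC(
        expected_kcat=expected_kcat,
        per_batch=per_batch,
        running_mean=float(values.mean()),
        running_se=se,
    )


def traces_from_long_csv(path) -> list[AssayTrace]:
    """Read long-format trace CSV (batch, well, variant, cabp_nM, time_s, a340)."""
    df = pd.read_csv(path)
    traces = []
    for (batch, well), grp in df.groupby(["batch", "well"], sort=False):
        grp = grp.sort_values("time_s")
        traces.append(
            AssayTrace(
                well_id=str(well),
                variant_id=str(grp["variant"].iloc[0]),
                cabp_nM=float(grp["cabp_nM"].iloc[0]),
                timestamps_s=grp["time_s"].to_numpy(),
                a340=grp["a340"].to_numpy(),
                batch_id=str(batch),
            )
        )
    return traces


def traces_to_long_csv(traces: Sequence[AssayTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "batch": tr.batch_id,
                    "well": tr.well_id,
                    "variant": tr.variant_id,
                    "cabp_nM": tr.cabp_nM,
                    "time_s": tr.timestamps_s,
                    "a340": tr.a340,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def results_to_tsv(results: Sequence[TitrationResult], path) -> None:
    rows = [
        {
            "variant": r.variant_id,
            "kcat_per_s": r.kcat_per_s,
            "active_sites_nM": r.active_sites_nM,
            "vmax_nM_per_s": r.vmax_nM_per_s,
            "r2": r.r_squared,
            "active": r.active,
            "flags": ";".join(r.flags),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
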