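"""Cross-variant kinetic statistics.

Temperature adjustment uses the Q10 convention
k(T2) = k(T1) * Q10^((T2-T1)/10) with Q10 = 2.2 for rubisco
carboxylation. Carboxylation efficiency is kcat/KM in s^-1 mM^-1. Two
Michaelis-Menten curves cross at
C* = (kcat_a*KM_b - kcat_b*KM_a) / (kcat_b - kcat_a); if C* is not a
finite positive concentration one enzyme is faster at every substrate
level. Kinetic similarity between two variants is the ratio of the larger
to the smaller kcat, summarized against pairwise sequence identity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Literal, Sequence

import numpy as np

Q10_DEFAULT = 2.2


@dataclass
class KineticRecord:
    variant_id: str
    kcat_per_s: float
    km_uM: float | None = None
    s_co: float | None = None
    temperature_C: float = 25.0
    oligomer: str | None = None
    form: str | None = None

    def __post_init__(self) -> None:
        if self.kcat_per_s < 0:
            raise ValueError("kcat must be >= 0")
        if not math.isfinite(self.temperature_C):
            raise ValueError("temperature must be finite")


@dataclass(frozen=True)
class SimilarityPair:
    id_i: str
    id_j: str
    identity: float
    ratio: float  # larger rate / smaller rate, >= 1


def q10_adjust(k: float, t_from_C: float, t_to_C: float, q10: float = Q10_DEFAULT) -> float:
    """Adjust a rate between temperatures with the Q10 rule."""
    if k < 0:
        raise ValueError("rate must be >= 0")
    return k * q10 ** ((t_to_C - t_from_C) / 10.0)


def carbox_efficiency(kcat_per_s: float, km_uM: float) -> float:
    """kcat/KM in s^-1 mM^-1 (KM given in uM)."""
    if km_uM <= 0:
        raise ValueError("KM must be positive")
    return kcat_per_s / (km_uM / 1000.0)


def mm_rate(kcat: float, km: float, s: float) -> float:
    """Michaelis-Menten rate at substrate concentration s (same units as km)."""
    return kcat * s / (km + s)


@dataclass(frozen=True)
class CrossoverResult:
    crossover_uM: float | None
    verdict: Literal["crossover", "a_dominant", "b_dominant", "identical"]


def crossover_concentration(
    params_a: tuple[float, float], params_b: tuple[float, float]
) -> CrossoverResult:
    """Where two MM curves cross, or which enzyme dominates everywhere.

    params are (kcat in s^-1, KM in uM). A positive finite crossover is
    returned as a concentration in uM; otherwise the verdict names the
    everywhere-faster enzyme.
    """
    (kc_a, km_a), (kc_b, km_b) = params_a, params_b
    if kc_a <= 0 or kc_b <= 0 or km_a <= 0 or km_b <= 0:
        raise ValueError("parameters must be positive")
    if kc_a == kc_b and km_a == km_b:
        return CrossoverResult(None, "identical")

    def dominant() -> Literal["a_dominant", "b_dominant"]:
        # compare at low-S limit (efficiency); if equal, at saturation
        eff_a, eff_b = kc_a / km_a, kc_b / km_b
        if eff_a != eff_b:
            return "a_dominant" if eff_a > eff_b else "b_dominant"
        return "a_dominant" if kc_a > kc_b else "b_dominant"

    denom = kc_b - kc_a
    if denom == 0:
        return CrossoverResult(None, dominant())
    c_star = (kc_a * km_b - kc_b * km_a) / denom
    if math.isfinite(c_star) and c_star > 0:
        return CrossoverResult(c_star, "crossover")
    return CrossoverResult(None, dominant())


def kinetic_similarity_pairs(
    records: Sequence[KineticRecord],
    identity_fn: Callable[[str, str], float],
) -> list[SimilarityPair]:
    """All unordered pairs with rate ratio (larger/smaller) and identity.

    Pairs involving a zero rate are skipped with a warning, as their ratio
    is undefined.
    """
    pairs: list[SimilarityPair] = []
    for a, b in combinations(records, 2):
        if a.kcat_per_s <= 0 or b.kcat_per_s <= 0:
            warnings.warn(f"skipping pair ({a.variant_id}, {b.variant_id}): zero rate")
            continue
        hi, lo = max(a.kcat_per_s, b.kcat_per_s), min(a.kcat_per_s, b.kcat_per_s)
        pairs.append(
            SimilarityPair(
                id_i=a.variant_id,
                id_j=b.variant_id,
                identity=identity_fn(a.variant_id, b.variant_id),
                ratio=hi / lo,
            )
        )
    return pairs


def similarity_by_identity_bin(
    pairs: Sequence[SimilarityPair],
    threshold: float = 0.80,
    mean: Literal["arithmetic", "geometric"] = "arithmetic",
) -> tuple[float | None, float]:
    """Mean rate ratio among high-identity pairs (> threshold) vs all pairs."""
    if not pairs:
        raise ValueError("no pairs supplied")

    def _mean(values: list[float]) -> float:
        if mean == "geometric":
            return float(np.exp(np.mean(np.log(values))))
        return float(np.mean(values))

    all_ratios = [p.ratio for p in pairs]
    high = [p.ratio for p in pairs if p.identity > threshold]
    return (_mean(high) if high else None), _mean(all_ratios)


@dataclass(frozen=True)
class RateSummary:
    median: float
    iqr: float
    q1: float
    q3: float
    count_active: int


def summarize_rates(
    records: Sequence[KineticRecord], activity_threshold: float = 0.5
) -> RateSummary:
    """Median and interquartile range of kcat over active records.

    Quantiles use linear interpolation (type 7). Records below the
    activity threshold are excluded.
    """
    if not records:
        raise ValueError("no records supplied")
    active = [r.kcat_per_s for r in records if r.kcat_per_s >= activity_threshold]
    if not active:
        raise ValueError("no active records above threshold")
    q1, med, q3 = np.percentile(active, [25, 50, 75])
    return RateSummary(
        median=float(med), iqr=float(q3 - q1), q1=float(q1), q3=float(q3),
        count_active=len(active),
    )
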