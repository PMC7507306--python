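"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of study input — sequence families with
controlled identity structure, plate-reader NADH decay traces under a
CABP series, 14C count series following Michaelis-Menten kinetics, and
labeled glycerate/glycolate counts under a defined gas mixture — and
emits a :class:`TruthManifest` recording the parameters it used, so that
recovery by the analysis modules can be tested without any external data.

All randomness flows through ``numpy.random.default_rng`` (PCG64);
identical seeds give identical outputs across runs and platforms.
Sequence evolution uses substitutions only (no indels) so identity
arithmetic stays exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .plate import AssayTrace
from .radiometric import RadioAssayPoint, bicarbonate_from_co2
from .records import KNOWN_FORMS, FormLabel, ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class TruthManifest:
    """Ground-truth parameters emitted alongside every synthetic dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"generator": self.generator, "seed": self.seed,
                 "params": self.params, "truth": self.truth},
                indent=2, default=str,
            )
            + "\n"
        )


def _mutate(rng: np.random.Generator, sequence: str, n_sites: int) -> str:
    """Substitute n_sites randomly chosen positions with a different residue."""
    seq = list(sequence)
    sites = rng.choice(len(seq), size=n_sites, replace=False)
    for pos in sites:
        alternatives = AA20.replace(seq[pos], "")
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def gen_sequence_family(
    n_families: int = 3,
    members_per_family: int = 5,
    length: int = 300,
    within_identity: float = 0.95,
    between_identity: float = 0.55,
    seed: int = 0,
) -> tuple[list[ProteinRecord], dict[str, FormLabel], TruthManifest]:
    """Sequence families with controlled within/between identity.

    Family ancestors are mutated copies of a shared root; members are
    mutated copies of their ancestor (the first member IS the ancestor).
    With substitution-only mutation at disjoint random sites, two members
    of one family differ at about twice the per-member mutation fraction,
    so per-member fractions of (1 - within)/2 and (1 - between)/2 put the
    realized pairwise identities near the requested values. One member
    per family is marked curated with a form drawn from the known forms.
    """
    if not 0 < between_identity < within_identity <= 1:
        raise ValueError("require 0 < between_identity < within_identity <= 1")
    rng = np.random.default_rng(seed)
    root = "".join(rng.choice(list(AA20), size=length))
    n_between = int(round((1 - between_identity) / 2 * length))
    n_within = int(round((1 - within_identity) / 2 * length))

    records: list[ProteinRecord] = []
    curated: dict[str, FormLabel] = {}
    membership: dict[str, str] = {}
    forms: dict[str, str] = {}
    for f in range(n_families):
        ancestor = _mutate(rng, root, n_between)
        form = KNOWN_FORMS[rng.integers(len(KNOWN_FORMS))]
        family_id = f"fam{f}"
        forms[family_id] = form.value
        for m in range(members_per_family):
            seq = ancestor if m == 0 else _mutate(rng, ancestor, n_within)
            rid = f"fam{f}_seq{m}"
            records.append(ProteinRecord(id=rid, sequence=seq, source="synthetic"))
            membership[rid] = family_id
            if m == 0:
                curated[rid] = form

    manifest = TruthManifest(
        generator="gen_sequence_family",
        seed=seed,
        params=dict(
            n_families=n_families, members_per_family=members_per_family,
            length=length, within_identity=within_identity,
            between_identity=between_identity,
        ),
        truth=dict(root_sequence=root, membership=membership, family_forms=forms,
                   curated={k: v.value for k, v in curated.items()}),
    )
    return records, curated, manifest


def gen_plate_traces(
    true_kcat: float,
    true_sites_nM: float = 50.0,
    cabp_series_nM: Sequence[float] = (0.0, 0.0, 10.0, 20.0, 30.0, 90.0),
    epsilon_eff: float = 1800.0,
    nadh0_uM: float = 800.0,
    noise_sd: float = 0.002,
    duration_s: float = 900.0,
    interval_s: float = 2.0,
    seed: int = 0,
    variant_id: str = "synthetic",
    batch_id: str = "batch0",
) -> tuple[list[AssayTrace], TruthManifest]:
    """NADH-decay traces under a CABP titration with tight-binding inhibition.

    The carboxylation rate at CABP concentration c is
    kcat * max(sites - c, 0) (nM/s); NADH is consumed at twice that rate.
    A340(t) = epsilon_eff * [NADH](t) plus homoscedastic Gaussian noise.
    Raises if NADH would be exhausted inside the measured window.
    """
    if true_kcat <= 0 or true_sites_nM <= 0 or epsilon_eff <= 0 or nadh0_uM <= 0:
        raise ValueError("parameters must be positive")
    max_nadh_rate_M_s = 2.0 * true_kcat * true_sites_nM * 1e-9
    if max_nadh_rate_M_s * duration_s >= nadh0_uM * 1e-6:
        raise ValueError(
            "NADH would be exhausted within the trace; increase nadh0_uM "
            f"above {max_nadh_rate_M_s * duration_s * 1e6:.0f} uM"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, interval_s)
    traces = []
    for i, cabp in enumerate(cabp_series_nM):
        carbox_rate_nM_s = true_kcat * max(true_sites_nM - cabp, 0.0)
        nadh_rate_M_s = 2.0 * carbox_rate_nM_s * 1e-9
        a340 = epsilon_eff * (nadh0_uM * 1e-6 - nadh_rate_M_s * t)
        if noise_sd > 0:
            a340 = a340 + rng.normal(0.0, noise_sd, size=t.shape)
        traces.append(
            AssayTrace(
                well_id=f"W{i + 1}", variant_id=variant_id, cabp_nM=float(cabp),
                timestamps_s=t.copy(), a340=a340, batch_id=batch_id,
            )
        )
    manifest = TruthManifest(
        generator="gen_plate_traces",
        seed=seed,
        params=dict(
            cabp_series_nM=list(cabp_series_nM), epsilon_eff=epsilon_eff,
            nadh0_uM=nadh0_uM, noise_sd=noise_sd, duration_s=duration_s,
            interval_s=interval_s,
        ),
        truth=dict(kcat_per_s=true_kcat, active_sites_nM=true_sites_nM),
    )
    return traces, manifest


def gen_radio_points(
    true_kcat: float,
    true_km_uM: float,
    sites_nmol: float = 0.1,
    co2_series_uM: Sequence[float] = (50.0, 100.0, 200.0, 350.0, 500.0, 700.0),
    replicates: int = 2,
    time_s: float = 120.0,
    sa_cpm_per_nmol: float = 200.0,
    poisson_noise: bool = True,
    pH: float = 8.0,
    seed: int = 0,
) -> tuple[list[RadioAssayPoint], TruthManifest]:
    """14C fixation points following MM kinetics with counting noise.

    Expected fixation is kcat*S/(KM+S) * sites * time nmol; observed CPM
    are Poisson around expected * specific activity (or exactly the
    expectation in noise-free mode). The bicarbonate field is filled via
    the CO2 equilibrium at the given pH.
    """
    if true_kcat <= 0 or true_km_uM <= 0 or sites_nmol <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    points = []
    for co2 in co2_series_uM:
        for _ in range(replicates):
            rate = true_kcat * co2 / (true_km_uM + co2)
            expected_cpm = rate * sites_nmol * time_s * sa_cpm_per_nmol
            cpm = float(rng.poisson(expected_cpm)) if poisson_noise else expected_cpm
            points.append(
                RadioAssayPoint(
                    co2_uM=float(co2), cpm=cpm,
                    specific_activity_cpm_per_nmol=sa_cpm_per_nmol,
                    active_sites_nmol=sites_nmol, assay_time_s=time_s,
                    bicarbonate_mM=bicarbonate_from_co2(co2, pH),
                )
            )
    manifest = TruthManifest(
        generator="gen_radio_points",
        seed=seed,
        params=dict(
            co2_series_uM=list(co2_series_uM), replicates=replicates, time_s=time_s,
            sa_cpm_per_nmol=sa_cpm_per_nmol, sites_nmol=sites_nmol,
            poisson_noise=poisson_noise, pH=pH,
        ),
        truth=dict(kcat_per_s=true_kcat, km_uM=true_km_uM),
    )
    return points, manifest


def gen_specificity_counts(
    true_sco: float,
    co2_uM: float,
    o2_uM: float,
    total_turnovers: int = 100_000,
    seed: int = 0,
) -> tuple[int, int, TruthManifest]:
    """Binomially partitioned turnover counts under a given gas mixture.

    Each turnover carboxylates with probability
    p = S_C/O * [CO2] / (S_C/O * [CO2] + [O2]), yielding one labeled
    glycerate; otherwise it oxygenates, yielding one labeled glycolate.
    """
    if true_sco <= 0 or co2_uM <= 0 or o2_uM <= 0:
        raise ValueError("parameters must be positive")
    if total_turnovers <= 0:
        raise ValueError("total_turnovers must be positive")
    rng = np.random.default_rng(seed)
    p = true_sco * co2_uM / (true_sco * co2_uM + o2_uM)
    glycerate = int(rng.binomial(total_turnovers, p))
    glycolate = total_turnovers - glycerate
    manifest = TruthManifest(
        generator="gen_specificity_counts",
        seed=seed,
        params=dict(co2_uM=co2_uM, o2_uM=o2_uM, total_turnovers=total_turnovers),
        truth=dict(s_co=true_sco, carboxylation_probability=p),
    )
    return glycerate, glycolate, manifest
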