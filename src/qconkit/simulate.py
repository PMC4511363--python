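"""Synthetic LC-MS data generation.

Stands in for the instrument so that the whole quantification chain can be
exercised, and audited against known ground truth, at desk scale.  A
simulated run contains, for each requested species (peptide × label state ×
charge), a Gaussian elution profile whose time-integrated intensity equals
``amount × response_factor``, distributed over the species' isotopologue
envelope (light: natural abundances; heavy: every nitrogen fixed at ¹⁵N,
mass shifted by N × 0.997035 Da).  Output is centroided; multiplicative
log-normal noise is applied per species per scan at a stated CV.

Three generators mirror the study designs the downstream statistics expect:

* :func:`simulate_run` — one LC-MS acquisition from an explicit spec;
* :func:`simulate_spike_series` — a calibration experiment: fixed
  endogenous light peptide, heavy standard spiked at increasing levels
  (default 10/30/100/300 fmol);
* :func:`simulate_cohort` — healthy and tumour serum cohorts with
  group concentration distributions (truncated normal) defaulting to the
  observed serum means/SDs for DcR3 (healthy 27.23 ± 9.47, tumour
  116.94 ± 57.37 fmol/ml) and GDF15 (98.11 ± 34.96, 164.44 ± 79.31 fmol/ml),
  pushed through the volume ledger so the quantifier can recover them.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import isotopes
from .masses import (
    N15_SHIFT,
    PROTON_MASS,
    Peptide,
    composition,
    nitrogen_count,
    peptide_mass,
)
from .quantify import Scan, SpectrumRun, VolumeLedger

__all__ = [
    "SpeciesSpec",
    "RunSpec",
    "CohortGroup",
    "CohortAnalyte",
    "CohortSpec",
    "simulate_run",
    "simulate_spike_series",
    "simulate_cohort",
]

DEFAULT_RESPONSE_FACTOR = 1.0e4  # integrated intensity per fmol
N_ISOTOPOLOGUES = 5


@dataclass(frozen=True)
class SpeciesSpec:
    """One peptide species in a simulated run."""

    peptide: str
    label_state: str  # "light" | "heavy"
    charge: int
    amount_fmol: float
    rt_min: float = 20.0
    peak_sd_min: float = 0.1

    def __post_init__(self) -> None:
        if self.amount_fmol < 0:
            raise ValueError("amount must be >= 0")
        if self.peak_sd_min <= 0:
            raise ValueError("peak sd must be positive")
        if self.label_state not in ("light", "heavy"):
            raise ValueError(f"unknown label state {self.label_state!r}")


@dataclass(frozen=True)
class RunSpec:
    """Full specification of one simulated LC-MS acquisition.

    ``seed`` is mandatory: runs must be reproducible.  ``noise_cv`` is the
    coefficient of variation of the per-species, per-scan multiplicative
    log-normal noise; ``additive_floor`` adds truncated-Gaussian counts per
    centroid.  RT limits default to 1.5 min beyond the extreme species RTs.
    """

    species: tuple[SpeciesSpec, ...]
    seed: int
    response_factor: float = DEFAULT_RESPONSE_FACTOR
    noise_cv: float = 0.0
    additive_floor: float = 0.0
    scan_interval_min: float = 0.05
    rt_start: float | None = None
    rt_end: float | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("run spec needs at least one species")
        if self.scan_interval_min <= 0:
            raise ValueError("scan interval must be positive")

    @property
    def rt_limits(self) -> tuple[float, float]:
        rts = [s.rt_min for s in self.species]
        lo = self.rt_start if self.rt_start is not None else max(min(rts) - 1.5, 0.0)
        hi = self.rt_end if self.rt_end is not None else max(rts) + 1.5
        return lo, hi


def _species_centroids(spec: SpeciesSpec) -> tuple[np.ndarray, np.ndarray]:
    """(m/z positions, envelope fractions) of a species' isotopologues."""
    mass = peptide_mass(spec.peptide, "monoisotopic")
    comp = composition(spec.peptide)
    if spec.label_state == "heavy":
        mass += nitrogen_count(spec.peptide) * N15_SHIFT
    env = isotopes.envelope(
        comp, label=spec.label_state, n_iso=N_ISOTOPOLOGUES, normalize=False
    )
    k = np.arange(N_ISOTOPOLOGUES)
    mzs = (mass + k * isotopes.ISOTOPE_SPACING + spec.charge * PROTON_MASS) / spec.charge
    return mzs, env


def simulate_run(spec: RunSpec) -> SpectrumRun:
    """Generate one centroided LC-MS run from a spec.

    Within each scan at time ``t`` a species contributes
    ``amount × response_factor × N(t; rt, sd)`` total intensity (so that the
    trapezoidal area of its XIC over RT equals ``amount × response_factor ×
    envelope fraction`` at each isotope position).  Centroids from different
    species falling on the same m/z grid position are summed.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.rt_limits
    times = np.arange(lo, hi + spec.scan_interval_min / 2, spec.scan_interval_min)

    species_centroids = [_species_centroids(s) for s in spec.species]
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2)) if spec.noise_cv > 0 else 0.0

    scans: list[Scan] = []
    for t in times:
        peaks: dict[float, float] = {}
        for s, (mzs, env) in zip(spec.species, species_centroids):
            if s.amount_fmol == 0:
                continue
            profile = (
                s.amount_fmol
                * spec.response_factor
                * math.exp(-0.5 * ((t - s.rt_min) / s.peak_sd_min) ** 2)
                / (s.peak_sd_min * math.sqrt(2.0 * math.pi))
            )
            if sigma > 0:
                profile *= math.exp(rng.normal(-0.5 * sigma**2, sigma))
            for mz_pos, frac in zip(mzs, env):
                key = round(float(mz_pos), 6)
                peaks[key] = peaks.get(key, 0.0) + profile * frac
        mz_arr = np.array(sorted(peaks), dtype=float)
        int_arr = np.array([peaks[m] for m in sorted(peaks)], dtype=float)
        if spec.additive_floor > 0 and len(int_arr):
            int_arr = np.maximum(
                int_arr + rng.normal(0.0, spec.additive_floor, size=len(int_arr)), 0.0
            )
        scans.append(Scan(rt=float(t), mz=mz_arr, intensity=int_arr))
    return SpectrumRun(
        scans=tuple(scans),
        metadata={
            "id": f"sim-seed{spec.seed}",
            "seed": spec.seed,
            "response_factor": spec.response_factor,
            "noise_cv": spec.noise_cv,
        },
    )


def simulate_spike_series(
    endogenous_fmol: float = 50.0,
    levels: Sequence[float] = (10.0, 30.0, 100.0, 300.0),
    cv: float = 0.03,
    seed: int = 0,
    peptide: str = "LLQALR",
    charge: int = 2,
    rt_min: float = 20.0,
    response_factor: float = DEFAULT_RESPONSE_FACTOR,
) -> list[tuple[float, SpectrumRun]]:
    """Calibration experiment: heavy standard spiked at increasing levels.

    One run per level; the light (endogenous) amount is fixed.  Per-run
    seeds are spawned deterministically from ``seed``.
    """
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly ascending")
    if any(l <= 0 for l in levels):
        raise ValueError("levels must be positive")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(levels)) % (2**31)
    runs = []
    for level, run_seed in zip(levels, child_seeds):
        spec = RunSpec(
            species=(
                SpeciesSpec(peptide, "light", charge, endogenous_fmol, rt_min),
                SpeciesSpec(peptide, "heavy", charge, float(level), rt_min),
            ),
            seed=int(run_seed),
            noise_cv=cv,
            response_factor=response_factor,
        )
        runs.append((float(level), simulate_run(spec)))
    return runs


@dataclass(frozen=True)
class CohortGroup:
    """Concentration distribution of one analyte in one group (fmol/ml)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("mean must be positive and sd non-negative")


@dataclass(frozen=True)
class CohortAnalyte:
    """Group parameters plus the fingerprint peptide used to measure it."""

    healthy: CohortGroup
    tumour: CohortGroup
    peptide: str
    charge: int = 2
    rt_min: float = 20.0


# Serum concentration structure of the two model biomarkers: healthy means
# with across-measurement SDs, and tumour-patient means with SDs.
DEFAULT_ANALYTES: dict[str, CohortAnalyte] = {
    "DcR3": CohortAnalyte(
        healthy=CohortGroup(27.23, 9.47),
        tumour=CohortGroup(116.94, 57.37),
        peptide="LLQALR",
        charge=2,
        rt_min=18.0,
    ),
    "GDF15": CohortAnalyte(
        healthy=CohortGroup(98.11, 34.96),
        tumour=CohortGroup(164.44, 79.31),
        peptide="TDTGVSLQTYDDLLAK",
        charge=2,
        rt_min=24.0,
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated serum cohort."""

    seed: int
    analytes: dict[str, CohortAnalyte] = field(
        default_factory=lambda: dict(DEFAULT_ANALYTES)
    )
    n_healthy: int = 3
    n_tumour: int = 17
    noise_cv: float = 0.05
    spike_fmol: float = 50.0
    ledger: VolumeLedger = field(default_factory=VolumeLedger)
    response_factor: float = DEFAULT_RESPONSE_FACTOR

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_tumour < 0:
            raise ValueError("group sizes must be >= 0")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw resampled until positive (degenerate sd=0 → the mean)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError("truncated normal failed to produce a positive draw")


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, dict[tuple[str, str], SpectrumRun]]:
    """Draw a cohort and generate one run per (sample, analyte).

    Each sample's true concentration is drawn from its group's
    truncated-at-zero normal distribution; the analysed amount follows the
    volume ledger (``fmol = fmol/ml × effective ml``), so quantifying the
    runs against the spiked standard and dividing by the same ledger
    recovers the generated concentrations.  Analytes sit in separate
    chromatographic fractions, hence separate runs.

    Returns a tidy sample table (sample, group, analyte, true_fmol_per_ml)
    and a dict of runs keyed by ``(sample, analyte)``.
    """
    rng = np.random.default_rng(spec.seed)
    seed_stream = np.random.SeedSequence(spec.seed).generate_state(
        max((spec.n_healthy + spec.n_tumour) * max(len(spec.analytes), 1), 1), dtype=np.uint64
    ) % (2**31)

    rows = []
    runs: dict[tuple[str, str], SpectrumRun] = {}
    labels = [("H", i + 1, "healthy") for i in range(spec.n_healthy)] + [
        ("T", i + 1, "tumour") for i in range(spec.n_tumour)
    ]
    seed_idx = 0
    for prefix, i, group in labels:
        sample = f"{prefix}{i:02d}"
        for name, analyte in spec.analytes.items():
            params = analyte.healthy if group == "healthy" else analyte.tumour
            true_conc = _truncated_normal(rng, params.mean, params.sd)
            amount = true_conc * spec.ledger.effective_ml
            run_spec = RunSpec(
                species=(
                    SpeciesSpec(
                        analyte.peptide, "light", analyte.charge, amount, analyte.rt_min
                    ),
                    SpeciesSpec(
                        analyte.peptide,
                        "heavy",
                        analyte.charge,
                        spec.spike_fmol,
                        analyte.rt_min,
                    ),
                ),
                seed=int(seed_stream[seed_idx]),
                noise_cv=spec.noise_cv,
                response_factor=spec.response_factor,
            )
            seed_idx += 1
            runs[(sample, name)] = simulate_run(run_spec)
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "analyte": name,
                    "true_fmol_per_ml": true_conc,
                    "analysed_fmol": amount,
                }
            )
    return pd.DataFrame(rows), runs
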