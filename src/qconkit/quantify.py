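"""XIC extraction, peak integration and isotope-dilution quantification.

The measurement chain is:

    LC-MS run ──extract_xic──▶ XICTrace ──integrate_peak──▶ PeakArea
    light area / heavy area ──quantify_ratio──▶ analyte fmol
    analyte fmol ──serum_concentration──▶ fmol per ml serum

The internal standard is a known spike (default 50 fmol) of a ¹⁵N-labelled
peptide released from a QconCAT; because light and heavy co-elute, the heavy
trace also serves to centre the retention-time window when no expected RT is
configured.

Extracted ion chromatograms use a 0.3 Th full-width m/z window over a 4 min
retention-time window by default.  At those widths an XIC captures only the
monoisotopic peak of a peptide's isotope envelope, and a fully ¹⁵N-labelled
species concentrates a *larger* fraction of its signal in the mono peak than
its light counterpart (nitrogen drops out of the isotope convolution).
:func:`measure_pair` therefore normalises each area by the species'
monoisotopic-envelope fraction before ratioing; without this the ratio is
biased by P(all N = ¹⁴N), a few percent for a typical tryptic peptide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import isotopes
from .masses import (
    LabeledSpecies,
    Peptide,
    composition,
    mz as compute_mz,
)

__all__ = [
    "Scan",
    "SpectrumRun",
    "XICRequest",
    "XICTrace",
    "PeakArea",
    "VolumeLedger",
    "QuantMeasurement",
    "QuantificationError",
    "extract_xic",
    "integrate_peak",
    "quantify_ratio",
    "serum_concentration",
    "mass_to_molar",
    "molar_to_mass",
    "measure_pair",
]

PeakFlag = Literal["ok", "no-peak", "edge-clipped"]


class QuantificationError(RuntimeError):
    """Quantification failed for a peptide (e.g. heavy standard not found)."""


@dataclass(frozen=True)
class Scan:
    """One centroided MS1 scan: retention time (min) + peak arrays."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must have equal length")


@dataclass(frozen=True)
class SpectrumRun:
    """An ordered sequence of MS1 scans with strictly increasing RT."""

    scans: tuple[Scan, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def rt_range(self) -> tuple[float, float]:
        if not self.scans:
            return (0.0, 0.0)
        return (self.scans[0].rt, self.scans[-1].rt)

    @classmethod
    def from_mzml(cls, path: str | Path) -> "SpectrumRun":
        from .mzml_io import read_mzml

        return read_mzml(path)

    def to_mzml(self, path: str | Path) -> None:
        from .mzml_io import write_mzml

        write_mzml(self, path)


@dataclass(frozen=True)
class XICRequest:
    """m/z ± window/2 over rt_center ± rt_width/2.

    Widths are full widths: the default 0.3 Th mass range means ±0.15 Th.
    """

    target_mz: float
    rt_center: float
    mz_width: float = 0.3
    rt_width: float = 4.0

    def __post_init__(self) -> None:
        if self.mz_width <= 0 or self.rt_width <= 0:
            raise ValueError("windows must be positive")


@dataclass(frozen=True)
class XICTrace:
    """Summed intensity vs RT within an extraction window."""

    rt: np.ndarray
    intensity: np.ndarray
    request: XICRequest | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rt", np.asarray(self.rt, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity arrays must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.rt)


@dataclass(frozen=True)
class PeakArea:
    """Integrated, baseline-corrected area of the main peak in a trace."""

    apex_rt: float
    bounds: tuple[float, float]
    raw_area: float
    area: float
    flag: PeakFlag = "ok"

    @property
    def ok(self) -> bool:
        return self.flag != "no-peak"


@dataclass(frozen=True)
class VolumeLedger:
    """Serum volume and aliquot bookkeeping from tube to analysed sample.

    ``aliquot_fractions`` are the fractions of serum-derived material that
    reach the analysed sample at each processing step (each in (0, 1]); the
    default empty ledger assumes the analysed sample represents the whole
    0.1 ml serum draw.
    """

    serum_ml: float = 0.1
    aliquot_fractions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.serum_ml <= 0:
            raise ValueError("serum volume must be positive")
        if any(not 0 < f <= 1 for f in self.aliquot_fractions):
            raise ValueError("aliquot fractions must be in (0, 1]")

    @property
    def effective_ml(self) -> float:
        return self.serum_ml * math.prod(self.aliquot_fractions)


@dataclass(frozen=True)
class QuantMeasurement:
    """One light/heavy quantification of an analyte via one peptide."""

    analyte: str
    peptide: str
    charge: int
    light_area: float
    heavy_area: float
    ratio: float
    spike_fmol: float
    analyte_fmol: float
    concentration_fmol_per_ml: float
    flag: str = "ok"


def extract_xic(run: SpectrumRun, request: XICRequest) -> XICTrace:
    """Sum per-scan intensity within the m/z window, over the RT window.

    An RT window with no scans yields an empty trace (flagged downstream as
    no-peak rather than raising here).
    """
    if not run.scans:
        raise ValueError("run has no scans")
    half_mz = request.mz_width / 2.0
    half_rt = request.rt_width / 2.0
    rts, vals = [], []
    for scan in run.scans:
        if abs(scan.rt - request.rt_center) > half_rt:
            continue
        sel = np.abs(scan.mz - request.target_mz) <= half_mz
        rts.append(scan.rt)
        vals.append(float(scan.intensity[sel].sum()))
    return XICTrace(rt=np.array(rts), intensity=np.array(vals), request=request)


def integrate_peak(trace: XICTrace, snr_mads: float = 3.0) -> PeakArea:
    """Integrate the dominant peak of a trace.

    The apex is the global intensity maximum (ties → earliest RT).  Bounds
    extend outward from the apex until the intensity falls to or below a
    baseline threshold — the trace median plus ``snr_mads`` × the median
    absolute deviation — or the window edge (flagged "edge-clipped").  A
    linear baseline between the bound points is subtracted and the remainder
    integrated by the trapezoidal rule.  An apex at or below the threshold
    means no detectable peak: flag "no-peak", area 0.
    """
    y = trace.intensity
    if len(trace) < 2:
        return PeakArea(apex_rt=float("nan"), bounds=(0.0, 0.0), raw_area=0.0, area=0.0, flag="no-peak")
    apex = int(np.argmax(y))  # argmax returns the first maximum → earliest RT
    median = float(np.median(y))
    mad = float(np.median(np.abs(y - median)))
    threshold = median + snr_mads * mad
    if y[apex] <= threshold or y[apex] <= 0:
        return PeakArea(apex_rt=float(trace.rt[apex]), bounds=(0.0, 0.0), raw_area=0.0, area=0.0, flag="no-peak")

    # Stop descending at the noise threshold, or at 0.1% of peak height above
    # the baseline level: a smooth peak's tail approaches zero asymptotically
    # and would otherwise drag the bounds to the window edge.
    stop = max(threshold, median + 1e-3 * (float(y[apex]) - median))
    lo = apex
    while lo > 0 and y[lo] > stop:
        lo -= 1
    hi = apex
    while hi < len(y) - 1 and y[hi] > stop:
        hi += 1
    flag: PeakFlag = "ok"
    if (lo == 0 and y[lo] > stop) or (hi == len(y) - 1 and y[hi] > stop):
        flag = "edge-clipped"

    rt_seg = trace.rt[lo : hi + 1]
    y_seg = y[lo : hi + 1]
    raw = float(np.trapezoid(y_seg, rt_seg))
    baseline = np.interp(rt_seg, [rt_seg[0], rt_seg[-1]], [y_seg[0], y_seg[-1]])
    corrected = max(float(np.trapezoid(y_seg - baseline, rt_seg)), 0.0)
    return PeakArea(
        apex_rt=float(trace.rt[apex]),
        bounds=(float(rt_seg[0]), float(rt_seg[-1])),
        raw_area=raw,
        area=corrected,
        flag=flag,
    )


def quantify_ratio(light_area: float, heavy_area: float, spike_fmol: float) -> float:
    """Analyte amount from the light/heavy area ratio and the heavy spike.

    analyte fmol = spike × light/heavy.  Scale-invariant to detector gain.
    """
    if spike_fmol <= 0:
        raise ValueError("spike amount must be positive")
    if heavy_area <= 0:
        raise QuantificationError(
            "heavy internal-standard peak not found (area <= 0); "
            "cannot quantify this peptide"
        )
    return spike_fmol * light_area / heavy_area


def serum_concentration(analyte_fmol: float, ledger: VolumeLedger = VolumeLedger()) -> float:
    """fmol measured in the analysed sample → fmol per ml of original serum."""
    return analyte_fmol / ledger.effective_ml


def mass_to_molar(ng_per_ml: float, molar_mass_da: float) -> float:
    """ng/ml → fmol/ml at a given molar mass (fmol/ml = ng/ml / M × 10⁶)."""
    if molar_mass_da <= 0:
        raise ValueError("molar mass must be positive")
    return ng_per_ml / molar_mass_da * 1e6


def molar_to_mass(fmol_per_ml: float, molar_mass_da: float) -> float:
    """Exact inverse of :func:`mass_to_molar`."""
    if molar_mass_da <= 0:
        raise ValueError("molar mass must be positive")
    return fmol_per_ml * molar_mass_da / 1e6


def measure_pair(
    run: SpectrumRun,
    peptide: Peptide | str,
    charge: int,
    spike_fmol: float = 50.0,
    expected_rt: float | None = None,
    mz_width: float = 0.3,
    rt_width: float = 4.0,
    mass_kind: str = "monoisotopic",
    ledger: VolumeLedger = VolumeLedger(),
    analyte: str = "",
    envelope_correction: bool = True,
) -> QuantMeasurement:
    """Quantify one analyte peptide against its ¹⁵N-labelled standard.

    Extracts light and heavy XICs at the peptide's charge-state m/z values.
    If ``expected_rt`` is None the heavy standard's apex centres the RT
    window (the standard is always present and co-elutes with the analyte);
    the heavy apex is located on a whole-run trace first.

    With ``envelope_correction`` each area is divided by the species'
    monoisotopic-envelope fraction so that light and heavy areas are on the
    same total-amount scale before ratioing.
    """
    pep = peptide if isinstance(peptide, Peptide) else Peptide(sequence=peptide)
    light = LabeledSpecies(peptide=pep, label_state="light", charge=charge, mass_kind=mass_kind)
    heavy = LabeledSpecies(peptide=pep, label_state="heavy", charge=charge, mass_kind=mass_kind)

    if expected_rt is None:
        lo, hi = run.rt_range
        survey = XICRequest(
            target_mz=heavy.mz,
            rt_center=(lo + hi) / 2.0,
            mz_width=mz_width,
            rt_width=max(hi - lo, 1e-6) + 1.0,
        )
        survey_peak = integrate_peak(extract_xic(run, survey))
        if not survey_peak.ok:
            raise QuantificationError(
                f"heavy standard for {pep.sequence} (z={charge}) not detected in run"
            )
        expected_rt = survey_peak.apex_rt

    def _area(species: LabeledSpecies) -> PeakArea:
        req = XICRequest(
            target_mz=species.mz,
            rt_center=expected_rt,
            mz_width=mz_width,
            rt_width=rt_width,
        )
        return integrate_peak(extract_xic(run, req))

    light_peak = _area(light)
    heavy_peak = _area(heavy)

    comp = composition(pep)
    light_area = light_peak.area
    heavy_area = heavy_peak.area
    if envelope_correction:
        light_area /= isotopes.mono_fraction(comp, "light")
        heavy_area /= isotopes.mono_fraction(comp, "heavy")

    if not heavy_peak.ok or heavy_area <= 0:
        raise QuantificationError(
            f"heavy internal-standard peak for {pep.sequence} (z={charge}) not found"
        )

    flag = "ok"
    if not light_peak.ok:
        flag = "light-no-peak"
        light_area = 0.0
    elif light_peak.flag == "edge-clipped" or heavy_peak.flag == "edge-clipped":
        flag = "edge-clipped"

    amount = quantify_ratio(light_area, heavy_area, spike_fmol)
    return QuantMeasurement(
        analyte=analyte or pep.parent_id or pep.sequence,
        peptide=pep.sequence,
        charge=charge,
        light_area=light_area,
        heavy_area=heavy_area,
        ratio=light_area / heavy_area,
        spike_fmol=spike_fmol,
        analyte_fmol=amount,
        concentration_fmol_per_ml=serum_concentration(amount, ledger),
        flag=flag,
    )
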