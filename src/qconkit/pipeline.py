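"""End-to-end assay pipeline: configuration, per-run quantification, summary.

An :class:`AssayConfig` names the targets (protein, fingerprint peptides,
charges, expected retention times, chromatographic fraction), the heavy
spike amount, the volume ledger and the extraction tolerances.  Running the
pipeline quantifies every configured peptide in every run and aggregates to
a per-analyte summary (unweighted mean ± SD across peptides and replicate
runs, mirroring the use of several fingerprint peptides per protein).

Outputs are deterministic for a given config + inputs; the configuration
hash is recorded in every output table so results are traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .masses import digest, validate_sequence
from .quantify import (
    QuantificationError,
    QuantMeasurement,
    SpectrumRun,
    VolumeLedger,
    measure_pair,
)
from .stats import replicate_summary

__all__ = [
    "PeptideTarget",
    "AnalyteTarget",
    "AssayConfig",
    "PipelineResult",
    "run_pipeline",
]

log = logging.getLogger("qconkit")


@dataclass(frozen=True)
class PeptideTarget:
    sequence: str
    charge: int = 2
    mass_kind: str = "monoisotopic"
    expected_rt: float | None = None


@dataclass(frozen=True)
class AnalyteTarget:
    protein_id: str
    peptides: tuple[PeptideTarget, ...]
    protein_sequence: str | None = None
    fraction: int | None = None

    def validate(self) -> None:
        """Check each fingerprint peptide is a tryptic peptide of its protein."""
        for p in self.peptides:
            validate_sequence(p.sequence)
            if p.charge < 1:
                raise ValueError(f"charge must be >= 1 for {p.sequence}")
        if self.protein_sequence:
            tryptic = {
                pep.sequence for pep in digest(self.protein_sequence, 1)
            }
            for p in self.peptides:
                if p.sequence not in tryptic:
                    raise ValueError(
                        f"{p.sequence} is not a tryptic peptide (<=1 missed "
                        f"cleavage) of {self.protein_id}"
                    )


@dataclass(frozen=True)
class AssayConfig:
    """Assay-level configuration with workflow-standard defaults.

    Defaults: 50 fmol heavy spike, 0.3 Th XIC m/z width, 4 min RT window,
    0.3 Da PMF tolerance, 0.1 ml serum with no aliquot losses.
    """

    targets: tuple[AnalyteTarget, ...]
    spike_fmol: float = 50.0
    ledger: VolumeLedger = field(default_factory=VolumeLedger)
    xic_mz_width: float = 0.3
    rt_width: float = 4.0
    pmf_tolerance: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spike_fmol <= 0:
            raise ValueError("spike amount must be positive")
        for t in self.targets:
            t.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssayConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AssayConfig":
        targets = tuple(
            AnalyteTarget(
                protein_id=t["protein_id"],
                protein_sequence=t.get("protein_sequence"),
                fraction=t.get("fraction"),
                peptides=tuple(
                    PeptideTarget(
                        sequence=p["sequence"],
                        charge=int(p.get("charge", 2)),
                        mass_kind=p.get("mass_kind", "monoisotopic"),
                        expected_rt=p.get("expected_rt"),
                    )
                    for p in t["peptides"]
                ),
            )
            for t in raw["targets"]
        )
        ledger_raw = raw.get("ledger", {})
        tol = raw.get("tolerances", {})
        return cls(
            targets=targets,
            spike_fmol=float(raw.get("spike_fmol", 50.0)),
            ledger=VolumeLedger(
                serum_ml=float(ledger_raw.get("serum_ml", 0.1)),
                aliquot_fractions=tuple(ledger_raw.get("aliquot_fractions", ())),
            ),
            xic_mz_width=float(tol.get("xic_mz_width", 0.3)),
            rt_width=float(tol.get("rt_width", 4.0)),
            pmf_tolerance=float(tol.get("pmf_tolerance", 0.3)),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "targets": [
                {
                    "protein_id": t.protein_id,
                    "protein_sequence": t.protein_sequence,
                    "fraction": t.fraction,
                    "peptides": [
                        {
                            "sequence": p.sequence,
                            "charge": p.charge,
                            "mass_kind": p.mass_kind,
                            "expected_rt": p.expected_rt,
                        }
                        for p in t.peptides
                    ],
                }
                for t in self.targets
            ],
            "spike_fmol": self.spike_fmol,
            "ledger": {
                "serum_ml": self.ledger.serum_ml,
                "aliquot_fractions": list(self.ledger.aliquot_fractions),
            },
            "tolerances": {
                "xic_mz_width": self.xic_mz_width,
                "rt_width": self.rt_width,
                "pmf_tolerance": self.pmf_tolerance,
            },
            "seed": self.seed,
        }

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PipelineResult:
    measurements: pd.DataFrame  # one row per run × analyte × peptide
    summary: pd.DataFrame       # one row per analyte
    config_hash: str

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(out / "measurements.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained by the caller."""


def run_pipeline(
    config: AssayConfig, runs: Sequence[tuple[str, SpectrumRun]]
) -> PipelineResult:
    """Quantify every configured peptide in every run and summarise.

    ``runs`` is a sequence of ``(run_id, SpectrumRun)``.  Failed
    quantifications (e.g. missing heavy standard) are reported as flagged
    rows with NaN amounts, never silently dropped.
    """
    if not runs:
        raise PipelineError("no input runs (validation)")
    rows = []
    for run_id, run in runs:
        for target in config.targets:
            for pep in target.peptides:
                base = {
                    "run": run_id,
                    "analyte": target.protein_id,
                    "peptide": pep.sequence,
                    "charge": pep.charge,
                    "config_hash": config.config_hash,
                }
                try:
                    m = measure_pair(
                        run,
                        pep.sequence,
                        pep.charge,
                        spike_fmol=config.spike_fmol,
                        expected_rt=pep.expected_rt,
                        mz_width=config.xic_mz_width,
                        rt_width=config.rt_width,
                        mass_kind=pep.mass_kind,
                        ledger=config.ledger,
                        analyte=target.protein_id,
                    )
                except QuantificationError as exc:
                    log.warning("quantification failed: %s", exc)
                    rows.append(
                        {
                            **base,
                            "light_area": float("nan"),
                            "heavy_area": float("nan"),
                            "ratio": float("nan"),
                            "analyte_fmol": float("nan"),
                            "fmol_per_ml": float("nan"),
                            "flag": "failed",
                        }
                    )
                    continue
                rows.append(
                    {
                        **base,
                        "light_area": m.light_area,
                        "heavy_area": m.heavy_area,
                        "ratio": m.ratio,
                        "analyte_fmol": m.analyte_fmol,
                        "fmol_per_ml": m.concentration_fmol_per_ml,
                        "flag": m.flag,
                    }
                )
    measurements = pd.DataFrame(rows)

    summary_rows = []
    for analyte, grp in measurements.groupby("analyte", sort=True):
        ok = grp[grp["flag"] != "failed"]["fmol_per_ml"].dropna()
        if len(ok) == 0:
            summary_rows.append(
                {
                    "analyte": analyte,
                    "n": 0,
                    "mean_fmol_per_ml": float("nan"),
                    "sd_fmol_per_ml": float("nan"),
                    "cv_percent": float("nan"),
                    "config_hash": config.config_hash,
                }
            )
            continue
        s = replicate_summary(ok.tolist())
        summary_rows.append(
            {
                "analyte": analyte,
                "n": s.n,
                "mean_fmol_per_ml": s.mean,
                "sd_fmol_per_ml": s.sd,
                "cv_percent": s.cv_percent,
                "config_hash": config.config_hash,
            }
        )
    summary = pd.DataFrame(summary_rows)
    return PipelineResult(
        measurements=measurements, summary=summary, config_hash=config.config_hash
    )
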