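"""Peptide-mass-fingerprint (PMF) identification.

Matches an observed list of singly-protonated monoisotopic peptide masses
(MALDI-TOF convention) against the theoretical tryptic digest of a candidate
protein within a mass tolerance, and reports the sequence coverage of the
matched peptides.  This is deliberately plain tolerance matching plus
coverage — no probabilistic search-engine scoring — because coverage percent
and match count are the quantities the workflow actually consumes.

Assignment is greedy per observed mass (closest theoretical wins), which is
adequate on the sparse mass lists of a purified fraction at a 0.3 Da
tolerance; it is not a globally optimal bipartite matching.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .masses import (
    MODIFICATIONS,
    PROTON_MASS,
    Peptide,
    apply_modification,
    digest,
    peptide_mass,
)

__all__ = ["MassList", "PeptideMatch", "PMFResult", "match_masses", "coverage"]

# Cap on simultaneous variable modifications per peptide: keeps the
# theoretical list from exploding combinatorially on Met/Tyr-rich peptides.
MAX_VARIABLE_MODS = 3


@dataclass(frozen=True)
class MassList:
    """Observed [M+H]+ monoisotopic masses, sorted ascending."""

    masses: tuple[float, ...]
    intensities: tuple[float, ...] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.masses):
            raise ValueError("observed masses must be positive")
        order = sorted(range(len(self.masses)), key=lambda i: self.masses[i])
        object.__setattr__(self, "masses", tuple(self.masses[i] for i in order))
        if self.intensities is not None:
            if len(self.intensities) != len(self.masses):
                raise ValueError("intensities must match masses in length")
            object.__setattr__(
                self, "intensities", tuple(self.intensities[i] for i in order)
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "MassList":
        """Load one-mass-per-line text, or CSV rows of ``mass[,intensity]``."""
        path = Path(path)
        masses: list[float] = []
        intensities: list[float] = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().startswith("#"):
                    continue
                try:
                    masses.append(float(row[0]))
                except ValueError:
                    continue  # header line
                if len(row) > 1 and row[1].strip():
                    intensities.append(float(row[1]))
        return cls(
            masses=tuple(masses),
            intensities=tuple(intensities) if len(intensities) == len(masses) else None,
            source=str(path),
        )


@dataclass(frozen=True)
class PeptideMatch:
    observed_mass: float
    theoretical_mass: float
    peptide: Peptide

    @property
    def delta(self) -> float:
        return self.observed_mass - self.theoretical_mass


@dataclass(frozen=True)
class PMFResult:
    protein_id: str
    protein_length: int
    matches: tuple[PeptideMatch, ...]
    tolerance: float

    @property
    def match_count(self) -> int:
        return len(self.matches)

    @property
    def coverage_percent(self) -> float:
        return coverage(self)

    def span_table(self) -> list[dict]:
        """BED-like rows (protein, start, end, peptide) for the matched spans."""
        return [
            {
                "protein": self.protein_id,
                "start": m.peptide.start,
                "end": m.peptide.end,
                "peptide": m.peptide.sequence,
            }
            for m in self.matches
        ]


def _theoretical_species(
    protein: str, protein_id: str, max_missed: int, variable_mods: Sequence[str]
) -> list[tuple[float, Peptide]]:
    """Enumerate (theoretical [M+H]+, peptide) over digest × modification combos."""
    species: list[tuple[float, Peptide]] = []
    for pep in digest(protein, max_missed, parent_id=protein_id):
        sites: list[tuple[str, int]] = []
        for name in variable_mods:
            target = MODIFICATIONS[name][0]
            sites.extend(
                (name, i + 1) for i, aa in enumerate(pep.sequence) if aa == target
            )
        for k in range(0, min(len(sites), MAX_VARIABLE_MODS) + 1):
            for combo in itertools.combinations(sites, k):
                modified = pep
                for name, site in combo:
                    modified = apply_modification(modified, name, site)
                species.append(
                    (peptide_mass(modified, "monoisotopic") + PROTON_MASS, modified)
                )
    return species


def match_masses(
    mass_list: MassList,
    protein: str,
    protein_id: str = "",
    tolerance: float = 0.3,
    max_missed: int = 1,
    variable_mods: Sequence[str] = ("nitro", "oxidation"),
) -> PMFResult:
    """Match observed [M+H]+ masses to a protein's theoretical digest.

    Each observed mass is assigned to at most one theoretical peptide: the
    closest within ``tolerance``; ties broken by fewer modifications, then
    fewer missed cleavages, then the N-terminal-most peptide.  The result is
    invariant under permutation of the observed list.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    theoretical = _theoretical_species(protein, protein_id, max_missed, variable_mods)
    matches: list[PeptideMatch] = []
    for obs in mass_list.masses:
        best: tuple | None = None
        for theo_mass, pep in theoretical:
            delta = abs(obs - theo_mass)
            if delta > tolerance:
                continue
            key = (delta, len(pep.modifications), pep.missed_cleavages, pep.start)
            if best is None or key < best[0]:
                best = (key, theo_mass, pep)
        if best is not None:
            matches.append(
                PeptideMatch(observed_mass=obs, theoretical_mass=best[1], peptide=best[2])
            )
    return PMFResult(
        protein_id=protein_id,
        protein_length=len(protein),
        matches=tuple(matches),
        tolerance=tolerance,
    )


def coverage(result: PMFResult) -> float:
    """Sequence coverage: % of protein residues under the union of matches.

    Overlapping matched peptides count each residue once.
    """
    if result.protein_length == 0:
        return 0.0
    covered: set[int] = set()
    for m in result.matches:
        covered.update(range(m.peptide.start, m.peptide.end + 1))
    return 100.0 * len(covered) / result.protein_length
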