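"""Amino-acid chemistry for stable-isotope peptide quantification.

Residue mass tables, in-silico tryptic digestion, nitrogen accounting for
¹⁵N metabolic labelling, variable modifications, and charge-state m/z
bookkeeping.  Everything downstream (candidate design, PMF identification,
XIC quantification, the simulator) is built on these primitives.

Conventions
-----------
* Peptide coordinates are 1-based and inclusive, matching how positions in
  a protein sequence are reported.
* Neutral masses are in daltons (Da); m/z in thomsons (Th).
* A "heavy" species has every nitrogen atom replaced by ¹⁵N (metabolic
  labelling on a ¹⁵N-only nitrogen source), shifting the neutral mass by
  ``nitrogen_count × 0.997035`` Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

__all__ = [
    "PROTON_MASS",
    "WATER_MONO",
    "WATER_AVG",
    "N15_SHIFT",
    "MODIFICATIONS",
    "InvalidSequenceError",
    "UnknownModificationError",
    "ResidueTable",
    "Modification",
    "Peptide",
    "LabeledSpecies",
    "digest",
    "cleavage_sites",
    "peptide_mass",
    "nitrogen_count",
    "heavy_mass",
    "mz",
    "apply_modification",
]

# Fixed to ≥6 decimals so that derived masses are bit-stable across platforms.
PROTON_MASS = 1.007276   # Da, mass of H+
WATER_MONO = 18.010565   # Da, monoisotopic H2O added on hydrolysis
WATER_AVG = 18.01528     # Da, average H2O
N15_SHIFT = 0.997035     # Da, m(15N) - m(14N)

MassKind = Literal["monoisotopic", "average"]
LabelState = Literal["light", "heavy"]


class InvalidSequenceError(ValueError):
    """A sequence contains a letter outside the 20 standard amino acids."""


class UnknownModificationError(KeyError):
    """A modification name is not in the modification registry."""


# Variable modifications used for peptide-mass-fingerprint searches:
# name -> (target residue, delta mass Da).
MODIFICATIONS: dict[str, tuple[str, float]] = {
    "oxidation": ("M", 15.994915),
    "nitro": ("Y", 44.985078),
}


# residue letter -> (monoisotopic mass, average mass, {element: count})
# Residue (i.e. water-free) formulas of the 20 standard amino acids.
_RESIDUE_DATA: dict[str, tuple[float, float, dict[str, int]]] = {
    "G": (57.02146, 57.0519, {"C": 2, "H": 3, "N": 1, "O": 1}),
    "A": (71.03711, 71.0788, {"C": 3, "H": 5, "N": 1, "O": 1}),
    "S": (87.03203, 87.0782, {"C": 3, "H": 5, "N": 1, "O": 2}),
    "P": (97.05276, 97.1167, {"C": 5, "H": 7, "N": 1, "O": 1}),
    "V": (99.06841, 99.1326, {"C": 5, "H": 9, "N": 1, "O": 1}),
    "T": (101.04768, 101.1051, {"C": 4, "H": 7, "N": 1, "O": 2}),
    "C": (103.00919, 103.1388, {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1}),
    "L": (113.08406, 113.1594, {"C": 6, "H": 11, "N": 1, "O": 1}),
    "I": (113.08406, 113.1594, {"C": 6, "H": 11, "N": 1, "O": 1}),
    "N": (114.04293, 114.1038, {"C": 4, "H": 6, "N": 2, "O": 2}),
    "D": (115.02694, 115.0886, {"C": 4, "H": 5, "N": 1, "O": 3}),
    "Q": (128.05858, 128.1307, {"C": 5, "H": 8, "N": 2, "O": 2}),
    "K": (128.09496, 128.1741, {"C": 6, "H": 12, "N": 2, "O": 1}),
    "E": (129.04259, 129.1155, {"C": 5, "H": 7, "N": 1, "O": 3}),
    "M": (131.04049, 131.1926, {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1}),
    "H": (137.05891, 137.1411, {"C": 6, "H": 7, "N": 3, "O": 1}),
    "F": (147.06841, 147.1766, {"C": 9, "H": 9, "N": 1, "O": 1}),
    "R": (156.10111, 156.1875, {"C": 6, "H": 12, "N": 4, "O": 1}),
    "Y": (163.06333, 163.1760, {"C": 9, "H": 9, "N": 1, "O": 2}),
    "W": (186.07931, 186.2132, {"C": 11, "H": 10, "N": 2, "O": 1}),
}


@dataclass(frozen=True)
class ResidueTable:
    """Per-residue masses and elemental compositions.

    The default table covers the 20 standard amino acids.  A custom table
    (e.g. for audit, or with alkylated cysteine) can be built with
    :meth:`with_overrides` or loaded from a mapping via :meth:`from_dict`;
    :meth:`to_dict` dumps the table for inspection.
    """

    data: Mapping[str, tuple[float, float, Mapping[str, int]]] = field(
        default_factory=lambda: dict(_RESIDUE_DATA)
    )

    def __post_init__(self) -> None:
        for aa, (mono, avg, comp) in self.data.items():
            if comp.get("N", 0) < 1:
                raise ValueError(f"residue {aa!r} must contain nitrogen")
            if not mono < avg:
                raise ValueError(f"residue {aa!r}: mono mass must be < average mass")

    def __contains__(self, aa: str) -> bool:
        return aa in self.data

    def mono(self, aa: str) -> float:
        return self._entry(aa)[0]

    def average(self, aa: str) -> float:
        return self._entry(aa)[1]

    def mass(self, aa: str, kind: MassKind) -> float:
        entry = self._entry(aa)
        return entry[0] if kind == "monoisotopic" else entry[1]

    def nitrogen(self, aa: str) -> int:
        return int(self._entry(aa)[2].get("N", 0))

    def composition(self, aa: str) -> dict[str, int]:
        return dict(self._entry(aa)[2])

    def _entry(self, aa: str):
        try:
            return self.data[aa]
        except KeyError:
            raise InvalidSequenceError(f"unknown residue {aa!r}") from None

    def with_overrides(
        self, overrides: Mapping[str, tuple[float, float, Mapping[str, int]]]
    ) -> "ResidueTable":
        merged = dict(self.data)
        merged.update(overrides)
        return ResidueTable(merged)

    def to_dict(self) -> dict[str, dict]:
        return {
            aa: {"monoisotopic": m, "average": a, "composition": dict(c)}
            for aa, (m, a, c) in sorted(self.data.items())
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping]) -> "ResidueTable":
        return cls(
            {
                aa: (e["monoisotopic"], e["average"], dict(e["composition"]))
                for aa, e in d.items()
            }
        )


DEFAULT_TABLE = ResidueTable()


def validate_sequence(sequence: str, table: ResidueTable = DEFAULT_TABLE) -> str:
    """Return the sequence unchanged, or raise naming the first bad position.

    Nonstandard letters (B, Z, X, U, ...) are rejected rather than guessed:
    a silently wrong mass is worse than a hard failure.
    """
    for i, aa in enumerate(sequence, start=1):
        if aa not in table:
            raise InvalidSequenceError(
                f"non-standard residue {aa!r} at position {i} of {sequence!r}"
            )
    return sequence


@dataclass(frozen=True)
class Modification:
    """A named mass modification placed on one residue of a peptide.

    ``site`` is 1-based within the peptide.
    """

    name: str
    site: int
    delta: float


@dataclass(frozen=True)
class Peptide:
    """A tryptic fragment with coordinates in its parent protein.

    ``start``/``end`` are 1-based inclusive positions in the parent;
    ``missed_cleavages`` counts internal uncleaved K/R sites (K·P-blocked
    sites are not cleavage sites and therefore do not count).
    """

    sequence: str
    parent_id: str = ""
    start: int = 1
    end: int = 0
    missed_cleavages: int = 0
    modifications: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        end = self.end if self.end else self.start + len(self.sequence) - 1
        object.__setattr__(self, "end", end)
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"span [{self.start}, {self.end}] does not match length "
                f"{len(self.sequence)} of {self.sequence!r}"
            )
        for mod in self.modifications:
            if not 1 <= mod.site <= len(self.sequence):
                raise ValueError(f"modification site {mod.site} outside peptide")
            target = MODIFICATIONS.get(mod.name, (None,))[0]
            if target is not None and self.sequence[mod.site - 1] != target:
                raise ValueError(
                    f"modification {mod.name!r} targets {target}, but site "
                    f"{mod.site} is {self.sequence[mod.site - 1]!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _coerce(peptide: "Peptide | str") -> Peptide:
    return peptide if isinstance(peptide, Peptide) else Peptide(sequence=validate_sequence(peptide))


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1.

    Trypsin cleaves C-terminal to K or R, except when the following residue
    is proline (the K·P / R·P rule).  The C-terminus of the protein is not a
    site.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    parent_sequence: str,
    max_missed_cleavages: int = 0,
    parent_id: str = "",
    table: ResidueTable = DEFAULT_TABLE,
) -> list[Peptide]:
    """In-silico tryptic digestion.

    Returns every fragment with 0..``max_missed_cleavages`` internal missed
    sites, ordered by start position then by missed-cleavage count.  The
    0-missed-cleavage fragments tile the parent exactly.
    """
    validate_sequence(parent_sequence, table)
    if not parent_sequence:
        raise InvalidSequenceError("empty sequence")
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")

    cuts = [-1] + cleavage_sites(parent_sequence) + [len(parent_sequence) - 1]
    peptides: list[Peptide] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + max_missed_cleavages, len(cuts))):
            start, end = cuts[a] + 1, cuts[b]  # 0-based inclusive
            peptides.append(
                Peptide(
                    sequence=parent_sequence[start : end + 1],
                    parent_id=parent_id,
                    start=start + 1,
                    end=end + 1,
                    missed_cleavages=b - a - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def peptide_mass(
    peptide: Peptide | str,
    mass_kind: MassKind = "monoisotopic",
    table: ResidueTable = DEFAULT_TABLE,
) -> float:
    """Neutral peptide mass: residue masses + water + modification deltas.

    An empty chain returns the mass of water.
    """
    if isinstance(peptide, str):
        validate_sequence(peptide, table)
        seq, mods = peptide, ()
    else:
        seq, mods = peptide.sequence, peptide.modifications
    water = WATER_MONO if mass_kind == "monoisotopic" else WATER_AVG
    total = water + sum(table.mass(aa, mass_kind) for aa in seq)
    total += sum(m.delta for m in mods)
    return total


def nitrogen_count(peptide: Peptide | str, table: ResidueTable = DEFAULT_TABLE) -> int:
    """Total nitrogen atoms (backbone + side chains) in the peptide."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else validate_sequence(peptide, table)
    return sum(table.nitrogen(aa) for aa in seq)


def composition(peptide: Peptide | str, table: ResidueTable = DEFAULT_TABLE) -> dict[str, int]:
    """Elemental composition of the neutral peptide (residues + H2O)."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else validate_sequence(peptide, table)
    comp: dict[str, int] = {"H": 2, "O": 1}
    for aa in seq:
        for el, n in table.composition(aa).items():
            comp[el] = comp.get(el, 0) + n
    return comp


def heavy_mass(
    peptide: Peptide | str,
    mass_kind: MassKind = "monoisotopic",
    table: ResidueTable = DEFAULT_TABLE,
) -> float:
    """Neutral mass of the fully ¹⁵N-labelled peptide.

    light mass + N × 0.997035 Da.  The same per-atom shift is used for the
    average kind; the approximation is far below the 0.3 Da tolerances used
    throughout.
    """
    return peptide_mass(peptide, mass_kind, table) + nitrogen_count(peptide, table) * N15_SHIFT


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of [M + z·H]^z+ : (M + z × 1.007276) / z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def apply_modification(peptide: Peptide | str, mod_name: str, site: int) -> Peptide:
    """Return a copy of the peptide with a variable modification recorded.

    ``site`` is 1-based within the peptide; the residue at the site must be
    the modification's target (M for oxidation, Y for nitro).
    """
    pep = _coerce(peptide)
    try:
        target, delta = MODIFICATIONS[mod_name]
    except KeyError:
        raise UnknownModificationError(
            f"unknown modification {mod_name!r}; known: {sorted(MODIFICATIONS)}"
        ) from None
    if not 1 <= site <= len(pep):
        raise ValueError(f"site {site} outside peptide of length {len(pep)}")
    if pep.sequence[site - 1] != target:
        raise ValueError(
            f"{mod_name} targets {target}, but residue at site {site} is "
            f"{pep.sequence[site - 1]!r}"
        )
    return replace(
        pep, modifications=pep.modifications + (Modification(mod_name, site, delta),)
    )


@dataclass(frozen=True)
class LabeledSpecies:
    """A peptide in a label state and charge, with its neutral mass and m/z."""

    peptide: Peptide
    label_state: LabelState
    charge: int
    mass_kind: MassKind = "monoisotopic"
    neutral_mass: float = field(init=False, default=0.0)
    mz: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.label_state == "light":
            m = peptide_mass(self.peptide, self.mass_kind)
        else:
            m = heavy_mass(self.peptide, self.mass_kind)
        object.__setattr__(self, "neutral_mass", m)
        object.__setattr__(self, "mz", mz(m, self.charge))

    @property
    def nitrogen_count(self) -> int:
        return nitrogen_count(self.peptide)
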