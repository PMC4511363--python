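"""Fingerprint-peptide selection and QconCAT assembly.

A QconCAT is an artificial protein concatenating tryptic "fingerprint"
peptides from one or more target proteins (plus an optional affinity tag).
Trypsin digestion releases each peptide in a strict 1:1 molar ratio to the
concatamer, so a known spike of the ¹⁵N-labelled concatamer yields a known
amount of every heavy internal-standard peptide.

Candidate evaluation applies the usual proteotypic-peptide heuristics as
*scored preferences*, not hard filters: a short peptide such as LLQALR can
still be a perfectly serviceable fingerprint, it just scores lower.  The
uniqueness screen is cleavage-context aware — a background protein that
contains the peptide's sequence only counts as a true conflict if trypsin
could actually liberate the peptide there (residue immediately N-terminal to
the hit is K or R, or the hit starts the protein).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .masses import (
    Peptide,
    digest,
    heavy_mass,
    nitrogen_count,
    peptide_mass,
    validate_sequence,
)

__all__ = [
    "DesignRules",
    "CandidateReport",
    "UniquenessResult",
    "QconCATDesign",
    "AssemblyError",
    "evaluate_candidates",
    "rank_candidates",
    "uniqueness_screen",
    "assemble_qconcat",
    "ug_to_pmol",
    "pmol_to_ug",
    "labelling_efficiency_correction",
]

Verdict = Literal["unique", "shared-sequence-but-context-unique", "shared"]


class AssemblyError(ValueError):
    """A peptide cannot be quantitatively released from the concatamer."""


@dataclass(frozen=True)
class DesignRules:
    """Preferences for fingerprint-peptide candidates.

    min_length/max_length
        Preferred tryptic peptide length (default 8–15 aa, short enough to
        keep the charge-state distribution narrow, long enough for
        specificity).
    forbid_proline_context
        Penalise peptides whose release requires cleaving next to a proline
        (P immediately C-terminal to a K/R site blocks trypsin).
    forbid_adjacent_basic
        Penalise adjacent basic residues (KK/KR/RK/RR) inside the peptide or
        straddling its boundaries; ragged cleavage around such sites makes
        release less quantitative.
    require_unique
        Whether uniqueness against a background proteome is part of the
        score.
    """

    min_length: int = 8
    max_length: int = 15
    forbid_proline_context: bool = True
    forbid_adjacent_basic: bool = True
    require_unique: bool = True

    def __post_init__(self) -> None:
        if self.min_length <= 0 or self.max_length <= 0:
            raise ValueError("length bounds must be positive")
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")


@dataclass(frozen=True)
class UniquenessResult:
    verdict: Verdict
    conflicts: tuple[str, ...] = ()       # proteins where trypsin could liberate the hit
    context_hits: tuple[str, ...] = ()    # sequence present but not liberable


@dataclass(frozen=True)
class CandidateReport:
    peptide: Peptide
    length_ok: bool
    no_proline_context: bool
    no_adjacent_basic: bool
    uniqueness: UniquenessResult | None = None

    @property
    def n_rules_passed(self) -> int:
        score = int(self.length_ok) + int(self.no_proline_context) + int(self.no_adjacent_basic)
        if self.uniqueness is not None:
            score += int(self.uniqueness.verdict != "shared")
        return score


def _adjacent_basic(parent: str, start0: int, end0: int) -> bool:
    """KK/KR/RK/RR inside [start0, end0] or straddling its boundaries."""
    lo = max(start0 - 1, 0)
    hi = min(end0 + 1, len(parent) - 1)
    window = parent[lo : hi + 1]
    return any(a in "KR" and b in "KR" for a, b in zip(window, window[1:]))


def _proline_context(parent: str, start0: int, end0: int) -> bool:
    """True if release of [start0, end0] involves a K/R·P junction.

    Either the fragment contains an internal K/R followed by P (a blocked
    site trypsin cannot cut, so the fragment is stuck carrying it), or the
    fragment itself starts with P right after a K/R.
    """
    seq = parent[start0 : end0 + 1]
    for i in range(len(seq) - 1):
        if seq[i] in "KR" and seq[i + 1] == "P":
            return True
    if seq.startswith("P") and start0 > 0 and parent[start0 - 1] in "KR":
        return True
    return False


def evaluate_candidates(
    protein_sequence: str,
    rules: DesignRules = DesignRules(),
    background: Sequence[tuple[str, str]] | None = None,
    parent_id: str = "",
) -> list[CandidateReport]:
    """Score every 0-missed-cleavage tryptic peptide of a protein.

    Returns one report per peptide in parent order.  Rules are evaluated
    independently; failing one does not remove the candidate.  If a
    ``background`` proteome (list of ``(identifier, sequence)``) is given and
    ``rules.require_unique`` is set, each candidate is screened for
    cleavage-context uniqueness.
    """
    validate_sequence(protein_sequence)
    if not protein_sequence:
        return []
    reports = []
    for pep in digest(protein_sequence, 0, parent_id=parent_id):
        start0, end0 = pep.start - 1, pep.end - 1
        uniq = None
        if background is not None and rules.require_unique:
            uniq = uniqueness_screen(pep.sequence, background, exclude=parent_id)
        reports.append(
            CandidateReport(
                peptide=pep,
                length_ok=rules.min_length <= len(pep) <= rules.max_length,
                no_proline_context=not (
                    rules.forbid_proline_context
                    and _proline_context(protein_sequence, start0, end0)
                ),
                no_adjacent_basic=not (
                    rules.forbid_adjacent_basic
                    and _adjacent_basic(protein_sequence, start0, end0)
                ),
                uniqueness=uniq,
            )
        )
    return reports


def rank_candidates(reports: Iterable[CandidateReport]) -> list[CandidateReport]:
    """Best-first ordering: most rules satisfied, ties by parent position."""
    return sorted(reports, key=lambda r: (-r.n_rules_passed, r.peptide.start))


def uniqueness_screen(
    peptide_sequence: str,
    background: Sequence[tuple[str, str]],
    exclude: str | None = None,
) -> UniquenessResult:
    """Screen a peptide against a background proteome, trypsin-aware.

    An exact subsequence hit in a background protein is a true conflict only
    if the residue immediately N-terminal to the hit is K or R, or the hit
    starts the protein (mature N-terminus — counted as liberable, erring
    toward declaring conflicts).  Otherwise trypsin cannot liberate that copy
    and the peptide remains quantitatively specific.  Matching is
    sequence-exact (no I/L equivalence).

    The verdict is invariant under background record order (identifier lists
    are sorted).
    """
    validate_sequence(peptide_sequence)
    conflicts: set[str] = set()
    context_only: set[str] = set()
    for ident, seq in background:
        if exclude is not None and ident == exclude:
            continue
        pos = seq.find(peptide_sequence)
        liberable = False
        found = pos >= 0
        while pos >= 0:
            if pos == 0 or seq[pos - 1] in "KR":
                liberable = True
                break
            pos = seq.find(peptide_sequence, pos + 1)
        if liberable:
            conflicts.add(ident)
        elif found:
            context_only.add(ident)
    if conflicts:
        verdict: Verdict = "shared"
    elif context_only:
        verdict = "shared-sequence-but-context-unique"
    else:
        verdict = "unique"
    return UniquenessResult(
        verdict=verdict,
        conflicts=tuple(sorted(conflicts)),
        context_hits=tuple(sorted(context_only)),
    )


@dataclass(frozen=True)
class QconCATDesign:
    """An ordered concatamer of fingerprint peptides plus an optional tag.

    Digesting the concatamer with 0 missed cleavages releases every design
    peptide; each concatamer molecule yields exactly one copy of each
    peptide (1:1 stoichiometry), which is what makes the spiked amount of a
    labelled concatamer a known amount of every internal-standard peptide.
    """

    peptides: tuple[Peptide, ...]
    tag_sequence: str = ""
    sequence: str = field(init=False, default="")
    molar_mass: float = field(init=False, default=0.0)
    release_stoichiometry: int = 1

    def __post_init__(self) -> None:
        seq = "".join(p.sequence for p in self.peptides) + self.tag_sequence
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "molar_mass", peptide_mass(seq, "average"))

    def peptide_table(self) -> list[dict]:
        """Sidecar rows: order, sequence, nitrogen count, light/heavy masses."""
        return [
            {
                "order": i + 1,
                "sequence": p.sequence,
                "parent_id": p.parent_id,
                "nitrogen_count": nitrogen_count(p),
                "light_mono_mass": peptide_mass(p, "monoisotopic"),
                "heavy_mono_mass": heavy_mass(p, "monoisotopic"),
            }
            for i, p in enumerate(self.peptides)
        ]


def assemble_qconcat(
    peptides: Sequence[Peptide | str], tag_sequence: str = ""
) -> QconCATDesign:
    """Concatenate fingerprint peptides (in order) into a QconCAT.

    Every peptide must end in K or R and must not begin with P, otherwise
    trypsin cannot release it from its neighbours; assembly verifies release
    by digesting the concatamer.
    """
    peps = tuple(p if isinstance(p, Peptide) else Peptide(sequence=p) for p in peptides)
    if not peps:
        raise AssemblyError("no peptides to assemble")
    for p in peps:
        if p.sequence[-1] not in "KR":
            raise AssemblyError(
                f"peptide {p.sequence!r} does not end in K/R; release not guaranteed"
            )
        if p.sequence.startswith("P"):
            raise AssemblyError(
                f"peptide {p.sequence!r} begins with P; the preceding cleavage "
                "site would be blocked"
            )
    design = QconCATDesign(peptides=peps, tag_sequence=tag_sequence)
    released = {f.sequence for f in digest(design.sequence, 0)}
    missing = [p.sequence for p in peps if p.sequence not in released]
    if missing:  # unreachable given the checks above; kept as a guard
        raise AssemblyError(f"digestion does not release: {missing}")
    return design


def ug_to_pmol(micrograms: float, molar_mass_da: float) -> float:
    """Convert a protein mass amount to a molar amount.

    pmol = μg / M(Da) × 10⁶  (e.g. 5.8 μg of a 58.5 kDa concatamer ≈ 99 pmol).
    """
    if molar_mass_da <= 0:
        raise ValueError("molar mass must be positive")
    return micrograms / molar_mass_da * 1e6


def pmol_to_ug(picomoles: float, molar_mass_da: float) -> float:
    """Exact inverse of :func:`ug_to_pmol`."""
    if molar_mass_da <= 0:
        raise ValueError("molar mass must be positive")
    return picomoles * molar_mass_da / 1e6


@dataclass(frozen=True)
class CorrectedRatio:
    ratio: float
    flagged: bool = False


def labelling_efficiency_correction(
    light_area: float, heavy_area: float, unlabeled_fraction: float = 0.0
) -> CorrectedRatio:
    """Light/heavy area ratio, corrected for incomplete ¹⁵N labelling.

    If a fraction ``f`` of the spiked standard escaped labelling, the
    measured heavy area represents only ``(1 − f)`` of the spike, and the
    unlabelled remainder leaks into the light channel.  The corrected ratio
    relates the leak-subtracted light area to the full-spike-equivalent
    heavy area:

        ratio = (light − f·heavy/(1−f)) / (heavy/(1−f))

    With ``f = 0`` (the default — appropriate when the unlabelled residue is
    below ~1% and not worth correcting) this is exactly ``light/heavy``.  A
    correction that drives the light area negative flags the measurement
    (leak estimate inconsistent with the observed signal) and clamps the
    ratio at 0.
    """
    if not 0.0 <= unlabeled_fraction < 1.0:
        raise ValueError("unlabeled_fraction must be in [0, 1)")
    if heavy_area <= 0:
        raise ValueError("heavy area must be positive")
    if unlabeled_fraction == 0.0:
        return CorrectedRatio(ratio=light_area / heavy_area)
    full_heavy = heavy_area / (1.0 - unlabeled_fraction)
    light_corrected = light_area - unlabeled_fraction * full_heavy
    if light_corrected < 0:
        return CorrectedRatio(ratio=0.0, flagged=True)
    return CorrectedRatio(ratio=light_corrected / full_heavy)
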