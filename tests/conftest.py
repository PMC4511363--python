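"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from qconkit.simulate import RunSpec, SpeciesSpec, simulate_run


def brute_force_digest(sequence: str, max_missed: int) -> set[tuple[str, int, int, int]]:
    """Independent tryptic-digestion oracle.

    Enumerates *every* substring of the parent and keeps those that start
    right after a cleavage boundary (or at the protein start), end on a
    cleavage boundary (or at the protein end), and contain at most
    ``max_missed`` internal cleavage boundaries.  A boundary after position
    i (0-based) exists iff sequence[i] is K/R and sequence[i+1] is not P.

    Returns {(fragment, start_1based, end_1based, n_missed)}.
    """

    def boundary_after(i: int) -> bool:
        return sequence[i] in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P")

    out = set()
    n = len(sequence)
    for s in range(n):
        for e in range(s, n):
            starts_ok = s == 0 or boundary_after(s - 1)
            ends_ok = e == n - 1 or boundary_after(e)
            if not (starts_ok and ends_ok):
                continue
            internal = sum(1 for i in range(s, e) if boundary_after(i))
            if internal <= max_missed:
                out.add((sequence[s : e + 1], s + 1, e + 1, internal))
    return out


@pytest.fixture
def paired_run() -> tuple[RunSpec, object]:
    """A noiseless run with a 30 fmol light / 50 fmol heavy LLQALR pair."""
    spec = RunSpec(
        species=(
            SpeciesSpec("LLQALR", "light", 2, 30.0, rt_min=20.0),
            SpeciesSpec("LLQALR", "heavy", 2, 50.0, rt_min=20.0),
        ),
        seed=11,
        noise_cv=0.0,
    )
    return spec, simulate_run(spec)


@pytest.fixture
def gaussian_trace():
    """A dense noiseless Gaussian XIC trace with known closed-form area."""
    from qconkit.quantify import XICTrace

    amplitude, sd, center = 1000.0, 0.1, 20.0
    rt = np.linspace(18.0, 22.0, 801)
    intensity = amplitude * np.exp(-0.5 * ((rt - center) / sd) ** 2)
    true_area = amplitude * sd * np.sqrt(2 * np.pi)
    return XICTrace(rt=rt, intensity=intensity), true_area
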