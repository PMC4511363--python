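"""Isotopologue envelopes from elemental composition.

Used by the simulator to place peptide signal at realistic isotope peaks and
by the quantifier to normalise a monoisotopic-window XIC area to the total
species amount.  The envelope is a convolution of per-element isotope
distributions on a nominal-mass-offset grid, truncated after a few
isotopologues (sufficient for tryptic peptides below ~2 kDa).

A fully ¹⁵N-labelled ("heavy") species has its nitrogen fixed at ¹⁵N: the
+0.997035 Da/N shift lives in the neutral mass, and nitrogen drops out of the
envelope convolution, which is why a heavy envelope is slightly *narrower*
than its light counterpart.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ISOTOPE_ABUNDANCES", "ISOTOPE_SPACING", "envelope", "mono_fraction"]

# element -> (nominal mass offsets, natural abundances)
ISOTOPE_ABUNDANCES: dict[str, tuple[tuple[int, ...], tuple[float, ...]]] = {
    "C": ((0, 1), (0.9893, 0.0107)),
    "H": ((0, 1), (0.999885, 0.000115)),
    "N": ((0, 1), (0.99636, 0.00364)),
    "O": ((0, 1, 2), (0.99757, 0.00038, 0.00205)),
    "S": ((0, 1, 2, 4), (0.9499, 0.0075, 0.0425, 0.0001)),
}

# Spacing between adjacent isotopologue peaks; dominated by 13C-12C.
ISOTOPE_SPACING = 1.003355  # Da


def _element_poly(offsets, probs, n_iso: int) -> np.ndarray:
    poly = np.zeros(n_iso)
    for off, p in zip(offsets, probs):
        if off < n_iso:
            poly[off] += p
    return poly


def _power(poly: np.ndarray, n: int, n_iso: int) -> np.ndarray:
    # poly^n by binary exponentiation, truncating to the first n_iso terms
    result = np.zeros(n_iso)
    result[0] = 1.0
    base = poly.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:n_iso]
        base = np.convolve(base, base)[:n_iso]
        n >>= 1
    return result


def envelope(
    composition: dict[str, int],
    label: str = "light",
    n_iso: int = 5,
    normalize: bool = True,
) -> np.ndarray:
    """Isotopologue abundances for the first ``n_iso`` peaks.

    ``composition`` maps element symbols to atom counts.  ``label`` "heavy"
    excludes nitrogen from the convolution (all N fixed at ¹⁵N).  With
    ``normalize=False`` the entries are absolute probabilities (each term is
    exact; truncation only discards higher isotopologues), so entry 0 equals
    :func:`mono_fraction`.
    """
    dist = np.zeros(n_iso)
    dist[0] = 1.0
    for el, n in composition.items():
        if n == 0 or (label == "heavy" and el == "N"):
            continue
        offsets, probs = ISOTOPE_ABUNDANCES[el]
        dist = np.convolve(dist, _power(_element_poly(offsets, probs, n_iso), n, n_iso))[
            :n_iso
        ]
    if normalize:
        total = dist.sum()
        return dist / total if total > 0 else dist
    return dist


def mono_fraction(composition: dict[str, int], label: str = "light") -> float:
    """Fraction of total species intensity in the monoisotopic peak.

    Computed without n_iso truncation (the un-normalised zeroth term), i.e.
    the probability that every atom is its lightest isotope — for a heavy
    species, every atom other than the (label-fixed) nitrogens.
    """
    frac = 1.0
    for el, n in composition.items():
        if n == 0 or (label == "heavy" and el == "N"):
            continue
        offsets, probs = ISOTOPE_ABUNDANCES[el]
        frac *= probs[offsets.index(0)] ** n
    return frac
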