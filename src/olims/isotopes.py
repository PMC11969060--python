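"""Aggregated isotope distributions and ion isotopologue peak series.

The distribution is computed at unit-mass (nominal neutron-count) binning:
each bin aggregates every isotopologue with the same total neutron excess
and carries the abundance-weighted mean mass offset from the monoisotopic
peak. At the 120k resolving power typical of Orbitrap intact-mass work on
5-8 kDa oligonucleotides, isotopologues of a given nominal shift are not
resolved from each other but adjacent shifts are, so this aggregated model
is the right granularity. Fine structure is out of scope.

The algorithm is the standard polynomial (convolution) method: the
single-atom distribution of each element is raised to its atom count by
repeated-squaring convolution, then element distributions are convolved
together, pruning negligible bins at each step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import ElementalComposition, OligoChemError
from .constants import ELEMENTS, ISOTOPES
from .species import Polarity, mz_from_neutral


@dataclass(frozen=True)
class IsotopePattern:
    """Offsets (Da, from the monoisotopic mass) and relative abundances.

    ``normalization`` is "sum" (abundances sum to the retained probability)
    or "max" (base peak scaled to 1).
    """

    offsets: tuple[float, ...]
    abundances: tuple[float, ...]
    normalization: str = "sum"

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.abundances):
            raise OligoChemError("negative abundance in isotope pattern")
        if any(b < a for a, b in zip(self.offsets, self.offsets[1:])):
            raise OligoChemError("isotope pattern offsets must be non-decreasing")

    def normalized(self, mode: str = "max") -> "IsotopePattern":
        ab = np.asarray(self.abundances, dtype=float)
        scale = ab.max() if mode == "max" else ab.sum()
        return IsotopePattern(self.offsets, tuple(ab / scale), normalization=mode)

    def mean_offset(self) -> float:
        """Abundance-weighted mean mass offset, Da."""
        ab = np.asarray(self.abundances)
        return float(np.dot(self.offsets, ab) / ab.sum())


def _convolve(p1, m1, p2, m2, prune):
    """Convolve two (probability, mean-offset) binned distributions."""
    p = np.convolve(p1, p2)
    # numerator of the abundance-weighted mean offset of each output bin
    num = np.convolve(p1 * m1, p2) + np.convolve(p1, p2 * m2)
    # prune the negligible high-mass tail only; interior bins are kept so
    # accuracy is limited by float arithmetic, not by the threshold
    above = np.nonzero(p > prune)[0]
    last = (above[-1] + 1) if len(above) else 1
    p, num = p[:last], num[:last]
    m = np.divide(num, p, out=np.zeros_like(num), where=p > 0)
    return p, m


def _element_distribution(element: str, n: int, prune: float):
    """Distribution of n atoms of one element, by repeated squaring."""
    isotopes = ISOTOPES[element]
    # single-atom distribution binned by nominal shift
    max_shift = int(round(isotopes[-1][0]))
    p1 = np.zeros(max_shift + 1)
    m1 = np.zeros(max_shift + 1)
    for off, ab in isotopes:
        j = int(round(off))
        p1[j] += ab
        m1[j] += ab * off
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.where(p1 > 0, m1 / np.where(p1 > 0, p1, 1.0), 0.0)
    acc_p, acc_m = np.array([1.0]), np.array([0.0])
    base_p, base_m = p1, m1
    k = n
    while k:
        if k & 1:
            acc_p, acc_m = _convolve(acc_p, acc_m, base_p, base_m, prune)
        k >>= 1
        if k:
            base_p, base_m = _convolve(base_p, base_m, base_p, base_m, prune)
    return acc_p, acc_m


def isotope_pattern(
    composition: ElementalComposition,
    prune: float = 1e-10,
    normalization: str = "sum",
) -> IsotopePattern:
    """Aggregated isotope distribution of a neutral composition.

    ``prune`` is the per-convolution-step probability threshold below which
    bins are dropped; the retained total probability is >= 1 - prune per
    step in the sense that no bin above the threshold is ever discarded.
    """
    if not composition:
        raise OligoChemError("cannot compute isotope pattern of empty composition")
    if not 0 < prune < 1e-3:
        raise OligoChemError("prune threshold must be in (0, 1e-3)")
    p, m = np.array([1.0]), np.array([0.0])
    for element, count in zip(ELEMENTS, composition.counts):
        if count:
            ep, em = _element_distribution(element, count, prune)
            p, m = _convolve(p, m, ep, em, prune)
    keep = p > 0
    p, m = p[keep], m[keep]
    if normalization == "max":
        p = p / p.max()
    return IsotopePattern(tuple(m), tuple(p), normalization=normalization)


def render_ion_peaks(
    pattern: IsotopePattern,
    Ms: float,
    z: int,
    polarity: Polarity = Polarity.NEGATIVE,
) -> list[tuple[float, float]]:
    """Isotopologue peak series of an ion of neutral monoisotopic mass Ms.

    Peak j sits at mz(Ms + offset_j, z); consecutive peaks are spaced by
    about 1.00336/z. Intensities are the pattern abundances, unscaled.
    """
    if z < 1:
        raise OligoChemError("charge must be >= 1")
    return [
        (mz_from_neutral(Ms + off, z, polarity), ab)
        for off, ab in zip(pattern.offsets, pattern.abundances)
    ]
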