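"""Isotope-resolved charge-state deconvolution of centroid spectra.

Mirrors the behaviour of commercial intact-mass deconvolution software
(XTRACT-style) at the level that matters for impurity profiling:

1. threshold peaks by relative intensity and signal-to-noise;
2. detect isotopologue series greedily, highest apex first, inferring the
   charge from the ~1.00336/z spacing of adjacent isotopologues;
3. convert each series to a neutral monoisotopic mass, group masses across
   charge states within a ppm merge tolerance, and apply the exclusion
   rules — minimum number of detected charge states and optional m/z cap —
   that suppress species observed on a single (low) charge state, such as
   residual alkylamine adducts.

The retention-time dimension is out of scope: "sliding window" averaging
over an elution profile reduces here to a single averaged spectrum per
analyte (see :func:`olims.spectrum.average_spectra`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .constants import NEUTRON_SPACING
from .species import Polarity, neutral_from_mz
from .spectrum import CentroidSpectrum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeconvolutionSettings:
    """Defaults follow routine intact-oligonucleotide practice: 1%
    relative-intensity threshold, 30 ppm merge tolerance, S/N 3, at least
    two detected charge states, output masses 1000-8000 Da. The charge
    range default (2-15) suits ~7 kDa RNA; shorter/lower-charging ASOs are
    typically run at 2-10."""

    rel_intensity_threshold: float = 0.01  # fraction of base peak
    merge_tolerance_ppm: float = 30.0
    sn_threshold: float = 3.0
    charge_range: tuple[int, int] = (2, 15)
    min_detected_charges: int = 2
    output_mass_range: tuple[float, float] = (1000.0, 8000.0)
    mz_range_cap: tuple[float, float] | None = None
    # series-walk controls (not part of the printed settings surface)
    max_consecutive_misses: int = 1
    min_series_peaks: int = 2
    noise_window_mz: float = 100.0
    #: expected-envelope model for monoisotopic assignment: "nucleotide"
    #: (phosphodiester, no sulfur) or "nucleotide-ps" (phosphorothioate
    #: backbone, whose sulfur widens the isotope envelope)
    averagine: str = "nucleotide"
    #: walk floor relative to the series apex: peaks weaker than this are
    #: not accepted as members, so a walk cannot drift through the deep
    #: isotope tail into a neighbouring species' envelope
    series_floor_rel: float = 0.005

    def __post_init__(self) -> None:
        if self.charge_range[0] < 1 or self.charge_range[1] < self.charge_range[0]:
            raise ValueError("invalid charge range")
        if self.min_detected_charges < 1:
            raise ValueError("min_detected_charges must be >= 1")


@dataclass
class IsotopologueSeries:
    monoisotopic_mz: float
    z: int
    intensity: float
    n_peaks: int
    apex_mz: float


@dataclass
class DeconvolvedComponent:
    """One neutral-mass component: the summed evidence for a species
    across its supporting charge states."""

    mass: float  # neutral monoisotopic mass, Da
    intensity: float
    charges: tuple[int, ...]
    per_charge_intensity: dict[int, float] = field(default_factory=dict)

    @property
    def n_charges(self) -> int:
        return len(self.charges)


# ---------------------------------------------------------------------------
# Stage 0: thresholding
# ---------------------------------------------------------------------------


def _noise_floor(mz: np.ndarray, intensity: np.ndarray, window: float) -> np.ndarray:
    """Per-peak local noise estimate from *isolated* peaks.

    Electronic/chemical baseline noise produces sparse, isolated centroids,
    whereas every genuine ion — however weak — contributes an isotopologue
    series with companions within one neutron spacing. The noise level in
    a +/- window is therefore the median + MAD of peaks that have no
    neighbour within 1.05 m/z. Windows with fewer than five isolated peaks
    (clean or sparse spectra) get a zero floor, which disables the S/N cut
    there rather than discarding real signal.
    """
    floor = np.zeros_like(intensity)
    n = len(mz)
    if n == 0:
        return floor
    gap_left = np.empty(n)
    gap_right = np.empty(n)
    gap_left[0] = np.inf
    gap_left[1:] = np.diff(mz)
    gap_right[-1] = np.inf
    gap_right[:-1] = np.diff(mz)
    isolated = (gap_left > 1.05) & (gap_right > 1.05)
    iso_mz = mz[isolated]
    iso_int = intensity[isolated]
    if len(iso_mz) == 0:
        return floor
    left = np.searchsorted(iso_mz, mz - window, side="left")
    right = np.searchsorted(iso_mz, mz + window, side="right")
    for i in range(n):
        local = iso_int[left[i] : right[i]]
        if len(local) >= 5:
            med = np.median(local)
            floor[i] = med + 1.4826 * np.median(np.abs(local - med))
    return floor


def threshold_peaks(
    spectrum: CentroidSpectrum, settings: DeconvolutionSettings
) -> CentroidSpectrum:
    """Apply the relative-intensity and S/N filters (and the m/z cap)."""
    mz, intensity = spectrum.mz, spectrum.intensity
    keep = np.ones(len(mz), dtype=bool)
    if settings.mz_range_cap is not None:
        lo, hi = settings.mz_range_cap
        keep &= (mz >= lo) & (mz <= hi)
    if keep.any() and settings.rel_intensity_threshold > 0:
        base_peak = intensity[keep].max()
        keep &= intensity >= settings.rel_intensity_threshold * base_peak
    if settings.sn_threshold > 0 and keep.any():
        floor = _noise_floor(mz[keep], intensity[keep], settings.noise_window_mz)
        sn_ok = np.ones(int(keep.sum()), dtype=bool)
        positive = floor > 0
        sn_ok[positive] = (
            intensity[keep][positive] / floor[positive] >= settings.sn_threshold
        )
        idx = np.nonzero(keep)[0]
        keep[idx[~sn_ok]] = False
    out = CentroidSpectrum(
        mz[keep], intensity[keep], spectrum.polarity, dict(spectrum.metadata)
    )
    logger.info(
        "threshold_peaks: %d -> %d peaks (rel>=%.3g, S/N>=%.3g, cap=%s)",
        len(mz),
        len(out),
        settings.rel_intensity_threshold,
        settings.sn_threshold,
        settings.mz_range_cap,
    )
    return out


# ---------------------------------------------------------------------------
# Stage 1: isotopologue series detection
# ---------------------------------------------------------------------------

#: Average elemental rates (atoms per Da) of a nucleotide chain — the
#: nucleic-acid analogue of the "averagine" model used for proteins.
#: "nucleotide" is an equimolar mix of the four ribonucleotide monomers;
#: "nucleotide-ps" the corresponding phosphorothioate deoxyribonucleotides
#: (sulfur's strong +2 isotope widens the envelope noticeably).
_AVERAGINE_RATES = {
    "nucleotide": {
        "C": 0.029567,
        "H": 0.036570,
        "N": 0.011672,
        "O": 0.021787,
        "P": 0.003112,
    },
    "nucleotide-ps": {
        "C": 0.028592,
        "H": 0.035922,
        "N": 0.010997,
        "O": 0.016862,
        "P": 0.002932,
        "S": 0.002932,
    },
}


@lru_cache(maxsize=64)
def _expected_pattern(mass_bucket: int, averagine: str) -> np.ndarray:
    """Aggregated isotope-envelope shape expected for an oligonucleotide of
    roughly ``mass_bucket`` Da (bucketed to 200 Da), max-normalized."""
    from .chem import ElementalComposition
    from .constants import ELEMENTS
    from .isotopes import isotope_pattern

    rates = _AVERAGINE_RATES[averagine]
    mass = max(mass_bucket, 200)
    counts = tuple(int(round(rates.get(e, 0.0) * mass)) for e in ELEMENTS)
    pattern = isotope_pattern(ElementalComposition(counts), normalization="max")
    return np.asarray(pattern.abundances)


def _monoisotopic_offset(
    bins: np.ndarray, intensities: np.ndarray, expected: np.ndarray
) -> int:
    """Offset (in isotopologue bins) of the series apex from the true
    monoisotopic peak, found by aligning the observed envelope with the
    expected pattern (cosine score over candidate shifts).

    ``bins`` are member positions relative to the apex; the leftmost
    observed member may sit one or more bins right of the monoisotopic
    peak when the latter fell below the intensity threshold.
    """
    leftmost = int(-bins.min())
    o = intensities / intensities.sum()
    best_m, best_score = leftmost, -np.inf
    for m in range(leftmost, min(leftmost + 7, len(expected))):
        idx = bins + m
        valid = idx < len(expected)
        p = np.where(valid, expected[np.clip(idx, 0, len(expected) - 1)], 0.0)
        norm = np.linalg.norm(p)
        if norm == 0:
            continue
        score = float(o @ p) / norm
        if score > best_score:
            best_score, best_m = score, m
    return best_m


def _walk_series(
    mz: np.ndarray,
    intensity: np.ndarray,
    assigned: np.ndarray,
    apex: int,
    z: int,
    settings: DeconvolutionSettings,
) -> list[int]:
    """Collect indices of unassigned peaks on the isotopologue grid of
    charge z anchored at the apex peak, walking both directions until the
    allowed number of consecutive misses is exceeded."""
    spacing = NEUTRON_SPACING / z
    tol = settings.merge_tolerance_ppm * 1e-6 * mz[apex]
    tol = min(tol, 0.3 * spacing)  # never accept a neighbour from the next rung
    floor = settings.series_floor_rel * intensity[apex]
    members = [apex]
    for direction in (+1, -1):
        misses = 0
        step = 1
        while misses <= settings.max_consecutive_misses:
            target = mz[apex] + direction * step * spacing
            if target <= 0:
                break
            j = np.searchsorted(mz, target)
            best = -1
            best_err = tol
            for cand in (j - 1, j):
                if (
                    0 <= cand < len(mz)
                    and not assigned[cand]
                    and intensity[cand] >= floor
                ):
                    err = abs(mz[cand] - target)
                    if err <= best_err:
                        best, best_err = cand, err
            if best >= 0:
                members.append(best)
                misses = 0
            else:
                misses += 1
            step += 1
    members = sorted(members)
    return _prune_off_grid(mz, intensity, members, apex, spacing)


def _prune_off_grid(
    mz: np.ndarray,
    intensity: np.ndarray,
    members: list[int],
    apex: int,
    spacing: float,
) -> list[int]:
    """Drop members whose residual from the series' own isotopologue grid
    is an outlier.

    A nearby species whose mass delta is a non-integer number of neutron
    units (the PS->PO substitution at -15.92 units, or the -A vs -G base
    losses 15.94 units apart, are the canonical cases) produces peaks that
    fall inside the walk tolerance but sit at a systematic fractional-bin
    offset from the true grid.
    """
    if len(members) < 4:
        return members
    idx = np.asarray(members)
    # fractional offset of each member from the integer isotopologue grid
    # anchored at the apex, in bin units
    frac = (mz[idx] - mz[apex]) / spacing
    offsets = frac - np.round(frac)
    center = _weighted_median(offsets, intensity[idx])
    deviation = np.abs(offsets - center)
    mad = np.median(deviation)
    cutoff = max(3.5 * 1.4826 * mad, 0.02)
    keep = deviation <= cutoff
    if keep.all():
        return members
    return [int(i) for i in idx[keep]]


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    cum = np.cumsum(weights[order])
    return float(values[order][np.searchsorted(cum, 0.5 * cum[-1])])


def detect_isotopologue_series(
    spectrum: CentroidSpectrum, settings: DeconvolutionSettings
) -> list[IsotopologueSeries]:
    """Greedy highest-apex-first charge inference from isotope spacing.

    For each unassigned apex, every charge in the allowed range is scored
    by the number (then summed intensity) of grid-consistent peaks; sparse
    matches (fewer than 60% of the walked grid positions filled) are
    rejected so a half-spaced harmonic (2z) cannot outscore the true
    charge. Ties prefer the larger charge: the tighter grid is the harder
    one to match by chance.
    """
    filtered = threshold_peaks(spectrum, settings)
    mz, intensity = filtered.mz, filtered.intensity
    assigned = np.zeros(len(mz), dtype=bool)
    series: list[IsotopologueSeries] = []
    z_lo, z_hi = settings.charge_range
    order = np.argsort(intensity)[::-1]
    for apex in order:
        if assigned[apex]:
            continue
        best: tuple | None = None
        for z in range(z_lo, z_hi + 1):
            members = _walk_series(mz, intensity, assigned, apex, z, settings)
            if len(members) < settings.min_series_peaks:
                continue
            span = round((mz[members[-1]] - mz[members[0]]) * z / NEUTRON_SPACING)
            fill = len(members) / (span + 1)
            if fill < 0.6:
                continue
            score = (len(members), float(intensity[members].sum()), z)
            if best is None or score > best[0]:
                best = (score, z, members)
        if best is None:
            continue
        _, z, members = best
        assigned[members] = True
        # locate the monoisotopic member by aligning the observed envelope
        # with the expected oligonucleotide pattern at this mass scale; the
        # leftmost *observed* peak may be A+1 or higher when the true
        # monoisotopic peak fell below the intensity threshold.
        spacing = NEUTRON_SPACING / z
        member_mz = mz[members]
        bins = np.round((member_mz - mz[apex]) / spacing).astype(int)
        approx_mass = neutral_from_mz(float(mz[apex]), z, Polarity.NEGATIVE)
        expected = _expected_pattern(
            int(round(approx_mass / 200.0)) * 200, settings.averagine
        )
        offset = _monoisotopic_offset(bins, intensity[members], expected)
        leftmost = int(-bins.min())
        mono_mz = float(member_mz.min() - (offset - leftmost) * spacing)
        series.append(
            IsotopologueSeries(
                monoisotopic_mz=mono_mz,
                z=z,
                intensity=float(intensity[members].sum()),
                n_peaks=len(members),
                apex_mz=float(mz[apex]),
            )
        )
    logger.info("detect_isotopologue_series: %d series", len(series))
    return series


# ---------------------------------------------------------------------------
# Stage 2: charge-state combination and exclusion rules
# ---------------------------------------------------------------------------


def combine_charge_states(
    series: list[IsotopologueSeries],
    settings: DeconvolutionSettings,
    polarity: Polarity = Polarity.NEGATIVE,
) -> list[DeconvolvedComponent]:
    """Group series by neutral mass; apply the exclusion rules.

    Components supported by fewer than ``min_detected_charges`` distinct
    charge states are dropped — the rule that keeps single-charge-state
    residual adducts out of the results — as are masses outside the output
    range. Grouping is single-linkage at the merge tolerance (ppm,
    evaluated against the intensity-weighted running mean mass).
    """
    entries = sorted(
        ((neutral_from_mz(s.monoisotopic_mz, s.z, polarity), s) for s in series),
        key=lambda pair: pair[0],
    )
    groups: list[dict] = []
    for mass, s in entries:
        placed = False
        if groups:
            g = groups[-1]
            tol = settings.merge_tolerance_ppm * 1e-6 * g["mean"]
            if abs(mass - g["mean"]) <= tol:
                g["members"].append((mass, s))
                total = g["intensity"] + s.intensity
                g["mean"] = (g["mean"] * g["intensity"] + mass * s.intensity) / total
                g["intensity"] = total
                placed = True
        if not placed:
            groups.append({"mean": mass, "intensity": s.intensity, "members": [(mass, s)]})

    components: list[DeconvolvedComponent] = []
    n_dropped_charges = n_dropped_mass = 0
    for g in groups:
        charges = sorted({s.z for _, s in g["members"]})
        if len(charges) < settings.min_detected_charges:
            n_dropped_charges += 1
            continue
        lo, hi = settings.output_mass_range
        if not lo <= g["mean"] <= hi:
            n_dropped_mass += 1
            continue
        per_charge: dict[int, float] = {}
        for _, s in g["members"]:
            per_charge[s.z] = per_charge.get(s.z, 0.0) + s.intensity
        components.append(
            DeconvolvedComponent(
                mass=float(g["mean"]),
                intensity=float(g["intensity"]),
                charges=tuple(charges),
                per_charge_intensity=per_charge,
            )
        )
    logger.info(
        "combine_charge_states: %d groups -> %d components "
        "(%d below min charges, %d outside mass range)",
        len(groups),
        len(components),
        n_dropped_charges,
        n_dropped_mass,
    )
    components.sort(key=lambda c: c.mass)
    return components


def deconvolve(
    spectrum: CentroidSpectrum, settings: DeconvolutionSettings | None = None
) -> list[DeconvolvedComponent]:
    """Full pipeline: threshold, series detection, charge combination."""
    settings = settings or DeconvolutionSettings()
    series = detect_isotopologue_series(spectrum, settings)
    return combine_charge_states(series, settings, spectrum.polarity)


def components_frame(components: list[DeconvolvedComponent]) -> pd.DataFrame:
    """Components as a DataFrame (mass_Da, intensity, charges, n_charges)."""
    return pd.DataFrame(
        [
            {
                "mass_Da": c.mass,
                "intensity": c.intensity,
                "charges": ";".join(str(z) for z in c.charges),
                "n_charges": c.n_charges,
            }
            for c in components
        ],
        columns=["mass_Da", "intensity", "charges", "n_charges"],
    )
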