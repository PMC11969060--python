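"""Centroided spectrum container shared by the simulator and deconvolution."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .species import Polarity


class SpectrumError(ValueError):
    pass


@dataclass
class CentroidSpectrum:
    """Polarity-tagged centroid peak list.

    Peaks are kept m/z-sorted with strictly positive intensities; metadata
    carries acquisition context (source conditions, scenario tags).
    """

    mz: np.ndarray
    intensity: np.ndarray
    polarity: Polarity = Polarity.NEGATIVE
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise SpectrumError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity <= 0):
            raise SpectrumError("intensities must be strictly positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def clipped(self, low: float, high: float) -> "CentroidSpectrum":
        """Restrict to the [low, high] m/z window."""
        keep = (self.mz >= low) & (self.mz <= high)
        return CentroidSpectrum(
            self.mz[keep], self.intensity[keep], self.polarity, dict(self.metadata)
        )


def merge_coincident_peaks(
    mz: np.ndarray, intensity: np.ndarray, decimals: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Sum intensities of peaks that coincide to ``decimals`` places in m/z
    (e.g. the neutral and charged base-loss channels land on identical
    centroids)."""
    if len(mz) == 0:
        return mz, intensity
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    key = np.round(mz, decimals)
    uniq, inverse = np.unique(key, return_inverse=True)
    summed = np.zeros(len(uniq))
    np.add.at(summed, inverse, intensity)
    # keep the intensity-weighted mean m/z of each merged group
    wmz = np.zeros(len(uniq))
    np.add.at(wmz, inverse, intensity * mz)
    return wmz / summed, summed


def average_spectra(
    spectra: list[CentroidSpectrum], tolerance_ppm: float = 10.0
) -> CentroidSpectrum:
    """Merge several centroid spectra into one averaged spectrum.

    A thin stand-in for retention-time window averaging: peak lists are
    concatenated, centroids within ``tolerance_ppm`` of their neighbour
    clustered into one intensity-weighted peak, intensities divided by the
    number of spectra. Averaging reduces m/z jitter and intensity noise by
    roughly the square root of the number of scans, as on-instrument
    spectral averaging does.
    """
    if not spectra:
        raise SpectrumError("no spectra to average")
    pol = spectra[0].polarity
    if any(s.polarity is not pol for s in spectra):
        raise SpectrumError("cannot average spectra of mixed polarity")
    mz = np.concatenate([s.mz for s in spectra])
    inten = np.concatenate([s.intensity for s in spectra])
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    # split sorted peaks into clusters wherever the gap exceeds tolerance
    gaps = np.diff(mz)
    new_cluster = np.concatenate(([True], gaps > tolerance_ppm * 1e-6 * mz[1:]))
    cluster = np.cumsum(new_cluster) - 1
    n = cluster[-1] + 1 if len(cluster) else 0
    summed = np.zeros(n)
    weighted = np.zeros(n)
    np.add.at(summed, cluster, inten)
    np.add.at(weighted, cluster, inten * mz)
    return CentroidSpectrum(
        weighted / summed, summed / len(spectra), pol, dict(spectra[0].metadata)
    )
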