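"""Phenomenological HESI spectrum simulator for oligonucleotide samples.

Generates centroid spectra of an oligonucleotide sample (full-length
product plus impurity fractions) as a function of electrospray source
conditions, encoding the trends seen in ion-pair LC-HESI-MS of
therapeutic oligonucleotides with alkylamine/fluoroalcohol mobile phases:

* a roughly Gaussian negative-mode charge-state envelope whose mean shifts
  up with vaporiser temperature (higher charge states appear only under
  hotter, more denaturing spray conditions);
* alkylamine adducts (hexylamine by default) concentrated on the lowest
  charge states, stripped progressively by in-source collision energy (CE)
  and by higher transfer-tube/vaporiser temperatures;
* gas-phase nucleobase loss that switches on as CE rises past a
  sequence-chemistry-dependent threshold — purines first, and earlier for
  2'-deoxy residues than for 2'-modified/RNA residues whose 2' substituent
  stabilises the glycosidic bond; higher charge states fragment at lower
  CE (greater coulombic repulsion lowers the critical energy);
* depletion of the highest charge states at high CE;
* greater overall gas-phase stability in positive mode, with more adducts
  on fewer, lower charge states.

All response curves are logistic in CE with linear temperature shifts:
the observed behaviour is monotone and bounded, which a logistic encodes
with the fewest parameters. Mechanistic droplet physics (CRM/CEM) is out
of scope; this module exists to make the downstream deconvolution and
quantification stages testable without instrument data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chem import Base, ElementalComposition, OligoChemError, OligoSequence
from .isotopes import isotope_pattern, render_ion_peaks
from .species import (
    Polarity,
    SpeciesDefinition,
    SpeciesKind,
    species_neutral_mass,
)
from .spectrum import CentroidSpectrum, merge_coincident_peaks


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Conditions and sample
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SourceConditions:
    """Instrument source settings.

    Defaults mirror routine intact-mass acquisition: ITT 275 °C, vaporiser
    300 °C, scan range 400-2500 m/z. CE grids of interest are 0-65 V in
    negative mode and 30-90 V in positive mode.
    """

    ce_volts: float = 0.0
    itt_temp_C: float = 275.0
    vap_temp_C: float = 300.0
    polarity: Polarity = Polarity.NEGATIVE
    scan_range: tuple[float, float] = (400.0, 2500.0)

    def __post_init__(self) -> None:
        if self.scan_range[0] >= self.scan_range[1]:
            raise SimulationError("empty scan range")


@dataclass(frozen=True)
class BaseLossChannel:
    """One gas-phase base-loss pathway of the response model.

    ``share`` apportions the preset's maximum base-loss fraction between
    channels; ``c50_volts`` is the CE midpoint at the lowest observed
    charge state, lowered by ``kappa`` volts per extra charge. ``charged``
    channels eject the base as an anion, so the product ion appears one
    charge state below its precursor.
    """

    base: Base
    c50_volts: float
    share: float
    charged: bool = False
    width_volts: float = 4.0


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal intensity noise, ppm-scale m/z jitter and
    a sparse uniform baseline below 0.1% of the base peak."""

    intensity_cv: float = 0.05
    mz_jitter_ppm: float = 2.0
    baseline_fraction: float = 0.001
    n_baseline_peaks: int = 200


@dataclass(frozen=True)
class SourceResponseModel:
    """Phenomenological map from source conditions to spectral features.

    All CE responses are logistic; temperatures shift the adduct-survival
    midpoint linearly. Positive-mode offsets encode the greater gas-phase
    stability (base-loss midpoints shifted up) and heavier adducting
    observed in positive ion mode.
    """

    # charge envelope (negative mode, charges as positive integers)
    mu_z: float = 6.0
    sigma_z: float = 1.4
    z_min: int = 3
    z_max: int = 10
    dmu_z_dVT: float = 0.010  # charges per °C of vaporiser temperature
    # adduct propensity
    lambda0: float = 1.2  # mean adduct count, lowest charge state, CE=0
    gamma: float = 0.8  # exponential decay of propensity per charge
    max_adducts: int = 3
    c50_adduct_volts: float = 22.0
    w_adduct_volts: float = 6.0
    itt_sens_adduct: float = 0.03  # midpoint shift, V per °C of ITT
    vt_sens_adduct: float = 0.05  # midpoint shift, V per °C of VT (stronger:
    # low vaporiser temperature leaves far more adducts than low ITT)
    # base loss
    base_loss_channels: tuple[BaseLossChannel, ...] = ()
    f_max_base_loss: float = 0.8
    kappa_volts_per_charge: float = 1.5
    # high-charge depletion with CE
    depletion_z_onset: int = 7
    depletion_rate: float = 0.0015  # per V per charge above onset
    # positive-mode offsets
    pos_mu_z: float = 4.0
    pos_sigma_z: float = 0.9
    pos_z_min: int = 3
    pos_z_max: int = 6
    pos_adduct_c50_shift: float = 26.0
    pos_lambda0_factor: float = 2.0
    pos_base_c50_shift: float = 27.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    adduct_identity: str = "HA"
    #: relative ionisation efficiency (scales the total ion current; <1 for
    #: signal-suppressing mobile phases such as TBuAA)
    ionisation_efficiency: float = 1.0

    def envelope(self, cond: SourceConditions) -> tuple[np.ndarray, np.ndarray]:
        """Charge states and their relative weights under ``cond``."""
        if cond.polarity is Polarity.NEGATIVE:
            mu, sigma = self.mu_z, self.sigma_z
            z_lo, z_hi = self.z_min, self.z_max
            mu = mu + self.dmu_z_dVT * (cond.vap_temp_C - 300.0)
        else:
            mu, sigma = self.pos_mu_z, self.pos_sigma_z
            z_lo, z_hi = self.pos_z_min, self.pos_z_max
        z = np.arange(z_lo, z_hi + 1)
        w = np.exp(-0.5 * ((z - mu) / sigma) ** 2)
        # high charge states destabilised by in-source activation
        over = np.clip(z - self.depletion_z_onset, 0, None)
        w = w * np.exp(-self.depletion_rate * cond.ce_volts * over)
        return z, w / w.sum()

    def adduct_survival(self, cond: SourceConditions) -> float:
        """Fraction of adducts surviving the source, in [0, 1], decreasing
        in CE and in both source temperatures."""
        c50 = self.c50_adduct_volts
        c50 -= self.itt_sens_adduct * (cond.itt_temp_C - 275.0)
        c50 -= self.vt_sens_adduct * (cond.vap_temp_C - 300.0)
        if cond.polarity is Polarity.POSITIVE:
            c50 += self.pos_adduct_c50_shift
        return 1.0 / (1.0 + math.exp((cond.ce_volts - c50) / self.w_adduct_volts))

    def adduct_mean(self, z: int, cond: SourceConditions) -> float:
        """Truncated-Poisson mean adduct count on charge state z."""
        lam0 = self.lambda0
        z_lo = self.z_min if cond.polarity is Polarity.NEGATIVE else self.pos_z_min
        if cond.polarity is Polarity.POSITIVE:
            lam0 *= self.pos_lambda0_factor
        return lam0 * math.exp(-self.gamma * (z - z_lo)) * self.adduct_survival(cond)

    def adduct_distribution(self, z: int, cond: SourceConditions) -> np.ndarray:
        """Weights over adduct counts k = 0..max_adducts (truncated Poisson)."""
        lam = self.adduct_mean(z, cond)
        k = np.arange(self.max_adducts + 1)
        log_w = k * math.log(lam) - np.cumsum(np.log(np.maximum(k, 1))) if lam > 0 else np.where(k == 0, 0.0, -np.inf)
        w = np.exp(log_w - log_w.max())
        return w / w.sum()

    def base_loss_fraction(
        self, channel: BaseLossChannel, z: int, cond: SourceConditions
    ) -> float:
        """Fraction of charge-state-z precursor intensity converted through
        one base-loss channel."""
        z_lo = self.z_min if cond.polarity is Polarity.NEGATIVE else self.pos_z_min
        c50 = channel.c50_volts - self.kappa_volts_per_charge * (z - z_lo)
        if cond.polarity is Polarity.POSITIVE:
            c50 += self.pos_base_c50_shift
        logistic = 1.0 / (1.0 + math.exp(-(cond.ce_volts - c50) / channel.width_volts))
        return self.f_max_base_loss * channel.share * logistic


@dataclass(frozen=True)
class SampleComposition:
    """An analyte plus the fractional abundances of its ledger species.

    Fractions must be non-negative and sum to 1 (e.g. FLP 0.97, PO 0.02,
    -A 0.01)."""

    sequence: OligoSequence
    fractions: tuple[tuple[SpeciesDefinition, float], ...]

    @classmethod
    def pure(cls, sequence: OligoSequence) -> "SampleComposition":
        flp = SpeciesDefinition("FLP", SpeciesKind.FLP)
        return cls(sequence, ((flp, 1.0),))

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.fractions)
        if any(f < 0 for _, f in self.fractions):
            raise SimulationError("species fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"species fractions sum to {total}, expected 1")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_TOTAL_ION_CURRENT = 1.0e7  # arbitrary intensity units per simulated sample


def _pattern_cache_key(comp: ElementalComposition) -> tuple[int, ...]:
    return comp.counts


class _PatternCache:
    def __init__(self) -> None:
        self._cache: dict[tuple[int, ...], object] = {}

    def get(self, comp: ElementalComposition):
        key = _pattern_cache_key(comp)
        if key not in self._cache:
            self._cache[key] = isotope_pattern(comp, normalization="sum")
        return self._cache[key]


@dataclass(frozen=True)
class SimulatedIon:
    """One expected ion current before isotope rendering and noise."""

    label: str  # e.g. "FLP", "FLP+2HA", "PO-A(charged)"
    origin: str  # name of the sample species it derives from
    category: str  # "precursor" | "adduct" | "base_loss"
    neutral_mass: float
    composition: ElementalComposition
    z: int
    intensity: float


def expected_ions(
    sample: SampleComposition,
    model: SourceResponseModel,
    cond: SourceConditions,
) -> list[SimulatedIon]:
    """Deterministic expected ion currents (the noiseless spectrum before
    isotope rendering and scan-range clipping).

    Base loss is applied to adduct-free ions only: by the CE where
    fragmentation matters, adducts have been stripped, and mixed
    adduct+fragment ions are not tracked.
    """
    from .species import ADDUCT_COMPOSITION

    flp_comp = sample.sequence.composition()
    M = sample.sequence.monoisotopic_mass()
    z_states, z_weights = model.envelope(cond)
    adduct_comp = ADDUCT_COMPOSITION[model.adduct_identity]

    ions: list[SimulatedIon] = []
    for species, fraction in sample.fractions:
        if fraction == 0.0:
            continue
        species_total = _TOTAL_ION_CURRENT * model.ionisation_efficiency * fraction
        comp_s = species.apply_composition(flp_comp)
        mass_s = species_neutral_mass(M, species)
        for z, zw in zip(z_states, z_weights):
            intensity_z = species_total * zw
            kdist = model.adduct_distribution(int(z), cond)
            for k, kw in enumerate(kdist):
                intensity_zk = intensity_z * kw
                if intensity_zk <= 0:
                    continue
                if k > 0:
                    ions.append(
                        SimulatedIon(
                            label=f"{species.name}+{k}{model.adduct_identity}",
                            origin=species.name,
                            category="adduct",
                            neutral_mass=mass_s + k * _adduct_mass(model),
                            composition=comp_s + k * adduct_comp,
                            z=int(z),
                            intensity=intensity_zk,
                        )
                    )
                    continue
                # adduct-free precursor: apportion base loss
                remaining = intensity_zk
                for channel in model.base_loss_channels:
                    frac = model.base_loss_fraction(channel, int(z), cond)
                    moved = intensity_zk * frac
                    if moved <= 0:
                        continue
                    product_z = int(z) - 1 if channel.charged else int(z)
                    if product_z < 1:
                        continue
                    try:
                        product_comp = comp_s - _base_comp(channel.base)
                    except OligoChemError:
                        continue  # species lacks that base (e.g. already lost)
                    tag = "charged" if channel.charged else "neutral"
                    ions.append(
                        SimulatedIon(
                            label=f"{species.name}-{channel.base.value}({tag})",
                            origin=species.name,
                            category="base_loss",
                            neutral_mass=mass_s - _base_mass(channel.base),
                            composition=product_comp,
                            z=product_z,
                            intensity=moved,
                        )
                    )
                    remaining -= moved
                if remaining > 0:
                    ions.append(
                        SimulatedIon(
                            label=species.name,
                            origin=species.name,
                            category="precursor",
                            neutral_mass=mass_s,
                            composition=comp_s,
                            z=int(z),
                            intensity=remaining,
                        )
                    )
    return ions


def category_fractions(
    sample: SampleComposition,
    model: SourceResponseModel,
    cond: SourceConditions,
) -> dict[str, float]:
    """Expected fraction of total ion current per category
    (precursor / adduct / base_loss), before scan-range clipping."""
    ions = expected_ions(sample, model, cond)
    total = sum(i.intensity for i in ions)
    out = {"precursor": 0.0, "adduct": 0.0, "base_loss": 0.0}
    for ion in ions:
        out[ion.category] += ion.intensity / total
    return out


def _adduct_mass(model: SourceResponseModel) -> float:
    from .species import ADDUCT_MASS_DELTA

    return ADDUCT_MASS_DELTA[model.adduct_identity]


def _base_comp(base: Base) -> ElementalComposition:
    from .chem import BASE_COMPOSITION

    return BASE_COMPOSITION[base]


def _base_mass(base: Base) -> float:
    from .chem import monoisotopic_mass

    return monoisotopic_mass(_base_comp(base))


def simulate_spectrum(
    sample: SampleComposition,
    model: SourceResponseModel,
    cond: SourceConditions,
    seed: int | np.random.SeedSequence | None = None,
    _cache: _PatternCache | None = None,
) -> CentroidSpectrum:
    """Simulate one centroid spectrum.

    ``seed=None`` gives the noiseless deterministic expectation; an integer
    (or SeedSequence) seed adds the noise model on top. The returned peaks
    are m/z-sorted and clipped to the scan range.
    """
    cache = _cache or _PatternCache()
    ions = expected_ions(sample, model, cond)
    mz_parts: list[np.ndarray] = []
    int_parts: list[np.ndarray] = []
    for ion in ions:
        pattern = cache.get(ion.composition)
        peaks = render_ion_peaks(pattern, ion.neutral_mass, ion.z, cond.polarity)
        arr = np.asarray(peaks)
        mz_parts.append(arr[:, 0])
        int_parts.append(arr[:, 1] * ion.intensity)
    mz = np.concatenate(mz_parts) if mz_parts else np.empty(0)
    intensity = np.concatenate(int_parts) if int_parts else np.empty(0)
    mz, intensity = merge_coincident_peaks(mz, intensity)

    if seed is not None:
        seq = (
            seed
            if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed)
        )
        rng = np.random.default_rng(seq)
        noise = model.noise
        if noise.intensity_cv > 0:
            sigma = math.sqrt(math.log(1.0 + noise.intensity_cv**2))
            intensity = intensity * rng.lognormal(
                mean=-0.5 * sigma**2, sigma=sigma, size=len(intensity)
            )
        if noise.mz_jitter_ppm > 0:
            mz = mz * (1.0 + rng.normal(0.0, noise.mz_jitter_ppm * 1e-6, len(mz)))
        if noise.n_baseline_peaks > 0 and len(intensity):
            base_mz = rng.uniform(*cond.scan_range, noise.n_baseline_peaks)
            base_int = rng.uniform(
                0.0, noise.baseline_fraction * intensity.max(), noise.n_baseline_peaks
            )
            keep = base_int > 0
            mz = np.concatenate([mz, base_mz[keep]])
            intensity = np.concatenate([intensity, base_int[keep]])

    keep = intensity > 0
    spectrum = CentroidSpectrum(
        mz[keep],
        intensity[keep],
        cond.polarity,
        metadata={
            "ce_volts": cond.ce_volts,
            "itt_temp_C": cond.itt_temp_C,
            "vap_temp_C": cond.vap_temp_C,
        },
    )
    return spectrum.clipped(*cond.scan_range)


def simulate_ce_sweep(
    sample: SampleComposition,
    model: SourceResponseModel,
    ce_grid: list[float],
    cond_base: SourceConditions | None = None,
    seed: int | None = None,
) -> list[tuple[float, CentroidSpectrum]]:
    """Simulate one spectrum per CE value.

    Seeded runs derive an independent substream per grid position from the
    master seed (counter-based split), so results do not depend on sweep
    order or on dropping grid points elsewhere.
    """
    if not ce_grid:
        raise SimulationError("empty CE grid")
    cond_base = cond_base or SourceConditions()
    cache = _PatternCache()
    out = []
    for index, ce in enumerate(ce_grid):
        cond = replace(cond_base, ce_volts=float(ce))
        sub = (
            np.random.SeedSequence(entropy=seed, spawn_key=(index,))
            if seed is not None
            else None
        )
        out.append((float(ce), simulate_spectrum(sample, model, cond, sub, cache)))
    return out


DEFAULT_SPIKE_FRACTIONS = (0.0002, 0.001, 0.005, 0.01, 0.02, 0.03)


def simulate_spikein_series(
    base_sample: SampleComposition,
    impurity: SpeciesDefinition,
    model: SourceResponseModel,
    cond: SourceConditions | None = None,
    fractions: tuple[float, ...] = DEFAULT_SPIKE_FRACTIONS,
    seed: int | None = None,
) -> list[tuple[float, CentroidSpectrum]]:
    """Spike an impurity into the sample at each fraction of the total.

    The FLP fraction is reduced correspondingly; fractions above 5% of
    total are outside the intended trace-impurity regime and rejected.
    """
    cond = cond or SourceConditions()
    cache = _PatternCache()
    out = []
    for index, frac in enumerate(fractions):
        if not 0.0 <= frac <= 0.05:
            raise SimulationError(f"spike fraction {frac} outside [0, 0.05]")
        spiked = [(s, f * (1.0 - frac)) for s, f in base_sample.fractions]
        if frac > 0:
            spiked.append((impurity, frac))
        sample = SampleComposition(base_sample.sequence, tuple(spiked))
        sub = (
            np.random.SeedSequence(entropy=seed, spawn_key=(index,))
            if seed is not None
            else None
        )
        out.append((float(frac), simulate_spectrum(sample, model, cond, sub, cache)))
    return out
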