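"""Charge-state deconvolution: round trips, exclusion rules, robustness."""

import numpy as np
import pytest

from olims.chem import parse_sequence
from olims.deconvolve import (
    DeconvolutionSettings,
    deconvolve,
    detect_isotopologue_series,
)
from olims.isotopes import isotope_pattern, render_ion_peaks
from olims.simulate import (
    SampleComposition,
    SourceConditions,
    SourceResponseModel,
    simulate_spectrum,
)
from olims.species import Polarity, SpeciesDefinition, SpeciesKind
from olims.spectrum import CentroidSpectrum


def render_species(entries, polarity=Polarity.NEGATIVE):
    """Build a noiseless spectrum from (composition, neutral mass, z,
    intensity) entries — a direct isotope rendering with no source model."""
    mz_parts, int_parts = [], []
    for composition, mass, z, intensity in entries:
        pattern = isotope_pattern(composition)
        peaks = np.asarray(render_ion_peaks(pattern, mass, z, polarity))
        mz_parts.append(peaks[:, 0])
        int_parts.append(peaks[:, 1] * intensity)
    mz = np.concatenate(mz_parts)
    inten = np.concatenate(int_parts)
    keep = inten > 0
    return CentroidSpectrum(mz[keep], inten[keep], polarity)


@pytest.fixture(scope="module")
def rna6k():
    return parse_sequence("rArGrCrU" * 5)  # ~6.4 kDa


def clean_model():
    """Source model with no adducts and no fragmentation: the spectrum
    contains exactly the sample species."""
    return SourceResponseModel(lambda0=0.0, base_loss_channels=())


class TestSeriesDetection:
    def test_single_series_exact_recovery(self, rna6k):
        M = rna6k.monoisotopic_mass()
        spec = render_species([(rna6k.composition(), M, 5, 1000.0)])
        settings = DeconvolutionSettings(charge_range=(2, 10))
        series = detect_isotopologue_series(spec, settings)
        assert len(series) == 1
        assert series[0].z == 5
        expected_mz = (M - 5 * 1.00727646688) / 5
        assert series[0].monoisotopic_mz == pytest.approx(expected_mz, abs=1e-6)

    def test_recovery_with_missing_isotopologue(self, rna6k):
        M = rna6k.monoisotopic_mass()
        spec = render_species([(rna6k.composition(), M, 5, 1000.0)])
        # delete one interior isotopologue
        keep = np.ones(len(spec), dtype=bool)
        keep[3] = False
        spec2 = CentroidSpectrum(spec.mz[keep], spec.intensity[keep], spec.polarity)
        series = detect_isotopologue_series(spec2, DeconvolutionSettings(charge_range=(2, 10)))
        assert len(series) == 1 and series[0].z == 5

    def test_monoisotopic_recovered_when_below_threshold(self, rna6k):
        """If the monoisotopic peak is removed (as the intensity threshold
        does to weak series), envelope alignment still reports the correct
        monoisotopic m/z."""
        M = rna6k.monoisotopic_mass()
        spec = render_species([(rna6k.composition(), M, 5, 1000.0)])
        spec2 = CentroidSpectrum(spec.mz[2:], spec.intensity[2:], spec.polarity)
        series = detect_isotopologue_series(spec2, DeconvolutionSettings(charge_range=(2, 10)))
        expected_mz = (M - 5 * 1.00727646688) / 5
        assert series[0].monoisotopic_mz == pytest.approx(expected_mz, abs=5e-3)

    def test_empty_spectrum(self):
        spec = CentroidSpectrum(np.array([]), np.array([]))
        assert detect_isotopologue_series(spec, DeconvolutionSettings()) == []

    def test_harmonic_charge_not_preferred(self, rna6k):
        """A z=4 series must not be read at z=8 (half spacing) even though
        the larger charge wins ties."""
        M = rna6k.monoisotopic_mass()
        spec = render_species([(rna6k.composition(), M, 4, 1000.0)])
        series = detect_isotopologue_series(spec, DeconvolutionSettings(charge_range=(2, 15)))
        assert [s.z for s in series] == [4]


class TestCombineAndExclude:
    def test_two_charge_states_one_component(self, rna6k):
        M = rna6k.monoisotopic_mass()
        comp_ = rna6k.composition()
        spec = render_species([(comp_, M, 4, 500.0), (comp_, M, 5, 800.0)])
        components = deconvolve(spec, DeconvolutionSettings(charge_range=(2, 10)))
        assert len(components) == 1
        c = components[0]
        assert c.charges == (4, 5)
        assert abs(c.mass - M) / M * 1e6 < 30  # within merge tolerance

    def test_adduct_on_single_charge_state_excluded(self, rna6k):
        """A species present on one charge state only (the residual-adduct
        situation) is suppressed at min_detected_charges=2 and appears at
        min_detected_charges=1."""
        from olims.chem import comp
        M = rna6k.monoisotopic_mass()
        flp = rna6k.composition()
        ha = flp + comp(C=6, H=15, N=1)
        M_ha = M + 101.120450
        entries = [(flp, M, z, 1000.0) for z in (3, 4, 5, 6)]
        entries.append((ha, M_ha, 3, 400.0))  # adduct only on lowest z
        spec = render_species(entries)
        strict = deconvolve(spec, DeconvolutionSettings(charge_range=(2, 10)))
        assert len(strict) == 1 and abs(strict[0].mass - M) < 0.5
        loose = deconvolve(
            spec,
            DeconvolutionSettings(charge_range=(2, 10), min_detected_charges=1),
        )
        masses = sorted(c.mass for c in loose)
        assert len(loose) == 2
        assert masses[1] - masses[0] == pytest.approx(101.1204, abs=0.05)

    def test_mz_cap_equivalent_to_min_charges(self, rna6k):
        """Capping the m/z range below the lowest charge state gives the
        same component mass list as the min-detected-charges rule."""
        from olims.chem import comp
        M = rna6k.monoisotopic_mass()
        flp = rna6k.composition()
        ha = flp + comp(C=6, H=15, N=1)
        entries = [(flp, M, z, 1000.0) for z in (3, 4, 5, 6)]
        entries.append((ha, M + 101.120450, 3, 400.0))
        spec = render_species(entries)
        by_min_charges = deconvolve(spec, DeconvolutionSettings(charge_range=(2, 10)))
        z3_mz = (M - 3 * 1.00727646688) / 3
        capped = deconvolve(
            spec,
            DeconvolutionSettings(
                charge_range=(2, 10),
                min_detected_charges=1,
                mz_range_cap=(0.0, z3_mz - 5.0),
            ),
        )
        assert [round(c.mass, 2) for c in capped] == [
            round(c.mass, 2) for c in by_min_charges
        ]

    def test_output_mass_range_filter(self, rna6k):
        M = rna6k.monoisotopic_mass()
        comp_ = rna6k.composition()
        spec = render_species([(comp_, M, 4, 500.0), (comp_, M, 5, 800.0)])
        none = deconvolve(
            spec,
            DeconvolutionSettings(charge_range=(2, 10), output_mass_range=(1000.0, 2000.0)),
        )
        assert none == []


class TestEndToEndRoundTrip:
    @pytest.mark.parametrize("n_species", [1, 2, 3, 5])
    def test_multi_species_roundtrip(self, rna6k, n_species):
        """Noiseless spectra of 1-5 species: every neutral mass recovered
        within the merge tolerance, abundance ranks exact."""
        from olims.chem import Base
        flp = SpeciesDefinition("FLP", SpeciesKind.FLP)
        candidates = [
            (flp, None),
            (SpeciesDefinition("+1HA", SpeciesKind.ALKYLAMINE_ADDUCT, "HA"), None),
            (SpeciesDefinition("-A", SpeciesKind.BASE_LOSS_NEUTRAL, base=Base.A), None),
            (SpeciesDefinition("-G", SpeciesKind.BASE_LOSS_NEUTRAL, base=Base.G), None),
            (SpeciesDefinition("+2HA", SpeciesKind.ALKYLAMINE_ADDUCT, "HA", multiplicity=2), None),
        ]
        fractions = [0.55, 0.22, 0.12, 0.08, 0.03][:n_species]
        fractions = [f / sum(fractions) for f in fractions]
        sample = SampleComposition(
            rna6k,
            tuple((candidates[i][0], fractions[i]) for i in range(n_species)),
        )
        spec = simulate_spectrum(sample, clean_model(), SourceConditions())
        components = deconvolve(spec, DeconvolutionSettings(charge_range=(2, 10)))
        assert len(components) == n_species
        M = rna6k.monoisotopic_mass()
        truth = sorted(
            ((M + candidates[i][0].neutral_mass_delta, fractions[i]) for i in range(n_species)),
            key=lambda t: t[0],
        )
        for component, (mass, _) in zip(components, truth):
            assert abs(component.mass - mass) / mass * 1e6 < 30
        # abundance rank order
        got_rank = np.argsort([-c.intensity for c in components])
        want_rank = np.argsort([-f for _, f in truth])
        assert np.array_equal(got_rank, want_rank)

    def test_total_component_intensity_bounded(self, rna6k):
        sample = SampleComposition.pure(rna6k)
        spec = simulate_spectrum(sample, clean_model(), SourceConditions())
        components = deconvolve(spec, DeconvolutionSettings(charge_range=(2, 10)))
        assert sum(c.intensity for c in components) <= spec.total_intensity() + 1e-6

    def test_monotone_filtering(self, rna6k):
        """Raising the thresholds never increases the component count."""
        sample = SampleComposition(
            rna6k,
            (
                (SpeciesDefinition("FLP", SpeciesKind.FLP), 0.9),
                (SpeciesDefinition("+1HA", SpeciesKind.ALKYLAMINE_ADDUCT, "HA"), 0.1),
            ),
        )
        spec = simulate_spectrum(sample, clean_model(), SourceConditions(), seed=42)
        counts = []
        for rel in (0.0, 0.01, 0.05, 0.2):
            settings = DeconvolutionSettings(charge_range=(2, 10), rel_intensity_threshold=rel)
            counts.append(len(deconvolve(spec, settings)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_noise_robustness(self, sirna_preset):
        """With the default noise model, the recovered FLP mass stays
        within 10 ppm of truth in at least 90% of seeded replicates."""
        M = sirna_preset.sequence.monoisotopic_mass()
        settings = DeconvolutionSettings(charge_range=(4, 15))
        ok = 0
        n = 20
        for seed in range(n):
            spec = simulate_spectrum(
                sirna_preset.sample(), sirna_preset.model,
                SourceConditions(ce_volts=45.0), seed=seed,
            )
            components = deconvolve(spec, settings)
            if not components:
                continue
            flp = max(components, key=lambda c: c.intensity)
            if abs(flp.mass - M) / M * 1e6 <= 10.0:
                ok += 1
        assert ok >= int(0.9 * n)


class TestSettingsValidation:
    def test_invalid_charge_range(self):
        with pytest.raises(ValueError):
            DeconvolutionSettings(charge_range=(5, 2))

    def test_invalid_min_charges(self):
        with pytest.raises(ValueError):
            DeconvolutionSettings(min_detected_charges=0)
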