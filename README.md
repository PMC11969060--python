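# olims

Intact-mass LC-HESI-MS analysis toolkit for chemically modified
oligonucleotide therapeutics.

## The problem

Therapeutic oligonucleotides (antisense oligonucleotides, siRNAs) are
characterised by ion-pair reversed-phase LC coupled to high-resolution
electrospray mass spectrometry. Two LC-MS artifacts complicate impurity
profiling with alkylamine/fluoroalcohol mobile phases such as
hexylamine/HFIP:

* **alkylamine adducts** (+k x 101.1204 Da for hexylamine) that survive
  ionisation and concentrate on the lowest charge states, and
* **in-source nucleobase loss** ([M−nH−B]ⁿ⁻ neutral loss, or
  [M−(n+1)H−B⁻]ⁿ⁻ with the base leaving as an anion), which fakes abasic
  impurities that were never in the vial.

Raising the in-source collision energy (CE) strips adducts but promotes
base loss; the practical optimum is chemistry-dependent: 2' modifications
(OMe, MOE, F) stabilise the glycosidic bond, so RNA-like analytes
tolerate more CE than deoxy backbones, and positive-mode ions tolerate
more than negative. Residual adducts on the lowest charge states can
then be excluded at the software level: deconvolution that requires a
minimum number of detected charge states (or caps the m/z range below the
lowest charge state) drops any species seen at a single charge state.

`olims` implements this entire workflow as importable, testable code:

| module | what it does |
| --- | --- |
| `olims.chem` | sequence mini-notation, elemental composition, exact masses |
| `olims.species` | adduct/base-loss/PO-substitution ledger, theoretical m/z |
| `olims.isotopes` | aggregated isotope patterns, ion isotopologue series |
| `olims.simulate` + `olims.presets` | phenomenological HESI spectrum generator |
| `olims.deconvolve` | isotope-resolved charge-state deconvolution + exclusion rules |
| `olims.quantify` | impurity matching, fractional abundance, sweeps, spike-ins |
| `olims.workflow` + `olims.cli` | end-to-end scenarios, YAML config, `olims` CLI |

Because vendor instrument data are not redistributable, the simulator is a
first-class component: it encodes the observed source-condition trends
(logistic CE responses, linear temperature shifts, charge-envelope
movement) so every downstream stage can be exercised and verified without
an instrument. See `docs/methods.md` for the model and its limits.

## Sequence notation

One token per residue: optional sugar prefix `d` (2'-deoxy), `r` (ribo),
`m` (2'-OMe), `e` (2'-MOE), `f` (2'-F), then base `A G C U T` or `5mC`.
`*` between residues marks a phosphorothioate linkage. Examples:

```
dA*dT                  PS dinucleotide
mU rA fC               2'-OMe-U, ribo-A, 2'-F-C, phosphodiester
eG*eA*e5mC*...         MOE gapmer wing with 5-methyl-C
```

Default terminals are 5'-OH/3'-OH (a 5'-phosphate is a flag). To analyse a
real drug product, transcribe its sequence into this notation and pass it
as `sequence_override` — the packaged presets ship synthetic placeholder
sequences of matching length and chemistry class, not the drug sequences.

## Worked example

Simulate the siRNA preset at 0 V CE (adducts abundant), deconvolve with
charge states −4 and above, and match against the impurity table:

```python
from olims import (DeconvolutionSettings, SourceConditions, deconvolve,
                   get_preset, match_impurities, simulate_spectrum)
from olims.species import build_impurity_table

preset = get_preset("sirna")
spectrum = simulate_spectrum(preset.sample(), preset.model, SourceConditions(ce_volts=0.0))
components = deconvolve(spectrum, DeconvolutionSettings(charge_range=(4, 15)))
report = match_impurities(components, build_impurity_table(preset.sequence))
print(report.table)
```

prints

```
species  theoretical_mass_Da  observed_mass_Da  mass_error_ppm    intensity  fractional_abundance_pct
    FLP            6788.9982         6788.9982          0.0000 8311748.0698                   87.3062
   +1HA            6890.1187         6890.1187          0.0000 1091728.3215                   11.4675
   +2HA            6991.2391         6991.2385         -0.0944  116745.1129                    1.2263
```

At 0 V the full-length product carries ~13% hexylamine-adduct signal
(one and two adducts, +101.12 Da each, recovered within a fraction of a
ppm). Sweeping CE over the acquisition grid and taking the argmax of the
FLP fractional abundance gives the per-chemistry optima:

```
 ce_volts    FLP  adducts  base_loss
     0.00  87.31    12.69       0.00
    30.00  96.22     3.78       0.00
    45.00 100.00     0.00       0.00
    55.00  88.55     0.00      11.45
    65.00  43.06     0.00      56.94
optimum CE: 45 V        (siRNA, negative mode)
```

The `examples/` scripts walk each capability: masses and ledgers (`01`),
simulate + deconvolve (`02`), CE-sweep optima (`03`), PO spike-in
linearity (`04`), packaged scenarios and the CLI (`05`).

## CLI

```
olims mass seqs.txt                      # formula + masses per sequence
olims table seqs.txt --mobile-phase TBuAA
olims simulate --preset sirna --ce 45 --seed 3 --out spec.mzML
olims deconvolve spec.mzML --out components.csv
olims run ce_sweep_negative --preset sirna --seed 3 --out run_out
```

Scenarios: `ce_sweep_negative`, `ce_sweep_positive`, `temp_sweeps`,
`spikein`, `tbuaa_compare`. Exit codes: 0 ok, 1 user error, 2 internal.
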