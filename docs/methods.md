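# Methods

This note documents the models, numerical choices and limitations behind
`olims`. It is written for a reader deciding whether a result produced by
this package transfers to real instrument data.

## Mass and composition model

Residues are nucleoside units (base + sugar moiety); each internucleotide
bridge contributes HPO₃ (phosphodiester) or HPO₂S (phosphorothioate — one
non-bridging oxygen replaced by sulfur, +15.977156 Da) and condenses out
one water. Terminals default to 5'-OH/3'-OH, the synthesis standard for
therapeutic oligonucleotides; a 5'-monophosphate is available as a flag.
Sugar modifications are composition deltas on ribose: 2'-OMe = +CH₂,
2'-MOE = +C₃H₆O (OH → O-CH₂CH₂-O-CH₃), 2'-F = OH → F.

Atomic constants are frozen in `olims.constants` (CIAAW/IUPAC monoisotopic
masses and representative isotopic abundances) rather than looked up at
run time, so every reported mass is bit-reproducible. Average atomic
masses are the abundance-weighted means of those same isotope tables; they
agree with the conventional standard atomic weights to the weights' quoted
precision, and make the package self-consistent: the mean of a computed
isotope pattern equals average − monoisotopic mass to <1e−4 Da by
construction, which the test suite asserts across modules.

Charging is modelled as proton transfer (m/z = (M ∓ z·1.00727646688)/z);
the electron mass is not tracked separately, identically on the simulation
and deconvolution sides, so the ~0.5 mDa/charge refinement cancels in
every round trip.

### Base-loss bookkeeping

Gas-phase N-glycosidic cleavage releases a nucleobase either as a neutral
([M−nH−B]ⁿ⁻) or as an anion carrying away one charge
([M−(n+1)H−B⁻]ⁿ⁻). The departing anion is the deprotonated base [B−H]⁻,
whose mass is B − m(H⁺) under proton-level bookkeeping, so the product
ion's m/z is (M − B − n·m(H⁺))/n for both channels: they differ only in
the charge state at which the product appears (the charged channel lands
one charge below its precursor). Re-neutralising either product recovers
M − B exactly, which is why a deconvolved result cannot distinguish the
channels and the impurity table carries one −B row per base.

## Isotope patterns

Patterns are computed at unit-mass (nominal neutron-count) binning by the
standard polynomial method: each element's single-atom distribution is
raised to its atom count by repeated-squaring convolution, then elements
are convolved together. Each bin carries its abundance-weighted mean mass
offset. Only the negligible high-mass tail is pruned (default threshold
1e−10 per step); interior bins are never dropped, so accuracy is limited
by float arithmetic — equivalence with brute-force isotopologue
enumeration is asserted to total-variation distance <1e−9 for small
molecules. At 120k resolving power on 6–8 kDa oligonucleotides adjacent
nominal-mass bins are resolved but their internal fine structure is not,
so this aggregation matches the instrument regime; hyperfine calculation
is out of scope.

## The HESI simulator

The simulator is phenomenological: it encodes the *trends* of
ion-pair-reversed-phase HESI of oligonucleotides as smooth parametric
responses, not droplet physics (no CRM/CEM mechanism, no chromatography).
All CE responses are logistic — the observed behaviour is monotone and
bounded, and a logistic encodes that with two parameters — with linear
temperature shifts of the midpoints.

Per sample species, intensity is distributed as:

1. **Charge envelope**: discrete Gaussian over z ∈ [z_min, z_max] with
   mean μ_z and width σ_z; μ_z shifts with vaporiser temperature
   (dμ_z/dVT, default +0.010 charges/°C: high charge states appear only
   under hot, denaturing spray). High charge states are additionally
   depleted at high CE (rate 0.0015 per V per charge above z=7), because
   coulombic repulsion lowers their critical fragmentation energy.
2. **Adducts**: per charge state, adduct count k = 0..3 is
   truncated-Poisson with mean λ(z) = λ₀·exp(−γ(z−z_min))·s(CE,T): γ>0
   concentrates adducts on the lowest charge states; the survival s is a
   falling logistic in CE (midpoint c50_adduct, width w_a) whose midpoint
   drops with both source temperatures (ITT 0.03 V/°C, vaporiser
   0.05 V/°C — the vaporiser matters more, so a cold vaporiser leaves the
   most adducts).
3. **Base loss**: a CE-dependent fraction of each adduct-free precursor is
   converted per channel: rising logistic with a per-base midpoint
   (purines more labile than pyrimidines; 2'-modified sugars ~8–15 V
   higher than deoxy), lowered by κ volts per charge above z_min (higher
   charge states fragment earlier). Charged-channel products appear at
   z−1, neutral at z. Base loss is applied only to adduct-free ions: at
   the CE where fragmentation matters the adducts are already stripped,
   and mixed adduct+fragment ions are not tracked.
4. **Positive mode**: its own (lower, narrower) charge envelope, adduct
   survival midpoint shifted up (+26 V) with λ₀ doubled (more adducts on
   fewer charge states), base-loss midpoints shifted up (+20–27 V,
   greater gas-phase stability).

Every ion is rendered as its full isotopologue series (patterns cached per
composition), clipped to the scan range (default 400–2500 m/z), and peaks
that coincide to 1e−6 m/z are merged — the neutral and charged loss of the
same base at the same observed z land on identical centroids by design.

**Noise model** (applied only when a seed is given; `seed=None` is the
noiseless expectation): multiplicative log-normal intensity noise with 5%
CV (mean-preserving), Gaussian m/z jitter of 2 ppm, and a sparse uniform
baseline of 200 peaks below 0.1% of the base peak. Sweeps derive one
substream per grid index from the master seed by counter-based
`SeedSequence` spawning, so results are independent of sweep order.

**Presets** (`olims.presets`) freeze one parameter set per chemistry
class, calibrated once so the full pipeline lands on each class's known
optimum CE: siRNA-class (partially 2'-OMe RNA, PO backbone; charged G
loss dominant, purine c50 63 V, optimum 45 V negative), MOE-gapmer-class
(deoxy core, neutral A loss dominant, c50 48 V, optimum 30 V negative),
and PS-DNA-class (c50 55 V negative; optimum 65–70 V positive). The
preset sequences are synthetic placeholders of matching length and
chemistry; every entry point accepts a sequence override. The TBuAA
preset models the tributylammonium-acetate mobile phase as a lower,
narrower charge envelope, TBA adducts that survive to much higher CE, and
a 0.35 relative ionisation efficiency; TBA N-oxide (+O, an assumed
N-oxide composition) is carried in the ledger table but not emitted as a
spectral species.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: chromatographic co-elution and truncation
products (n−1mers), real Orbitrap noise statistics and dynamic range,
space-charge effects, adduct heterogeneity (Na/K present but default-off),
fine isotope structure, and any CE/temperature interaction beyond linear
midpoint shifts. Passing the pipeline tests shows the *analysis logic* is
correct under controlled conditions, not that a particular instrument will
produce these exact abundances.

## Deconvolution

Three stages, mirroring commercial intact-mass software behaviourally
(printed defaults: 1% relative intensity, 30 ppm merge tolerance, S/N 3,
min 2 detected charges, output mass 1000–8000 Da; charge range 2–15 for
~7 kDa RNA, 2–10 for shorter ASOs):

1. **Thresholding.** Relative-intensity cut against the base peak, then an
   S/N cut against a local noise floor estimated from *isolated* peaks
   (no neighbour within 1.05 m/z): baseline noise is sparse and isolated,
   whereas any genuine ion has isotopologue companions within one neutron
   spacing. Windows with fewer than five isolated peaks get a zero floor —
   the cut disables itself on clean spectra rather than discard real
   signal. An optional m/z cap implements the "put the lowest charge state
   out of range" strategy.
2. **Series detection.** Greedy, highest apex first. Each candidate charge
   z in range is scored by walking the ±1.00336/z grid (tolerance = merge
   tolerance, capped at 0.3 spacing) and counting matched peaks, then
   summed intensity; ties prefer larger z (the tighter grid is harder to
   match by chance). Three guards matter in practice:
   * a *fill-fraction* requirement (≥60% of walked grid positions
     matched) rejects half-spaced 2z harmonics;
   * a *per-series floor* (members must exceed 0.5% of the series apex)
     stops a walk from drifting through deep isotope tails into a
     neighbouring species' envelope;
   * *off-grid pruning*: members whose fractional-bin offset from the
     apex-anchored grid is an outlier (≥max(3.5·1.4826·MAD, 0.02 bins))
     are removed. This is what separates species whose mass deltas are
     near-integer neutron multiples — the PS→PO substitution is −15.92
     neutron units, −A vs −G differ by 15.94 — which otherwise
     cross-contaminate at trace-level thresholds.

   The monoisotopic member is then located by aligning the observed
   envelope against the expected pattern for an oligonucleotide of that
   mass — a nucleotide analogue of the protein "averagine" model, in two
   flavours (phosphodiester, and phosphorothioate whose sulfur broadens
   the envelope) — because the true monoisotopic peak of a weak series
   routinely falls below the intensity threshold and taking the leftmost
   *observed* peak would bias the mass by +1 neutron.
3. **Charge combination.** Series convert to neutral masses, single-linkage
   grouped within the merge tolerance (ppm, against the intensity-weighted
   running mean), then the exclusion rules apply: fewer distinct charge
   states than the minimum → dropped (this is what removes residual
   low-charge-state adducts), outside the output mass range → dropped.
   Component intensity is the sum over its series.

Retention time is out of scope; "sliding-window" averaging over an elution
profile reduces to `average_spectra`, which clusters concatenated
centroids within 10 ppm and intensity-weights each cluster — averaging n
scans shrinks jitter and intensity noise by ~√n, as on-instrument
averaging does.

## Quantification

Components match to the nearest impurity-table mass within an absolute
target tolerance (1 Da default — at ~6.5 kDa this separates everything in
the ledger, including PO at −15.977 Da). One component per species
(highest intensity wins; losers join the unmatched list). Fractional
abundance is percent of *matched* intensity (the reporting convention of
targeted impurity tables); a flag switches the denominator to all
components. Sweep optima are the argmax of FLP fractional abundance,
ties resolving to the mildest setting. Spike-in linearity is ordinary
least squares of recovered abundance (%) against spiked percentage.

The packaged spike-in scenario runs at 40 V CE — mild optimized
conditions, per the method's own rationale that quantification should
happen where in-source impurity generation is minimal — and averages
three seeded acquisitions per level. Observed behaviour across seeds:
slope 0.95–0.97, R² ≥ 0.99. The ~3–5% slope deficit is real and
explained: the denominator includes the small in-source adduct and
base-loss components, and spike levels below ~0.5% sit at the simulated
baseline-noise floor and may recover as zero.

## Numerical and degenerate-input choices

* Empty spectra deconvolve to empty component lists (not an error);
  empty component lists produce empty reports.
* Compositions are closed under addition; subtraction below zero atoms
  raises (a base loss from a species lacking that base is skipped by the
  simulator, not fabricated).
* Metal adducts (+Na−H, +K−H) are mass-only deltas: they displace a
  proton, which an integer composition cannot express; they are
  default-off in the ledger.
* `polyfit`-based OLS; R² defined as 1 on a zero-variance response.
* All randomness flows through a single integer seed via
  `numpy.random.SeedSequence`; fixed config + seed reproduces scenario
  CSV artifacts byte-for-byte.

## Problem sizes in the test and acceptance runs

Test analytes are 10–21-mers (3.2–7.2 kDa); sweeps use the 8-point
negative and 11-point positive CE grids; the spike-in uses 6 levels ×3
averaged scans; the noise-robustness check runs 20 seeded replicates.
These sizes make the full suite and the acceptance script each complete
in seconds while exercising every stage at realistic mass scale.
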