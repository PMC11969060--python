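"""Trace-level PO impurity quantification: spike-in linearity.

Spikes a PO impurity (one phosphorothioate linkage replaced by
phosphodiester, -15.977 Da) into a PS DNA analyte at 0.02-3% of total,
averages three seeded acquisitions per level, and fits recovered vs
spiked abundance. Run twice with the same seed for identical numbers.
"""

import dataclasses

from olims import spikein_linearity
from olims.presets import get_preset
from olims.species import Polarity
from olims.workflow import default_settings, run_spikein_levels

preset = get_preset("ps-dna")
settings = dataclasses.replace(
    default_settings(preset, Polarity.NEGATIVE), rel_intensity_threshold=0.0
)
levels = (0.0002, 0.001, 0.005, 0.01, 0.02, 0.03)
_, results = run_spikein_levels(
    preset, levels, ce_volts=40.0, settings=settings, seed=7
)
print("spiked%   recovered%")
for frac, report in results:
    print(f"{100 * frac:7.2f}   {report.abundance('PO'):9.4f}")
slope, intercept, r2 = spikein_linearity(results, "PO")
print(f"\nslope = {slope:.4f}, intercept = {intercept:.4f}, R^2 = {r2:.5f}")
print()
print("Recovery is linear across two orders of magnitude; the lowest")
print("levels sit at the baseline-noise floor and may read as zero.")
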