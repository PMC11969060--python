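"""Find the optimum in-source collision energy for each chemistry class.

Runs the full pipeline (simulate -> deconvolve -> quantify -> argmax) on
the printed CE grids: adducts are stripped as CE rises, base loss sets in
past a chemistry-dependent threshold, and the optimum is the grid point
with the highest full-length-product fractional abundance.
"""

from olims.presets import get_preset
from olims.species import Polarity
from olims.workflow import NEGATIVE_CE_GRID, POSITIVE_CE_GRID, default_settings, run_sweep

for name, grid, polarity in (
    ("sirna", NEGATIVE_CE_GRID, Polarity.NEGATIVE),
    ("moe-aso", NEGATIVE_CE_GRID, Polarity.NEGATIVE),
    ("ps-dna", POSITIVE_CE_GRID, Polarity.POSITIVE),
):
    preset = get_preset(name)
    settings = default_settings(preset, polarity)
    _, _, summary = run_sweep(preset, grid, polarity, settings)
    print(f"== {name} ({polarity.value} mode)")
    print(summary.table.to_string(index=False, float_format="%.2f"))
    print(f"optimum CE: {summary.optimum:g} V\n")

print("The 2'-modified siRNA tolerates 45 V before fragmenting; the")
print("MOE/DNA gapmer's deoxy core fragments earlier (optimum 30 V); in")
print("positive mode ions are more stable but more adducted, pushing the")
print("optimum to 65-70 V.")
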