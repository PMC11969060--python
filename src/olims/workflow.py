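"""End-to-end scenario orchestration: simulate -> deconvolve -> quantify ->
summarize, with YAML-serializable run configuration and deterministic
artifact output.

Packaged scenarios reproduce the headline experiments of the method:

* ``ce_sweep_negative`` — in-source CE sweep (0-65 V grid) in negative
  mode; reports per-CE fractional abundances and the optimum CE.
* ``ce_sweep_positive`` — CE sweep 30-80 V in positive mode.
* ``temp_sweeps`` — ITT (150-350 °C) and vaporiser (150-350 °C) sweeps at
  fixed CE 30 V.
* ``spikein`` — PO impurity spiked at trace levels into a
  phosphorothioate analyte; linearity of recovery.
* ``tbuaa_compare`` — the same analyte sprayed from a tributylammonium
  acetate mobile phase (lower charge states, TBA/TBA-oxide adducts,
  reduced ionisation efficiency) against the hexylamine/HFIP preset.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .deconvolve import DeconvolutionSettings, deconvolve
from .io import write_mzml, write_peaklist_csv
from .presets import Preset, get_preset
from .quantify import (
    ImpurityReport,
    match_impurities,
    spikein_linearity,
    summarize_sweep,
)
from .simulate import DEFAULT_SPIKE_FRACTIONS, SourceConditions, simulate_ce_sweep
from .species import Polarity, SpeciesDefinition, SpeciesKind, build_impurity_table

logger = logging.getLogger(__name__)

SCENARIOS = (
    "ce_sweep_negative",
    "ce_sweep_positive",
    "temp_sweeps",
    "spikein",
    "tbuaa_compare",
)

NEGATIVE_CE_GRID = (0.0, 20.0, 25.0, 30.0, 45.0, 55.0, 60.0, 65.0)
POSITIVE_CE_GRID = tuple(float(v) for v in range(30, 85, 5))
ITT_GRID = (150.0, 250.0, 275.0, 350.0)
VT_GRID = (150.0, 250.0, 300.0, 350.0)


class WorkflowError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable run configuration; a run re-executed from its
    saved config and seed produces identical artifacts."""

    preset: str = "sirna"
    sequence_override: str | None = None
    ce_grid: tuple[float, ...] | None = None
    spike_fractions: tuple[float, ...] = DEFAULT_SPIKE_FRACTIONS
    spike_ce_volts: float = 40.0
    #: seeded acquisitions averaged per spike level (emulates averaging
    #: scans across the elution window)
    scans_per_level: int = 3
    deconvolution: dict = field(default_factory=dict)
    seed: int | None = None
    output_dir: str = "olims_run"

    def to_yaml(self) -> str:
        payload = dataclasses.asdict(self)
        payload = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in payload.items()
        }
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise WorkflowError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ce_grid", "spike_fractions"):
            if raw.get(key) is not None:
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)


def default_settings(preset: Preset, polarity: Polarity) -> DeconvolutionSettings:
    """Analyte-appropriate deconvolution settings.

    Charge states -4 and above (3 and above in positive mode, where the
    envelope sits lower); PS backbones get the sulfur-aware expected
    envelope for monoisotopic assignment.
    """
    z_lo = 4 if polarity is Polarity.NEGATIVE else 3
    averagine = "nucleotide-ps" if preset.sequence.n_ps_linkages else "nucleotide"
    return DeconvolutionSettings(
        charge_range=(z_lo, preset.charge_range[1]), averagine=averagine
    )


def _settings_from_config(
    preset: Preset, polarity: Polarity, overrides: dict
) -> DeconvolutionSettings:
    base = default_settings(preset, polarity)
    if not overrides:
        return base
    kwargs = dataclasses.asdict(base)
    for key, value in overrides.items():
        if key not in kwargs:
            raise WorkflowError(f"unknown deconvolution setting {key!r}")
        if isinstance(kwargs[key], tuple) and value is not None:
            value = tuple(value)
        kwargs[key] = value
    return DeconvolutionSettings(**kwargs)


def _write_report(report: ImpurityReport, path: Path) -> None:
    report.table.to_csv(path, index=False, float_format="%.6f")


def run_sweep(
    preset: Preset,
    ce_grid,
    polarity: Polarity,
    settings: DeconvolutionSettings,
    seed: int | None = None,
    cond_base: SourceConditions | None = None,
):
    """Simulate a CE sweep and quantify each grid point.

    Returns (list of (ce, spectrum), list of (ce, report), SweepSummary).
    """
    cond_base = cond_base or SourceConditions(polarity=polarity)
    table = build_impurity_table(preset.sequence, mobile_phase=preset.mobile_phase)
    sweep = simulate_ce_sweep(preset.sample(), preset.model, list(ce_grid), cond_base, seed)
    results = []
    for ce, spectrum in sweep:
        components = deconvolve(spectrum, settings)
        results.append((ce, match_impurities(components, table)))
    summary = summarize_sweep(results, table)
    return sweep, results, summary


def run_scenario(name: str, config: RunConfig) -> Path:
    """Execute one packaged scenario; returns the artifact directory.

    Artifacts: simulated spectra (mzML + peak-list CSVs), per-condition
    impurity reports (CSV), a sweep summary or linearity JSON, and the
    effective configuration echo.
    """
    if name not in SCENARIOS:
        raise WorkflowError(f"unknown scenario {name!r}; available: {SCENARIOS}")
    out = Path(config.output_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    preset = get_preset(config.preset, config.sequence_override)
    (out / "config.yaml").write_text(config.to_yaml())
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("olims")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        _SCENARIO_RUNNERS[name](preset, config, out)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
    return out


def _run_ce_sweep(preset: Preset, config: RunConfig, out: Path, polarity: Polarity):
    grid = config.ce_grid or (
        NEGATIVE_CE_GRID if polarity is Polarity.NEGATIVE else POSITIVE_CE_GRID
    )
    settings = _settings_from_config(preset, polarity, config.deconvolution)
    sweep, results, summary = run_sweep(preset, grid, polarity, settings, config.seed)
    write_mzml([s for _, s in sweep], out / "spectra.mzML")
    for (ce, spectrum), (_, report) in zip(sweep, results):
        tag = f"ce{ce:g}"
        write_peaklist_csv(spectrum, out / f"spectrum_{tag}.csv")
        _write_report(report, out / f"report_{tag}.csv")
    summary.table.to_csv(out / "sweep_summary.csv", index=False, float_format="%.6f")
    (out / "optimum.json").write_text(
        json.dumps({"optimum_ce_volts": summary.optimum}, indent=2) + "\n"
    )
    logger.info("optimum CE for %s (%s): %g V", preset.name, polarity.value, summary.optimum)


def _run_temp_sweeps(preset: Preset, config: RunConfig, out: Path):
    from .simulate import simulate_spectrum

    settings = _settings_from_config(preset, Polarity.NEGATIVE, config.deconvolution)
    table = build_impurity_table(preset.sequence, mobile_phase=preset.mobile_phase)
    for axis, grid, fixed in (
        ("itt", ITT_GRID, {"vap_temp_C": 300.0}),
        ("vt", VT_GRID, {"itt_temp_C": 275.0}),
    ):
        results = []
        spectra = []
        for index, temp in enumerate(grid):
            kwargs = dict(fixed)
            kwargs["itt_temp_C" if axis == "itt" else "vap_temp_C"] = temp
            cond = SourceConditions(ce_volts=30.0, **kwargs)
            import numpy as np

            sub = (
                np.random.SeedSequence(entropy=config.seed, spawn_key=(index,))
                if config.seed is not None
                else None
            )
            spectrum = simulate_spectrum(preset.sample(), preset.model, cond, sub)
            spectra.append(spectrum)
            report = match_impurities(deconvolve(spectrum, settings), table)
            results.append((temp, report))
            _write_report(report, out / f"report_{axis}{temp:g}.csv")
        summary = summarize_sweep(results, table, condition_name=f"{axis}_temp_C")
        summary.table.to_csv(out / f"{axis}_summary.csv", index=False, float_format="%.6f")
        write_mzml(spectra, out / f"spectra_{axis}.mzML")


def run_spikein_levels(
    preset: Preset,
    fractions,
    ce_volts: float,
    settings: DeconvolutionSettings,
    seed: int | None,
    scans_per_level: int = 3,
):
    """Simulate, average and quantify a PO spike-in series.

    Per level, ``scans_per_level`` seeded acquisitions are averaged before
    deconvolution (noiseless when seed is None). Returns
    (list of (fraction, averaged spectrum), list of (fraction, report)).
    """
    import numpy as np

    from .spectrum import average_spectra

    po = SpeciesDefinition("PO", SpeciesKind.PO_SUBSTITUTION)
    flp = SpeciesDefinition("FLP", SpeciesKind.FLP)
    cond = SourceConditions(ce_volts=ce_volts)
    table = build_impurity_table(preset.sequence, mobile_phase=preset.mobile_phase)
    from .simulate import SampleComposition, SimulationError, simulate_spectrum

    spectra, results = [], []
    for index, frac in enumerate(fractions):
        if not 0.0 <= frac <= 0.05:
            raise SimulationError(f"spike fraction {frac} outside [0, 0.05]")
        species = [(flp, 1.0 - frac)]
        if frac > 0:
            species.append((po, frac))
        sample = SampleComposition(preset.sequence, tuple(species))
        if seed is None:
            averaged = simulate_spectrum(sample, preset.model, cond)
        else:
            scans = [
                simulate_spectrum(
                    sample, preset.model, cond,
                    np.random.SeedSequence(entropy=seed, spawn_key=(index, r)),
                )
                for r in range(scans_per_level)
            ]
            averaged = average_spectra(scans)
        spectra.append((frac, averaged))
        results.append((frac, match_impurities(deconvolve(averaged, settings), table)))
    return spectra, results


def _run_spikein(preset: Preset, config: RunConfig, out: Path):
    overrides = {"rel_intensity_threshold": 0.0, **config.deconvolution}
    settings = _settings_from_config(preset, Polarity.NEGATIVE, overrides)
    series, results = run_spikein_levels(
        preset, config.spike_fractions, config.spike_ce_volts,
        settings, config.seed, config.scans_per_level,
    )
    for (frac, _), (_, report) in zip(series, results):
        _write_report(report, out / f"report_spike{100 * frac:g}pct.csv")
    write_mzml([s for _, s in series], out / "spectra.mzML")
    slope, intercept, r2 = spikein_linearity(results, "PO")
    (out / "linearity.json").write_text(
        json.dumps(
            {"species": "PO", "slope": slope, "intercept": intercept, "r_squared": r2},
            indent=2,
        )
        + "\n"
    )
    logger.info("spike-in linearity: slope=%.4f R2=%.5f", slope, r2)


def _run_tbuaa_compare(preset: Preset, config: RunConfig, out: Path):
    """Same analyte under HA/HFIP vs TBuAA mobile phases."""
    ha = preset
    tba = get_preset("tbuaa", config.sequence_override)
    rows = []
    for label, pre in (("HA-HFIP", ha), ("TBuAA", tba)):
        settings = _settings_from_config(pre, Polarity.NEGATIVE, config.deconvolution)
        grid = config.ce_grid or NEGATIVE_CE_GRID
        sweep, results, summary = run_sweep(pre, grid, Polarity.NEGATIVE, settings, config.seed)
        summary.table.to_csv(
            out / f"sweep_summary_{label}.csv", index=False, float_format="%.6f"
        )
        write_mzml([s for _, s in sweep], out / f"spectra_{label}.mzML")
        for ce, spectrum in sweep:
            rows.append(
                {
                    "mobile_phase": label,
                    "ce_volts": ce,
                    "total_intensity": spectrum.total_intensity(),
                    "max_charge_state": _max_flp_charge(spectrum, pre, settings),
                }
            )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "intensity_comparison.csv", index=False, float_format="%.6f")


def _max_flp_charge(spectrum, preset: Preset, settings: DeconvolutionSettings) -> int:
    components = deconvolve(spectrum, settings)
    M = preset.sequence.monoisotopic_mass()
    flp = [c for c in components if abs(c.mass - M) < 1.0]
    if not flp:
        return 0
    return max(max(c.charges) for c in flp)


_SCENARIO_RUNNERS = {
    "ce_sweep_negative": lambda p, c, o: _run_ce_sweep(p, c, o, Polarity.NEGATIVE),
    "ce_sweep_positive": lambda p, c, o: _run_ce_sweep(p, c, o, Polarity.POSITIVE),
    "temp_sweeps": _run_temp_sweeps,
    "spikein": _run_spikein,
    "tbuaa_compare": _run_tbuaa_compare,
}
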