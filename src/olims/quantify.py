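"""Impurity matching, fractional abundance, sweep summaries and spike-in
linearity.

Fractional abundance follows the reporting convention of targeted
impurity tables: each deconvolved component is matched to the nearest
theoretical mass within an absolute target tolerance (1 Da by default),
and abundances are expressed as percentages of the summed intensity of
*matched* species only. Unmatched components are listed but excluded from
the denominator (switchable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconvolve import DeconvolvedComponent


class QuantifyError(ValueError):
    pass


@dataclass
class ImpurityReport:
    """Matched species rows plus the leftover unmatched components.

    ``table`` columns: species, theoretical_mass_Da, observed_mass_Da,
    mass_error_ppm, intensity, fractional_abundance_pct. Matched rows'
    fractional abundances sum to 100%.
    """

    table: pd.DataFrame
    unmatched: list[DeconvolvedComponent] = field(default_factory=list)

    def abundance(self, species: str) -> float:
        """Fractional abundance (%) of one species; 0 if unobserved."""
        rows = self.table[self.table["species"] == species]
        if rows.empty:
            return 0.0
        return float(rows["fractional_abundance_pct"].iloc[0])

    @property
    def species_names(self) -> list[str]:
        return list(self.table["species"])


_REPORT_COLUMNS = [
    "species",
    "theoretical_mass_Da",
    "observed_mass_Da",
    "mass_error_ppm",
    "intensity",
    "fractional_abundance_pct",
]


def match_impurities(
    components: list[DeconvolvedComponent],
    impurity_table: pd.DataFrame,
    target_tolerance_da: float = 1.0,
    denominator: str = "matched",
) -> ImpurityReport:
    """Assign components to the nearest theoretical mass within tolerance.

    Nearest-wins per component; at most one component per species (highest
    intensity wins, losers fall back to the unmatched list). ``denominator``
    is "matched" (default) or "all" (include unmatched intensity in the
    fractional-abundance denominator).
    """
    if denominator not in ("matched", "all"):
        raise QuantifyError(f"unknown denominator mode {denominator!r}")
    theo = impurity_table.reset_index(drop=True)
    assignments: dict[int, DeconvolvedComponent] = {}
    unmatched: list[DeconvolvedComponent] = []
    for component in sorted(components, key=lambda c: -c.intensity):
        if len(theo):
            errors = np.abs(theo["theoretical_mass_Da"].to_numpy() - component.mass)
            best = int(np.argmin(errors))
        else:
            best = -1
        if best < 0 or errors[best] > target_tolerance_da or best in assignments:
            unmatched.append(component)
            continue
        assignments[best] = component
    matched_total = sum(c.intensity for c in assignments.values())
    denom = matched_total
    if denominator == "all":
        denom += sum(c.intensity for c in unmatched)
    rows = []
    for idx, component in sorted(assignments.items()):
        t_mass = float(theo["theoretical_mass_Da"].iloc[idx])
        rows.append(
            {
                "species": theo["name"].iloc[idx],
                "theoretical_mass_Da": t_mass,
                "observed_mass_Da": component.mass,
                "mass_error_ppm": (component.mass - t_mass) / t_mass * 1e6,
                "intensity": component.intensity,
                "fractional_abundance_pct": (
                    100.0 * component.intensity / denom if denom > 0 else 0.0
                ),
            }
        )
    return ImpurityReport(pd.DataFrame(rows, columns=_REPORT_COLUMNS), unmatched)


# ---------------------------------------------------------------------------
# Sweep summaries
# ---------------------------------------------------------------------------

#: Species-name prefixes defining report families.
_FAMILY_RULES = (
    ("FLP", lambda name, kind: kind == "FLP"),
    ("adducts", lambda name, kind: kind == "alkylamine_adduct" or kind == "metal_adduct"),
    ("base_loss", lambda name, kind: kind.startswith("base_loss")),
    ("PO", lambda name, kind: kind == "PO_substitution"),
)


def _family_of(name: str, impurity_table: pd.DataFrame) -> str:
    kinds = dict(zip(impurity_table["name"], impurity_table["kind"]))
    kind = kinds.get(name, "")
    for family, rule in _FAMILY_RULES:
        if rule(name, kind):
            return family
    return "other"


@dataclass
class SweepSummary:
    """Per-condition family abundances and the optimum condition.

    The optimum is the grid point with the highest FLP fractional
    abundance; exact ties resolve to the mildest (lowest) setting.
    """

    table: pd.DataFrame  # one row per condition, one column per family
    optimum: float
    condition_name: str = "ce_volts"


def summarize_sweep(
    results: list[tuple[float, ImpurityReport]],
    impurity_table: pd.DataFrame,
    condition_name: str = "ce_volts",
) -> SweepSummary:
    """Aggregate a condition sweep into family abundances and an optimum."""
    if len(results) < 2:
        raise QuantifyError("a sweep needs at least two grid points")
    values = [v for v, _ in results]
    if len(set(values)) != len(values):
        raise QuantifyError("duplicate conditions in sweep")
    rows = []
    for value, report in results:
        row = {condition_name: value, "FLP": 0.0, "adducts": 0.0, "base_loss": 0.0, "PO": 0.0, "other": 0.0}
        for _, r in report.table.iterrows():
            family = _family_of(r["species"], impurity_table)
            row[family] += r["fractional_abundance_pct"]
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(condition_name).reset_index(drop=True)
    best_flp = table["FLP"].max()
    optimum = float(table.loc[table["FLP"] == best_flp, condition_name].min())
    return SweepSummary(table=table, optimum=optimum, condition_name=condition_name)


# ---------------------------------------------------------------------------
# Spike-in linearity and replicates
# ---------------------------------------------------------------------------


def spikein_linearity(
    results: list[tuple[float, ImpurityReport]], impurity_name: str
) -> tuple[float, float, float]:
    """OLS fit of recovered fractional abundance (%) vs spiked percentage.

    Returns (slope, intercept, R^2). Spiked fractions are given as
    fractions of total (0.03 -> 3%); recovered abundances are already %.
    """
    if len(results) < 3:
        raise QuantifyError("linearity fit needs at least three levels")
    x = np.array([100.0 * frac for frac, _ in results])
    y = np.array([report.abundance(impurity_name) for _, report in results])
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def replicate_stats(reports: list[ImpurityReport]) -> pd.DataFrame:
    """Per-species mean, SD and %CV of fractional abundance across
    replicate injections."""
    if len(reports) < 2:
        raise QuantifyError("replicate statistics need at least two replicates")
    names = set(reports[0].species_names)
    for r in reports[1:]:
        if set(r.species_names) != names:
            raise QuantifyError("replicates report different species sets")
    rows = []
    for name in sorted(names):
        values = np.array([r.abundance(name) for r in reports])
        mean = values.mean()
        sd = values.std(ddof=1)
        rows.append(
            {
                "species": name,
                "mean_pct": mean,
                "sd_pct": sd,
                "cv_pct": 100.0 * sd / mean if mean > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["species", "mean_pct", "sd_pct", "cv_pct"])
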