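"""Frozen physical constants: atomic masses, weights and isotopic abundances.

Monoisotopic masses and isotopic abundances are the IUPAC/CIAAW 2021
recommendations; standard atomic weights are the conventional (abridged)
values. They are embedded as constants rather than looked up at run time so
that every mass this package reports is reproducible bit-for-bit across
installations.
"""

from __future__ import annotations

#: Elements supported in oligonucleotide compositions.
ELEMENTS = ("C", "H", "N", "O", "P", "S", "F")

#: Monoisotopic (lightest-isotope) atomic masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "F": 18.99840322,
}

#: Average atomic masses, Da, computed as the abundance-weighted mean over
#: the isotope tables below (see ``ISOTOPES``) so that average masses and
#: isotope-pattern means are mutually consistent by construction. They agree
#: with the standard atomic weights to their quoted precision.
AVERAGE_MASS: dict[str, float] = {
    "H": 1.00794075,
    "C": 12.01073590,
    "N": 14.00670321,
    "O": 15.99940492,
    "P": 30.97376163,
    "S": 32.06478724,
    "F": 18.99840322,
}

#: Mass of the proton, Da (CODATA). Charging is modelled as proton
#: transfer; the electron mass is not tracked separately, consistently on
#: both the simulation and the deconvolution side.
PROTON_MASS = 1.00727646688

#: Average spacing between adjacent isotopologue peaks of C/H/N/O-dominated
#: biomolecules, Da (the "averaged neutron" offset, dominated by 13C-12C).
NEUTRON_SPACING = 1.00336

#: Isotope tables: per element, a list of (mass offset from the lightest
#: isotope in Da, natural abundance). Offsets are exact isotope-mass
#: differences; abundances are the IUPAC representative values.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(0.0, 0.999885), (1.00627675, 0.000115)],
    "C": [(0.0, 0.9893), (1.0033548378, 0.0107)],
    "N": [(0.0, 0.99636), (0.9970349, 0.00364)],
    "O": [(0.0, 0.99757), (1.0042171, 0.00038), (2.0042449, 0.00205)],
    "P": [(0.0, 1.0)],
    "S": [(0.0, 0.9499), (0.9993878, 0.0075), (1.9957959, 0.0425), (3.9950096, 0.0001)],
    "F": [(0.0, 1.0)],
}
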