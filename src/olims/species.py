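"""Ledger of adduct, fragment and substitution species for intact-mass
impurity profiling, with theoretical m/z for any charge state and polarity.

Each :class:`SpeciesDefinition` is a neutral-mass delta relative to the
full-length product (FLP) mass M, plus the composition delta needed to
compute isotope patterns:

* alkylamine adducts: +k x amine (hexylamine HA, tributylamine TBA, or
  TBA N-oxide) retained non-covalently through ionisation;
* gas-phase nucleobase loss: the in-source cleavage of the N-glycosidic
  bond releases the base either as a neutral ([M-nH-B]^n-) or as an anion
  that carries away one charge ([M-(n+1)H-B^-]^n-). Both channels leave the
  same neutral composition M-B behind: in the charged channel the departing
  base anion [B-H]^- takes the glycosidic-bond proton bookkeeping with it,
  so re-neutralising the product ion recovers M-B exactly. The two channels
  therefore deconvolve to one neutral mass and differ only in the charge
  state at which the product appears (z vs z-1 of the precursor);
* PO substitution: one phosphorothioate linkage replaced by phosphodiester
  (S -> O, -15.977156 Da per site) — the classic synthesis impurity;
* metal adducts (Na/K, replacing a proton), default-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .chem import (
    BASE_COMPOSITION,
    Base,
    ElementalComposition,
    OligoChemError,
    OligoSequence,
    comp,
    monoisotopic_mass,
)
from .constants import PROTON_MASS


class SpeciesKind(str, Enum):
    FLP = "FLP"
    ALKYLAMINE_ADDUCT = "alkylamine_adduct"
    BASE_LOSS_NEUTRAL = "base_loss_neutral"
    BASE_LOSS_CHARGED = "base_loss_charged"
    PO_SUBSTITUTION = "PO_substitution"
    METAL_ADDUCT = "metal_adduct"
    COMBINATION = "combination"


class Polarity(str, Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"


#: Adduct composition deltas. Metal adducts displace one proton, which a
#: composition cannot express; their deltas are mass-only (no isotope
#: pattern shift beyond the monoisotopic approximation is tracked).
ADDUCT_COMPOSITION: dict[str, ElementalComposition] = {
    "HA": comp(C=6, H=15, N=1),  # hexylamine
    "TBA": comp(C=12, H=27, N=1),  # tributylamine
    "TBA_oxide": comp(C=12, H=27, N=1, O=1),  # modelled as the N-oxide
}

_NA_MINUS_H = 22.9897692820 - 1.00782503207
_K_MINUS_H = 38.9637064864 - 1.00782503207
ADDUCT_MASS_DELTA: dict[str, float] = {
    **{k: monoisotopic_mass(v) for k, v in ADDUCT_COMPOSITION.items()},
    "Na": _NA_MINUS_H,
    "K": _K_MINUS_H,
}

#: Monoisotopic mass shift of converting one PS linkage to PO (S -> O).
PS_TO_PO_DELTA = monoisotopic_mass(comp(S=1)) - monoisotopic_mass(comp(O=1))


@dataclass(frozen=True)
class SpeciesDefinition:
    name: str
    kind: SpeciesKind
    adduct_identity: str | None = None
    multiplicity: int = 1
    base: Base | None = None
    # mass-only delta for species without a representable composition delta
    extra_mass_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise OligoChemError("multiplicity must be >= 1")
        if self.kind in (SpeciesKind.ALKYLAMINE_ADDUCT, SpeciesKind.METAL_ADDUCT):
            if self.adduct_identity not in ADDUCT_MASS_DELTA:
                raise OligoChemError(
                    f"unknown adduct identity {self.adduct_identity!r}"
                )
        if self.kind in (SpeciesKind.BASE_LOSS_NEUTRAL, SpeciesKind.BASE_LOSS_CHARGED):
            if self.base is None:
                raise OligoChemError("base-loss species requires a base identity")

    @property
    def neutral_mass_delta(self) -> float:
        """Neutral-mass shift relative to the full-length product, Da."""
        k = self.multiplicity
        if self.kind is SpeciesKind.FLP:
            return 0.0
        if self.kind in (SpeciesKind.ALKYLAMINE_ADDUCT, SpeciesKind.METAL_ADDUCT):
            return k * ADDUCT_MASS_DELTA[self.adduct_identity]
        if self.kind in (SpeciesKind.BASE_LOSS_NEUTRAL, SpeciesKind.BASE_LOSS_CHARGED):
            return -monoisotopic_mass(BASE_COMPOSITION[self.base])
        if self.kind is SpeciesKind.PO_SUBSTITUTION:
            return -k * PS_TO_PO_DELTA
        if self.kind is SpeciesKind.COMBINATION:
            return self.extra_mass_delta
        raise OligoChemError(f"unhandled species kind {self.kind}")

    def apply_composition(self, flp: ElementalComposition) -> ElementalComposition:
        """Composition of this species given the FLP composition.

        Raises for species whose delta is mass-only (metal adducts,
        free-form combinations).
        """
        k = self.multiplicity
        if self.kind is SpeciesKind.FLP:
            return flp
        if self.kind is SpeciesKind.ALKYLAMINE_ADDUCT:
            return flp + k * ADDUCT_COMPOSITION[self.adduct_identity]
        if self.kind in (SpeciesKind.BASE_LOSS_NEUTRAL, SpeciesKind.BASE_LOSS_CHARGED):
            return flp - BASE_COMPOSITION[self.base]
        if self.kind is SpeciesKind.PO_SUBSTITUTION:
            return flp - k * comp(S=1) + k * comp(O=1)
        raise OligoChemError(
            f"species kind {self.kind.value} has no composition delta"
        )


@dataclass(frozen=True)
class IonSpecies:
    species: SpeciesDefinition
    z: int
    polarity: Polarity = Polarity.NEGATIVE

    def __post_init__(self) -> None:
        if self.z < 1:
            raise OligoChemError("charge must be >= 1")


def species_neutral_mass(M: float, species: SpeciesDefinition) -> float:
    """Neutral (deconvolved) mass of a ledger species given FLP mass M."""
    if M <= 0:
        raise OligoChemError("FLP mass must be positive")
    out = M + species.neutral_mass_delta
    if out <= 0:
        raise OligoChemError(
            f"species {species.name!r} delta drives mass non-positive"
        )
    return out


def mz_from_neutral(Ms: float, z: int, polarity: Polarity) -> float:
    """m/z of a z-fold (de)protonated ion of neutral mass Ms."""
    if not 1 <= z <= 30:
        raise OligoChemError(f"charge {z} outside supported range 1..30")
    if polarity is Polarity.NEGATIVE:
        out = (Ms - z * PROTON_MASS) / z
    else:
        out = (Ms + z * PROTON_MASS) / z
    if out <= 0:
        raise OligoChemError("non-positive m/z")
    return out


def neutral_from_mz(mz: float, z: int, polarity: Polarity) -> float:
    """Inverse of :func:`mz_from_neutral`."""
    if polarity is Polarity.NEGATIVE:
        return z * mz + z * PROTON_MASS
    return z * mz - z * PROTON_MASS


def mz(ion: IonSpecies, M: float) -> float:
    """Theoretical m/z of a ledger ion for FLP neutral mass M."""
    return mz_from_neutral(species_neutral_mass(M, ion.species), ion.z, ion.polarity)


# ---------------------------------------------------------------------------
# Impurity table
# ---------------------------------------------------------------------------


def default_species(
    seq: OligoSequence,
    mobile_phase: str = "HA-HFIP",
    max_adducts: int = 3,
    include_metal: bool = False,
    max_po_sites: int = 1,
) -> list[SpeciesDefinition]:
    """Default ledger for one analyte: FLP, amine adducts k=1..max, one
    base-loss entry per base present in the sequence, and PO substitution
    (only meaningful if the backbone carries PS linkages).
    """
    out = [SpeciesDefinition("FLP", SpeciesKind.FLP)]
    if mobile_phase == "HA-HFIP":
        for k in range(1, max_adducts + 1):
            out.append(
                SpeciesDefinition(
                    f"+{k}HA", SpeciesKind.ALKYLAMINE_ADDUCT, "HA", multiplicity=k
                )
            )
    elif mobile_phase == "TBuAA":
        out.append(SpeciesDefinition("+TBA", SpeciesKind.ALKYLAMINE_ADDUCT, "TBA"))
        out.append(
            SpeciesDefinition("+TBA_oxide", SpeciesKind.ALKYLAMINE_ADDUCT, "TBA_oxide")
        )
    else:
        raise OligoChemError(f"unknown mobile phase {mobile_phase!r}")
    bases_present = {r.base for r in seq.residues}
    # 5mC base loss folded under C chemistry is not assumed; each base gets
    # its own entry. Neutral vs charged channel share a neutral mass, so the
    # table needs one row per base.
    for b in sorted(bases_present, key=lambda b: b.value):
        out.append(SpeciesDefinition(f"-{b.value}", SpeciesKind.BASE_LOSS_NEUTRAL, base=b))
    if seq.n_ps_linkages >= 1:
        for k in range(1, max_po_sites + 1):
            label = "PO" if k == 1 else f"{k}PO"
            out.append(
                SpeciesDefinition(label, SpeciesKind.PO_SUBSTITUTION, multiplicity=k)
            )
    if include_metal:
        out.append(SpeciesDefinition("+Na", SpeciesKind.METAL_ADDUCT, "Na"))
        out.append(SpeciesDefinition("+K", SpeciesKind.METAL_ADDUCT, "K"))
    return out


def build_impurity_table(
    seq: OligoSequence,
    species: list[SpeciesDefinition] | None = None,
    mobile_phase: str = "HA-HFIP",
    **kwargs,
) -> pd.DataFrame:
    """Theoretical-mass table for reporting, sorted by ascending mass.

    Columns: name, kind, delta_Da, theoretical_mass_Da. Duplicate species
    names are an error.
    """
    if species is None:
        species = default_species(seq, mobile_phase=mobile_phase, **kwargs)
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        raise OligoChemError("duplicate species names in impurity table")
    M = seq.monoisotopic_mass()
    rows = [
        {
            "name": s.name,
            "kind": s.kind.value,
            "delta_Da": s.neutral_mass_delta,
            "theoretical_mass_Da": species_neutral_mass(M, s),
        }
        for s in species
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("theoretical_mass_Da", kind="stable")
        .reset_index(drop=True)
    )
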