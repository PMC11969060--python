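"""Packaged simulator presets for the three oligonucleotide chemistry
classes studied.

Each preset bundles a placeholder sequence of the right length and
chemistry class together with a frozen :class:`SourceResponseModel`. The
sequences are synthetic stand-ins — drug-product sequences are not
embedded; users analysing a real oligonucleotide should parse its actual
sequence and pass it in via ``sequence_override``.

The response parameters are documented constants, calibrated once so the
end-to-end pipeline (simulate -> deconvolve -> quantify -> argmax over the
CE grid) lands on the optimum collision energies characteristic of each
chemistry class: 45 V for the partially 2'-O-methylated siRNA strand in
negative mode, 30 V for the 2'-MOE/DNA gapmer ASO in negative mode, and
65-70 V for the phosphorothioate DNA in positive mode. The ordering
follows from the chemistry: 2' modification stabilises the glycosidic bond
(base loss sets in at higher CE), and positive-mode ions are more stable
still but carry more adducts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import Base, OligoSequence, parse_sequence
from .simulate import BaseLossChannel, SampleComposition, SourceResponseModel

#: Placeholder 21-mer ssRNA, partially 2'-O-methylated, PO backbone —
#: chemistry class of an siRNA antisense strand (synthetic sequence).
SIRNA_SEQUENCE = "mUrGrArCmUrArGrCrGrUmUrArCrGrArGmCrUrArGrA"

#: Placeholder 20-mer 5-10-5 gapmer: 2'-MOE wings (5mC in wings), central
#: 2'-deoxy gap, fully phosphorothioate — chemistry class of an MOE ASO
#: (synthetic sequence).
MOE_ASO_SEQUENCE = (
    "eG*eA*e5mC*eU*eU*" "dC*dA*dT*dG*dA*dC*dT*dG*dC*dA*" "eU*eG*e5mC*eA*eG"
)

#: Placeholder 20-mer fully phosphorothioate ssDNA (synthetic sequence).
PS_DNA_SEQUENCE = "dC*dA*dG*dT*dC*dT*dG*dA*dC*dG*dT*dA*dC*dT*dG*dA*dC*dT*dG*dC"


def _sirna_model() -> SourceResponseModel:
    # 2'-modified RNA: charged G loss dominates at high CE, neutral A and C
    # secondary; glycosidic bonds stabilised by the 2' substituent push the
    # base-loss midpoints high (~63 V for purines at the lowest charge).
    return SourceResponseModel(
        mu_z=6.0,
        sigma_z=1.4,
        z_min=3,
        z_max=10,
        lambda0=1.2,
        gamma=0.8,
        c50_adduct_volts=25.0,
        w_adduct_volts=6.0,
        base_loss_channels=(
            BaseLossChannel(Base.G, c50_volts=63.0, share=0.5, charged=True, width_volts=3.5),
            BaseLossChannel(Base.A, c50_volts=63.0, share=0.3, width_volts=3.5),
            BaseLossChannel(Base.C, c50_volts=69.0, share=0.2, width_volts=3.5),
        ),
        f_max_base_loss=0.8,
        kappa_volts_per_charge=1.0,
    )


def _moe_aso_model() -> SourceResponseModel:
    # Gapmer: the 2'-deoxy core fragments like DNA (neutral A loss
    # predominant, midpoint ~48 V); predominant charge state -4.
    return SourceResponseModel(
        mu_z=4.6,
        sigma_z=1.1,
        z_min=3,
        z_max=10,
        lambda0=1.2,
        gamma=0.8,
        c50_adduct_volts=18.0,
        w_adduct_volts=5.0,
        base_loss_channels=(
            BaseLossChannel(Base.A, c50_volts=48.0, share=0.6),
            BaseLossChannel(Base.G, c50_volts=52.0, share=0.3),
            BaseLossChannel(Base.C, c50_volts=58.0, share=0.1),
        ),
        f_max_base_loss=0.8,
        kappa_volts_per_charge=1.5,
    )


def _ps_dna_model() -> SourceResponseModel:
    # Fully PS DNA: least stable in the gas phase in negative mode; in
    # positive mode base loss shifts up ~27 V and adducting is heavier on
    # the few low charge states observed.
    return SourceResponseModel(
        mu_z=5.5,
        sigma_z=1.3,
        z_min=3,
        z_max=10,
        lambda0=1.2,
        gamma=0.8,
        c50_adduct_volts=22.0,
        w_adduct_volts=6.0,
        base_loss_channels=(
            BaseLossChannel(Base.A, c50_volts=55.0, share=0.6),
            BaseLossChannel(Base.G, c50_volts=58.0, share=0.3),
            BaseLossChannel(Base.C, c50_volts=64.0, share=0.1),
        ),
        f_max_base_loss=0.8,
        kappa_volts_per_charge=1.5,
        pos_mu_z=4.0,
        pos_sigma_z=0.9,
        pos_z_min=3,
        pos_z_max=6,
        pos_adduct_c50_shift=26.0,
        pos_lambda0_factor=2.0,
        pos_base_c50_shift=20.0,
    )


def _tbuaa_model() -> SourceResponseModel:
    # TBuAA mobile phase (neutral pH): envelope shifted to lower charge
    # states, lower overall ionisation efficiency, and tributylamine
    # adducts that survive to higher CE than hexylamine.
    model = _moe_aso_model()
    from dataclasses import replace

    return replace(
        model,
        mu_z=3.8,
        sigma_z=0.9,
        z_min=3,
        z_max=7,
        adduct_identity="TBA",
        lambda0=0.7,
        c50_adduct_volts=50.0,
        w_adduct_volts=8.0,
        ionisation_efficiency=0.35,
    )


@dataclass(frozen=True)
class Preset:
    name: str
    sequence: OligoSequence
    model: SourceResponseModel
    #: default deconvolution charge range for this analyte class
    charge_range: tuple[int, int]
    mobile_phase: str = "HA-HFIP"

    def sample(self) -> SampleComposition:
        return SampleComposition.pure(self.sequence)


def get_preset(name: str, sequence_override: str | None = None) -> Preset:
    """Look up a packaged preset: sirna, moe-aso, ps-dna or tbuaa."""
    registry = {
        "sirna": (SIRNA_SEQUENCE, _sirna_model, (2, 15), "HA-HFIP"),
        "moe-aso": (MOE_ASO_SEQUENCE, _moe_aso_model, (2, 10), "HA-HFIP"),
        "ps-dna": (PS_DNA_SEQUENCE, _ps_dna_model, (2, 10), "HA-HFIP"),
        "tbuaa": (MOE_ASO_SEQUENCE, _tbuaa_model, (2, 10), "TBuAA"),
    }
    if name not in registry:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(registry)}"
        )
    notation, model_fn, charge_range, mobile_phase = registry[name]
    seq = parse_sequence(sequence_override or notation, name=name)
    return Preset(name, seq, model_fn(), charge_range, mobile_phase)


PRESET_NAMES = ("sirna", "moe-aso", "ps-dna", "tbuaa")
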