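"""Experimental-design arithmetic for in vitro rumen batch cultures.

A treatment is a basal substrate (typically grass silage plus a compound
feed, dosed 1:1 on a dry-matter basis) topped with a protein supplement at
an isonitrogenous dose: supplements with different crude-protein (CP)
content receive different dry-matter doses so that every vessel gets the
same CP mass.  Because the supplements also differ in amino-acid
composition, the amount of each branched-chain amino acid (BCAA) — valine,
isoleucine, leucine — introduced per vessel differs between treatments and
must be tracked explicitly: it is the denominator of the downstream
BCAA-to-BCVFA conversion estimate.

Units follow the conventions of the data schema: dry matter in mg per
vessel, CP as a fraction of dry matter, amino acids in mmol per vessel,
vessel liquid volume in mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "InvalidSpecError",
    "MOLAR_MASS_G_PER_MOL",
    "BCVFA_PARTNER",
    "BCAAS",
    "BCVFAS",
    "AminoAcidConstants",
    "SupplementSpec",
    "BasalComponent",
    "TreatmentSpec",
    "isonitrogenous_dose",
    "diet_fractions",
    "bcaa_mmol_from_composition",
    "aa_percent_of_protein",
    "study_design",
]


class InvalidSpecError(ValueError):
    """A design spec violates its invariants (doses, fractions, keys)."""


#: Molar masses of the FREE amino acids, g/mol.  Residue masses (free mass
#: minus water) would understate the mass of supplement protein attributable
#: to each amino acid; the free-acid convention reproduces published
#: percent-of-protein figures from mmol dosing tables.
MOLAR_MASS_G_PER_MOL: dict[str, float] = {
    "Val": 117.15,
    "Ile": 131.17,
    "Leu": 131.17,
}

#: Oxidative deamination + decarboxylation maps each BCAA one-to-one onto a
#: branched-chain volatile fatty acid with one carbon fewer.
BCVFA_PARTNER: dict[str, str] = {
    "Val": "isobutyric",
    "Ile": "methylbutyric2",
    "Leu": "isovaleric",
}

BCAAS: tuple[str, ...] = ("Val", "Ile", "Leu")
BCVFAS: tuple[str, ...] = ("isobutyric", "methylbutyric2", "isovaleric")


@dataclass(frozen=True)
class AminoAcidConstants:
    """Molar masses and the BCAA -> BCVFA product mapping.

    The partner mapping must be a bijection onto the three BCVFAs; this is
    enforced at construction so a mistyped mapping fails loudly.
    """

    molar_mass_g_per_mol: dict[str, float] = field(
        default_factory=lambda: dict(MOLAR_MASS_G_PER_MOL)
    )
    bcvfa_partner: dict[str, str] = field(
        default_factory=lambda: dict(BCVFA_PARTNER)
    )

    def __post_init__(self) -> None:
        if set(self.bcvfa_partner) != set(self.molar_mass_g_per_mol):
            raise InvalidSpecError("partner mapping and molar masses must cover the same amino acids")
        if len(set(self.bcvfa_partner.values())) != len(self.bcvfa_partner):
            raise InvalidSpecError("BCAA -> BCVFA partner mapping must be a bijection")


DEFAULT_CONSTANTS = AminoAcidConstants()


@dataclass(frozen=True)
class SupplementSpec:
    """One protein supplement.

    Parameters
    ----------
    name
        Supplement identifier, e.g. ``"SBM"``.
    cp_frac
        Crude-protein fraction of supplement dry matter, in (0, 1].
    bcaa_mg_per_g_protein
        Optional assayed composition: mg of each BCAA per g of crude
        protein.  May be omitted when per-dose mmol amounts are supplied
        directly on the treatments.
    """

    name: str
    cp_frac: float
    bcaa_mg_per_g_protein: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.cp_frac <= 1.0:
            raise InvalidSpecError(
                f"supplement {self.name!r}: cp_frac must be in (0, 1], got {self.cp_frac}"
            )
        if self.bcaa_mg_per_g_protein is not None:
            unknown = set(self.bcaa_mg_per_g_protein) - set(BCAAS)
            if unknown:
                raise InvalidSpecError(f"unknown amino-acid keys: {sorted(unknown)}")
            if any(v < 0 for v in self.bcaa_mg_per_g_protein.values()):
                raise InvalidSpecError("BCAA contents must be >= 0")


@dataclass(frozen=True)
class BasalComponent:
    """One basal-diet component: dry matter per vessel and its CP fraction."""

    name: str
    dm_mg: float
    cp_frac: float

    def __post_init__(self) -> None:
        if self.dm_mg < 0:
            raise InvalidSpecError(f"basal {self.name!r}: dm_mg must be >= 0")
        if not 0.0 <= self.cp_frac <= 1.0:
            raise InvalidSpecError(f"basal {self.name!r}: cp_frac must be in [0, 1]")


@dataclass(frozen=True)
class TreatmentSpec:
    """Substrate loaded into one set of replicate vessels.

    ``bcaa_mmol`` is the amount of each BCAA introduced with the supplement
    dose.  When the supplement also carries an assayed composition the two
    are cross-checked (5% relative tolerance — dosing tables are typically
    printed to 3 decimal places in mmol, which alone introduces ~2%
    rounding error on the smallest doses).
    """

    id: str
    basal: tuple[BasalComponent, ...]
    supplement: SupplementSpec | None = None
    dose_mg_dm: float = 0.0
    vessel_volume_mL: float = 40.0
    bcaa_mmol: dict[str, float] = field(default_factory=lambda: {aa: 0.0 for aa in BCAAS})

    def __post_init__(self) -> None:
        if self.dose_mg_dm < 0:
            raise InvalidSpecError(f"treatment {self.id!r}: dose_mg_dm must be >= 0")
        if self.vessel_volume_mL <= 0:
            raise InvalidSpecError(f"treatment {self.id!r}: vessel_volume_mL must be > 0")
        unknown = set(self.bcaa_mmol) - set(BCAAS)
        if unknown:
            raise InvalidSpecError(f"treatment {self.id!r}: unknown amino acids {sorted(unknown)}")
        if any(v < 0 for v in self.bcaa_mmol.values()):
            raise InvalidSpecError(f"treatment {self.id!r}: bcaa_mmol must be >= 0")
        if (
            self.supplement is not None
            and self.supplement.bcaa_mg_per_g_protein is not None
            and self.dose_mg_dm > 0
        ):
            derived = bcaa_mmol_from_composition(
                self.dose_mg_dm, self.supplement.cp_frac, self.supplement.bcaa_mg_per_g_protein
            )
            for aa, mmol in self.bcaa_mmol.items():
                ref = derived.get(aa, 0.0)
                if ref == 0.0 and mmol == 0.0:
                    continue
                if ref == 0.0 or abs(mmol - ref) / ref > 0.05:
                    raise InvalidSpecError(
                        f"treatment {self.id!r}: {aa} dose {mmol} mmol disagrees with "
                        f"composition-derived {ref:.4f} mmol by more than 5%"
                    )

    @property
    def is_control(self) -> bool:
        return self.supplement is None or self.dose_mg_dm == 0.0

    @property
    def basal_dm_mg(self) -> float:
        return sum(c.dm_mg for c in self.basal)

    @property
    def basal_cp_mg(self) -> float:
        return sum(c.dm_mg * c.cp_frac for c in self.basal)

    @property
    def supplement_cp_mg(self) -> float:
        if self.supplement is None:
            return 0.0
        return self.dose_mg_dm * self.supplement.cp_frac


def isonitrogenous_dose(
    ref_dose_mg_dm: float, ref_cp_frac: float, target_cp_frac: float
) -> float:
    """Dry-matter dose of a target supplement delivering the same crude protein.

    Solves ``dose * target_cp_frac == ref_dose_mg_dm * ref_cp_frac`` — the
    defining equation of isonitrogenous dosing.

    >>> round(isonitrogenous_dose(16.0, 0.458, 0.542), 1)
    13.5
    """
    for name, value in (
        ("ref_dose_mg_dm", ref_dose_mg_dm),
        ("ref_cp_frac", ref_cp_frac),
        ("target_cp_frac", target_cp_frac),
    ):
        if value <= 0:
            raise InvalidSpecError(f"{name} must be > 0, got {value}")
    if ref_cp_frac > 1 or target_cp_frac > 1:
        raise InvalidSpecError("crude-protein fractions must be <= 1")
    return ref_dose_mg_dm * ref_cp_frac / target_cp_frac


def diet_fractions(t: TreatmentSpec) -> dict[str, float]:
    """Supplement share of total diet DM and of total diet CP, in percent.

    Returns a dict with keys ``supp_pct_of_diet_dm`` and
    ``supp_cp_pct_of_diet_cp``.
    """
    if not t.basal:
        raise InvalidSpecError(f"treatment {t.id!r}: basal list is empty")
    total_dm = t.basal_dm_mg + t.dose_mg_dm
    if total_dm <= 0:
        raise InvalidSpecError(f"treatment {t.id!r}: total diet DM is zero")
    supp_cp = t.supplement_cp_mg
    total_cp = t.basal_cp_mg + supp_cp
    return {
        "supp_pct_of_diet_dm": 100.0 * t.dose_mg_dm / total_dm,
        "supp_cp_pct_of_diet_cp": (100.0 * supp_cp / total_cp) if total_cp > 0 else 0.0,
    }


def bcaa_mmol_from_composition(
    dose_mg_dm: float,
    cp_frac: float,
    bcaa_mg_per_g_protein: dict[str, float],
    constants: AminoAcidConstants = DEFAULT_CONSTANTS,
) -> dict[str, float]:
    """mmol of each BCAA introduced with a supplement dose.

    ``dose_mg_dm * cp_frac`` mg of crude protein times ``content / 1000``
    (mg amino acid per mg protein) gives mg of amino acid; dividing by the
    molar mass in g/mol yields mmol directly (mg / (g/mol) = mmol).
    """
    if dose_mg_dm < 0 or cp_frac < 0:
        raise InvalidSpecError("dose and cp_frac must be >= 0")
    unknown = set(bcaa_mg_per_g_protein) - set(constants.molar_mass_g_per_mol)
    if unknown:
        raise InvalidSpecError(f"unknown amino-acid keys: {sorted(unknown)}")
    out = {}
    for aa, content in bcaa_mg_per_g_protein.items():
        aa_mg = dose_mg_dm * cp_frac * content / 1000.0
        out[aa] = aa_mg / constants.molar_mass_g_per_mol[aa]
    return out


def aa_percent_of_protein(
    aa: str,
    aa_mmol: float,
    dose_mg_dm: float,
    cp_frac: float,
    constants: AminoAcidConstants = DEFAULT_CONSTANTS,
) -> float:
    """Mass of one amino acid as a percentage of supplement crude protein.

    Algebraic inverse of :func:`bcaa_mmol_from_composition` (up to the
    mg/g-vs-percent factor of 10).
    """
    if aa not in constants.molar_mass_g_per_mol:
        raise InvalidSpecError(f"unknown amino acid {aa!r}")
    protein_mg = dose_mg_dm * cp_frac
    if protein_mg <= 0:
        raise InvalidSpecError("dose_mg_dm * cp_frac must be > 0")
    return 100.0 * aa_mmol * constants.molar_mass_g_per_mol[aa] / protein_mg


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


# ---------------------------------------------------------------------------
# The reference study layout: 3 supplements x 3 isonitrogenous dose levels
# plus an unsupplemented control, on a 400 mg + 400 mg silage/compound-feed
# basal substrate in 40-mL cultures.

_SUPPLEMENTS = {
    "SBM": SupplementSpec("SBM", cp_frac=0.542),
    "WHEY": SupplementSpec("WHEY", cp_frac=0.892),
    "YMP": SupplementSpec("YMP", cp_frac=0.458),
}

_BASAL = (
    BasalComponent("grass silage", dm_mg=400.0, cp_frac=0.16),
    BasalComponent("compound feed", dm_mg=400.0, cp_frac=0.19),
)

# (dose mg DM, {BCAA mmol per vessel}) per supplement and dose level, as
# assayed for the reference experiment.
_DOSING: dict[str, dict[str, tuple[float, dict[str, float]]]] = {
    "SBM": {
        "Low": (13.5, {"Val": 0.003, "Ile": 0.002, "Leu": 0.004}),
        "Medium": (75.3, {"Val": 0.016, "Ile": 0.013, "Leu": 0.023}),
        "High": (290.0, {"Val": 0.062, "Ile": 0.052, "Leu": 0.088}),
    },
    "WHEY": {
        "Low": (8.22, {"Val": 0.004, "Ile": 0.004, "Leu": 0.006}),
        "Medium": (45.7, {"Val": 0.023, "Ile": 0.022, "Leu": 0.036}),
        "High": (176.0, {"Val": 0.088, "Ile": 0.085, "Leu": 0.139}),
    },
    "YMP": {
        "Low": (16.0, {"Val": 0.003, "Ile": 0.002, "Leu": 0.003}),
        "Medium": (89.0, {"Val": 0.017, "Ile": 0.012, "Leu": 0.019}),
        "High": (343.0, {"Val": 0.065, "Ile": 0.047, "Leu": 0.074}),
    },
}

DOSE_LEVELS: tuple[str, ...] = ("Low", "Medium", "High")


def study_design(vessel_volume_mL: float = 40.0) -> list[TreatmentSpec]:
    """The reference 10-treatment design (control + 3 supplements x 3 doses)."""
    treatments = [
        TreatmentSpec(id="Control", basal=_BASAL, vessel_volume_mL=vessel_volume_mL)
    ]
    for supp_name in ("SBM", "WHEY", "YMP"):
        for level in DOSE_LEVELS:
            dose, bcaa = _DOSING[supp_name][level]
            treatments.append(
                TreatmentSpec(
                    id=f"{supp_name} {level}",
                    basal=_BASAL,
                    supplement=_SUPPLEMENTS[supp_name],
                    dose_mg_dm=dose,
                    vessel_volume_mL=vessel_volume_mL,
                    bcaa_mmol=dict(bcaa),
                )
            )
    return treatments
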