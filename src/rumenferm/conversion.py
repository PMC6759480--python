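"""BCAA-to-BCVFA conversion: the degradability estimator.

When rumen microbes ferment protein, the branched-chain amino acids are
oxidatively deaminated and decarboxylated to branched-chain volatile fatty
acids mole for mole: Val -> isobutyric, Ile -> 2-methylbutyric,
Leu -> isovaleric acid.  Because the BCVFAs arise from no other common
substrate, the control-subtracted BCVFA yield, expressed as a percentage of
the BCAA introduced with a protein supplement, estimates the fraction of
that supplement's protein degraded by the microbial community.  Its
complement, 100 minus the conversion percentage, estimates the
rumen-undegradable protein (RUP) fraction.

Two aggregates over the three acids are computed: the molar-sum conversion
(total BCVFA moles over total BCAA moles — equivalently the BCAA-mole-
weighted mean of the per-acid conversions) and the unweighted mean of the
three per-acid conversions.  The molar-sum value is the headline statistic;
both are reported.

Negative conversions (treatment below control) are reported as-is and
flagged, never truncated: truncation would bias dose-response comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    BCAAS,
    BCVFA_PARTNER,
    AminoAcidConstants,
    DEFAULT_CONSTANTS,
    TreatmentSpec,
)
from .fermentation import total_bcvfa

__all__ = [
    "AlignmentError",
    "ConfigurationError",
    "BcvfaPanel",
    "ConversionResult",
    "bcvfa_increase",
    "mM_to_mmol",
    "percent_conversion",
    "rup_percent",
    "replicate_conversions",
    "conversion_table",
]


class AlignmentError(ValueError):
    """Panels to be compared were measured at different timepoints."""


class ConfigurationError(ValueError):
    """The experiment layout cannot support the requested computation."""


@dataclass(frozen=True)
class BcvfaPanel:
    """Mean BCVFA concentrations (mM) for one treatment at one timepoint.

    Per-acid concentrations may be absent when only the total was measured
    or published; ``total`` then falls back to the reported total.
    """

    treatment_id: str
    time_h: float
    isobutyric: float | None = None
    methylbutyric2: float | None = None
    isovaleric: float | None = None
    reported_total: float | None = None

    def __post_init__(self) -> None:
        for name in ("isobutyric", "methylbutyric2", "isovaleric", "reported_total"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} concentration must be >= 0, got {v}")

    @property
    def total(self) -> float:
        acids = (self.isobutyric, self.methylbutyric2, self.isovaleric)
        if all(a is not None for a in acids):
            return float(sum(acids))  # type: ignore[arg-type]
        if self.reported_total is not None:
            return self.reported_total
        raise ValueError("neither all three acids nor a reported total available")


@dataclass
class ConversionResult:
    """Per-acid and aggregate conversion percentages for one treatment.

    ``per_acid_pct`` is keyed by amino acid (NaN where that BCAA was not
    introduced or the acid not measured).  ``rup_pct`` is 100 minus the
    headline aggregate (molar-sum).  Values outside [0, 100] are kept and
    recorded in ``flags``.
    """

    treatment_id: str
    time_h: float
    per_acid_pct: dict[str, float]
    total_pct_molar: float
    mean_of_acids_pct: float
    rup_pct: float
    flags: list[str] = field(default_factory=list)


def bcvfa_increase(
    treatment_mean: BcvfaPanel, control_mean: BcvfaPanel
) -> dict[str, float]:
    """Control-subtracted BCVFA concentrations, per acid and in total (mM).

    Products of basal-substrate fermentation in unamended control vessels
    are subtracted so that the increase attributable to the supplement
    remains.  Negative differences are legitimate outputs (sampling noise,
    or BCVFA uptake) and are returned unchanged.
    """
    if treatment_mean.time_h != control_mean.time_h:
        raise AlignmentError(
            f"timepoint mismatch: treatment at {treatment_mean.time_h} h, "
            f"control at {control_mean.time_h} h"
        )
    delta: dict[str, float] = {}
    for acid in ("isobutyric", "methylbutyric2", "isovaleric"):
        t = getattr(treatment_mean, acid)
        c = getattr(control_mean, acid)
        if t is not None and c is not None:
            delta[acid] = t - c
    delta["total"] = treatment_mean.total - control_mean.total
    return delta


def mM_to_mmol(conc_mM: float, volume_mL: float) -> float:
    """Convert a concentration (mM) to an absolute amount (mmol) in a vessel."""
    if volume_mL <= 0:
        raise ValueError(f"volume must be > 0, got {volume_mL}")
    return conc_mM * volume_mL / 1000.0


def percent_conversion(
    delta_bcvfa_mmol: dict[str, float],
    bcaa_introduced_mmol: dict[str, float],
    constants: AminoAcidConstants = DEFAULT_CONSTANTS,
    *,
    treatment_id: str = "",
    time_h: float = float("nan"),
) -> ConversionResult:
    """Percent of introduced BCAA recovered as the partner BCVFA.

    Stoichiometry is mole-for-mole (one BCAA yields one BCVFA).  The
    molar-sum aggregate uses the ``"total"`` entry of ``delta_bcvfa_mmol``
    when present, otherwise the sum over the three acids.  A per-acid value
    is NaN when the corresponding BCAA was not introduced (0 mmol) or its
    acid increment is unavailable.
    """
    positive = [v for v in bcaa_introduced_mmol.values() if v > 0]
    if not positive:
        raise ValueError("at least one BCAA must be introduced in a positive amount")

    per_acid: dict[str, float] = {}
    flags: list[str] = []
    for aa in BCAAS:
        acid = constants.bcvfa_partner.get(aa, BCVFA_PARTNER[aa])
        mmol_aa = bcaa_introduced_mmol.get(aa, 0.0)
        if mmol_aa <= 0 or acid not in delta_bcvfa_mmol:
            per_acid[aa] = float("nan")
            continue
        pct = 100.0 * delta_bcvfa_mmol[acid] / mmol_aa
        per_acid[aa] = pct
        if pct < 0:
            flags.append(f"negative conversion for {aa}")

    if "total" in delta_bcvfa_mmol:
        delta_total = delta_bcvfa_mmol["total"]
    else:
        acids = [constants.bcvfa_partner[aa] for aa in BCAAS]
        missing = [a for a in acids if a not in delta_bcvfa_mmol]
        if missing:
            raise ValueError(f"no 'total' entry and missing per-acid increments: {missing}")
        delta_total = sum(delta_bcvfa_mmol[a] for a in acids)

    total_pct = 100.0 * delta_total / sum(positive)
    finite = [v for v in per_acid.values() if not math.isnan(v)]
    mean_of_acids = float(np.mean(finite)) if finite else float("nan")

    if total_pct < 0:
        flags.append("negative total conversion")
    rup = rup_percent(total_pct)
    if not 0.0 <= rup <= 100.0:
        flags.append("RUP outside [0, 100]")

    return ConversionResult(
        treatment_id=treatment_id,
        time_h=time_h,
        per_acid_pct=per_acid,
        total_pct_molar=total_pct,
        mean_of_acids_pct=mean_of_acids,
        rup_pct=rup,
        flags=flags,
    )


def rup_percent(conversion_pct: float) -> float:
    """Rumen-undegradable protein percentage: the unconverted complement.

    Values outside [0, 100] (possible when the conversion estimate is
    negative or exceeds 100% through noise) are returned unchanged; callers
    flag them.
    """
    return 100.0 - conversion_pct


def _panel_from_row(row: pd.Series, treatment_id: str, time_h: float) -> BcvfaPanel:
    def get(col: str) -> float | None:
        v = row.get(col)
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    return BcvfaPanel(
        treatment_id=treatment_id,
        time_h=time_h,
        isobutyric=get("isobutyric_mM"),
        methylbutyric2=get("methylbutyric2_mM"),
        isovaleric=get("isovaleric_mM"),
        reported_total=get("total_bcvfa_mM"),
    )


def replicate_conversions(
    records: pd.DataFrame,
    design: list[TreatmentSpec],
    time_h: float,
    *,
    control_id: str = "Control",
    constants: AminoAcidConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Per-replicate conversion estimates against the control replicate mean.

    Each supplemented vessel at ``time_h`` is compared with the MEAN of the
    control replicates at the same timepoint, so replicate-level standard
    errors can be attached to the treatment summaries.

    Returns a tidy frame with one row per vessel and columns
    ``treatment_id, replicate, time_h, total_pct_molar, mean_of_acids_pct,
    rup_pct, Val_pct, Ile_pct, Leu_pct, flags``.
    """
    by_id = {t.id: t for t in design}
    if control_id not in by_id:
        raise ConfigurationError(f"control treatment {control_id!r} not in design")

    at_t = records[records["time_h"] == time_h]
    controls = at_t[at_t["treatment_id"] == control_id]
    if controls.empty:
        raise ConfigurationError(f"no control records at {time_h} h")
    control_mean = _panel_from_row(
        controls.mean(numeric_only=True), control_id, time_h
    )

    rows = []
    for _, rec in at_t.iterrows():
        tid = rec["treatment_id"]
        spec = by_id.get(tid)
        if spec is None:
            raise ConfigurationError(f"record references unknown treatment {tid!r}")
        if spec.is_control:
            continue
        panel = _panel_from_row(rec, tid, time_h)
        delta_mM = bcvfa_increase(panel, control_mean)
        delta_mmol = {
            k: mM_to_mmol(v, spec.vessel_volume_mL) for k, v in delta_mM.items()
        }
        res = percent_conversion(
            delta_mmol, spec.bcaa_mmol, constants, treatment_id=tid, time_h=time_h
        )
        rows.append(
            {
                "treatment_id": tid,
                "replicate": rec.get("replicate", pd.NA),
                "time_h": time_h,
                "total_pct_molar": res.total_pct_molar,
                "mean_of_acids_pct": res.mean_of_acids_pct,
                "rup_pct": res.rup_pct,
                **{f"{aa}_pct": res.per_acid_pct[aa] for aa in BCAAS},
                "flags": ";".join(res.flags),
            }
        )
    columns = [
        "treatment_id", "replicate", "time_h", "total_pct_molar",
        "mean_of_acids_pct", "rup_pct", "Val_pct", "Ile_pct", "Leu_pct", "flags",
    ]
    return pd.DataFrame(rows, columns=columns)


def conversion_table(
    records: pd.DataFrame,
    design: list[TreatmentSpec],
    time_h: float,
    *,
    control_id: str = "Control",
    constants: AminoAcidConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Treatment-level conversion summary at one timepoint.

    Means and replicate-level standard errors of the per-replicate
    conversions from :func:`replicate_conversions`; one row per
    supplemented treatment present in ``records``.  SE columns are NaN for
    single-replicate (means-only) inputs.
    """
    reps = replicate_conversions(
        records, design, time_h, control_id=control_id, constants=constants
    )
    if reps.empty:
        return pd.DataFrame(
            columns=[
                "treatment_id", "time_h", "n", "total_pct_molar", "total_pct_se",
                "mean_of_acids_pct", "rup_pct",
                "Val_pct", "Ile_pct", "Leu_pct", "flags",
            ]
        )

    def se(x: pd.Series) -> float:
        x = x.dropna()
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    order = [t.id for t in design if t.id in set(reps["treatment_id"])]
    rows = []
    for tid in order:
        g = reps[reps["treatment_id"] == tid]
        rows.append(
            {
                "treatment_id": tid,
                "time_h": time_h,
                "n": len(g),
                "total_pct_molar": g["total_pct_molar"].mean(),
                "total_pct_se": se(g["total_pct_molar"]),
                "mean_of_acids_pct": g["mean_of_acids_pct"].mean(),
                "rup_pct": g["rup_pct"].mean(),
                **{f"{aa}_pct": g[f"{aa}_pct"].mean() for aa in BCAAS},
                "flags": ";".join(sorted({f for fl in g["flags"] if fl for f in fl.split(";")})),
            }
        )
    return pd.DataFrame(rows)
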