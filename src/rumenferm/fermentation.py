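"""Overall-fermentation summaries: acid totals, gas, ammonia, bacterial growth.

Vessel observations live in a tidy pandas DataFrame, one row per vessel x
sampling time, with units embedded in the column names (``acetic_mM``,
``gas_mL``, ``bacteria_copies_per_mL``) so unit drift is visible in every
file and plot.  Missing analytes are NaN, never zero, and propagate as
missing through the totals.

"Total VFA" is the sum of the four straight-chain acids plus the three
branched-chain acids; lactic acid — a transient fermentation intermediate,
not a terminal volatile fatty acid — is excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "InvalidDataError",
    "STRAIGHT_VFA_COLUMNS",
    "BCVFA_COLUMNS",
    "ANALYTE_COLUMNS",
    "OBS_COLUMNS",
    "total_bcvfa",
    "total_vfa",
    "log10_bacteria",
    "doublings",
    "doublings_rounded",
    "treatment_summary",
    "parameter_table",
]


class InvalidDataError(ValueError):
    """An observation violates the data schema (e.g. non-positive density)."""


STRAIGHT_VFA_COLUMNS = ("acetic_mM", "propionic_mM", "butyric_mM", "valeric_mM")
BCVFA_COLUMNS = ("isobutyric_mM", "methylbutyric2_mM", "isovaleric_mM")
ANALYTE_COLUMNS = (
    *STRAIGHT_VFA_COLUMNS,
    *BCVFA_COLUMNS,
    "lactic_mM",
    "nh3_mM",
    "gas_mL",
    "bacteria_copies_per_mL",
)
#: Canonical observation-table column order.
OBS_COLUMNS = ("treatment_id", "replicate", "time_h", *ANALYTE_COLUMNS)


def _as_frame(records: pd.DataFrame | pd.Series) -> tuple[pd.DataFrame, bool]:
    if isinstance(records, pd.Series):
        return records.to_frame().T, True
    return records, False


def _maybe_scalar(s: pd.Series, scalar: bool) -> pd.Series | float:
    return float(s.iloc[0]) if scalar else s


def total_bcvfa(records: pd.DataFrame | pd.Series) -> pd.Series | float:
    """Sum of the three branched-chain acids (mM).

    Computed from the components when all three are present; rows where any
    component is missing fall back to a reported ``total_bcvfa_mM`` column
    if one exists (published summary tables often print only the total),
    otherwise NaN.
    """
    df, scalar = _as_frame(records)
    have = [c for c in BCVFA_COLUMNS if c in df.columns]
    if len(have) == len(BCVFA_COLUMNS):
        out = df[list(BCVFA_COLUMNS)].astype(float).sum(axis=1, skipna=False)
    else:
        out = pd.Series(np.nan, index=df.index)
    if "total_bcvfa_mM" in df.columns:
        out = out.fillna(pd.to_numeric(df["total_bcvfa_mM"]).astype(float))
    return _maybe_scalar(out.astype(float), scalar)


def total_vfa(records: pd.DataFrame | pd.Series) -> pd.Series | float:
    """Total volatile fatty acids (mM): straight-chain VFAs plus BCVFA.

    Lactic acid is excluded.  Missing components make the total missing.
    """
    df, scalar = _as_frame(records)
    straight = df.reindex(columns=list(STRAIGHT_VFA_COLUMNS)).astype(float)
    out = straight.sum(axis=1, skipna=False) + pd.Series(
        total_bcvfa(df), index=df.index
    )
    return _maybe_scalar(out.astype(float), scalar)


def log10_bacteria(records: pd.DataFrame | pd.Series) -> pd.Series | float:
    """Base-10 log of bacterial density (16S gene copies/mL)."""
    df, scalar = _as_frame(records)
    dens = pd.to_numeric(df["bacteria_copies_per_mL"])
    bad = dens[dens.notna() & (dens <= 0)]
    if not bad.empty:
        raise InvalidDataError(
            f"non-positive bacterial density in rows {list(bad.index)}"
        )
    return _maybe_scalar(np.log10(dens.astype(float)), scalar)


def doublings(density_start: float, density_end: float) -> float:
    """Number of bacterial doublings between two density measurements.

    Additive over consecutive intervals:
    ``doublings(a, b) + doublings(b, c) == doublings(a, c)``.
    """
    if density_start <= 0 or density_end <= 0:
        raise InvalidDataError("bacterial densities must be > 0")
    return float(np.log2(density_end / density_start))


def doublings_rounded(density_start: float, density_end: float) -> int:
    """`doublings` rounded to the nearest whole division."""
    return int(round(doublings(density_start, density_end)))


def treatment_summary(
    records: pd.DataFrame,
    group_keys: tuple[str, ...] = ("treatment_id", "time_h"),
    analytes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Mean, standard error and n per group x analyte, in long format.

    SE is the sample SD over sqrt(n) and is NaN for single-observation
    groups.  Derived totals (``total_bcvfa_mM``, ``total_vfa_mM``) are
    appended to the analyte set when computable.  Groups are taken from the
    data; empty groups cannot arise.
    """
    df = records.copy()
    df["total_bcvfa_mM"] = total_bcvfa(records)
    df["total_vfa_mM"] = total_vfa(records)
    if analytes is None:
        analytes = (*ANALYTE_COLUMNS, "total_bcvfa_mM", "total_vfa_mM")
    analytes = tuple(a for a in analytes if a in df.columns)

    long = df.melt(
        id_vars=list(group_keys),
        value_vars=list(analytes),
        var_name="analyte",
        value_name="value",
    ).dropna(subset=["value"])

    def _agg(g: pd.Series) -> pd.Series:
        n = g.count()
        return pd.Series(
            {
                "mean": g.mean(),
                "se": g.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n": n,
            }
        )

    out = (
        long.groupby([*group_keys, "analyte"], sort=False)["value"]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def parameter_table(records: pd.DataFrame, time_h: float) -> pd.DataFrame:
    """Per-vessel fermentation parameters at one timepoint, for correlation.

    One row per vessel sampled at ``time_h`` with the five summary
    parameters: cumulative gas, total VFA, log10 bacterial density, total
    BCVFA and ammonia.  Vessels missing a parameter keep NaN there
    (pairwise-complete handling happens downstream).
    """
    at_t = records[records["time_h"] == time_h]
    dens = pd.to_numeric(at_t.get("bacteria_copies_per_mL"), errors="coerce")
    with np.errstate(invalid="ignore"):
        log_dens = np.where(dens > 0, np.log10(dens.astype(float)), np.nan)
    return pd.DataFrame(
        {
            "gas_mL": at_t.get("gas_mL"),
            "total_vfa_mM": total_vfa(at_t),
            "log10_bacteria": log_dens,
            "total_bcvfa_mM": total_bcvfa(at_t),
            "nh3_mM": at_t.get("nh3_mM"),
        },
        index=at_t.index,
    )
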