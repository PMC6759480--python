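"""CSV/YAML input-output and the end-to-end analysis runner.

All tabular I/O is plain CSV (UTF-8, "." decimal separator) with a
schema-version comment as the first line, so outputs are diffable across
runs and versions.  Units are embedded in the column names; missing values
are empty cells, never 0.  Experiment designs are read from a YAML file
listing supplements, basal components and treatments.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (
    BCAAS,
    BasalComponent,
    InvalidSpecError,
    SupplementSpec,
    TreatmentSpec,
    bcaa_mmol_from_composition,
    study_design,
)
from .fermentation import (
    ANALYTE_COLUMNS,
    OBS_COLUMNS,
    parameter_table,
    treatment_summary,
)
from .stats import anova_by_analyte, pearson_pairwise

logger = logging.getLogger("rumenferm")

__all__ = [
    "SchemaError",
    "OBS_SCHEMA_LINE",
    "read_observations",
    "write_observations",
    "write_table",
    "design_from_config",
    "read_design",
    "RunConfig",
    "run_full_analysis",
]


class SchemaError(ValueError):
    """An input file does not match the documented schema."""


OBS_SCHEMA_LINE = "# rumenferm observations schema v1"
_MANDATORY = ("treatment_id", "replicate", "time_h")
#: Optional reported-total columns (published summary tables carry totals
#: where per-acid values were not printed).
_EXTRA_KNOWN = ("total_bcvfa_mM", "total_vfa_mM")
_CONCENTRATION_COLUMNS = tuple(c for c in ANALYTE_COLUMNS if c != "gas_mL") + _EXTRA_KNOWN


def write_table(df: pd.DataFrame, path: str | Path, name: str = "table") -> Path:
    """Write a DataFrame as CSV with a schema-version comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# rumenferm {name} schema v1\n")
        df.to_csv(fh, index=False)
    return path


def write_observations(records: pd.DataFrame, path: str | Path) -> Path:
    """Write an observation table in the canonical column order."""
    cols = [c for c in (*OBS_COLUMNS, *_EXTRA_KNOWN) if c in records.columns]
    return write_table(records[cols], path, name="observations")


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and validate a vessel-observation CSV.

    Mandatory columns: ``treatment_id, replicate, time_h``.  Analyte
    columns are optional but must be numeric and non-negative where given;
    unknown columns are warned about and dropped.  Malformed numeric cells
    and negative concentrations raise :class:`SchemaError` naming the
    offending data rows (1-based, excluding header and comment lines).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")

    known = (*_MANDATORY, *ANALYTE_COLUMNS, *_EXTRA_KNOWN)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", path.name, unknown)
        df = df.drop(columns=unknown)

    out = pd.DataFrame({"treatment_id": df["treatment_id"].astype(str)})
    errors: list[str] = []
    for col in df.columns:
        if col == "treatment_id":
            continue
        raw = df[col]
        values = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & raw.str.strip().ne("") & values.isna()
        if bad.any():
            rows = [int(i) + 1 for i in raw.index[bad]]
            errors.append(f"column {col!r}: malformed numeric cells in data row(s) {rows}")
        out[col] = values
    if errors:
        raise SchemaError(f"{path.name}: " + "; ".join(errors))

    for col in _CONCENTRATION_COLUMNS:
        if col in out.columns:
            neg = out[col] < 0
            if neg.any():
                rows = [int(i) + 1 for i in out.index[neg]]
                raise SchemaError(
                    f"{path.name}: negative concentration in column {col!r}, data row(s) {rows}"
                )
    if "bacteria_copies_per_mL" in out.columns:
        bad = out["bacteria_copies_per_mL"] <= 0
        if bad.any():
            rows = [int(i) + 1 for i in out.index[bad]]
            raise SchemaError(
                f"{path.name}: non-positive bacterial density in data row(s) {rows}"
            )
    return out


# ---------------------------------------------------------------------------
# Design configuration.


def design_from_config(cfg: dict) -> list[TreatmentSpec]:
    """Build a treatment list from a parsed design-config mapping.

    Expected structure::

        vessel_volume_mL: 40
        basal:
          - {name: grass silage, dm_mg: 400, cp_frac: 0.16}
          - {name: compound feed, dm_mg: 400, cp_frac: 0.19}
        supplements:
          SBM:
            cp_frac: 0.542
            bcaa_mg_per_g_protein: {Val: 46.2, Ile: 43.8, Leu: 73.4}  # optional
        treatments:
          - {id: Control}
          - {id: SBM High, supplement: SBM, dose_mg_dm: 290,
             bcaa_mmol: {Val: 0.062, Ile: 0.052, Leu: 0.088}}

    A treatment may omit ``bcaa_mmol`` if its supplement carries an assayed
    composition, from which the amounts are derived; when both are present
    they are cross-checked by :class:`~rumenferm.design.TreatmentSpec`.
    """
    try:
        volume = float(cfg.get("vessel_volume_mL", 40.0))
        basal = tuple(
            BasalComponent(c["name"], float(c["dm_mg"]), float(c["cp_frac"]))
            for c in cfg["basal"]
        )
        supplements = {
            name: SupplementSpec(
                name,
                cp_frac=float(s["cp_frac"]),
                bcaa_mg_per_g_protein=s.get("bcaa_mg_per_g_protein"),
            )
            for name, s in cfg.get("supplements", {}).items()
        }
        treatments = []
        for t in cfg["treatments"]:
            supp = supplements[t["supplement"]] if t.get("supplement") else None
            dose = float(t.get("dose_mg_dm", 0.0))
            bcaa = t.get("bcaa_mmol")
            if bcaa is None:
                if supp is not None and supp.bcaa_mg_per_g_protein is not None:
                    bcaa = bcaa_mmol_from_composition(
                        dose, supp.cp_frac, supp.bcaa_mg_per_g_protein
                    )
                else:
                    bcaa = {aa: 0.0 for aa in BCAAS}
            treatments.append(
                TreatmentSpec(
                    id=str(t["id"]),
                    basal=basal,
                    supplement=supp,
                    dose_mg_dm=dose,
                    vessel_volume_mL=volume,
                    bcaa_mmol={k: float(v) for k, v in bcaa.items()},
                )
            )
    except (KeyError, TypeError) as exc:
        raise InvalidSpecError(f"malformed design config: {exc!r}") from exc
    return treatments


def read_design(path: str | Path) -> list[TreatmentSpec]:
    """Read a design-config YAML file into a treatment list."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidSpecError(f"{Path(path).name}: design config must be a mapping")
    return design_from_config(cfg)


# ---------------------------------------------------------------------------
# End-to-end runner.


@dataclass
class RunConfig:
    """Options for one end-to-end analysis run."""

    observations: str | Path | pd.DataFrame
    design: str | Path | list[TreatmentSpec] | None = None
    output_dir: str | Path = "rumenferm-run"
    timepoints: tuple[float, ...] = (4.0, 10.0, 24.0)
    correlation_time_h: float = 10.0
    alpha: float = 0.05
    anova_analytes: tuple[str, ...] = field(
        default_factory=lambda: tuple(ANALYTE_COLUMNS)
    )
    seed: int = 0


def _config_hash(cfg: RunConfig) -> str:
    # analysis options only — paths excluded so identical analyses of the
    # same data hash identically wherever their outputs land
    key = (
        cfg.timepoints,
        cfg.correlation_time_h,
        cfg.alpha,
        cfg.anova_analytes,
        cfg.seed,
    )
    return hashlib.sha256(repr(key).encode()).hexdigest()[:12]


def run_full_analysis(cfg: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write all report tables.

    Stages: treatment summaries (means +/- SE), conversion/RUP tables per
    timepoint, per-analyte ANOVA with Tukey letters, and the
    fermentation-parameter correlation table at ``correlation_time_h``,
    plus a plain-text report of the headline conversion and RUP figures.
    Returns the mapping of output names to written paths.
    """
    from .conversion import conversion_table  # deferred: avoids cycle at import

    logger.info(
        "rumenferm %s run: config %s, seed %d", __version__, _config_hash(cfg), cfg.seed
    )
    records = (
        cfg.observations
        if isinstance(cfg.observations, pd.DataFrame)
        else read_observations(cfg.observations)
    )
    if cfg.design is None:
        design = study_design()
    elif isinstance(cfg.design, (str, Path)):
        design = read_design(cfg.design)
    else:
        design = list(cfg.design)

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    stage = "summaries"
    try:
        summary = treatment_summary(records)
        written["summary"] = write_table(summary, outdir / "summary.csv", "summary")

        stage = "conversion"
        conv_frames = []
        for t in cfg.timepoints:
            present = records[records["time_h"] == t]
            if present.empty:
                continue
            conv_frames.append(conversion_table(records, design, t))
        conversion = (
            pd.concat(conv_frames, ignore_index=True) if conv_frames else pd.DataFrame()
        )
        written["conversion"] = write_table(
            conversion, outdir / "conversion.csv", "conversion"
        )

        stage = "stats"
        anova, letters = anova_by_analyte(
            records, list(cfg.anova_analytes), alpha=cfg.alpha
        )
        written["anova"] = write_table(anova, outdir / "anova.csv", "anova")
        written["letters"] = write_table(letters, outdir / "letters.csv", "letters")

        params = parameter_table(records, cfg.correlation_time_h)
        corr = pearson_pairwise(params.dropna(axis=1, how="all"))
        tidy = (
            corr.r.stack()
            .rename("r")
            .to_frame()
            .join(corr.p.stack().rename("p"))
            .join(corr.n.stack().rename("n"))
            .reset_index(names=["parameter_1", "parameter_2"])
        )
        written["correlation"] = write_table(
            tidy, outdir / "correlation.csv", "correlation"
        )

        stage = "report"
        report_path = outdir / "report.txt"
        with open(report_path, "w", encoding="utf-8") as fh:
            fh.write(f"rumenferm {__version__} analysis report\n")
            fh.write(f"config hash {_config_hash(cfg)}, seed {cfg.seed}\n\n")
            fh.write("BCAA -> BCVFA conversion and apparent RUP\n")
            fh.write("-----------------------------------------\n")
            for _, row in conversion.iterrows():
                fh.write(
                    f"{row['treatment_id']:<14s} {row['time_h']:>5.1f} h  "
                    f"conversion {row['total_pct_molar']:6.1f} %  "
                    f"RUP {row['rup_pct']:6.1f} %"
                    + (f"  [{row['flags']}]" if row.get("flags") else "")
                    + "\n"
                )
        written["report"] = report_path
    except Exception:
        logger.exception("analysis failed in stage %r", stage)
        raise
    logger.info("analysis complete: %d outputs in %s", len(written), outdir)
    return written
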