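"""Lesion-table CSV I/O and the cohort analysis pipeline.

The interchange format is a plain UTF-8 CSV with one row per lesion and
required columns ``patient_id``, ``lesion_id``, ``volume_ml``, ``dose_gy``.
Validation reports the offending file row (1-based, header = row 1) and
field. ``run_analysis`` ties the pipeline together: per-patient inverse
solves (with optional TCP-cutoff and alpha sensitivity variants),
burden-reduction curve export, a cohort results table and a JSON run
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .burden import MBRCurve, Patient, Lesion, mbr_curve, plan_patient
from .cohort import CohortSummary, summarize_cohort, variability_measures
from .errors import ValidationError
from .params import RadiobioParams

__all__ = [
    "REQUIRED_COLUMNS",
    "read_lesion_table",
    "write_lesion_table",
    "write_curve_csv",
    "AnalysisOptions",
    "run_analysis",
]

logger = logging.getLogger("mbrplan")

REQUIRED_COLUMNS = ("patient_id", "lesion_id", "volume_ml", "dose_gy")

#: Significant digits used when serialising numbers.
FLOAT_FORMAT = "%.6g"


def read_lesion_table(path: str | Path) -> list[Patient]:
    """Read and validate a lesion-table CSV, grouped into patients.

    Patients appear in file order; lesions keep their file order within a
    patient. Errors name the file row and field responsible.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "lesion_id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"{path}: could not parse CSV: {exc}") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ValidationError(f"{path}: lesion table is empty")

    def row_no(i: int) -> int:  # 1-based file row including the header
        return i + 2

    for col in ("volume_ml", "dose_gy"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: row {row_no(i)}: field {col!r} is missing or non-numeric"
            )
        df[col] = numeric

    bad_v = df["volume_ml"] <= 0
    if bad_v.any():
        i = int(np.flatnonzero(bad_v.to_numpy())[0])
        raise ValidationError(
            f"{path}: row {row_no(i)}: field 'volume_ml' must be > 0, "
            f"got {df['volume_ml'].iloc[i]:g}"
        )
    bad_d = df["dose_gy"] < 0
    if bad_d.any():
        i = int(np.flatnonzero(bad_d.to_numpy())[0])
        raise ValidationError(
            f"{path}: row {row_no(i)}: field 'dose_gy' must be >= 0, "
            f"got {df['dose_gy'].iloc[i]:g}"
        )
    dup = df.duplicated(subset=["patient_id", "lesion_id"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"{path}: row {row_no(i)}: duplicate lesion key "
            f"({df['patient_id'].iloc[i]!r}, {df['lesion_id'].iloc[i]!r})"
        )

    patients: list[Patient] = []
    for pid in df["patient_id"].unique():
        sub = df[df["patient_id"] == pid]
        lesions = tuple(
            Lesion(str(r.lesion_id), float(r.volume_ml), float(r.dose_gy))
            for r in sub.itertuples()
        )
        patients.append(Patient(str(pid), lesions))
    return patients


def write_lesion_table(patients: Iterable[Patient], path: str | Path) -> None:
    """Write patients to the standard lesion-table CSV."""
    rows = [
        {
            "patient_id": p.patient_id,
            "lesion_id": l.lesion_id,
            "volume_ml": l.volume,
            "dose_gy": l.dose,
        }
        for p in patients
        for l in p.lesions
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def write_curve_csv(curve: MBRCurve, path: str | Path,
                    grid_step: float | None = None) -> None:
    """Export a burden-reduction curve as CSV breakpoints.

    With ``grid_step`` set, a densified right-continuous evaluation on a
    regular PMAD grid (step in Gy) is appended for plotting.
    """
    frames = [pd.DataFrame({
        "pmad_gy": curve.pmad_values(),
        "mbr": curve.mbr_values(),
        "kind": "breakpoint",
    })]
    if grid_step is not None:
        if grid_step <= 0:
            raise ValidationError(f"grid_step must be positive, got {grid_step!r}")
        finite = curve.pmad_values()
        top = finite.max() if finite.size else 0.0
        grid = np.arange(0.0, top + grid_step, grid_step)
        frames.append(pd.DataFrame({
            "pmad_gy": grid,
            "mbr": curve(grid),
            "kind": "grid",
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=FLOAT_FORMAT)


@dataclass(frozen=True)
class AnalysisOptions:
    """Options for :func:`run_analysis`."""

    mbr_fraction: float = 0.5
    tcp_cutoffs: tuple[float, ...] = ()     # sensitivity variants beside the default
    alpha_variants: tuple[float, ...] = ()  # e.g. (0.25,)
    grid_step: float | None = None          # densified curve grid, Gy
    write_curves: bool = True
    seed: int | None = None                 # recorded in the manifest only


def _results_table(patients: Sequence[Patient], params: RadiobioParams,
                   options: AnalysisOptions) -> tuple[pd.DataFrame, list]:
    results = []
    rows = []
    for p in patients:
        res = plan_patient(p, params, mbr_fraction=options.mbr_fraction)
        results.append(res)
        var = variability_measures(p.doses, p.patient_id)
        row = {
            "patient_id": p.patient_id,
            "n_lesions": p.n_lesions,
            "burden_ml": p.burden,
            "pmad_delivered_gy": p.pmad,
            "pmad_mcp_gy": res.pmad_mcp,
            f"pmad_mbr{options.mbr_fraction * 100:.0f}_gy": res.pmad_mbr,
            "min_dose_gy": var.min_dose,
            "max_dose_gy": var.max_dose,
            "max_min_ratio": var.max_min_ratio,
        }
        for cutoff in options.tcp_cutoffs:
            variant = params.replace(tcp_cutoff=cutoff, mcp_target=cutoff)
            v = plan_patient(p, variant, mbr_fraction=options.mbr_fraction)
            row[f"pmad_mcp_gy_cutoff{cutoff:g}"] = v.pmad_mcp
            row[f"pmad_mbr{options.mbr_fraction * 100:.0f}_gy_cutoff{cutoff:g}"] = v.pmad_mbr
        for alpha in options.alpha_variants:
            variant = params.replace(alpha=alpha)
            v = plan_patient(p, variant, mbr_fraction=options.mbr_fraction)
            row[f"pmad_mcp_gy_alpha{alpha:g}"] = v.pmad_mcp
            row[f"pmad_mbr{options.mbr_fraction * 100:.0f}_gy_alpha{alpha:g}"] = v.pmad_mbr
        row["flags"] = ";".join(res.flags)
        rows.append(row)
    return pd.DataFrame(rows), results


def run_analysis(patients: Sequence[Patient], params: RadiobioParams,
                 out_dir: str | Path,
                 options: AnalysisOptions = AnalysisOptions()) -> CohortSummary:
    """Run the full planning pipeline over a cohort and write outputs.

    Writes ``results.csv`` (one row per patient, sensitivity variants as
    extra columns), per-patient burden-reduction curve CSVs under
    ``curves/``, and ``manifest.json`` recording parameters, options and
    package version. Zero-dose lesions produce flagged rows, not aborts.
    Returns the cohort summary.
    """
    if len(patients) == 0:
        raise ValidationError("no patients to analyse")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("analysing %d patients", len(patients))
    table, results = _results_table(patients, params, options)
    table.to_csv(out_dir / "results.csv", index=False, float_format=FLOAT_FORMAT)

    if options.write_curves:
        curve_dir = out_dir / "curves"
        curve_dir.mkdir(exist_ok=True)
        for p in patients:
            curve = mbr_curve(p, params)
            write_curve_csv(curve, curve_dir / f"{p.patient_id}_mbr_curve.csv",
                            grid_step=options.grid_step)

    manifest = {
        "tool": "mbrplan",
        "version": __version__,
        "n_patients": len(patients),
        "params": dataclasses.asdict(params),
        "options": {
            "mbr_fraction": options.mbr_fraction,
            "tcp_cutoffs": list(options.tcp_cutoffs),
            "alpha_variants": list(options.alpha_variants),
            "grid_step": options.grid_step,
        },
        "seed": options.seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n",
                                           encoding="utf-8")
    summary = summarize_cohort(results)
    logger.info(
        "median PMAD: delivered %.1f Gy, MCP target %.1f Gy, MBR %.0f%% %.1f Gy",
        summary.median_pmad_delivered, summary.median_pmad_mcp,
        options.mbr_fraction * 100, summary.median_pmad_mbr,
    )
    return summary
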