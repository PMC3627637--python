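"""File I/O, run configuration, and the end-to-end batch pipeline.

Volumes and masks travel as NIfTI-1 (``.nii``/``.nii.gz``); the format's
scl_slope/scl_inter rescaling is applied on read, and any nonzero mask
voxel counts as lung. Batch runs are manifest-driven: a CSV maps each
subject to its four files and smoking status, optionally joined with a
clinical table for the cohort statistics. Every run echoes its seed and
exclusion accounting into the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .densitometry import compute_scan_pair_metrics
from .errors import ConfigError, ScanReadError, ValidationError
from .residuals import GasTrappingResidualModel
from .volumes import AttenuationVolume, LungSegmentation, ScanPair, SmokingStatus

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = (
    "subject_id", "insp_volume", "insp_mask", "exp_volume", "exp_mask", "smoking_status",
)

METRIC_COLUMNS = (
    "subject_id", "insp_950", "exp_856", "ei_mla", "rvc_856_950",
    "tlc_l", "frc_l", "frc_tlc", "emphysema_class",
)

DEFAULT_OUTCOMES = (
    "fev1_pct_pred", "fvc_pct_pred", "fev1_fvc", "fef2575",
    "frc_tlc", "sixmwd", "exacerbation_freq", "sgrq_total", "mmrc",
)


# ---------------------------------------------------------------------------
# NIfTI round trips
# ---------------------------------------------------------------------------

def read_attenuation_volume(path) -> AttenuationVolume:
    """Load a NIfTI volume as HU, applying the header's scale/intercept."""
    path = Path(path)
    if not path.exists():
        raise ScanReadError(f"missing file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)  # applies scl_slope/inter
    if data.ndim != 3:
        raise ScanReadError(f"{path}: expected 3D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ScanReadError(f"{path}: non-finite voxel values")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return AttenuationVolume(data, spacing)


def read_mask(path) -> LungSegmentation:
    """Load a NIfTI segmentation; any nonzero voxel is lung."""
    path = Path(path)
    if not path.exists():
        raise ScanReadError(f"missing file: {path}")
    data = np.asarray(nib.load(str(path)).get_fdata())
    if data.ndim != 3:
        raise ScanReadError(f"{path}: expected 3D mask, got shape {data.shape}")
    return LungSegmentation(data != 0)


def write_attenuation_volume(volume: AttenuationVolume, path) -> None:
    affine = np.diag([*volume.spacing, 1.0])
    nib.save(nib.Nifti1Image(volume.grid.astype(np.float32), affine), str(path))


def write_mask(mask: LungSegmentation, path,
               spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))


def write_scan_pair(pair: ScanPair, directory, prefix: str = "subject") -> dict:
    """Write the four NIfTI files of a pair; returns a manifest row dict."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "insp_volume": directory / f"{prefix}_insp.nii.gz",
        "insp_mask": directory / f"{prefix}_insp_mask.nii.gz",
        "exp_volume": directory / f"{prefix}_exp.nii.gz",
        "exp_mask": directory / f"{prefix}_exp_mask.nii.gz",
    }
    write_attenuation_volume(pair.insp_volume, paths["insp_volume"])
    write_mask(pair.insp_mask, paths["insp_mask"], pair.insp_volume.spacing)
    write_attenuation_volume(pair.exp_volume, paths["exp_volume"])
    write_mask(pair.exp_mask, paths["exp_mask"], pair.exp_volume.spacing)
    return {
        "subject_id": pair.subject_id or prefix,
        **{k: str(v) for k, v in paths.items()},
        "smoking_status": SmokingStatus(pair.smoking_status).value,
    }


def read_scan_pair(row) -> ScanPair:
    """Build a validated ScanPair from one manifest row (mapping or Series)."""
    row = dict(row)
    subject = str(row.get("subject_id", ""))

    def _load(kind, loader, phase):
        try:
            return loader(row[kind])
        except ScanReadError as exc:
            raise ScanReadError(f"subject {subject}, {phase}: {exc}",
                                subject_id=subject, phase=phase) from exc

    pair = ScanPair(
        insp_volume=_load("insp_volume", read_attenuation_volume, "inspiratory"),
        insp_mask=_load("insp_mask", read_mask, "inspiratory"),
        exp_volume=_load("exp_volume", read_attenuation_volume, "expiratory"),
        exp_mask=_load("exp_mask", read_mask, "expiratory"),
        smoking_status=SmokingStatus(row.get("smoking_status", "former")),
        subject_id=subject,
    )
    return pair


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for a manifest-driven batch analysis."""

    manifest: Path
    output_dir: Path
    clinical_table: Path | None = None
    emphysema_threshold_hu: float = -950.0
    gas_trapping_threshold_hu: float = -856.0
    stratify: bool = True
    outcomes: tuple = DEFAULT_OUTCOMES
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        self.manifest = Path(self.manifest)
        self.output_dir = Path(self.output_dir)
        if self.clinical_table is not None:
            self.clinical_table = Path(self.clinical_table)
        if not self.emphysema_threshold_hu < self.gas_trapping_threshold_hu:
            raise ConfigError(
                "emphysema threshold must be below the gas-trapping threshold "
                f"({self.emphysema_threshold_hu} vs {self.gas_trapping_threshold_hu})"
            )


@dataclass
class PipelineResult:
    n_manifest: int
    n_analyzed: int
    n_excluded: int
    exclusions: list
    metrics: pd.DataFrame
    artifacts: dict


def compute_manifest_metrics(manifest: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-subject metrics for every readable pair; unreadable ones are
    dropped and counted, mirroring the exclusion of failed scans."""
    rows, exclusions = [], []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        try:
            pair = read_scan_pair(row)
            metrics = compute_scan_pair_metrics(pair)
        except Exception as exc:
            logger.warning("excluding subject %s: %s", sid, exc)
            exclusions.append({"subject_id": sid, "reason": str(exc)})
            continue
        rows.append({"subject_id": sid,
                     "smoking_status": SmokingStatus(row["smoking_status"]).value,
                     **metrics.to_dict()})
    return pd.DataFrame(rows), exclusions


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Manifest → metrics → residual fit → correlations → models → report."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "seed.json").write_text(json.dumps({"seed": config.seed}))

    manifest = pd.read_csv(config.manifest)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ConfigError(f"manifest is missing columns: {missing}")

    metrics, exclusions = compute_manifest_metrics(manifest)
    if metrics.empty:
        raise ValidationError("no subject produced metrics; nothing to analyze")
    artifacts = {}

    if exclusions:
        excl = pd.DataFrame(exclusions)
        excl.to_csv(out / "exclusions.csv", index=False)
        artifacts["exclusions"] = out / "exclusions.csv"

    table = metrics
    if config.clinical_table is not None:
        clinical = pd.read_csv(config.clinical_table)
        table = table.merge(clinical, on="subject_id", how="left",
                            suffixes=("", "_clinical"))

    # residualized gas trapping (cohort-level fourth measure)
    if len(table) >= 3 and table["insp_950"].nunique() > 1:
        fit = GasTrappingResidualModel.from_dataframe(table).fit()
        table = table.assign(residual=fit.residuals)
        fit.to_json(out / "residual_fit.json")
        artifacts["residual_fit"] = out / "residual_fit.json"

    table.to_csv(out / "metrics.csv", index=False)
    artifacts["metrics"] = out / "metrics.csv"

    measures = [m for m in ("exp_856", "ei_mla", "rvc_856_950", "residual")
                if m in table.columns]
    outcomes = [o for o in config.outcomes if o in table.columns]
    report_lines = [
        "# Paired inspiratory-expiratory CT analysis",
        "",
        f"Subjects in manifest: {len(manifest)}",
        f"Analyzed: {len(metrics)}; excluded (unreadable/failed scans): {len(exclusions)}",
        "",
    ]

    strata = cohort_mod.stratify_cohort(table) if config.stratify else {"all": table}
    corr_rows, model_rows = [], []
    for name, subset in strata.items():
        report_lines.append(f"## Stratum: {name} (n = {len(subset)})")
        if len(subset) < 4 or not outcomes:
            report_lines.append("too few subjects or no clinical outcomes; skipped\n")
            continue
        ctab = cohort_mod.correlation_matrix(subset, measures, outcomes)
        tidy = ctab.to_tidy().assign(stratum=name)
        corr_rows.append(tidy)
        report_lines.append(ctab.r.round(3).to_string())
        report_lines.append("")
        for outcome in outcomes:
            for gas in ("exp_856", "ei_mla", "rvc_856_950"):
                if gas not in subset.columns or outcome == gas:
                    continue
                try:
                    res = cohort_mod.joint_outcome_model(subset, outcome, gas)
                except Exception as exc:
                    logger.info("model %s~%s in %s skipped: %s", outcome, gas, name, exc)
                    continue
                model_rows.append({**res.to_row(), "stratum": name})

    if corr_rows:
        pd.concat(corr_rows).to_csv(out / "correlations.csv", index=False)
        artifacts["correlations"] = out / "correlations.csv"
    if model_rows:
        pd.DataFrame(model_rows).to_csv(out / "models.csv", index=False)
        artifacts["models"] = out / "models.csv"
        report_lines.append("## Joint emphysema + gas-trapping models")
        report_lines.append(
            pd.DataFrame(model_rows).round(4).to_string(index=False)
        )

    (out / "report.md").write_text("\n".join(report_lines) + "\n")
    artifacts["report"] = out / "report.md"

    return PipelineResult(
        n_manifest=len(manifest),
        n_analyzed=len(metrics),
        n_excluded=len(exclusions),
        exclusions=exclusions,
        metrics=table,
        artifacts=artifacts,
    )
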