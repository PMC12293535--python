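"""Batch orchestration: images -> contours -> DS cohort -> reports.

File naming convention for images and contour CSVs is
``<subjectID>_<vertebra>.<ext>`` with the vertebra token drawn from the
19-label vocabulary (C7, T1..T12, L1..L5, S1). Every stage writes a manifest
(one record per attempted unit, failures carry reasons) and records the
configuration hash and seed, so reruns with the same configuration are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_stats
from . import ml, power
from .contour import image_to_contour, load_image
from .ellipse import FitConfig, fit_ellipse
from .errors import ValidationError, VertdsError
from .phantoms import VERTEBRAE

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_extract_batch", "run_ds_batch", "run_full_report"]


@dataclass(frozen=True)
class RunConfig:
    """Shared settings of a batch run."""

    ref_len_mm: float = 35.0
    ref_len_px: float = 350.0
    tau_px: float = 2.0
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 42
    strict: bool = True  # drop subjects missing any vertebra
    models: tuple = ml.MODEL_NAMES

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a flat YAML mapping.

        Keys mirror the dataclass fields; ``fit.*`` entries populate the
        nested :class:`FitConfig`. Unknown keys raise.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: expected a key-value mapping")
        fit_kwargs = raw.pop("fit", {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(fit=FitConfig(**fit_kwargs), **raw)


def _parse_name(path: Path) -> tuple[str, str]:
    stem = path.stem
    if "_" not in stem:
        raise ValidationError(f"{path.name}: expected <subject>_<vertebra> naming")
    subject, vertebra = stem.rsplit("_", 1)
    if vertebra not in VERTEBRAE:
        raise ValidationError(f"{path.name}: unknown vertebra token {vertebra!r}")
    return subject, vertebra


def _write_manifest(records: list[dict], out_dir: Path, stage: str, config: RunConfig):
    man = pd.DataFrame(records)
    man["stage"] = stage
    man["config_hash"] = config.config_hash()
    man["seed"] = config.seed
    man.to_csv(out_dir / f"manifest_{stage}.csv", index=False)
    return man


def run_extract_batch(image_dir: str | Path, out_dir: str | Path,
                      config: RunConfig | None = None) -> pd.DataFrame:
    """Extract one contour CSV per ``subject_vertebra`` image.

    Per-image failures are logged in the manifest and the run continues; an
    unreadable directory is fatal.
    """
    config = config or RunConfig()
    image_dir, out_dir = Path(image_dir), Path(out_dir)
    if not image_dir.is_dir():
        raise ValidationError(f"not a directory: {image_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    paths = sorted(p for p in image_dir.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    for path in paths:
        rec = {"file": path.name, "status": "ok", "reason": ""}
        try:
            subject, vertebra = _parse_name(path)
            contour = image_to_contour(
                load_image(path), config.ref_len_mm, config.ref_len_px,
                tau_px=config.tau_px,
            )
            contour.to_csv(out_dir / f"{subject}_{vertebra}.csv")
            rec.update(subject=subject, vertebra=vertebra, n_points=len(contour))
        except (VertdsError, OSError) as exc:
            rec.update(status="failed", reason=str(exc))
            logger.warning("extraction failed for %s: %s", path.name, exc)
        records.append(rec)
    return _write_manifest(records, out_dir, "extract", config)


def run_ds_batch(contour_dir: str | Path, metadata_csv: str | Path,
                 out_dir: str | Path, config: RunConfig | None = None) -> pd.DataFrame:
    """Fit every contour, assemble the cohort table with 19 DS columns.

    ``metadata_csv`` must carry ``subject_id, sex, age``. Contours whose
    subject is absent from the metadata raise an error listing the orphans.
    Subjects missing any vertebra are flagged; in strict mode they are
    dropped from the cohort CSV.
    """
    config = config or RunConfig()
    contour_dir, out_dir = Path(contour_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(metadata_csv, dtype={"subject_id": str})
    if not {"subject_id", "sex", "age"} <= set(meta.columns):
        raise ValidationError("metadata needs subject_id, sex, age columns")
    known = set(meta["subject_id"])
    ds: dict[str, dict[str, float]] = {}
    records = []
    csvs = sorted(contour_dir.glob("*.csv"))
    csvs = [p for p in csvs if not p.name.startswith("manifest")]
    orphans = sorted({_parse_name(p)[0] for p in csvs} - known)
    if orphans:
        raise ValidationError(f"contours without metadata for subjects: {orphans}")
    for path in csvs:
        subject, vertebra = _parse_name(path)
        rec = {"file": path.name, "subject": subject, "vertebra": vertebra,
               "status": "ok", "reason": ""}
        try:
            from .contour import Contour

            result = fit_ellipse(Contour.from_csv(path), config=config.fit)
            ds.setdefault(subject, {})[vertebra] = result.ds
            rec["ds"] = result.ds
            rec["converged"] = result.converged
        except VertdsError as exc:
            rec.update(status="failed", reason=str(exc))
            logger.warning("fit failed for %s: %s", path.name, exc)
        records.append(rec)
    rows = []
    for _, m in meta.iterrows():
        values = ds.get(m["subject_id"], {})
        missing = [v for v in VERTEBRAE if v not in values]
        if missing:
            logger.warning("subject %s missing vertebrae %s", m["subject_id"], missing)
            if config.strict:
                records.append({"file": "", "subject": m["subject_id"], "vertebra": "",
                                "status": "dropped",
                                "reason": f"missing {','.join(missing)}"})
                continue
        row = {"subject_id": m["subject_id"], "sex": m["sex"], "age": m["age"]}
        row.update({v: values.get(v, np.nan) for v in VERTEBRAE})
        rows.append(row)
    cohort = pd.DataFrame(rows)
    cohort.to_csv(out_dir / "cohort.csv", index=False)
    _write_manifest(records, out_dir, "ds", config)
    return cohort


def run_full_report(cohort_csv: str | Path, out_dir: str | Path,
                    config: RunConfig | None = None) -> dict:
    """Descriptives, correlations, ANCOVA screen, MLR, LASSO, ML and power.

    Writes tidy CSV/JSON tables plus a human-readable ``summary.txt``; every
    artifact carries the configuration hash and seed. Returns the bundle as
    a dict of in-memory objects.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = cohort_stats.load_cohort(cohort_csv)
    bundle: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    desc = cohort_stats.descriptive_stats(cohort)
    desc.to_csv(out_dir / "descriptives.csv")
    bundle["descriptives"] = desc

    corr = cohort_stats.age_correlations(cohort)
    corr.to_csv(out_dir / "age_correlations.csv")
    bundle["correlations"] = corr

    screen = cohort_stats.ancova_interaction_screen(cohort)
    bundle["ancova"] = screen

    summary_lines = [
        f"vertds full report  (config {config.config_hash()}, seed {config.seed})",
        "",
        f"ANCOVA sex-interaction screen: F = {screen.statistic:.2f}, "
        f"p = {screen.p_joint:.4g} (min term p = {screen.p_min_term:.4g}) -> "
        + ("sex-stratified models" if screen.stratify() else "pooled model acceptable"),
        "",
    ]
    spec = ml.SplitSpec(seed=config.seed)
    ml_rows = []
    for sex in ("M", "F"):
        sub = cohort[cohort["sex"] == sex]
        mlr = cohort_stats.mlr_fit(cohort, sex)
        bundle[f"mlr_{sex}"] = mlr
        summary_lines += [mlr.summary(), ""]
        lasso = cohort_stats.lasso_fit(cohort, sex, seed=config.seed)
        bundle[f"lasso_{sex}"] = lasso
        summary_lines.append(
            f"LASSO ({sex}): alpha = {lasso.alpha:.3g}, {lasso.k_nonzero} nonzero, "
            f"test SEE = {lasso.test_see:.2f} y")
        pw = power.power_report(mlr.r2, mlr.n, mlr.k)
        bundle[f"power_{sex}"] = pw
        summary_lines += ["", f"Power analysis ({sex}):", pw.summary(), ""]
        train, test = ml.make_split(sub, spec)
        for name in config.models:
            model, cv_r2 = ml.tune_model(train, name, spec=spec)
            report = ml.evaluate(model, test, model_name=name, sex=sex,
                                 cv_r2=cv_r2, seed=config.seed)
            bundle[f"ml_{name}_{sex}"] = report
            ml_rows.append({
                "sex": sex, "model": name, "holdout_r2": report.holdout_r2,
                "r2_ci_lo": report.r2_ci_lo, "r2_ci_hi": report.r2_ci_hi,
                "see_years": report.see_years, "see_ci_lo": report.see_ci_lo,
                "see_ci_hi": report.see_ci_hi, "mae_years": report.mae_years,
                "rmse_years": report.rmse_years, "cv_r2": report.cv_r2,
                "oob_r2": report.oob_r2,
            })
            summary_lines += [report.summary(), ""]
    ml_table = pd.DataFrame(ml_rows)
    ml_table.to_csv(out_dir / "ml_performance.csv", index=False)
    bundle["ml_table"] = ml_table
    (out_dir / "summary.txt").write_text("\n".join(summary_lines))
    with open(out_dir / "power.json", "w") as fh:
        json.dump({s: dataclasses.asdict(bundle[f"power_{s}"]) for s in ("M", "F")},
                  fh, indent=2)
    return bundle
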