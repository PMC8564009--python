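"""Configuration-driven end-to-end experiments and report generation.

An experiment runs the full analysis grid — feature sets (three
single-modality, three fused) crossed with the three classifiers — on
either a synthetic dataset or a directory of stored cubes, and writes:

* ``cv_accuracy.csv`` / ``prediction_accuracy.csv`` — feature-set x
  classifier grids of mean 10-fold cross-validation accuracy and held-out
  prediction accuracy (percent);
* ``confusion_<set>_<classifier>.csv`` (+ ``.png`` heatmaps) — per-cell
  confusion matrices;
* ``report.json`` — everything above plus per-class precision/recall, the
  config snapshot, its hash and the seed;
* ``run.log`` — per-stage wall times (informational only; no result
  depends on timing, and the log is the only timestamped output).

Reports regenerate byte-identically from the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cube import MultispectralCube, RoiMask, load_cube, save_cube, segment_roi
from .evaluate import (
    CLASS_ORDER,
    CLASSIFIER_KINDS,
    ClassifierSpec,
    SplitSpec,
    cross_validate,
    make_split,
    train_predict,
)
from .fusion import FeatureMatrix, fuse
from .spectral import (
    CIELAB_FEATURE_NAMES,
    DEFAULT_WHITE_POINT,
    RgbMapping,
    cielab_features,
    ms_feature_names,
    ms_features,
)
from .synthetic import GeneratorConfig, iter_dataset
from .texture import GlcmConfig, extract_texture, texture_feature_names

__all__ = [
    "DEFAULT_FEATURE_SETS",
    "PipelineConfig",
    "extract_features",
    "features_from_cubes",
    "run_experiment",
    "write_feature_table",
    "read_feature_table",
]

logger = logging.getLogger("msibeef")

#: The experiment grid's feature sets, in report row order.
DEFAULT_FEATURE_SETS: tuple[tuple[str, ...], ...] = (
    ("MS",),
    ("CIELAB",),
    ("Texture",),
    ("MS", "Texture"),
    ("CIELAB", "Texture"),
    ("MS", "Texture", "CIELAB"),
)

_CLASSIFIER_LABELS = {"lda": "LDA", "linear_svm": "LSVM", "random_forest": "RF"}


def feature_set_name(modalities: tuple[str, ...]) -> str:
    return "+".join(modalities)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one experiment run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_directory: str | None = None  # overrides the generator when set
    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    rgb_mapping: RgbMapping = field(default_factory=RgbMapping)
    white_point: tuple[float, float, float] = DEFAULT_WHITE_POINT
    roi_method: str = "full_frame"
    split: SplitSpec = field(default_factory=SplitSpec)
    cv_folds: int = 10
    svm_c: float = 0.6
    rf_n_trees: int = 160
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    feature_sets: tuple[tuple[str, ...], ...] = DEFAULT_FEATURE_SETS
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(
            self,
            seed=seed,
            generator=replace(self.generator, seed=seed),
            split=replace(self.split, seed=seed),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["class_templates"] = [
            asdict(t) for t in self.generator.class_templates
        ]
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        if "generator" in raw:
            g = dict(raw["generator"])
            if "image_size" in g:
                g["image_size"] = tuple(g["image_size"])
            if "class_templates" in g:
                from .synthetic import ClassTemplate

                g["class_templates"] = tuple(
                    ClassTemplate(**t) for t in g["class_templates"]
                )
            kwargs["generator"] = GeneratorConfig(**g)
        if "glcm" in raw:
            g = dict(raw["glcm"])
            rename = {
                "levels": "n_levels",
                "angles": "angles_deg",
                "average_angles": "average_over_angles",
            }
            g = {rename.get(k, k): v for k, v in g.items()}
            if "angles_deg" in g:
                g["angles_deg"] = tuple(g["angles_deg"])
            kwargs["glcm"] = GlcmConfig(**g)
        if "rgb_bands_nm" in raw:
            r, g_, b = raw["rgb_bands_nm"]
            kwargs["rgb_mapping"] = RgbMapping(r, g_, b)
        if "white_point" in raw:
            kwargs["white_point"] = tuple(raw["white_point"])
        if "split" in raw:
            kwargs["split"] = SplitSpec(**raw["split"])
        if "feature_sets" in raw:
            kwargs["feature_sets"] = tuple(tuple(fs) for fs in raw["feature_sets"])
        if "classifiers" in raw:
            kwargs["classifiers"] = tuple(raw["classifiers"])
        for key in ("input_directory", "roi_method", "cv_folds", "svm_c", "rf_n_trees", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _extract_one(
    cube: MultispectralCube, mask: RoiMask, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ms = ms_features(cube, mask)
    lab = cielab_features(cube, mask, config.rgb_mapping, config.white_point)
    tex = extract_texture(cube, mask, config.glcm)
    return ms, lab, tex


def _assemble(
    ms_rows, lab_rows, tex_rows, labels, band_centers
) -> FeatureMatrix:
    ms_block = FeatureMatrix(
        np.vstack(ms_rows),
        tuple(ms_feature_names(band_centers)),
        ("MS",) * len(band_centers),
        labels=np.asarray(labels),
    )
    tex_block = FeatureMatrix(
        np.vstack(tex_rows),
        tuple(texture_feature_names(band_centers)),
        ("Texture",) * (4 * len(band_centers)),
        labels=np.asarray(labels),
    )
    lab_block = FeatureMatrix(
        np.vstack(lab_rows),
        CIELAB_FEATURE_NAMES,
        ("CIELAB",) * 3,
        labels=np.asarray(labels),
    )
    # block order MS, Texture, CIELAB fixes the fused column ordering
    return fuse([ms_block, tex_block, lab_block])


def extract_features(config: PipelineConfig) -> FeatureMatrix:
    """All-modality feature table for the configured input source.

    Synthetic samples are generated and consumed one at a time, so memory
    stays flat regardless of dataset size.
    """
    if config.input_directory is not None:
        return features_from_cubes(Path(config.input_directory), config)
    ms_rows, lab_rows, tex_rows, labels = [], [], [], []
    for sample in iter_dataset(config.generator):
        mask = (
            sample.mask
            if config.roi_method == "full_frame"
            else segment_roi(sample.cube, config.roi_method)
        )
        ms, lab, tex = _extract_one(sample.cube, mask, config)
        ms_rows.append(ms)
        lab_rows.append(lab)
        tex_rows.append(tex)
        labels.append(sample.label)
    return _assemble(ms_rows, lab_rows, tex_rows, labels, config.generator.band_centers_nm)


def features_from_cubes(directory: Path, config: PipelineConfig) -> FeatureMatrix:
    """Feature table from a directory of stored cubes plus ``manifest.csv``."""
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"{directory} has no manifest.csv (sample_id,class) mapping cubes to labels"
        )
    manifest = pd.read_csv(manifest_path)
    for col in ("sample_id", "class"):
        if col not in manifest.columns:
            raise ValueError(f"manifest.csv must have a {col!r} column")
    ms_rows, lab_rows, tex_rows, labels = [], [], [], []
    band_centers: tuple[float, ...] | None = None
    for _, row in manifest.iterrows():
        cube = load_cube(directory / f"{row['sample_id']}.tif")
        band_centers = cube.band_centers_nm
        mask = (
            RoiMask(np.ones(cube.spatial_shape, dtype=bool))
            if config.roi_method == "full_frame"
            else segment_roi(cube, config.roi_method)
        )
        ms, lab, tex = _extract_one(cube, mask, config)
        ms_rows.append(ms)
        lab_rows.append(lab)
        tex_rows.append(tex)
        labels.append(row["class"])
    if band_centers is None:
        raise ValueError(f"manifest.csv in {directory} lists no samples")
    return _assemble(ms_rows, lab_rows, tex_rows, labels, band_centers)


def write_feature_table(features: FeatureMatrix, path: str | Path) -> None:
    """Persist a feature table as CSV with a JSON schema sidecar."""
    path = Path(path)
    # default float formatting is the shortest round-trippable repr
    features.to_dataframe().to_csv(path, index=False)
    schema = {
        "names": list(features.names),
        "modalities": list(features.modalities),
        "normalized": features.normalization is not None,
    }
    path.with_name(path.name + ".schema.json").write_text(json.dumps(schema, indent=2))


def read_feature_table(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    schema_path = path.with_name(path.name + ".schema.json")
    if not schema_path.exists():
        raise FileNotFoundError(f"feature table schema sidecar missing: {schema_path}")
    schema = json.loads(schema_path.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    fm = FeatureMatrix.from_dataframe(df, schema["modalities"])
    if list(fm.names) != schema["names"]:
        raise ValueError("feature table columns disagree with schema sidecar")
    return fm


def _grid_tables(results: dict, feature_sets, classifiers) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows_cv, rows_pred = [], []
    for fs in feature_sets:
        name = feature_set_name(fs)
        cv_row = {"feature_set": name, "n_features": results[name]["n_features"]}
        pred_row = dict(cv_row)
        for kind in classifiers:
            label = _CLASSIFIER_LABELS[kind]
            cell = results[name][kind]
            cv_row[label] = round(cell["cv_mean_accuracy"], 2)
            pred_row[label] = round(cell["prediction_accuracy"], 2)
        rows_cv.append(cv_row)
        rows_pred.append(pred_row)
    return pd.DataFrame(rows_cv), pd.DataFrame(rows_pred)


def _save_confusion_heatmap(counts: np.ndarray, class_names, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    ax.imshow(counts, cmap="Blues")
    ax.set_xticks(range(len(class_names)), class_names, rotation=45, ha="right")
    ax.set_yticks(range(len(class_names)), class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title, fontsize=9)
    for i in range(len(class_names)):
        for j in range(len(class_names)):
            ax.text(j, i, str(counts[i, j]), ha="center", va="center", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_experiment(
    config: PipelineConfig,
    out_dir: str | Path,
    features: FeatureMatrix | None = None,
    heatmaps: bool = True,
) -> dict:
    """Run the full feature-set x classifier grid and write all reports.

    A failure in one grid cell is logged and recorded; remaining cells
    still run.  Returns the report dictionary (also written as JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    log_lines = [f"config_hash={cfg_hash}", f"seed={config.seed}"]

    t0 = time.perf_counter()
    if features is None:
        features = extract_features(config)
    log_lines.append(f"feature_extraction_s={time.perf_counter() - t0:.2f}")

    calibration, prediction = make_split(features, config.split)
    results: dict = {}
    for fs in config.feature_sets:
        name = feature_set_name(fs)
        cal_fs = calibration.select_modalities(fs)
        pred_fs = prediction.select_modalities(fs)
        results[name] = {"n_features": cal_fs.n_features}
        for kind in config.classifiers:
            spec = ClassifierSpec(
                kind=kind, svm_c=config.svm_c, rf_n_trees=config.rf_n_trees, seed=config.seed
            )
            t1 = time.perf_counter()
            try:
                cv = cross_validate(cal_fs, spec, k=config.cv_folds, seed=config.seed)
                pred = train_predict(cal_fs, pred_fs, spec)
            except Exception as exc:  # pragma: no cover - defensive per-cell isolation
                logger.error("grid cell (%s, %s) failed: %s", name, kind, exc)
                results[name][kind] = {"error": str(exc)}
                log_lines.append(f"cell {name}/{kind}: FAILED ({exc})")
                continue
            results[name][kind] = {
                "cv_mean_accuracy": cv.mean_accuracy,
                "cv_fold_accuracies": list(cv.fold_accuracies),
                "prediction_accuracy": pred.accuracy,
                "confusion": pred.confusion.counts.tolist(),
                "confusion_classes": list(pred.confusion.class_names),
                "per_class": pred.per_class,
            }
            log_lines.append(
                f"cell {name}/{kind}: cv={cv.mean_accuracy:.2f}% "
                f"pred={pred.accuracy:.2f}% ({time.perf_counter() - t1:.2f}s)"
            )
            stem = f"confusion_{name.replace('+', '_')}_{kind}"
            pd.DataFrame(
                pred.confusion.counts,
                index=pred.confusion.class_names,
                columns=pred.confusion.class_names,
            ).to_csv(out / f"{stem}.csv")
            if heatmaps:
                _save_confusion_heatmap(
                    pred.confusion.counts,
                    pred.confusion.class_names,
                    out / f"{stem}.png",
                    f"{name} / {_CLASSIFIER_LABELS[kind]}",
                )

    cv_table, pred_table = _grid_tables(results, config.feature_sets, config.classifiers)
    cv_table.to_csv(out / "cv_accuracy.csv", index=False)
    pred_table.to_csv(out / "prediction_accuracy.csv", index=False)
    report = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "config": config.to_dict(),
        "results": results,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=list))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report


def simulate_to_directory(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Write the synthetic dataset as cube files plus a ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in iter_dataset(config.generator):
        save_cube(sample.cube, out / f"{sample.sample_id}.tif")
        row = {"sample_id": sample.sample_id, "class": sample.label, "seed": config.generator.seed}
        row.update(sample.truth)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out
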