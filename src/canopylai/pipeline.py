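"""One-command reproduction of the full study design on synthetic data.

``run_experiment`` wires every stage together: scene generation ->
feature engineering (23 vegetation indices + 40 GLCM textures) ->
feature optimization per input regime -> a seeded 70/30 split -> PLSR and
RF on the selected features, CNN on raw augmented patches -> test-set
evaluation -> (optionally) scene-wide LAI maps and a pairwise
model-agreement report.  A single integer seed fans out deterministically
to all stages.
"""

from __future__ import annotations

import dataclasses
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BandOptics, GLCMConfig, SceneConfig, SplitSpec, save_config
from .evaluation import EvalReport, agreement_report, metrics, render_lai_map
from .indices import VI_NAMES, vi_feature_table
from .models import CNNRegressor, fit_plsr, fit_rf
from .raster import extract_patches, write_raster
from .selection import ImportanceCorrelationSelector
from .splits import augment_patches, split_samples
from .synthetic import make_scene
from .texture import texture_feature_table

#: the three feature regimes for the classical models
REGIMES = ("VI", "T", "VI+T")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails, naming the stage."""


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, driven by a single seed."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    optics: BandOptics | None = None
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    regimes: tuple = REGIMES
    weight_threshold: float = 0.03
    p_threshold: float = 0.01
    selection_trees: int = 500
    rf_trees: int = 1000
    plsr_cv_folds: int = 10
    cnn_epochs: int = 60
    cnn_patience: int = 10
    cnn_batch_size: int = 32
    fit_cnn: bool = True
    make_maps: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        # the experiment seed fans out to every stage
        self.scene = dataclasses.replace(self.scene, seed=self.seed)
        self.split = dataclasses.replace(self.split, seed=self.seed + 1)

    def to_dict(self) -> dict:
        return {
            "scene": self.scene.to_dict(),
            "optics": None if self.optics is None else self.optics.to_dict(),
            "glcm": self.glcm.to_dict(),
            "split": self.split.to_dict(),
            "regimes": list(self.regimes),
            "weight_threshold": self.weight_threshold,
            "p_threshold": self.p_threshold,
            "selection_trees": self.selection_trees,
            "rf_trees": self.rf_trees,
            "plsr_cv_folds": self.plsr_cv_folds,
            "cnn_epochs": self.cnn_epochs,
            "cnn_patience": self.cnn_patience,
            "cnn_batch_size": self.cnn_batch_size,
            "fit_cnn": self.fit_cnn,
            "make_maps": self.make_maps,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d) -> "ExperimentConfig":
        d = dict(d)
        d["scene"] = SceneConfig.from_dict(d.get("scene", {}))
        if d.get("optics") is not None:
            d["optics"] = BandOptics.from_dict(d["optics"])
        d["glcm"] = GLCMConfig.from_dict(d.get("glcm", {}))
        d["split"] = SplitSpec.from_dict(d.get("split", {}))
        if "regimes" in d:
            d["regimes"] = tuple(d["regimes"])
        return cls(**d)


@dataclass
class ExperimentResult:
    """Artifacts of one experiment run."""

    results: pd.DataFrame  # Table-4-shaped: model x input variable x metrics
    selections: dict[str, pd.DataFrame]
    selected_features: dict[str, list[str]]
    reports: dict[tuple[str, str], EvalReport]
    test_predictions: dict[str, np.ndarray]
    y_test: np.ndarray
    agreement: pd.DataFrame
    models: dict
    maps: dict[str, np.ndarray]
    artifact_paths: dict[str, str]


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(f"pipeline stage {name!r} failed: {exc}") from exc

    return wrap


def select_for_regime(
    regime: str,
    vi_table: pd.DataFrame,
    tex_table: pd.DataFrame,
    y,
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Run feature optimization within one input regime.

    "VI" and "T" select within their own candidate pool; "VI+T" selects
    from the joint pool.  If the strict threshold pair keeps nothing
    (possible on very noisy scenes), the three largest-weight
    significant features are used so the downstream models remain
    fittable; the selection table still records the strict outcome.
    """
    if regime == "VI":
        pool = vi_table
    elif regime == "T":
        pool = tex_table
    elif regime == "VI+T":
        pool = pd.concat([vi_table, tex_table], axis=1)
    else:
        raise ValueError(f"unknown regime {regime!r}; valid: {REGIMES}")
    selector = ImportanceCorrelationSelector(
        weight_threshold=config.weight_threshold,
        p_threshold=config.p_threshold,
        n_trees=config.selection_trees,
        random_state=config.seed + 2,
    )
    selector.fit(pool, y)
    selected = list(selector.selected_features_)
    if not selected:
        significant = selector.result_[selector.result_["p"] <= config.p_threshold]
        fallback = significant.sort_values("weight", ascending=False)["feature"].head(3)
        selected = [str(f) for f in fallback]
    return pool, selected, selector.result_


def run_experiment(config: ExperimentConfig | None = None, out_dir=None) -> ExperimentResult:
    """Execute the full synthetic study and return all artifacts.

    With ``out_dir`` set, rasters, tables, per-regime selection results,
    serialized models and a manifest of every artifact path are written
    there as well.
    """
    config = config or ExperimentConfig()
    paths: dict[str, str] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stack, lai_true, quadrats = _stage("simulate")(make_scene, config.scene, config.optics)
    patches = _stage("patches")(extract_patches, stack, quadrats)
    y = quadrats.lai_measured

    vi_table = _stage("vegetation_indices")(vi_feature_table, stack, quadrats)
    tex_table = _stage("texture_features")(
        texture_feature_table, stack, quadrats, None, config.glcm
    )

    trainval_ids, test_ids = _stage("split")(split_samples, quadrats.ids, config.split)
    id_index = pd.Index(quadrats.ids)
    tv = id_index.get_indexer(trainval_ids)
    te = id_index.get_indexer(test_ids)
    y_test = y[te]

    results_rows = []
    selections: dict[str, pd.DataFrame] = {}
    selected_features: dict[str, list[str]] = {}
    reports: dict[tuple[str, str], EvalReport] = {}
    predictions: dict[str, np.ndarray] = {}
    models: dict = {}

    for regime in config.regimes:
        pool, selected, table = _stage(f"select[{regime}]")(
            select_for_regime, regime, vi_table.iloc[tv], tex_table.iloc[tv], y[tv], config
        )
        selections[regime] = table
        selected_features[regime] = selected
        full_pool = pd.concat([vi_table, tex_table], axis=1)[selected]

        plsr = _stage(f"plsr[{regime}]")(
            fit_plsr, full_pool.iloc[tv], y[tv],
            cv_folds=config.plsr_cv_folds, seed=config.seed + 3,
        )
        rf = _stage(f"rf[{regime}]")(
            fit_rf, full_pool.iloc[tv], y[tv], n_trees=config.rf_trees, seed=config.seed + 4
        )
        for name, model in (("PLSR", plsr), ("RF", rf)):
            pred = np.asarray(model.predict(full_pool.iloc[te].to_numpy())).ravel() \
                if name == "RF" else model.predict(full_pool.iloc[te])
            report = metrics(y_test, pred)
            reports[(name, regime)] = report
            predictions[f"{name}:{regime}"] = pred
            models[(name, regime)] = model
            results_rows.append(
                {"model": name, "input_variable": regime,
                 "n_features": len(selected), **report.to_dict()}
            )

    cnn = None
    if config.fit_cnn:
        # CNN on raw patches: augment the train+val pool sixfold, never the test set
        cnn = CNNRegressor(
            epochs=config.cnn_epochs,
            patience=config.cnn_patience,
            batch_size=config.cnn_batch_size,
            val_fraction=1 - config.split.cnn_train_fraction,
            random_state=config.seed + 5,
        )
        augmented = _stage("augment")(augment_patches, patches.subset(tv))
        _stage("cnn")(cnn.fit, augmented.patches, augmented.lai)
        cnn_pred = cnn.predict(patches.subset(te).patches)
        report = metrics(y_test, cnn_pred)
        reports[("CNN", "Scaled raw image")] = report
        predictions["CNN"] = cnn_pred
        models[("CNN", "Scaled raw image")] = cnn
        results_rows.append(
            {"model": "CNN", "input_variable": "Scaled raw image", "n_features": np.nan,
             **report.to_dict()}
        )

    results = pd.DataFrame(results_rows)

    # pairwise agreement of the models' best test predictions
    best_regime = "VI+T" if "VI+T" in config.regimes else config.regimes[0]
    agree_preds = {
        "PLSR": predictions[f"PLSR:{best_regime}"],
        "RF": predictions[f"RF:{best_regime}"],
    }
    if cnn is not None:
        agree_preds["CNN"] = predictions["CNN"]
    agreement = agreement_report(agree_preds)

    maps: dict[str, np.ndarray] = {}
    if config.make_maps:
        feats = selected_features[best_regime]
        maps["PLSR"] = render_lai_map(
            models[("PLSR", best_regime)], stack, feats, config.glcm
        )
        maps["RF"] = render_lai_map(models[("RF", best_regime)], stack, feats, config.glcm)
        if cnn is not None:
            maps["CNN"] = render_lai_map(cnn, stack)

    if out is not None:
        gt = stack.geotransform
        write_raster(stack.values, gt, out / "scene.tif", band_names=list(stack.band_names))
        write_raster(lai_true, gt, out / "lai_true.tif", band_names=["lai"])
        quadrats.to_csv(out / "quadrats.csv")
        pd.concat([vi_table, tex_table], axis=1).to_csv(out / "features.csv")
        paths.update(
            scene=str(out / "scene.tif"), lai_true=str(out / "lai_true.tif"),
            quadrats=str(out / "quadrats.csv"), features=str(out / "features.csv"),
        )
        for regime, table in selections.items():
            p = out / f"selection_{regime.replace('+', '_')}.csv"
            table.to_csv(p, index=False)
            paths[f"selection[{regime}]"] = str(p)
        results.to_csv(out / "results.csv", index=False)
        try:
            (out / "results.md").write_text(results.to_markdown(index=False))
        except ImportError:  # markdown rendering needs optional tabulate
            (out / "results.md").write_text(results.to_string(index=False))
        agreement.to_csv(out / "agreement.csv", index=False)
        paths.update(results=str(out / "results.csv"), agreement=str(out / "agreement.csv"))
        scatter = pd.DataFrame({"y_measured": y_test, **agree_preds})
        scatter.to_csv(out / "test_predictions.csv", index=False)
        paths["test_predictions"] = str(out / "test_predictions.csv")
        for name, plane in maps.items():
            p = out / f"lai_map_{name.lower()}.tif"
            write_raster(plane, gt, p, band_names=["lai"])
            paths[f"map[{name}]"] = str(p)
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for (name, regime), model in models.items():
            p = models_dir / f"{name.lower()}_{regime.replace('+', '_').replace(' ', '_')}.pkl"
            save_model(model, p, feature_names=selected_features.get(regime))
            paths[f"model[{name}:{regime}]"] = str(p)
        save_config(config.scene, out / "scene_config.yaml")
        (out / "manifest.json").write_text(json.dumps(paths, indent=2, sort_keys=True))
        paths["manifest"] = str(out / "manifest.json")

    return ExperimentResult(
        results=results,
        selections=selections,
        selected_features=selected_features,
        reports=reports,
        test_predictions=predictions,
        y_test=y_test,
        agreement=agreement,
        models=models,
        maps=maps,
        artifact_paths=paths,
    )


def save_model(model, path, feature_names=None) -> None:
    """Serialize a fitted model plus its preprocessing state."""
    payload = {"model": model, "feature_names": feature_names, "format_version": 1}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> tuple[object, list[str] | None]:
    """Load a model saved by :func:`save_model`."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return payload["model"], payload.get("feature_names")
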