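"""End-to-end orchestration: images -> features -> preprocess -> split ->
tune -> test -> report, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .classifiers import make_classifier
from .errors import LabelError, RainbowSpecError
from .evaluation import (
    default_grids,
    duplex_split,
    evaluate_predictions,
    grid_search,
)
from .features import DEFAULT_CHANNEL_WEIGHTS, FeatureMatrix, patch_to_vector
from .preprocess import preprocess
from .segmentation import SegmentationConfig, extract_rainbow

log = logging.getLogger("rainbowspec")

IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass
class RunConfig:
    """Settings of one experiment run; serializable to/from JSON."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    channel_weights: tuple = DEFAULT_CHANNEL_WEIGHTS
    preprocess_method: str = "savgol"
    preprocess_kwargs: dict = field(default_factory=dict)
    algorithms: tuple = ("knn", "svm", "plsda", "kplsda", "lwplsc")
    grids: dict | None = None
    split_ratio: tuple = (2, 1)
    label_task: str = "type"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segmentation"] = asdict(self.segmentation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        seg = d.pop("segmentation", {})
        if isinstance(seg, dict):
            seg = {**seg}
            if seg.get("gray_weights") is not None:
                seg["gray_weights"] = tuple(seg["gray_weights"])
            seg = SegmentationConfig(**seg)
        cfg = cls(segmentation=seg, **{k: v for k, v in d.items() if k in cls.__dataclass_fields__ and k != "segmentation"})
        cfg.channel_weights = tuple(cfg.channel_weights)
        cfg.split_ratio = tuple(cfg.split_ratio)
        cfg.algorithms = tuple(cfg.algorithms)
        return cfg

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


def _read_labels(labels_csv) -> dict:
    df = pd.read_csv(labels_csv)
    for col in ("sample_id", "species", "type"):
        if col not in df.columns:
            raise LabelError(f"labels CSV is missing column {col!r}")
    return {row.sample_id: (row.species, row.type) for row in df.itertuples()}


def run_extract(images_dir, config: RunConfig | None = None, labels_csv=None):
    """Segment every image in a directory into one feature-vector row.

    Per-image failures are logged and skipped; returns
    ``(FeatureMatrix, failures)`` and raises if nothing succeeds.
    """
    config = config or RunConfig()
    images_dir = Path(images_dir)
    paths = sorted(p for p in images_dir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS)
    if not paths:
        raise RainbowSpecError(f"no readable images found in {images_dir}")
    labels = _read_labels(labels_csv) if labels_csv else {}
    vectors, species, types, ids, failures = [], [], [], [], []
    for path in paths:
        t0 = time.perf_counter()
        try:
            img = iio.imread(path)
            patch = extract_rainbow(img, config.segmentation)
            vectors.append(patch_to_vector(patch, config.channel_weights))
        except Exception as exc:  # noqa: BLE001 - per-image robustness is the contract
            log.warning("segmentation failed for %s: %s", path.name, exc)
            failures.append((path.name, str(exc)))
            continue
        stem = path.stem
        sp, ty = labels.get(stem, ("unknown", "unknown"))
        species.append(sp)
        types.append(ty)
        ids.append(stem)
        log.info("extracted %s in %.3fs", path.name, time.perf_counter() - t0)
    if not vectors:
        raise RainbowSpecError(
            f"segmentation failed for all {len(paths)} images: {failures}"
        )
    fm = FeatureMatrix(np.vstack(vectors), species, types, ids)
    return fm, failures


def run_experiment(fm: FeatureMatrix, config: RunConfig | None = None) -> dict:
    """Preprocess, DUPLEX-split, tune by LOOCV grid search, fit and test.

    Returns a dict with the split, per-algorithm grid-search results and
    per-algorithm :class:`~rainbowspec.evaluation.EvaluationReport`.
    """
    config = config or RunConfig()
    y = fm.labels(config.label_task)
    if "unknown" in set(y.tolist()):
        raise LabelError("feature matrix contains unlabelled samples")
    processed = preprocess(fm, config.preprocess_method, **config.preprocess_kwargs)
    split = duplex_split(processed.X, config.split_ratio)
    X_train, X_test = processed.X[split.train_idx], processed.X[split.test_idx]
    y_train, y_test = y[split.train_idx], y[split.test_idx]
    grids = config.grids or {}
    reports, searches = {}, {}
    for algorithm in config.algorithms:
        t0 = time.perf_counter()
        grid = grids.get(algorithm) or default_grids()[algorithm]
        search = grid_search(X_train, y_train, algorithm, grid)
        clf = make_classifier(algorithm, search.best_params)
        clf.fit(X_train, y_train)
        pred = clf.predict(X_test)
        report = evaluate_predictions(y_test, pred, sorted(set(y_train.tolist())))
        report.algorithm = algorithm
        report.selected_params = search.best_params
        report.validation_accuracy = search.best_accuracy
        reports[algorithm] = report
        searches[algorithm] = search
        log.info(
            "%s: validation %.1f%% -> test %.1f%% (%.2fs)",
            algorithm, search.best_accuracy, report.overall,
            time.perf_counter() - t0,
        )
    return {"split": split, "searches": searches, "reports": reports}


def write_experiment_outputs(results: dict, out_dir, config: RunConfig,
                             fm: FeatureMatrix | None = None) -> None:
    """Write report.json, report.txt, per-algorithm surfaces and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports = {alg: r.to_dict() for alg, r in results["reports"].items()}
    payload = {
        "split": {
            "train_idx": results["split"].train_idx.tolist(),
            "test_idx": results["split"].test_idx.tolist(),
        },
        "reports": reports,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    lines = [r.to_text() for r in results["reports"].values()]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    for alg, search in results["searches"].items():
        search.surface_to_csv(out / f"surface_{alg}.csv")
    import scipy
    import skimage
    import sklearn

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": None if fm is None else fm.n_samples,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
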