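"""End-to-end orchestration: generate -> denoise -> extract -> train -> evaluate.

A run is fully described by a flat INI-style :class:`RunConfig` that
round-trips losslessly through its text form; all randomness derives from one
root seed through named substreams, so any stage can be rerun independently
and an identical config reproduces the metrics table byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from configparser import ConfigParser
from pathlib import Path

import numpy as np
import pandas as pd

from . import images as im
from .classifiers import CLASSIFIER_NAMES, TargetScheme, check_target_separation
from .clustering import (
    ClusteringConfig,
    FeatureNormalizer,
    SampEnConfig,
    extract_features,
)
from .evaluation import CVPlan, cross_validate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "compare_classifiers",
            "generate_dataset", "extract_feature_table", "substream_seed"]


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic named substream seed derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclasses.dataclass
class RunConfig:
    """Flat, text-serialisable description of one pipeline run."""

    n_per_class: int = 40
    height: int = 96
    width: int = 96
    noise_sigma: float = 0.1
    speckle_mode: str = "additive"
    wiener_window: int = 3
    feature_method: str = "fcm"
    clusters: int = 3
    fuzzifier: float = 2.0
    sampen_m: int = 2
    sampen_r: float = 0.2
    classifier: str = "gmm"
    n_folds: int = 10
    seed: int = 0
    out_dir: str = "run"

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; "
                f"choose from {CLASSIFIER_NAMES}"
            )
        if self.feature_method not in ("fcm", "pcm", "pfcm", "sampen"):
            raise ValueError(f"unknown feature_method {self.feature_method!r}")

    def to_ini(self) -> str:
        cp = ConfigParser()
        cp["run"] = {k: repr(v) for k, v in dataclasses.asdict(self).items()}
        from io import StringIO

        buf = StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def from_ini(cls, text: str) -> "RunConfig":
        cp = ConfigParser()
        cp.read_string(text)
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, raw in cp["run"].items():
            if key not in fields:
                raise ValueError(f"unknown config field {key!r}")
            import ast

            kwargs[key] = ast.literal_eval(raw)
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_ini().encode()).hexdigest()[:16]


def generate_dataset(cfg: RunConfig) -> tuple[list[np.ndarray], list[int], list[str]]:
    """Generate, corrupt, and denoise the two-class image set.

    Returns (denoised images, labels 0/1, image ids).  Every image gets its
    own derived seed for both texture and noise.
    """
    imgs: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[str] = []
    for label, class_name in ((0, "normal"), (1, "cirrhotic")):
        spec = im.default_spec(class_name)
        for i in range(cfg.n_per_class):
            gen_seed = substream_seed(cfg.seed, f"image:{class_name}:{i}")
            clean = im.generate_image(spec, cfg.height, cfg.width, gen_seed)
            noisy = im.add_speckle(
                clean,
                im.SpeckleParams(
                    noise_sigma=cfg.noise_sigma,
                    mode=im.SpeckleMode(cfg.speckle_mode),
                    seed=substream_seed(cfg.seed, f"speckle:{class_name}:{i}"),
                ),
            )
            imgs.append(im.adaptive_wiener(noisy, window=cfg.wiener_window))
            labels.append(label)
            ids.append(f"{class_name}_{i:04d}")
    return imgs, labels, ids


def extract_feature_table(
    imgs: list[np.ndarray], labels: list[int], ids: list[str], cfg: RunConfig
) -> pd.DataFrame:
    """Raw (un-normalised) feature table: image_id, label, method, v1..vk."""
    if cfg.feature_method == "sampen":
        fcfg: ClusteringConfig | SampEnConfig = SampEnConfig(
            m_template=cfg.sampen_m, r_tolerance=cfg.sampen_r
        )
    else:
        fcfg = ClusteringConfig(
            c=cfg.clusters, fuzzifier=cfg.fuzzifier,
            seed=substream_seed(cfg.seed, "clustering"),
        )
    rows = []
    for img, label, image_id in zip(imgs, labels, ids):
        fv = extract_features(
            img, cfg.feature_method, fcfg, image_id=image_id,
            label="cirrhotic" if label else "normal",
        )
        row = {"image_id": image_id, "label": fv.label, "method": fv.method}
        row.update({f"v{i + 1}": v for i, v in enumerate(fv.values)})
        rows.append(row)
    return pd.DataFrame(rows)


def _feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    value_cols = [c for c in table.columns if c.startswith("v")]
    X = table[value_cols].to_numpy(dtype=float)
    y = (table["label"] == "cirrhotic").to_numpy(dtype=int)
    return X, y


def run_pipeline(cfg: RunConfig, write_images: bool = False) -> Path:
    """Execute all stages and write the run directory.

    Produces features.csv, metrics.csv, model.json (hyperparameters and
    seeds), run.log, and config.ini; rerunning with the same config
    reproduces metrics.csv byte-identically.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config_hash {cfg.config_hash()}", f"root_seed {cfg.seed}"]
    stage = "generate"
    try:
        t0 = time.perf_counter()
        imgs, labels, ids = generate_dataset(cfg)
        log.append(f"generate: {len(imgs)} images in {time.perf_counter() - t0:.2f}s")
        if write_images:
            img_dir = out / "images"
            img_dir.mkdir(exist_ok=True)
            for img, image_id in zip(imgs, ids):
                im.write_image(img_dir / f"{image_id}.png", img)

        stage = "extract"
        t0 = time.perf_counter()
        table = extract_feature_table(imgs, labels, ids, cfg)
        table.to_csv(out / "features.csv", index=False)
        log.append(
            f"extract[{cfg.feature_method}]: {len(table)} vectors in "
            f"{time.perf_counter() - t0:.2f}s"
        )

        stage = "evaluate"
        t0 = time.perf_counter()
        X, y = _feature_matrix(table)
        norm_all = FeatureNormalizer().fit(X)
        Xn = norm_all.transform(X)
        check_target_separation(
            {"normal": Xn[y == 0], "abnormal": Xn[y == 1]}, TargetScheme()
        )
        plan = CVPlan(n_folds=cfg.n_folds, seed=substream_seed(cfg.seed, "folds"))
        result = cross_validate(X, y, cfg.classifier, plan)
        rep = result.pooled_metrics.rounded()
        metrics = pd.DataFrame(
            [
                {
                    "feature": cfg.feature_method,
                    "classifier": cfg.classifier,
                    "tp": result.pooled.tp, "tn": result.pooled.tn,
                    "fp": result.pooled.fp, "fn": result.pooled.fn,
                    "mse": result.mean_mse, **rep.as_dict(),
                }
            ]
        )
        metrics.to_csv(out / "metrics.csv", index=False)
        log.append(
            f"evaluate[{cfg.classifier}]: accuracy {rep.accuracy:.2f} "
            f"mse {result.mean_mse:.3e} in {time.perf_counter() - t0:.2f}s"
        )

        (out / "model.json").write_text(
            json.dumps(
                {
                    "classifier": cfg.classifier,
                    "feature_method": cfg.feature_method,
                    "seed": cfg.seed,
                    "config_hash": cfg.config_hash(),
                    "pooled_confusion": dataclasses.asdict(result.pooled),
                    "mean_mse": result.mean_mse,
                },
                indent=2,
            )
        )
        (out / "config.ini").write_text(cfg.to_ini())
        (out / "run.log").write_text("\n".join(log) + "\n")
    except Exception as exc:
        (out / "run.log").write_text(
            "\n".join(log + [f"FAILED at stage {stage}: {exc}"]) + "\n"
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def compare_classifiers(
    cfg: RunConfig, classifiers: list[str]
) -> pd.DataFrame:
    """Evaluate several classifiers on the same images, features, and folds.

    Returns one row per classifier, ranked by MSE then accuracy (best first).
    """
    if len(classifiers) < 2:
        raise ValueError("need at least 2 classifiers to compare")
    for name in classifiers:
        if name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {name!r}")
    imgs, labels, ids = generate_dataset(cfg)
    table = extract_feature_table(imgs, labels, ids, cfg)
    X, y = _feature_matrix(table)
    plan = CVPlan(n_folds=cfg.n_folds, seed=substream_seed(cfg.seed, "folds"))
    rows = []
    for name in classifiers:
        result = cross_validate(X, y, name, plan)
        rep = result.pooled_metrics.rounded()
        rows.append(
            {
                "feature": cfg.feature_method, "classifier": name,
                "mse": result.mean_mse, **rep.as_dict(),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["mse", "accuracy"], ascending=[True, False]
    )
    return out.reset_index(drop=True)
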