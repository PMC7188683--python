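"""Experiment orchestration: single runs, the LV x class-ratio ablation grid,
and the 2-D latent-vs-PCA projection comparison.

The ablation grid mirrors the published protocol: for each combination of
training class ratio (1:1, 1:2, 1:3) and latent size LV (1..25), R
independent runs each redraw the train/test partition and the network
initialization from a derived seed, and the cell stores mean +/- std of
every metric (sensitivity, specificity, balanced accuracy, Youden's index,
MCC, F1, reconstruction MSE in dB).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestCentroid

from . import metrics as m
from .model import (
    JointModel,
    JointModelConfig,
    TrainConfig,
    TrainedModel,
    build_model,
    mse_db,
    train,
)
from .synthetic import parse_ratio, ratio_split

logger = logging.getLogger(__name__)

#: Metrics summarized per ablation cell, in reporting order.
ABLATION_METRICS = (
    "sensitivity",
    "specificity",
    "balanced_accuracy",
    "youden",
    "mcc",
    "f1",
    "mse_db",
)


@dataclass(frozen=True)
class ExperimentResult:
    report: m.MetricsReport
    model: TrainedModel
    test_mse: float
    test_mse_db: float


@dataclass(frozen=True)
class AblationCell:
    """Mean +/- std of every metric for one (ratio, LV) configuration."""

    ratio: str
    lv: int
    n_runs: int
    seeds: Tuple[int, ...]
    mean: Dict[str, float]
    std: Dict[str, float]
    per_run: Tuple[Dict[str, float], ...] = ()


def run_experiment(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    model_cfg: JointModelConfig,
    train_cfg: TrainConfig,
) -> ExperimentResult:
    """Train on the training set, evaluate every metric on the test set.

    Requires both classes in both sets.  If the test set is numerically
    identical to the training set, a leakage warning is emitted (the run
    still proceeds — useful only as a smoke test).
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=int)
    y_test = np.asarray(y_test, dtype=int)
    for name, y in (("train", y_train), ("test", y_test)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} set contains a single class")
    if X_train.shape == X_test.shape and np.array_equal(X_train, X_test):
        warnings.warn(
            "test set is identical to the training set: metrics reflect "
            "training-data leakage",
            stacklevel=2,
        )
    net = build_model(model_cfg, seed=train_cfg.seed)
    tm = train(net, X_train, y_train, train_cfg)
    _, labels = tm.predict(X_test)
    report = m.compute_metrics(m.confusion(y_test, labels))
    _, mse = tm.reconstruct(X_test)
    return ExperimentResult(
        report=report, model=tm, test_mse=mse, test_mse_db=mse_db(mse)
    )


def run_ablation(
    X: np.ndarray,
    y: np.ndarray,
    lv_list: Sequence[int],
    ratio_list: Sequence[str],
    n_runs: int,
    base_seed: int,
    n_pos_train: int,
    model_cfg: JointModelConfig,
    train_cfg: TrainConfig,
) -> List[AblationCell]:
    """The (ratio, LV) grid with R seeded repeats per cell.

    Run i of any cell uses seed ``base_seed + i + 1``; the seed drives both
    the fresh 1:r train/test split and the network initialization, so the
    whole grid is reproducible from ``base_seed`` alone.  A run that fails
    is logged with its seed and excluded from the cell summary.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    cells: List[AblationCell] = []
    for ratio in ratio_list:
        for lv in lv_list:
            per_run: List[Dict[str, float]] = []
            seeds: List[int] = []
            for i in range(n_runs):
                seed = base_seed + i + 1
                try:
                    tr_idx, te_idx = ratio_split(y, ratio, n_pos_train, seed)
                    res = run_experiment(
                        X[tr_idx],
                        y[tr_idx],
                        X[te_idx],
                        y[te_idx],
                        replace(model_cfg, latent_dim=lv),
                        replace(train_cfg, seed=seed),
                    )
                except Exception:
                    logger.exception(
                        "ablation run failed (ratio=%s, LV=%d, seed=%d); excluded",
                        ratio,
                        lv,
                        seed,
                    )
                    continue
                row = {k: v for k, v in res.report.as_dict().items() if k in ABLATION_METRICS}
                row["mse_db"] = res.test_mse_db
                per_run.append(row)
                seeds.append(seed)
            if not per_run:
                raise RuntimeError(f"every run failed for cell (ratio={ratio}, LV={lv})")
            mean = {
                k: float(np.mean([r[k] for r in per_run])) for k in ABLATION_METRICS
            }
            std = {
                k: float(np.std([r[k] for r in per_run], ddof=1))
                if len(per_run) >= 2
                else float("nan")
                for k in ABLATION_METRICS
            }
            cells.append(
                AblationCell(
                    ratio=f"1:{parse_ratio(ratio)}",
                    lv=lv,
                    n_runs=len(per_run),
                    seeds=tuple(seeds),
                    mean=mean,
                    std=std,
                    per_run=tuple(per_run),
                )
            )
    return cells


def ablation_long_table(cells: Sequence[AblationCell]) -> pd.DataFrame:
    """Long-format table: one row per (ratio, LV, metric)."""
    rows = []
    for c in cells:
        for k in ABLATION_METRICS:
            rows.append(
                {
                    "ratio": c.ratio,
                    "lv": c.lv,
                    "metric": k,
                    "mean": c.mean[k],
                    "std": c.std[k],
                    "n_runs": c.n_runs,
                }
            )
    return pd.DataFrame(rows)


def ablation_wide_table(cells: Sequence[AblationCell]) -> pd.DataFrame:
    """Wide rendering: ratio x metric rows, one ``LV<n>`` column per latent
    size, cells formatted ``mean ± std`` (percent metrics scaled x100)."""
    pct = {"sensitivity", "specificity", "balanced_accuracy"}
    records = {}
    lvs = sorted({c.lv for c in cells})
    for c in cells:
        for k in ABLATION_METRICS:
            scale = 100.0 if k in pct else 1.0
            records.setdefault((c.ratio, k), {})[f"LV{c.lv}"] = (
                f"{scale * c.mean[k]:.2f} ± {scale * c.std[k]:.2f}"
            )
    idx = pd.MultiIndex.from_tuples(records.keys(), names=["ratio", "metric"])
    return pd.DataFrame(
        [[records[key].get(f"LV{lv}", "") for lv in lvs] for key in records],
        index=idx,
        columns=[f"LV{lv}" for lv in lvs],
    )


@dataclass(frozen=True)
class Projection2D:
    """Two 2-D projections of the same rows plus a separability summary."""

    latent_train: np.ndarray
    pca_train: np.ndarray
    latent_test: np.ndarray
    pca_test: np.ndarray
    latent_balanced_accuracy: float
    pca_balanced_accuracy: float
    pca_components: np.ndarray


def _nearest_centroid_ba(
    train2d: np.ndarray, y_train: np.ndarray, test2d: np.ndarray, y_test: np.ndarray
) -> float:
    # standardize per dimension (train-fit) before the centroid rule:
    # Euclidean nearest-centroid is not scale-invariant, and the two 2-D
    # coordinate systems being compared carry arbitrary, different units
    mu, sd = train2d.mean(axis=0), train2d.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    clf = NearestCentroid()
    clf.fit((train2d - mu) / sd, y_train)
    pred = clf.predict((test2d - mu) / sd)
    return m.compute_metrics(m.confusion(y_test, pred)).balanced_accuracy


def project_2d(
    tm: TrainedModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: Optional[np.ndarray] = None,
    y_test: Optional[np.ndarray] = None,
) -> Projection2D:
    """Compare the 2-neuron latent embedding with the top-2 PCA projection.

    Both maps are fit on the training rows only and then applied unchanged
    to the test rows.  Separability in each plane is summarized as the
    balanced accuracy of a nearest-centroid rule fit on the projected
    training rows and scored on the projected test rows (a deliberately
    simple operationalization of "the classes separate visually").
    """
    if tm.model_config.latent_dim != 2:
        raise ValueError(
            f"2-D projection needs a 2-latent-variable model, got LV="
            f"{tm.model_config.latent_dim}"
        )
    X_train = np.asarray(X_train, dtype=np.float64)
    if X_train.shape[0] < 3:
        raise ValueError("need at least 3 rows to fit a 2-D projection")
    if X_test is None:
        X_test, y_test = X_train, y_train
    X_test = np.asarray(X_test, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=int)
    y_test = np.asarray(y_test, dtype=int)

    pca = PCA(n_components=2, svd_solver="full")
    pca_train = pca.fit_transform(X_train)
    pca_test = pca.transform(X_test)
    lat_train = tm.embed(X_train)
    lat_test = tm.embed(X_test)
    return Projection2D(
        latent_train=lat_train,
        pca_train=pca_train,
        latent_test=lat_test,
        pca_test=pca_test,
        latent_balanced_accuracy=_nearest_centroid_ba(
            lat_train, y_train, lat_test, y_test
        ),
        pca_balanced_accuracy=_nearest_centroid_ba(
            pca_train, y_train, pca_test, y_test
        ),
        pca_components=pca.components_.copy(),
    )
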