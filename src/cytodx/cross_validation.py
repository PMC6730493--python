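"""Leave-one-experiment-day-out cross-validation.

Cytometry batches drift day to day, so naive cross-validation that
mixes a day's samples between train and test overestimates accuracy.
Here every fold holds out all samples of one acquisition day; the SOM is
retrained on an aggregate of the remaining files only, the healthy-
control z-scoring is refit on training samples only, and the held-out
day is mapped onto the trained model for prediction — exactly the
protocol a deployed diagnostic model would face with a new batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cytodx.classification import (
    FEATURE_SETS,
    ModelConfig,
    balanced_accuracy,
    fit_predict,
    make_labels,
)
from cytodx.fcs_io import EventMatrix
from cytodx.feature_extraction import (
    FeatureTable,
    ZScoreParams,
    apply_zscore,
    extract_table,
    fit_zscore,
)
from cytodx.feature_selection import SelectionResult, greedy_select, rank_features
from cytodx.som_gating import aggregate, fit_som_model, map_events

logger = logging.getLogger(__name__)


@dataclass
class CVConfig:
    """One cross-validated model configuration."""

    classifier: str = "svm"
    n_classes: int = 2
    feature_set: str = "total"
    with_selection: bool = False
    panel: str = "combined"
    markers: list[str] | None = None  # default: all transformed non-aux channels
    grid: tuple[int, int] = (10, 10)
    n_meta: int = 18
    rlen: int = 10
    meta_mode: str = "hclust"
    selection_threshold: float = 0.2
    aggregate_cap: int = 3_000_000
    per_file_target: int = 10_000

    def model_config(self, seed: int) -> ModelConfig:
        return ModelConfig(
            classifier=self.classifier,
            n_classes=self.n_classes,
            feature_set=self.feature_set,
            with_selection=self.with_selection,
            panel=self.panel,
            seed=seed,
        )


@dataclass
class FoldResult:
    day: int
    test_ids: list[str]
    y_true: pd.Series
    y_pred: pd.Series
    zscore_params: ZScoreParams | None = None
    selection: SelectionResult | None = None
    skipped: bool = False

    @property
    def balanced_accuracy(self) -> float:
        return balanced_accuracy(self.y_true.to_numpy(), self.y_pred.to_numpy())


@dataclass
class CVResult:
    config: CVConfig
    seed: int
    folds: list[FoldResult]
    predictions: pd.DataFrame  # sample_id index: day, y_true, y_pred
    skipped_days: list[int] = field(default_factory=list)

    @property
    def fold_scores(self) -> list[float]:
        return [f.balanced_accuracy for f in self.folds if not f.skipped]

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def sd_balanced_accuracy(self) -> float:
        return float(np.std(self.fold_scores, ddof=1)) if len(self.fold_scores) > 1 else 0.0

    @property
    def pooled_balanced_accuracy(self) -> float:
        """Balanced accuracy over all out-of-fold predictions."""
        return balanced_accuracy(
            self.predictions["y_true"].to_numpy(),
            self.predictions["y_pred"].to_numpy(),
        )


def lobo_folds(meta: pd.DataFrame) -> list[tuple[list[str], list[str]]]:
    """Leave-one-day-out folds: one per distinct experiment day."""
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    if meta["day"].isna().any():
        raise ValueError("every sample needs an experiment day")
    days = sorted(meta["day"].unique())
    if len(days) < 2:
        raise ValueError("a single experiment day cannot be cross-validated")
    folds = []
    for d in days:
        test = list(meta.index[meta["day"] == d])
        train = list(meta.index[meta["day"] != d])
        folds.append((train, test))
    return folds


def _manual_feature_table(manual_table: pd.DataFrame) -> FeatureTable:
    desc = pd.DataFrame(
        {
            "block": "manual",
            "cluster": None,
            "meta": None,
            "marker": None,
            "panel": "manual",
        },
        index=pd.Index(manual_table.columns, name="feature"),
    )
    return FeatureTable(values=manual_table.copy(), descriptors=desc, panel="manual")


def run_fold(
    samples: dict[str, EventMatrix] | None,
    meta: pd.DataFrame,
    train_ids: list[str],
    test_ids: list[str],
    config: CVConfig,
    seeds: tuple[int, int],
    manual_table: pd.DataFrame | None = None,
) -> FoldResult:
    """Fit one leave-one-day-out fold and predict its held-out samples.

    ``seeds`` is (som_seed, classifier_seed).  All fitted artifacts
    (SOM, z-score parameters, feature selection, classifier) are
    functions of the training samples only; the held-out files are only
    mapped and predicted.
    """
    som_seed, clf_seed = seeds
    day = int(meta.loc[test_ids[0], "day"])
    y_all = make_labels(meta, config.n_classes)

    if config.feature_set == "manual":
        if manual_table is None:
            raise ValueError("feature_set 'manual' requires a manual table")
        ft = _manual_feature_table(manual_table)
    else:
        train_files = [samples[s] for s in train_ids]
        total_n = min(config.aggregate_cap, config.per_file_target * len(train_ids))
        agg = aggregate(train_files, total_n, seed=som_seed)
        markers = config.markers
        if markers is None:
            markers = [
                ch
                for ch, t in zip(agg.channels, agg.transformed)
                if t and ch != "File"
            ]
        model = fit_som_model(
            agg,
            markers,
            grid=config.grid,
            n_meta=config.n_meta,
            rlen=config.rlen,
            seed=som_seed,
            meta_mode=config.meta_mode,
        )
        all_ids = train_ids + test_ids
        assignments = {sid: map_events(samples[sid], model) for sid in all_ids}
        ft = extract_table(assignments, samples, model, panel=config.panel)
        if config.feature_set != "total":
            ft = ft.block(*FEATURE_SETS[config.feature_set])

    zp = fit_zscore(ft, meta, train_ids)
    ftz = apply_zscore(ft, zp, meta)

    selection = None
    cols = list(ftz.values.columns)
    if config.with_selection:
        p = rank_features(ftz.values.loc[train_ids], y_all.loc[train_ids])
        selection = greedy_select(
            p, ftz.values.loc[train_ids], threshold=config.selection_threshold
        )
        cols = selection.selected

    _, preds = fit_predict(
        ftz.values.loc[train_ids, cols],
        y_all.loc[train_ids],
        ftz.values.loc[test_ids, cols],
        config.model_config(clf_seed),
    )
    return FoldResult(
        day=day,
        test_ids=list(test_ids),
        y_true=y_all.loc[test_ids],
        y_pred=pd.Series(preds, index=test_ids),
        zscore_params=zp,
        selection=selection,
    )


def _fold_seeds(master_seed: int, fold_index: int, n: int = 2) -> tuple[int, ...]:
    ss = np.random.SeedSequence([master_seed, fold_index])
    return tuple(int(s) % (2**31) for s in ss.generate_state(n))


def run_cv(
    samples: dict[str, EventMatrix] | None,
    meta: pd.DataFrame,
    config: CVConfig,
    seed: int = 0,
    manual_table: pd.DataFrame | None = None,
) -> CVResult:
    """Leave-one-experiment-day-out cross-validation of one configuration.

    Per fold the whole pipeline is rebuilt without the held-out day
    (aggregate, SOM, metaclustering, HC z-scoring, optional feature
    selection, classifier); then every file is mapped and the held-out
    day predicted.  Folds whose training data lack a class are skipped
    with a warning.  Deterministic for a fixed master seed.
    """
    folds = lobo_folds(meta)
    y_all = make_labels(meta, config.n_classes)
    results: list[FoldResult] = []
    skipped_days: list[int] = []
    rows = []
    for i, (train_ids, test_ids) in enumerate(folds):
        day = int(meta.loc[test_ids[0], "day"])
        n_class = y_all.loc[train_ids].nunique()
        if n_class < 2:
            logger.warning("fold for day %s lacks a training class; skipped", day)
            skipped_days.append(day)
            continue
        fr = run_fold(
            samples, meta, train_ids, test_ids, config,
            seeds=_fold_seeds(seed, i), manual_table=manual_table,
        )
        results.append(fr)
        for sid in test_ids:
            rows.append(
                {
                    "sample_id": sid,
                    "day": day,
                    "y_true": fr.y_true[sid],
                    "y_pred": fr.y_pred[sid],
                }
            )
    predictions = pd.DataFrame(rows).set_index("sample_id")
    return CVResult(
        config=config,
        seed=seed,
        folds=results,
        predictions=predictions,
        skipped_days=skipped_days,
    )


def misclassification_report(results: list[CVResult]) -> pd.Series:
    """Per-sample count of configurations that misclassified it.

    All results must cover the same samples; the counts come back
    sorted descending (ties by sample id).
    """
    if not results:
        raise ValueError("no CV results given")
    base = set(results[0].predictions.index)
    counts = pd.Series(0, index=sorted(base), dtype=int)
    for r in results:
        if set(r.predictions.index) != base:
            raise ValueError("CV results cover inconsistent sample sets")
        wrong = r.predictions["y_true"] != r.predictions["y_pred"]
        counts = counts.add(wrong.astype(int), fill_value=0)
    df = counts.to_frame("n_misclassified").reset_index(names="sample_id")
    df = df.sort_values(["n_misclassified", "sample_id"], ascending=[False, True])
    return df.set_index("sample_id")["n_misclassified"]
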