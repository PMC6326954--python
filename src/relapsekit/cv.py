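"""Nested leave-one-out cross-validated prediction.

Every fold removes one sample, re-runs the covariate-adjusted per-variant
association filter on the remaining samples only, fits a random-forest
probability classifier on the fold-selected variants, and scores the held-out
sample.  The held-out sample's dosages and label are physically absent from
the training arrays, which is what makes the prediction-error estimate
unbiased: performing variant selection on the full data first (the classic
leakage mistake) inflates the apparent AUC, and the test suite certifies the
contrast between the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .assoc import logistic_scan
from .datatypes import CohortMetadata, FoldResult, GenotypeMatrix, PredictionSet

DEFAULT_COVARIATES = ("donor_age", "diagnosis", "graft_type")


@dataclass
class CVConfig:
    """Configuration of the nested LOOCV procedure."""

    p_threshold: float = 0.001
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    rf_n_trees: int = 1_000
    rf_mtry: int | str = "sqrt"
    rf_min_node: int = 1
    base_seed: int = 0
    include_covariates_in_rf: bool = False
    include_pcs_in_rf: bool = False
    include_variants: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.rf_n_trees < 1:
            raise ValueError("rf_n_trees must be >= 1")


class CovariateEncoder:
    """Fold-safe covariate design: categories and scaling learned on the
    training samples only, then applied to held-out samples."""

    def __init__(self, covariates: Sequence[str]) -> None:
        self.covariates = list(covariates)
        self._levels: dict[str, list] = {}
        self._center: dict[str, tuple[float, float]] = {}

    def fit(self, meta: CohortMetadata) -> "CovariateEncoder":
        for name in self.covariates:
            if name not in meta.table.columns:
                raise KeyError(f"covariate {name!r} missing from metadata")
            col = meta.table[name]
            if pd.api.types.is_numeric_dtype(col):
                sd = float(col.std(ddof=0)) or 1.0
                self._center[name] = (float(col.mean()), sd)
            else:
                # drop one reference level; unseen levels encode as all-zero
                self._levels[name] = sorted(col.unique())[1:]
        return self

    def transform(self, meta: CohortMetadata) -> np.ndarray:
        cols: list[np.ndarray] = []
        for name in self.covariates:
            col = meta.table[name]
            if name in self._center:
                mean, sd = self._center[name]
                cols.append((col.to_numpy(dtype=float) - mean) / sd)
            else:
                for level in self._levels[name]:
                    cols.append((col == level).to_numpy(dtype=float))
        if not cols:
            return np.empty((meta.n_samples, 0))
        return np.column_stack(cols)

    def feature_names(self) -> list[str]:
        names = []
        for name in self.covariates:
            if name in self._center:
                names.append(name)
            else:
                names.extend(f"{name}={lvl}" for lvl in self._levels[name])
        return names


def rf_importance(clf: RandomForestClassifier) -> np.ndarray:
    """Per-feature mean impurity decrease, *unnormalized*.

    sklearn's ``feature_importances_`` normalizes per tree to sum to one,
    which makes importances incomparable across models with different
    feature counts (a permuted-label refit selecting fewer variants would
    inflate every null importance).  The raw impurity decrease is the
    model-size-invariant quantity.
    """
    totals = np.zeros(clf.n_features_in_)
    for tree in clf.estimators_:
        totals += tree.tree_.compute_feature_importances(normalize=False)
    return totals / len(clf.estimators_)


def _median_impute(train: np.ndarray, test: np.ndarray | None = None):
    """Per-variant training-median imputation of NaN dosages."""
    if not np.isnan(train).any() and (test is None or not np.isnan(test).any()):
        return train if test is None else (train, test)
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    train = np.where(np.isnan(train), med[None, :], train)
    if test is None:
        return train
    test = np.where(np.isnan(test), med[None, :], test)
    return train, test


def _scan_select(
    y: np.ndarray,
    train_meta: CohortMetadata,
    covariates: Sequence[str],
    G: np.ndarray,
    p_threshold: float,
    G2: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    G = _median_impute(G)
    if p_threshold >= 1.0:
        # filter disabled: keep every polymorphic variant (a perfectly
        # separating variant never converges in logistic regression, yet
        # must stay available downstream)
        poly = np.flatnonzero(G.var(axis=0) > 1e-12)
        return poly, {"n_nonconverged": 0, "n_monomorphic": int(G.shape[1] - len(poly))}
    enc = CovariateEncoder(covariates).fit(train_meta)
    X_cov = np.column_stack([np.ones(train_meta.n_samples), enc.transform(train_meta)])
    scan = logistic_scan(y, X_cov, G, p_threshold=p_threshold, G2=G2)
    with np.errstate(invalid="ignore"):
        selected = np.flatnonzero(
            scan.converged & np.nan_to_num(scan.pvalue < p_threshold, nan=False)
        )
    diagnostics = {
        "n_nonconverged": scan.n_nonconverged,
        "n_monomorphic": scan.n_monomorphic,
        **scan.diagnostics,
    }
    return selected, diagnostics


def association_filter(
    train_gm: GenotypeMatrix,
    train_meta: CohortMetadata,
    covariates: Sequence[str],
    p_threshold: float,
) -> tuple[np.ndarray, dict]:
    """Indices of variants with covariate-adjusted Wald p < threshold.

    Fits, per variant, a logistic regression of the outcome on additive
    dosage plus the named covariates; selection uses strict inequality on the
    genotype-term p-value.  Non-converging or monomorphic variants are
    excluded and tallied, never fatal.
    """
    return _scan_select(
        train_meta.relapse,
        train_meta,
        covariates,
        train_gm.dosage_float(),
        p_threshold,
    )


def fit_classifier(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    config: CVConfig,
    seed: int,
) -> RandomForestClassifier:
    """Probability forest over the given feature matrix (deterministic per seed)."""
    labels = np.asarray(train_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    if train_features.shape[1] < 1:
        raise ValueError("need at least one feature")
    clf = RandomForestClassifier(
        n_estimators=config.rf_n_trees,
        max_features=config.rf_mtry,
        min_samples_leaf=config.rf_min_node,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(train_features, labels)
    return clf


def _fold_features(
    G_float: np.ndarray,
    meta: CohortMetadata,
    selected: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: CVConfig,
):
    """Assemble fold train/test feature matrices without touching test labels."""
    train_meta = meta.subset(train_idx)
    blocks_train: list[np.ndarray] = []
    blocks_test: list[np.ndarray] = []
    if len(selected):
        dosage = G_float[:, selected]
        tr, te = _median_impute(dosage[train_idx], dosage[test_idx])
        blocks_train.append(tr)
        blocks_test.append(te)
    if config.include_covariates_in_rf or not config.include_variants:
        enc = CovariateEncoder(config.covariates).fit(train_meta)
        blocks_train.append(enc.transform(train_meta))
        blocks_test.append(enc.transform(meta.subset(test_idx)))
    if config.include_pcs_in_rf and meta.pcs is not None:
        blocks_train.append(meta.pcs[train_idx])
        blocks_test.append(meta.pcs[test_idx])
    if not blocks_train:
        n_tr, n_te = len(train_idx), len(test_idx)
        return np.empty((n_tr, 0)), np.empty((n_te, 0))
    return np.column_stack(blocks_train), np.column_stack(blocks_test)


def _run_loocv(
    gm: GenotypeMatrix,
    meta: CohortMetadata,
    config: CVConfig,
    fixed_variants: np.ndarray | None,
) -> PredictionSet:
    n = gm.n_samples
    y = meta.relapse
    if n < 10:
        raise ValueError(f"LOOCV needs >= 10 samples, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")

    scores = np.empty(n)
    folds: list[FoldResult] = []
    all_idx = np.arange(n)
    G_float = gm.dosage_float()
    G2_float = None
    if config.include_variants and fixed_variants is None and not np.isnan(G_float).any():
        G2_float = G_float * G_float
    for i in range(n):
        train_idx = np.delete(all_idx, i)
        test_idx = np.array([i])
        fold_seed = config.base_seed + i
        fallback = None
        diagnostics: dict[str, int] = {}

        if fixed_variants is not None:
            selected = np.asarray(fixed_variants)
        elif config.include_variants:
            selected, diagnostics = _scan_select(
                y[train_idx],
                meta.subset(train_idx),
                config.covariates,
                G_float[train_idx],
                config.p_threshold,
                None if G2_float is None else G2_float[train_idx],
            )
        else:
            selected = np.array([], dtype=int)

        importance: dict[int, float] = {}
        if len(selected) == 0 and not (
            config.include_covariates_in_rf or not config.include_variants
        ):
            # zero-variant fold without covariate fallback: training prevalence
            score = float(y[train_idx].mean())
            fallback = "train_prevalence"
        else:
            Xtr, Xte = _fold_features(G_float, meta, selected, train_idx, test_idx, config)
            if Xtr.shape[1] == 0:
                score = float(y[train_idx].mean())
                fallback = "train_prevalence"
            else:
                if len(selected) == 0 and config.include_variants:
                    fallback = "covariates_only"
                clf = fit_classifier(Xtr, y[train_idx], config, fold_seed)
                score = float(clf.predict_proba(Xte)[0, list(clf.classes_).index(1)])
                imp = rf_importance(clf)
                importance = {
                    int(v): float(imp[k]) for k, v in enumerate(selected)
                }
        scores[i] = score
        folds.append(
            FoldResult(
                held_out_sample=gm.sample_ids[i],
                selected_variants=[int(v) for v in selected],
                prediction_score=score,
                per_variant_importance=importance,
                converged_flags=diagnostics,
                fallback=fallback,
            )
        )
    return PredictionSet(list(gm.sample_ids), scores, y, folds, config)


def loocv_predict(
    gm: GenotypeMatrix, meta: CohortMetadata, config: CVConfig
) -> PredictionSet:
    """Nested LOOCV: per-fold association filtering + RF fit + held-out score."""
    meta = meta.align_to(gm.sample_ids)
    return _run_loocv(gm, meta, config, fixed_variants=None)


def loocv_fixed_variants(
    gm: GenotypeMatrix,
    meta: CohortMetadata,
    config: CVConfig,
    variants: Sequence[int],
) -> PredictionSet:
    """LOOCV with the variant set frozen (no per-fold selection).

    This is the replication-cohort mode — and, when handed variants selected
    on the *full* dataset, the deliberately leaky pipeline the test suite
    uses as the negative control for nesting correctness.
    """
    meta = meta.align_to(gm.sample_ids)
    return _run_loocv(gm, meta, config, fixed_variants=np.asarray(variants, dtype=int))


def leaky_loocv_predict(
    gm: GenotypeMatrix, meta: CohortMetadata, config: CVConfig
) -> PredictionSet:
    """The intentionally broken pipeline: selection once on ALL samples.

    Exists only to demonstrate selection leakage; never use its output as a
    performance estimate.
    """
    meta = meta.align_to(gm.sample_ids)
    selected, _ = association_filter(gm, meta, config.covariates, config.p_threshold)
    return _run_loocv(gm, meta, config, fixed_variants=selected)


def subgroup_loocv(
    gm: GenotypeMatrix,
    meta: CohortMetadata,
    config: CVConfig,
    diagnosis_filter: str,
) -> PredictionSet:
    """Full nested procedure restricted to one diagnosis stratum."""
    meta = meta.align_to(gm.sample_ids)
    mask = (meta.table["diagnosis"] == diagnosis_filter).to_numpy()
    idx = np.flatnonzero(mask)
    if len(idx) < 10:
        raise ValueError(
            f"stratum {diagnosis_filter!r} has {len(idx)} samples (< 10)"
        )
    sub_y = meta.relapse[idx]
    if len(np.unique(sub_y)) < 2:
        raise ValueError(f"stratum {diagnosis_filter!r} contains a single class")
    return _run_loocv(gm.subset_samples(idx), meta.subset(idx), config, None)


def factorize_predictions(
    pred: PredictionSet, meta: CohortMetadata
) -> dict[str, PredictionSet]:
    """Partition an existing PredictionSet's scores by diagnosis stratum."""
    meta = meta.align_to(pred.sample_ids)
    diagnosis = meta.table["diagnosis"].to_numpy()
    out: dict[str, PredictionSet] = {}
    for group in pd.unique(diagnosis):
        idx = np.flatnonzero(diagnosis == group)
        sub_labels = pred.labels[idx]
        if len(np.unique(sub_labels)) < 2:
            raise ValueError(f"stratum {group!r} contains a single class")
        out[str(group)] = PredictionSet(
            [pred.sample_ids[i] for i in idx],
            pred.scores[idx],
            sub_labels,
            [pred.fold_results[i] for i in idx] if pred.fold_results else [],
            pred.config,
        )
    return out
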