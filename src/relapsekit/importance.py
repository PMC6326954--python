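"""Variant ranking by two importance metrics.

The first metric aggregates the random-forest importance of each variant
over the LOOCV folds in which it was selected; the second is a full-data
importance calibrated against an outcome-label-permutation null (Altmann
scheme: the association filter and the forest are refit under every
permutation, so the selection step contributes to the null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cv import CVConfig, association_filter, fit_classifier, rf_importance, _median_impute
from .datatypes import CohortMetadata, GenotypeMatrix, PredictionSet


@dataclass
class SelectionRule:
    """Default rule: permutation p <= p_cut AND LOOCV selection frequency
    >= f_cut, ordered by full-data importance; set top_n for a fixed-size
    list instead."""

    p_cut: float = 0.05
    f_cut: float = 0.5
    top_n: int | None = None


def aggregate_loocv_importance(
    prediction_set: PredictionSet, n_variants: int
) -> pd.DataFrame:
    """Mean fold importance + selection frequency per variant.

    Variants never selected in any fold get frequency 0 and NaN importance
    (flagged by the ``defined`` column).
    """
    if not prediction_set.fold_results:
        raise ValueError("prediction set carries no fold results")
    n_folds = len(prediction_set.fold_results)
    totals = np.zeros(n_variants)
    counts = np.zeros(n_variants, dtype=int)
    for fold in prediction_set.fold_results:
        for v, imp in fold.per_variant_importance.items():
            totals[v] += imp
            counts[v] += 1
    with np.errstate(invalid="ignore"):
        mean_imp = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "variant": np.arange(n_variants),
            "loocv_importance": mean_imp,
            "selection_frequency": counts / n_folds,
            "defined": counts > 0,
        }
    )


def _full_data_importance(
    gm: GenotypeMatrix,
    y_meta: CohortMetadata,
    config: CVConfig,
    seed: int,
) -> dict[int, float]:
    selected, _ = association_filter(gm, y_meta, config.covariates, config.p_threshold)
    if len(selected) == 0:
        return {}
    dosage = _median_impute(gm.subset_variants(selected).dosage_float())
    clf = fit_classifier(dosage, y_meta.relapse, config, seed)
    imp = rf_importance(clf)
    return {int(v): float(imp[k]) for k, v in enumerate(selected)}


def permutation_importance_null(
    gm: GenotypeMatrix,
    meta: CohortMetadata,
    config: CVConfig,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Full-data importance with an outcome-permutation p-value per variant.

    perm_pvalue = (1 + #{null importance >= observed}) / (n_perm + 1); a
    variant unselected in a permuted refit contributes null importance 0.
    Variants absent from the observed full-data selection are reported as not
    testable (NaN importance and p).
    """
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50")
    meta = meta.align_to(gm.sample_ids)
    observed = _full_data_importance(gm, meta, config, config.base_seed)

    rng = np.random.default_rng(seed)
    null_ge = {v: 0 for v in observed}
    y = meta.relapse
    for b in range(n_perm):
        perm = rng.permutation(len(y))
        table = meta.table.copy()
        table["relapse"] = y[perm]
        perm_meta = CohortMetadata(table, meta.pcs)
        null_imp = _full_data_importance(
            gm, perm_meta, config, config.base_seed + 1 + b
        )
        for v, obs in observed.items():
            if null_imp.get(v, 0.0) >= obs:
                null_ge[v] += 1

    m = gm.n_variants
    perm_importance = np.full(m, np.nan)
    perm_pvalue = np.full(m, np.nan)
    for v, obs in observed.items():
        perm_importance[v] = obs
        perm_pvalue[v] = (1 + null_ge[v]) / (n_perm + 1)
    return pd.DataFrame(
        {
            "variant": np.arange(m),
            "perm_importance": perm_importance,
            "perm_pvalue": perm_pvalue,
            "testable": ~np.isnan(perm_importance),
        }
    )


def rank_correlation(
    loocv_metric: np.ndarray, perm_metric: np.ndarray
) -> tuple[float, int]:
    """Pearson r between the two metrics over their common defined variants.

    Returns (r, number of variants excluded because either metric was
    undefined)."""
    a = np.asarray(loocv_metric, dtype=float)
    b = np.asarray(perm_metric, dtype=float)
    if a.shape != b.shape:
        raise ValueError("metric vectors must align")
    ok = ~np.isnan(a) & ~np.isnan(b)
    excluded = int((~ok).sum())
    if ok.sum() < 3:
        raise ValueError(
            f"need >= 3 variants with both metrics defined, got {int(ok.sum())}"
        )
    r = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return r, excluded


def build_importance_table(
    gm: GenotypeMatrix,
    loocv_agg: pd.DataFrame,
    perm: pd.DataFrame,
) -> pd.DataFrame:
    """Merge the two metrics into the ranked per-variant table."""
    table = loocv_agg.merge(perm, on="variant")
    table["rank_loocv"] = (
        table["loocv_importance"].rank(ascending=False, method="first", na_option="bottom")
    ).astype(int)
    table["rank_perm"] = (
        table["perm_importance"].rank(ascending=False, method="first", na_option="bottom")
    ).astype(int)
    table["variant_id"] = [gm.variants[v].id for v in table["variant"]]
    table["chrom"] = [gm.variants[v].chrom for v in table["variant"]]
    table["pos"] = [gm.variants[v].pos for v in table["variant"]]
    table["ref"] = [gm.variants[v].ref for v in table["variant"]]
    table["alt"] = [",".join(gm.variants[v].alt) for v in table["variant"]]
    return table


def select_top_variants(
    table: pd.DataFrame, rule: SelectionRule | None = None
) -> list[int]:
    """Apply the selection rule; returns variant indices ordered by
    full-data importance (descending)."""
    rule = rule or SelectionRule()
    if rule.top_n is not None:
        ranked = table.dropna(subset=["perm_importance"]).sort_values(
            "perm_importance", ascending=False
        )
        return ranked["variant"].head(rule.top_n).tolist()
    mask = (
        (table["perm_pvalue"] <= rule.p_cut)
        & (table["selection_frequency"] >= rule.f_cut)
        & table["perm_pvalue"].notna()
    )
    hits = table[mask].sort_values("perm_importance", ascending=False)
    return hits["variant"].tolist()
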