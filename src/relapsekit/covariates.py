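"""Covariate analysis: genetic PCA, scree stabilization, collinearity
pruning, and a nominal univariable association screen against relapse.

Also provides a PC-loading locality report used to check whether a
component's top loadings concentrate in a genomic region (e.g. the MHC on
chromosome 6, a signature of local LD rather than population structure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .datatypes import CohortMetadata, GenotypeMatrix, VariantRecord

#: MHC region, GRCh37.
MHC_REGION = ("6", 28_477_797, 33_448_354)

DEFAULT_PRIORITY = (
    "donor_age",
    "graft_type",
    "diagnosis",
    "sex",
    "pc",  # prefix: any principal component outranks what follows
    "recipient_age",
    "transplant_direction",
    "batch",
)


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_samples, k)
    loadings: np.ndarray  # (n_used_variants, k)
    eigenvalues: np.ndarray  # (k,), nonincreasing
    variant_indices: np.ndarray  # columns of the input matrix used
    n_zero_variance: int = 0

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be nonnegative")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted nonincreasing")


@dataclass
class ScreenResult:
    kept_covariates: list[str]
    dropped_collinear: list[tuple[str, str, float]] = field(default_factory=list)
    nominal_pvalues: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dropped = {d for d, _, _ in self.dropped_collinear}
        if dropped & set(self.kept_covariates):
            raise ValueError("kept and dropped covariate sets overlap")


# ---------------------------------------------------------------------------
# PCA


def compute_pcs(
    gm: GenotypeMatrix, k: int, max_variants: int = 50_000
) -> PCAResult:
    """PCA of the column-standardized dosage matrix.

    Missing dosages are mean-imputed per variant; zero-variance variants are
    excluded (counted in the result).  When the matrix is wider than
    ``max_variants`` an even thinning (every m-th variant) is applied.
    """
    if k > min(gm.n_samples, gm.n_variants):
        raise ValueError("k exceeds matrix rank bound")
    X = gm.dosage_float()
    col_mean = np.nanmean(X, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]

    idx = np.arange(gm.n_variants)
    if gm.n_variants > max_variants:
        step = int(np.ceil(gm.n_variants / max_variants))
        idx = idx[::step]
        X = X[:, idx]

    sd = X.std(axis=0)
    keep = sd > 1e-12
    n_zero = int((~keep).sum())
    idx = idx[keep]
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    u, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(k, len(s))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    eigenvalues = (s[:k] ** 2) / (gm.n_samples - 1)
    return PCAResult(scores, loadings, eigenvalues, idx, n_zero)


def select_pc_count(eigenvalues: Sequence[float], tol: float = 0.02) -> int:
    """Smallest k whose trailing eigenvalue gaps have all stabilized.

    Gaps are normalized by the total eigenvalue span; k is the smallest index
    such that every normalized gap at or beyond it falls below ``tol``.  A
    flat scree returns 1.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if len(lam) < 2:
        raise ValueError("need at least 2 eigenvalues")
    if np.any(np.diff(lam) > 1e-10):
        raise ValueError("eigenvalues must be nonincreasing")
    span = lam[0] - lam[-1]
    if span <= 0:
        return 1
    gaps = (lam[:-1] - lam[1:]) / span
    below = gaps < tol
    # suffix scan: smallest k with all gaps j >= k below tol
    for k in range(1, len(lam)):
        if below[k - 1 :].all():
            return k
    return len(lam)


# ---------------------------------------------------------------------------
# collinearity pruning


def _covariate_columns(meta: CohortMetadata) -> dict[str, pd.DataFrame]:
    """Numeric encodings: one DataFrame of columns per covariate."""
    out: dict[str, pd.DataFrame] = {}
    for name in meta.table.columns:
        if name == "relapse":
            continue
        col = meta.table[name]
        if pd.api.types.is_numeric_dtype(col):
            out[name] = col.to_frame()
        else:
            out[name] = pd.get_dummies(col, prefix=name, dtype=float)
    if meta.pcs is not None:
        for j in range(meta.pcs.shape[1]):
            out[f"pc{j + 1}"] = pd.DataFrame(
                {f"pc{j + 1}": meta.pcs[:, j]}, index=meta.table.index
            )
    return out


def _pair_correlation(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Max |Pearson r| over the dummy-column cross product."""
    best = 0.0
    for ca in a.columns:
        va = a[ca].to_numpy(dtype=float)
        if va.std() == 0:
            continue
        for cb in b.columns:
            vb = b[cb].to_numpy(dtype=float)
            if vb.std() == 0:
                continue
            r = abs(float(np.corrcoef(va, vb)[0, 1]))
            best = max(best, r)
    return best


def _priority_rank(name: str, priority: Sequence[str]) -> int:
    for i, p in enumerate(priority):
        if name == p or (p == "pc" and name.startswith("pc") and name[2:].isdigit()):
            return i
    return len(priority)


def collinearity_prune(
    meta: CohortMetadata,
    r_threshold: float = 0.45,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> ScreenResult:
    """Greedy pruning: among each |r| >= threshold pair, drop the
    lower-priority covariate; records every (dropped, kept, r) triple."""
    columns = _covariate_columns(meta)
    names = list(columns)
    alive = set(names)
    dropped: list[tuple[str, str, float]] = []

    corr = {
        (a, b): _pair_correlation(columns[a], columns[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    while True:
        worst = None
        for (a, b), r in corr.items():
            if a in alive and b in alive and r >= r_threshold:
                if worst is None or r > worst[2]:
                    worst = (a, b, r)
        if worst is None:
            break
        a, b, r = worst
        loser = a if _priority_rank(a, priority) > _priority_rank(b, priority) else b
        winner = b if loser == a else a
        alive.remove(loser)
        dropped.append((loser, winner, r))
    return ScreenResult(
        kept_covariates=[n for n in names if n in alive],
        dropped_collinear=dropped,
    )


# ---------------------------------------------------------------------------
# nominal association screen


def _lrt_pvalue(y: np.ndarray, X: np.ndarray) -> float:
    """Likelihood-ratio p of adding X's columns to an intercept-only model."""
    n = len(y)
    Xfull = np.column_stack([np.ones(n), X])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xfull).fit(disp=0, maxiter=200)
            llf = fit.llf
        except Exception:
            fit = sm.Logit(y, Xfull).fit(disp=0, method="bfgs", maxiter=500)
            llf = fit.llf
    p1 = y.mean()
    llnull = n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1)) if 0 < p1 < 1 else 0.0
    stat = max(0.0, 2.0 * (llf - llnull))
    return float(chi2.sf(stat, df=X.shape[1]))


def nominal_screen(
    meta: CohortMetadata,
    alpha: float = 0.1,
    covariates: Sequence[str] | None = None,
) -> ScreenResult:
    """Univariable logistic screen of relapse on each covariate.

    Covariates with likelihood-ratio p < ``alpha`` are kept.  Zero-variance
    covariates and fits that fail outright are flagged and not selected;
    perfect separation yields p ~ 0 and is flagged but selected.
    """
    columns = _covariate_columns(meta)
    if covariates is not None:
        unknown = set(covariates) - set(columns)
        if unknown:
            raise KeyError(f"unknown covariates: {sorted(unknown)}")
        columns = {name: columns[name] for name in covariates}
    y = meta.relapse.astype(float)

    kept: list[str] = []
    pvalues: dict[str, float] = {}
    flags: dict[str, str] = {}
    for name, cols in columns.items():
        X = cols.to_numpy(dtype=float)
        # drop degenerate / redundant dummy columns
        X = X[:, X.std(axis=0) > 1e-12]
        if X.shape[1] > 1:
            X = X[:, :-1] if np.allclose(X.sum(axis=1), X.sum(axis=1)[0]) else X
        if X.shape[1] == 0:
            flags[name] = "zero_variance"
            continue
        try:
            p = _lrt_pvalue(y, X)
        except Exception:
            flags[name] = "nonconverged"
            continue
        pvalues[name] = p
        if p < 1e-10:
            flags[name] = "separation_or_extreme"
        if p < alpha:
            kept.append(name)
    return ScreenResult(kept_covariates=kept, nominal_pvalues=pvalues, flags=flags)


# ---------------------------------------------------------------------------
# PC loading locality


def pc_loading_report(
    pca: PCAResult,
    variants: Sequence[VariantRecord],
    component: int,
    top_q: int = 100,
    region: tuple[str, int, int] = MHC_REGION,
) -> dict:
    """Fraction of a component's top |loading| variants inside a region.

    ``component`` is 1-based.  Returns per-chromosome counts of the top set
    and notes truncation when ``top_q`` exceeds the variant count.
    """
    if component < 1 or component > pca.loadings.shape[1]:
        raise ValueError(f"component {component} outside 1..{pca.loadings.shape[1]}")
    load = np.abs(pca.loadings[:, component - 1])
    truncated = top_q > len(load)
    q = min(top_q, len(load))
    top_local = np.argsort(load)[::-1][:q]
    top_global = pca.variant_indices[top_local]

    chrom, start, end = region
    in_region = 0
    per_chrom: dict[str, int] = {}
    for g in top_global:
        v = variants[g]
        per_chrom[v.chrom] = per_chrom.get(v.chrom, 0) + 1
        if v.chrom == chrom and start <= v.pos <= end:
            in_region += 1
    return {
        "component": component,
        "top_q": q,
        "truncated": truncated,
        "region": {"chrom": chrom, "start": start, "end": end},
        "fraction_in_region": in_region / q if q else float("nan"),
        "per_chromosome_counts": dict(sorted(per_chrom.items())),
        "top_variant_indices": top_global.tolist(),
    }
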