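"""Synthetic case/control cohorts with known causal structure.

Genotypes are drawn from a latent-Gaussian threshold model: within each LD
block the two haplotype latents follow an AR(1) process with per-adjacent
correlation ``ld_rho``, thresholded at the quantile of the target allele
frequency.  Outcomes follow a logistic model over planted variant effects and
clinical covariate effects, with the intercept calibrated by root finding on
a pilot sample so the realized prevalence approximates the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm, truncnorm

from .datatypes import MISSING, CohortMetadata, DosageTable, GenotypeMatrix, VariantRecord

DIAGNOSIS_GROUPS = ("AML", "ALL", "lymphoma_myeloma", "other")
DIAGNOSIS_PROBS = (0.36, 0.16, 0.30, 0.18)
GRAFT_PERIPHERAL_PROB = 0.76  # peripheral blood share of stem cell sources
PILOT_N = 10_000


class SimulationError(ValueError):
    """Raised when a simulation request is infeasible."""


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort."""

    n_samples: int = 151
    n_variants: int = 1_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.5
    n_causal: int = 0
    causal_beta: float | Sequence[float] = 0.0
    intercept_beta0: float = 0.0
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    prevalence_target: float | None = 0.31
    seed: int = 0
    gq_low_fraction: float = 0.32
    causal_indices: Sequence[int] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0 <= self.ld_rho < 1):
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal exceeds n_variants")
        if self.prevalence_target is not None and not (0 < self.prevalence_target < 1):
            raise ValueError("prevalence_target must be in (0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.causal_indices is not None and len(self.causal_indices) != self.n_causal:
            raise ValueError("causal_indices length must equal n_causal")

    @property
    def causal_beta_vector(self) -> np.ndarray:
        if np.isscalar(self.causal_beta):
            return np.full(self.n_causal, float(self.causal_beta))
        beta = np.asarray(self.causal_beta, dtype=float)
        if beta.shape != (self.n_causal,):
            raise ValueError("causal_beta vector length must equal n_causal")
        return beta


@dataclass
class SimTruth:
    """Ground truth recorded by the generator, for recovery tests."""

    causal_indices: list[int]
    causal_betas: list[float]
    covariate_betas: dict[str, float]
    realized_prevalence: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if len(self.causal_indices) != len(self.causal_betas):
            raise ValueError("causal_indices and causal_betas must align")
        if not (0.0 <= self.realized_prevalence <= 1.0):
            raise ValueError("realized_prevalence outside [0, 1]")


@dataclass
class DuplicateErrorModel:
    """Step function mapping per-call GQ to genotype discordance probability.

    ``error_rate_at_gq[i]`` applies to calls with GQ >= ``gq_grid[i]`` and
    (if any) GQ < ``gq_grid[i + 1]``; rates must be nonincreasing in GQ.
    """

    gq_grid: Sequence[int]
    error_rate_at_gq: Sequence[float]

    def __post_init__(self) -> None:
        grid = np.asarray(self.gq_grid)
        rates = np.asarray(self.error_rate_at_gq, dtype=float)
        if grid.shape != rates.shape or grid.ndim != 1:
            raise ValueError("gq_grid and error_rate_at_gq must align")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("gq_grid must be strictly increasing")
        if np.any((rates < 0) | (rates > 1)):
            raise ValueError("error rates must be in [0, 1]")
        if np.any(np.diff(rates) > 0):
            raise ValueError("error rates must be nonincreasing in GQ")

    def rate(self, gq: np.ndarray) -> np.ndarray:
        grid = np.asarray(self.gq_grid)
        rates = np.asarray(self.error_rate_at_gq, dtype=float)
        idx = np.searchsorted(grid, np.asarray(gq), side="right") - 1
        idx = np.clip(idx, 0, len(grid) - 1)
        return rates[idx]


# ---------------------------------------------------------------------------
# genotype generation


def _block_slices(n_variants: int, block_size: int) -> list[slice]:
    return [slice(s, min(s + block_size, n_variants)) for s in range(0, n_variants, block_size)]


def _draw_block_genotypes(
    rng: np.random.Generator, mafs: np.ndarray, rho: float, n: int
) -> np.ndarray:
    """Genotypes for one LD block: 2 thresholded AR(1) haplotype latents."""
    b = len(mafs)
    eps = rng.standard_normal((n, 2, b))
    z = np.empty_like(eps)
    z[:, :, 0] = eps[:, :, 0]
    scale = math.sqrt(1.0 - rho * rho)
    for t in range(1, b):
        z[:, :, t] = rho * z[:, :, t - 1] + scale * eps[:, :, t]
    tau = norm.ppf(mafs)
    return (z < tau).sum(axis=1).astype(np.int8)


def _draw_genotypes(
    rng: np.random.Generator,
    mafs: np.ndarray,
    block_size: int,
    rho: float,
    n: int,
    columns: np.ndarray | None = None,
) -> np.ndarray:
    """Draw the full genotype matrix (or only ``columns``, block-aware)."""
    m = len(mafs)
    slices = _block_slices(m, block_size)
    if columns is None:
        out = np.empty((n, m), dtype=np.int8)
        for sl in slices:
            out[:, sl] = _draw_block_genotypes(rng, mafs[sl], rho, n)
        return out
    columns = np.asarray(columns)
    wanted = set(columns.tolist())
    chunks: dict[int, np.ndarray] = {}
    for sl in slices:
        block_cols = [j for j in range(sl.start, sl.stop) if j in wanted]
        if not block_cols:
            continue
        g = _draw_block_genotypes(rng, mafs[sl], rho, n)
        for j in block_cols:
            chunks[j] = g[:, j - sl.start]
    return np.stack([chunks[j] for j in columns], axis=1)


def _simulate_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Clinical covariates mirroring the discovery-cohort marginals."""
    z_donor = rng.standard_normal(n)
    donor_age = np.clip(49 + 12 * z_donor, None, None)
    # truncate to the observed donor age range via rejection-free clipping of
    # the latent: resample the tail quantiles through truncnorm
    a, b = (7 - 49) / 12, (72 - 49) / 12
    u = norm.cdf(z_donor)
    donor_age = 49 + 12 * truncnorm.ppf(u, a, b)
    # recipient age correlated ~0.8 with donor age
    z_rec = 0.8 * truncnorm.ppf(u, a, b) + 0.6 * rng.standard_normal(n)
    recipient_age = np.clip(51 + 12 * z_rec, 3, 70)
    diagnosis = rng.choice(DIAGNOSIS_GROUPS, size=n, p=DIAGNOSIS_PROBS)
    graft = np.where(
        rng.random(n) < GRAFT_PERIPHERAL_PROB, "peripheral_blood", "bone_marrow"
    )
    sex = np.where(rng.random(n) < 0.51, "male", "female")
    donor_sex = np.where(rng.random(n) < 0.5, "male", "female")
    direction = np.char.add(np.char.add(donor_sex, "_to_"), sex)
    batch = np.where(rng.random(n) < 0.3, "center_A", "center_B")
    return pd.DataFrame(
        {
            "donor_age": np.round(donor_age, 1),
            "recipient_age": np.round(recipient_age, 1),
            "diagnosis": diagnosis,
            "graft_type": graft,
            "sex": sex,
            "transplant_direction": direction,
            "batch": batch,
        }
    )


def _covariate_design(covariates: pd.DataFrame) -> dict[str, np.ndarray]:
    """Numeric encodings the effect map may refer to."""
    design = {
        "donor_age": (covariates["donor_age"].to_numpy() - 49.0) / 12.0,
        "recipient_age": (covariates["recipient_age"].to_numpy() - 51.0) / 12.0,
        "graft_type": (covariates["graft_type"] == "peripheral_blood").to_numpy(float),
        "sex": (covariates["sex"] == "male").to_numpy(float),
        "batch": (covariates["batch"] == "center_A").to_numpy(float),
    }
    for grp in DIAGNOSIS_GROUPS:
        design[f"diagnosis:{grp}"] = (covariates["diagnosis"] == grp).to_numpy(float)
    return design


def _covariate_eta(
    covariates: pd.DataFrame, effects: Mapping[str, float]
) -> np.ndarray:
    design = _covariate_design(covariates)
    eta = np.zeros(len(covariates))
    for name, gamma in effects.items():
        if name not in design:
            raise SimulationError(
                f"unknown covariate effect {name!r}; known: {sorted(design)}"
            )
        eta = eta + gamma * design[name]
    return eta


def _calibrate_intercept(eta_pilot: np.ndarray, target: float) -> float:
    def realized(b0: float) -> float:
        return float(np.mean(expit(b0 + eta_pilot)))

    lo, hi = -30.0, 30.0
    p_lo, p_hi = realized(lo), realized(hi)
    if not (p_lo <= target <= p_hi):
        raise SimulationError(
            f"prevalence target {target} not achievable; "
            f"achievable range under the given effects is [{p_lo:.4g}, {p_hi:.4g}]"
        )
    return float(brentq(lambda b0: realized(b0) - target, lo, hi, xtol=1e-8))


def _variant_records(rng: np.random.Generator, mafs: np.ndarray) -> list[VariantRecord]:
    m = len(mafs)
    bases = np.array(list("ACGT"))
    refs = rng.integers(0, 4, size=m)
    alts = (refs + rng.integers(1, 4, size=m)) % 4
    records = []
    per_chrom = max(1, math.ceil(m / 22))
    for j in range(m):
        chrom = str(1 + j // per_chrom)
        pos = 10_000 + (j % per_chrom) * 1_000
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                id=f"var{j}",
                ref=str(bases[refs[j]]),
                alt=(str(bases[alts[j]]),),
            )
        )
    return records


def simulate_cohort(
    config: SimConfig, sample_seed: int | None = None
) -> tuple[GenotypeMatrix, CohortMetadata, SimTruth]:
    """Generate a cohort with planted genotype and covariate effects.

    ``sample_seed`` redraws samples (genotypes, covariates, outcomes) while
    keeping the variant panel and causal structure fixed — use it to build
    replication cohorts sharing the discovery cohort's ground truth.
    """
    ss = np.random.SeedSequence(config.seed)
    variant_ss, default_sample_ss = ss.spawn(2)
    rng_var = np.random.default_rng(variant_ss)
    rng = (
        np.random.default_rng(default_sample_ss)
        if sample_seed is None
        else np.random.default_rng(sample_seed)
    )

    n, m = config.n_samples, config.n_variants
    lo, hi = config.maf_range
    mafs = rng_var.uniform(lo, hi, size=m)
    records = _variant_records(rng_var, mafs)

    if config.causal_indices is not None:
        causal_idx = np.asarray(sorted(config.causal_indices), dtype=int)
    elif config.n_causal > 0:
        causal_idx = np.sort(rng_var.choice(m, size=config.n_causal, replace=False))
    else:
        causal_idx = np.array([], dtype=int)
    betas = config.causal_beta_vector

    covariates = _simulate_covariates(rng, n)
    dosages = _draw_genotypes(rng, mafs, config.ld_block_size, config.ld_rho, n)

    eta = _covariate_eta(covariates, config.covariate_effects)
    if len(causal_idx):
        eta = eta + dosages[:, causal_idx].astype(float) @ betas

    if config.prevalence_target is None:
        b0 = float(config.intercept_beta0)
    elif len(causal_idx) == 0 and not any(config.covariate_effects.values()):
        b0 = float(logit(config.prevalence_target))
    else:
        rng_pilot = np.random.default_rng(ss.spawn(1)[0])
        pilot_cov = _simulate_covariates(rng_pilot, PILOT_N)
        eta_pilot = _covariate_eta(pilot_cov, config.covariate_effects)
        if len(causal_idx):
            g_pilot = _draw_genotypes(
                rng_pilot, mafs, config.ld_block_size, config.ld_rho, PILOT_N,
                columns=causal_idx,
            )
            eta_pilot = eta_pilot + g_pilot.astype(float) @ betas
        b0 = _calibrate_intercept(eta_pilot, config.prevalence_target)

    y = (rng.random(n) < expit(b0 + eta)).astype(int)

    # per-call quality: low/high two-component mixture so GQ thresholding has
    # a visible effect on the duplicate-concordance curve
    low = rng.random((n, m)) < config.gq_low_fraction
    call_gq = np.where(
        low, rng.integers(0, 18, size=(n, m)), rng.integers(30, 100, size=(n, m))
    ).astype(np.int32)
    call_dp = rng.integers(10, 60, size=(n, m)).astype(np.int32)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    gm = GenotypeMatrix(
        sample_ids,
        records,
        dosages,
        missing=np.zeros((n, m), dtype=bool),
        call_gq=call_gq,
        call_dp=call_dp,
    )
    from .qc import alt_allele_frequencies  # late import to avoid a cycle

    freqs = alt_allele_frequencies(gm)
    gm.variants = [
        VariantRecord(r.chrom, r.pos, r.id, r.ref, r.alt, float(freqs[j]))
        for j, r in enumerate(records)
    ]

    meta_table = covariates.copy()
    meta_table.insert(0, "relapse", y)
    meta_table.index = pd.Index(sample_ids, name="sample_id")
    meta = CohortMetadata(meta_table)

    truth = SimTruth(
        causal_indices=causal_idx.tolist(),
        causal_betas=betas.tolist(),
        covariate_betas=dict(config.covariate_effects),
        realized_prevalence=float(y.mean()),
        intercept=b0,
    )
    return gm, meta, truth


# ---------------------------------------------------------------------------
# perturbations


def inject_duplicates(
    gm: GenotypeMatrix,
    sample_ids: Sequence[str],
    model: DuplicateErrorModel,
    seed: int,
) -> GenotypeMatrix:
    """Append one duplicate row per listed sample, with GQ-dependent errors.

    Each duplicated non-missing call is perturbed to a *different* genotype
    with probability ``model.rate(GQ)``; the duplicate inherits the original's
    per-call GQ/DP.  Duplicate ids are ``<sample_id>__dup``.
    """
    if gm.call_gq is None:
        raise ValueError("inject_duplicates requires per-call GQ annotations")
    rng = np.random.default_rng(seed)
    rows = [gm.sample_index(s) for s in sample_ids]

    dup_dos = gm.dosages[rows].copy()
    dup_miss = gm.missing[rows].copy()
    gq = gm.call_gq[rows]
    err = model.rate(gq)
    flip = (rng.random(dup_dos.shape) < err) & ~dup_miss
    # move to one of the two other genotypes, uniformly
    shift = rng.integers(1, 3, size=dup_dos.shape)
    dup_dos[flip] = ((dup_dos[flip].astype(np.int16) + shift[flip]) % 3).astype(np.int8)

    return GenotypeMatrix(
        gm.sample_ids + [f"{s}__dup" for s in sample_ids],
        gm.variants,
        np.vstack([gm.dosages, dup_dos]),
        np.vstack([gm.missing, dup_miss]),
        None if gm.call_gq is None else np.vstack([gm.call_gq, gq]),
        None if gm.call_dp is None else np.vstack([gm.call_dp, gm.call_dp[rows]]),
    )


def inject_missingness(
    gm: GenotypeMatrix,
    per_variant_missing: Mapping[int, int] | Sequence[int],
    seed: int,
) -> GenotypeMatrix:
    """Blank exactly the requested number of calls per variant."""
    rng = np.random.default_rng(seed)
    out = gm.copy()
    if isinstance(per_variant_missing, Mapping):
        items = per_variant_missing.items()
    else:
        items = enumerate(per_variant_missing)
    for j, count in items:
        if count > gm.n_samples:
            raise ValueError(
                f"variant {j}: requested {count} missing calls but cohort has "
                f"{gm.n_samples} samples"
            )
        if count == 0:
            continue
        rows = rng.choice(gm.n_samples, size=count, replace=False)
        out.dosages[rows, j] = MISSING
        out.missing[rows, j] = True
    return out


def simulate_imputed_dosages(
    gm: GenotypeMatrix,
    quality: float | np.ndarray,
    seed: int,
    base_alpha: float = 0.3,
) -> DosageTable:
    """Dirichlet-perturbed genotype posteriors around the true genotypes.

    ``quality`` is a per-variant (or scalar) concentration; higher values give
    sharper posteriors (smaller per-call dosage SD).  Missing true genotypes
    get a posterior centred on the variant's empirical allele frequency under
    Hardy-Weinberg proportions.
    """
    quality = np.broadcast_to(np.asarray(quality, dtype=float), (gm.n_variants,))
    if np.any(quality <= 0):
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    n, m = gm.shape

    from .qc import alt_allele_frequencies

    p_alt = alt_allele_frequencies(gm)
    p_alt = np.where(np.isnan(p_alt), 0.5, p_alt)
    hwe = np.stack(
        [(1 - p_alt) ** 2, 2 * p_alt * (1 - p_alt), p_alt**2], axis=-1
    )  # (m, 3)

    onehot = np.zeros((n, m, 3))
    dos = np.clip(gm.dosages, 0, 2)
    np.put_along_axis(onehot, dos[..., None].astype(int), 1.0, axis=2)
    onehot[gm.missing] = hwe[np.nonzero(gm.missing)[1]]

    inf_cols = np.isinf(quality)
    finite_q = np.where(inf_cols, 1.0, quality)
    alpha = base_alpha + finite_q[None, :, None] * onehot
    draws = rng.gamma(shape=alpha)
    probs = draws / draws.sum(axis=2, keepdims=True)
    probs[:, inf_cols, :] = onehot[:, inf_cols, :]  # degenerate point-mass limit

    dosage = probs[..., 1] + 2.0 * probs[..., 2]
    second = probs[..., 1] + 4.0 * probs[..., 2]
    sd = np.sqrt(np.maximum(second - dosage**2, 0.0))
    return DosageTable(list(gm.sample_ids), list(gm.variants), probs, dosage, sd)
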