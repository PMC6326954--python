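"""Replication-cohort evaluation of a fixed top-variant list.

Covers variant matching across genotyping platforms (position + alleles,
with allele-swap dosage flips and strand-ambiguity flags), the
missing-genotype complete-case trade-off, imputed-dosage SD quality
filtering, and LOOCV refitting with the variant set frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cv import CVConfig, fit_classifier, loocv_fixed_variants
from .datatypes import (
    CohortMetadata,
    DosageTable,
    FoldResult,
    GenotypeMatrix,
    PredictionSet,
    VariantRecord,
)


@dataclass
class ReplicationConfig:
    max_missing_per_variant: int = 1
    dosage_sd_max: float = 0.3
    use_dosages: bool = False
    cv: CVConfig = field(default_factory=CVConfig)

    def __post_init__(self) -> None:
        if self.max_missing_per_variant < 0:
            raise ValueError("max_missing_per_variant must be >= 0")
        if self.dosage_sd_max <= 0:
            raise ValueError("dosage_sd_max must be > 0")


@dataclass
class MatchReport:
    requested_variants: int
    found_on_panel: int
    matched_panel_indices: list[int]
    flipped: list[bool]
    ambiguous: list[bool]
    missing_counts: list[int]
    unmatched: list[str]

    def __post_init__(self) -> None:
        if self.found_on_panel > self.requested_variants:
            raise ValueError("found cannot exceed requested")


def match_variants(
    top_list: Sequence[VariantRecord], panel_gm: GenotypeMatrix
) -> tuple[GenotypeMatrix, MatchReport]:
    """Match requested variants onto the panel by chrom+pos and alleles.

    Variant ID strings are ignored (they differ across platforms).  A panel
    record with REF/ALT exchanged is matched with its dosages flipped
    (g -> 2 - g); strand-ambiguous (A/T, C/G) sites are matched but flagged.
    Returns the matched (and flip-corrected) panel subset in request order,
    plus the match report.
    """
    by_pos: dict[tuple[str, int], int] = {}
    for j, v in enumerate(panel_gm.variants):
        by_pos[v.key] = j

    idx: list[int] = []
    flipped: list[bool] = []
    ambiguous: list[bool] = []
    unmatched: list[str] = []
    for want in top_list:
        j = by_pos.get(want.key)
        hit = None
        if j is not None:
            panel_v = panel_gm.variants[j]
            if panel_v.is_biallelic and want.is_biallelic:
                if (panel_v.ref, panel_v.alt[0]) == (want.ref, want.alt[0]):
                    hit = (j, False)
                elif (panel_v.ref, panel_v.alt[0]) == (want.alt[0], want.ref):
                    hit = (j, True)
        if hit is None:
            unmatched.append(want.id)
            continue
        idx.append(hit[0])
        flipped.append(hit[1])
        ambiguous.append(want.is_palindromic)

    sub = panel_gm.subset_variants(idx)
    flip_cols = np.flatnonzero(flipped)
    for c in flip_cols:
        col = sub.dosages[:, c]
        ok = ~sub.missing[:, c]
        col[ok] = 2 - col[ok]
        v = sub.variants[c]
        sub.variants[c] = VariantRecord(
            v.chrom, v.pos, v.id, ref=v.alt[0], alt=(v.ref,),
            alt_frequency=1.0 - v.alt_frequency if np.isfinite(v.alt_frequency) else float("nan"),
        )
    missing_counts = sub.missing.sum(axis=0).astype(int).tolist()
    report = MatchReport(
        requested_variants=len(top_list),
        found_on_panel=len(idx),
        matched_panel_indices=idx,
        flipped=flipped,
        ambiguous=ambiguous,
        missing_counts=missing_counts,
        unmatched=unmatched,
    )
    return sub, report


def missingness_filter(
    gm: GenotypeMatrix, max_missing: int
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Keep variants with missing count strictly below ``max_missing``, then
    drop every sample missing any kept variant (complete-case).

    Returns (filtered matrix, kept variant indices, kept sample indices).
    """
    miss_per_variant = gm.missing.sum(axis=0)
    keep_v = np.flatnonzero(miss_per_variant < max_missing)
    sub = gm.subset_variants(keep_v)
    keep_s = np.flatnonzero(~sub.missing.any(axis=1))
    if len(keep_s) == 0:
        trade = {int(c): int((miss_per_variant < c).sum()) for c in
                 sorted(set(miss_per_variant.tolist()))}
        raise ValueError(
            "complete-case removal leaves zero samples; variants kept per "
            f"max_missing value: {trade}"
        )
    return sub.subset_samples(keep_s), keep_v, keep_s


def dosage_sd_filter(table: DosageTable, sd_max: float) -> np.ndarray:
    """Indices of variants whose mean per-call dosage SD is < sd_max."""
    if table.sd is None:
        raise ValueError("dosage table carries no per-call SDs")
    quality = table.variant_quality()
    return np.flatnonzero(quality < sd_max)


def _loocv_on_features(
    features: np.ndarray,
    sample_ids: list[str],
    meta: CohortMetadata,
    cfg: CVConfig,
) -> PredictionSet:
    """LOOCV random-forest on a fixed real-valued feature matrix."""
    meta = meta.align_to(sample_ids)
    y = meta.relapse
    n = len(sample_ids)
    if n < 10:
        raise ValueError(f"LOOCV needs >= 10 samples, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    scores = np.empty(n)
    folds: list[FoldResult] = []
    all_idx = np.arange(n)
    for i in range(n):
        tr = np.delete(all_idx, i)
        clf = fit_classifier(features[tr], y[tr], cfg, cfg.base_seed + i)
        scores[i] = float(
            clf.predict_proba(features[[i]])[0, list(clf.classes_).index(1)]
        )
        folds.append(
            FoldResult(
                held_out_sample=sample_ids[i],
                selected_variants=list(range(features.shape[1])),
                prediction_score=scores[i],
            )
        )
    return PredictionSet(list(sample_ids), scores, y, folds, cfg)


def replicate_loocv(
    panel: GenotypeMatrix | DosageTable,
    panel_meta: CohortMetadata,
    matched_variants: Sequence[int],
    cfg: ReplicationConfig,
) -> PredictionSet:
    """LOOCV with the variant set fixed (selection happened in discovery).

    With ``use_dosages`` the features are the expected imputed dosages from a
    :class:`DosageTable`; otherwise hard-call dosages from the genotype
    matrix (which must be complete — apply :func:`missingness_filter` first).
    """
    matched_variants = np.asarray(matched_variants, dtype=int)
    if len(matched_variants) == 0:
        raise ValueError("matched variant set is empty")
    if cfg.use_dosages:
        if not isinstance(panel, DosageTable):
            raise TypeError("use_dosages requires a DosageTable panel")
        feats = panel.dosage[:, matched_variants]
        return _loocv_on_features(feats, list(panel.sample_ids), panel_meta, cfg.cv)
    if not isinstance(panel, GenotypeMatrix):
        raise TypeError("hard-call replication requires a GenotypeMatrix panel")
    return loocv_fixed_variants(panel, panel_meta, cfg.cv, matched_variants)
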