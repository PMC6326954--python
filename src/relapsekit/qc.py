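"""Genotype quality control.

Implements the duplicate-sample concordance curve over GQ hard-cutoff
thresholds (the tool used to choose the GQ filter), hard GQ/DP filtering,
restriction to biallelic variants, and ALT allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import MISSING, GenotypeMatrix, VariantRecord


@dataclass
class QCConfig:
    """Hard-filter thresholds.

    Calls with GQ < ``gq_min`` or DP < ``dp_min`` are set to missing.  The
    default ``gq_min`` corresponds to keeping calls above the GQ 18 knee of a
    typical duplicate-concordance curve; ``dp_min=0`` disables depth
    filtering.  Variants failing QC in more than ``max_fail_fraction`` of
    samples are dropped entirely.
    """

    gq_min: int = 18
    dp_min: int = 0
    biallelic_only: bool = True
    max_fail_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.gq_min < 0 or self.dp_min < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class ConcordanceCurve:
    """Duplicate-pair genotype similarity across GQ thresholds."""

    thresholds: list[int]
    mean_similarity: list[float]
    fraction_discarded: list[float]
    n_compared: list[int]
    undefined: list[bool]

    def __post_init__(self) -> None:
        k = len(self.thresholds)
        if not all(
            len(x) == k
            for x in (
                self.mean_similarity,
                self.fraction_discarded,
                self.n_compared,
                self.undefined,
            )
        ):
            raise ValueError("curve lists must align with thresholds")


@dataclass
class QCSummary:
    fraction_calls_discarded: float
    fraction_variants_discarded: float
    n_variants_in: int
    n_variants_out: int


def duplicate_concordance(
    gm: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]],
    gq_grid: Sequence[int],
) -> ConcordanceCurve:
    """Mean genotype similarity between duplicate pairs per GQ threshold.

    At each threshold ``t`` only calls where *both* members have GQ > t and
    neither is missing are compared.  ``fraction_discarded`` is relative to
    the calls passing the smallest threshold in the grid.  Genotypes are
    compared as unordered ALT counts.
    """
    if gm.call_gq is None:
        raise ValueError("duplicate_concordance requires per-call GQ")
    idx_pairs = [(gm.sample_index(a), gm.sample_index(b)) for a, b in pairs]
    thresholds = sorted(int(t) for t in gq_grid)

    mean_sim: list[float] = []
    frac_disc: list[float] = []
    n_compared: list[int] = []
    undefined: list[bool] = []
    base_calls: int | None = None

    for t in thresholds:
        sims = []
        total = 0
        for ia, ib in idx_pairs:
            ok = (
                (gm.call_gq[ia] > t)
                & (gm.call_gq[ib] > t)
                & ~gm.missing[ia]
                & ~gm.missing[ib]
            )
            compared = int(ok.sum())
            total += compared
            if compared:
                sims.append(float((gm.dosages[ia, ok] == gm.dosages[ib, ok]).mean()))
        if base_calls is None:
            base_calls = total
        n_compared.append(total)
        if sims:
            mean_sim.append(float(np.mean(sims)))
            undefined.append(False)
        else:
            mean_sim.append(float("nan"))
            undefined.append(True)
        frac_disc.append(0.0 if not base_calls else 1.0 - total / base_calls)

    return ConcordanceCurve(thresholds, mean_sim, frac_disc, n_compared, undefined)


def apply_quality_filter(
    gm: GenotypeMatrix, qc: QCConfig
) -> tuple[GenotypeMatrix, QCSummary]:
    """Blank calls failing the GQ/DP cutoffs; drop variants failing broadly.

    Variants whose calls fail QC (or were already missing) in more than
    ``qc.max_fail_fraction`` of samples are removed, as are variants left
    entirely missing.  Returns the filtered matrix plus discard fractions for
    both calls and variants.
    """
    fail = np.zeros(gm.shape, dtype=bool)
    if qc.gq_min > 0:
        if gm.call_gq is None:
            raise ValueError("GQ filtering requested but call_gq absent")
        fail |= gm.call_gq < qc.gq_min
    if qc.dp_min > 0:
        if gm.call_dp is None:
            raise ValueError("DP filtering requested but call_dp absent")
        fail |= gm.call_dp < qc.dp_min
    fail &= ~gm.missing

    n_calls = gm.dosages.size
    out = gm.copy()
    out.dosages[fail] = MISSING
    out.missing |= fail

    miss_frac = out.missing.mean(axis=0)
    keep = miss_frac <= qc.max_fail_fraction
    keep &= miss_frac < 1.0
    out = out.subset_variants(np.flatnonzero(keep))
    summary = QCSummary(
        fraction_calls_discarded=float(fail.sum() / n_calls) if n_calls else 0.0,
        fraction_variants_discarded=float(1.0 - keep.mean()) if len(keep) else 0.0,
        n_variants_in=gm.n_variants,
        n_variants_out=out.n_variants,
    )
    return out, summary


def filter_biallelic(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep exactly the variants with one REF and one ALT allele."""
    keep = np.flatnonzero([v.is_biallelic for v in gm.variants])
    return gm.subset_variants(keep)


def classify_variants(variants: Sequence[VariantRecord]) -> dict[str, int]:
    """Counts of SNP / INDEL / other variant classes."""
    counts = {"snp": 0, "indel": 0, "other": 0}
    for v in variants:
        if v.is_snp:
            counts["snp"] += 1
        elif v.is_indel:
            counts["indel"] += 1
        else:
            counts["other"] += 1
    return counts


def alt_allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant ALT allele frequency: sum(dosage) / (2 x non-missing).

    Variants with no non-missing calls get NaN.
    """
    dos = gm.dosages.astype(float)
    dos[gm.missing] = 0.0
    called = (~gm.missing).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = dos.sum(axis=0) / (2.0 * called)
    return np.where(called > 0, freq, np.nan)


def alt_allele_frequency(gm: GenotypeMatrix, variant: int) -> float:
    """ALT allele frequency of one variant (by column index)."""
    freq = alt_allele_frequencies(gm.subset_variants([variant]))[0]
    if np.isnan(freq):
        raise ValueError(f"variant {variant}: all calls missing, frequency undefined")
    return float(freq)
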