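"""Core containers shared across the pipeline.

The central object is :class:`GenotypeMatrix`: a samples x variants table of
additive ALT-allele dosages with an authoritative missingness mask and
optional per-call GQ/DP quality annotations.  :class:`CohortMetadata` carries
the binary outcome and clinical covariates; :class:`PredictionSet` carries
out-of-fold prediction scores from leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel stored in the dosage matrix where a call is missing.  The boolean
#: mask is authoritative; the sentinel only keeps the array self-describing.
MISSING = -1

PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _as_index(index) -> np.ndarray:
    """Coerce a position/boolean selection to an integer index array."""
    index = np.asarray(index)
    if index.dtype == bool:
        return np.flatnonzero(index)
    return index.astype(np.intp, copy=False)


@dataclass(frozen=True)
class VariantRecord:
    """A single variant site (1-based GRCh37 coordinates)."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: tuple[str, ...]
    alt_frequency: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if isinstance(self.alt, str):
            object.__setattr__(self, "alt", (self.alt,))
        else:
            object.__setattr__(self, "alt", tuple(self.alt))
        if len(self.alt) == 0:
            raise ValueError(f"variant {self.id}: needs at least one ALT allele")
        if self.ref in self.alt:
            raise ValueError(f"variant {self.id}: REF equals an ALT allele")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt) == 1

    @property
    def is_snp(self) -> bool:
        return (
            len(self.ref) == 1
            and all(len(a) == 1 for a in self.alt)
            and self.ref in "ACGT"
            and all(a in "ACGT" for a in self.alt)
        )

    @property
    def is_indel(self) -> bool:
        if self.is_snp:
            return False
        ok = self.ref.isalpha() and all(a.isalpha() for a in self.alt)
        return ok and any(len(a) != len(self.ref) for a in self.alt)

    @property
    def is_palindromic(self) -> bool:
        return self.is_biallelic and (self.ref, self.alt[0]) in PALINDROMIC_PAIRS

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


class GenotypeMatrix:
    """Samples x variants additive dosage matrix.

    Parameters
    ----------
    sample_ids:
        Unique sample identifiers, one per row.
    variants:
        One :class:`VariantRecord` per column.
    dosages:
        ``(n_samples, n_variants)`` integer array with values in ``{0, 1, 2}``
        and :data:`MISSING` where the mask is set.
    missing:
        Boolean mask, same shape; ``True`` marks a missing call.  The mask is
        authoritative — dosage values under the mask are ignored.
    call_gq, call_dp:
        Optional same-shape per-call genotype quality / read depth.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variants: Sequence[VariantRecord],
        dosages: np.ndarray,
        missing: np.ndarray | None = None,
        call_gq: np.ndarray | None = None,
        call_dp: np.ndarray | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.variants = list(variants)
        dosages = np.asarray(dosages)
        if dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Series(self.sample_ids).value_counts()
            raise ValueError(
                "duplicate sample ids: " + ", ".join(dupes[dupes > 1].index[:5])
            )
        if missing is None:
            missing = dosages == MISSING
        missing = np.asarray(missing, dtype=bool)
        if missing.shape != dosages.shape:
            raise ValueError("mask shape does not match dosages")
        self.dosages = dosages.astype(np.int8, copy=True)
        self.dosages[missing] = MISSING
        self.missing = missing
        for name, arr in (("call_gq", call_gq), ("call_dp", call_dp)):
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != dosages.shape:
                    raise ValueError(f"{name} shape does not match dosages")
        self.call_gq = None if call_gq is None else np.asarray(call_gq, dtype=np.int32)
        self.call_dp = None if call_dp is None else np.asarray(call_dp, dtype=np.int32)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_variants)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    # -- views -------------------------------------------------------------
    def dosage_float(self) -> np.ndarray:
        """Dosages as float64 with NaN at missing calls."""
        out = self.dosages.astype(np.float64)
        out[self.missing] = np.nan
        return out

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = _as_index(index)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in index],
            self.variants,
            self.dosages[index],
            self.missing[index],
            None if self.call_gq is None else self.call_gq[index],
            None if self.call_dp is None else self.call_dp[index],
        )

    def subset_variants(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = _as_index(index)
        return GenotypeMatrix(
            self.sample_ids,
            [self.variants[i] for i in index],
            self.dosages[:, index],
            self.missing[:, index],
            None if self.call_gq is None else self.call_gq[:, index],
            None if self.call_dp is None else self.call_dp[:, index],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.variants),
            self.dosages.copy(),
            self.missing.copy(),
            None if self.call_gq is None else self.call_gq.copy(),
            None if self.call_dp is None else self.call_dp.copy(),
        )


METADATA_COLUMNS = (
    "relapse",
    "donor_age",
    "recipient_age",
    "diagnosis",
    "graft_type",
    "sex",
    "transplant_direction",
    "batch",
)


class CohortMetadata:
    """Per-sample outcome + clinical covariates (+ optional genetic PCs).

    Backed by a :class:`pandas.DataFrame` indexed by sample id.  The binary
    outcome column ``relapse`` must be present and complete.
    """

    def __init__(self, table: pd.DataFrame, pcs: np.ndarray | None = None) -> None:
        if "relapse" not in table.columns:
            raise ValueError("metadata must contain a 'relapse' column")
        relapse = table["relapse"]
        if relapse.isna().any():
            raise ValueError("missing relapse outcome for some samples")
        if not set(np.unique(relapse)).issubset({0, 1}):
            raise ValueError("relapse outcome must be coded 0/1")
        if table.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        self.table = table.copy()
        self.table["relapse"] = self.table["relapse"].astype(int)
        if pcs is not None:
            pcs = np.asarray(pcs, dtype=float)
            if pcs.shape[0] != len(table):
                raise ValueError("PC matrix row count does not match samples")
        self.pcs = pcs

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def relapse(self) -> np.ndarray:
        return self.table["relapse"].to_numpy(dtype=int)

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def with_pcs(self, pcs: np.ndarray) -> "CohortMetadata":
        return CohortMetadata(self.table, pcs)

    def subset(self, index: Sequence[int] | np.ndarray) -> "CohortMetadata":
        index = np.asarray(index)
        return CohortMetadata(
            self.table.iloc[index],
            None if self.pcs is None else self.pcs[index],
        )

    def align_to(self, sample_ids: Sequence[str]) -> "CohortMetadata":
        """Reorder/subset rows to match ``sample_ids`` exactly."""
        pos = {s: i for i, s in enumerate(self.table.index)}
        try:
            idx = np.array([pos[s] for s in sample_ids])
        except KeyError as exc:
            raise KeyError(f"sample missing from metadata: {exc.args[0]!r}") from None
        return self.subset(idx)


@dataclass
class FoldResult:
    """Bookkeeping for one leave-one-out fold."""

    held_out_sample: str
    selected_variants: list[int]
    prediction_score: float
    per_variant_importance: dict[int, float] = field(default_factory=dict)
    converged_flags: dict[str, int] = field(default_factory=dict)
    fallback: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.prediction_score <= 1.0):
            raise ValueError(
                f"fold {self.held_out_sample}: score {self.prediction_score} "
                "outside [0, 1]"
            )


@dataclass
class PredictionSet:
    """Out-of-fold prediction scores paired with true labels."""

    sample_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    fold_results: list[FoldResult] = field(default_factory=list)
    config: object | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sample_ids) != len(self.scores) or len(self.scores) != len(
            self.labels
        ):
            raise ValueError("sample_ids, scores and labels must align")
        if self.fold_results and len(self.fold_results) != len(self.sample_ids):
            raise ValueError("one fold result per sample expected")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "label": self.labels,
                "score": self.scores,
            }
        )
        if self.fold_results:
            frame["n_selected_variants"] = [
                len(f.selected_variants) for f in self.fold_results
            ]
        return frame


@dataclass
class DosageTable:
    """Imputed genotype posteriors: expected dosages plus per-call uncertainty.

    ``probs[i, j]`` is the posterior over genotypes {0, 1, 2} for sample ``i``
    at variant ``j``; ``dosage`` is its mean and ``sd`` its standard deviation
    ``sqrt(E[g^2] - E[g]^2)``.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    probs: np.ndarray
    dosage: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.sample_ids), len(self.variants)
        if self.probs.shape != (n, m, 3):
            raise ValueError("probs must have shape (n_samples, n_variants, 3)")
        if self.dosage.shape != (n, m) or self.sd.shape != (n, m):
            raise ValueError("dosage/sd must have shape (n_samples, n_variants)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, index: Sequence[int] | np.ndarray) -> "DosageTable":
        index = _as_index(index)
        return DosageTable(
            self.sample_ids,
            [self.variants[i] for i in index],
            self.probs[:, index],
            self.dosage[:, index],
            self.sd[:, index],
        )

    def variant_quality(self) -> np.ndarray:
        """Per-variant imputation quality: mean per-call dosage SD."""
        return self.sd.mean(axis=0)
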