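"""Magnitude-of-missingness profiles and observation-count thresholds.

The central statistic is the normalized missing count

    alpha = (missing values for a protein in a stratum) / (samples in the stratum)

computed per protein within each level of a grouping axis — collection time
point or disease-activity group.  Thresholding removes proteins detected in
too few samples overall before any correlation analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

from .core_data import QuantMatrix, SampleMetadata, ValidationError, align, levels_of

__all__ = [
    "ThresholdSpec",
    "compute_alpha",
    "profile",
    "missing_share",
    "apply_threshold",
    "missingness_histogram",
    "percent",
]

_THRESHOLD_MODES = (
    "min_observed_fraction",
    "max_missing_fraction",
    "min_observed_count",
    "max_missing_count",
)

#: columns of the long-format profile frame returned by :func:`profile`
PROFILE_COLUMNS = ("protein_id", "axis", "level", "missing_count", "n_samples", "alpha")


@dataclass(frozen=True)
class ThresholdSpec:
    """Observation/missingness threshold applied against the total sample count.

    ``min_observed_fraction f`` retains proteins observed in at least
    ``ceil(f * N)`` of the N samples (the default, f = 0.10, reproduces the
    ">10% observations" rule).  ``max_missing_fraction`` bounds the missing
    fraction from above; the two count modes take absolute counts.
    """

    mode: str = "min_observed_fraction"
    value: float = 0.10

    def __post_init__(self) -> None:
        if self.mode not in _THRESHOLD_MODES:
            raise ValidationError(
                f"unknown threshold mode {self.mode!r}; expected one of {_THRESHOLD_MODES}"
            )
        if self.mode.endswith("fraction") and not 0.0 <= self.value <= 1.0:
            raise ValidationError(f"fraction threshold must be in [0, 1], got {self.value}")
        if self.mode.endswith("count") and (self.value < 0 or self.value != int(self.value)):
            raise ValidationError(f"count threshold must be a non-negative integer, got {self.value}")

    def min_observed(self, n_samples: int) -> int:
        """Minimum observed count implied for a matrix with ``n_samples`` columns."""
        # guard against float fuzz turning an exact multiple into ceil+1
        eps = 1e-9
        if self.mode == "min_observed_fraction":
            return math.ceil(self.value * n_samples - eps)
        if self.mode == "max_missing_fraction":
            return n_samples - math.floor(self.value * n_samples + eps)
        if self.mode == "min_observed_count":
            return int(self.value)
        return n_samples - int(self.value)


def compute_alpha(missing_count: int, n_samples: int) -> float:
    """Normalized missing count: ``missing_count / n_samples`` (exact ratio)."""
    if n_samples <= 0:
        raise ValidationError("alpha is undefined for a stratum with no samples")
    if not 0 <= missing_count <= n_samples:
        raise ValidationError(
            f"missing_count {missing_count} outside [0, n_samples={n_samples}]"
        )
    return missing_count / n_samples


def percent(x: float) -> int:
    """Round a fraction to integer percent, half away from zero (report style)."""
    return int(Decimal(100 * x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def profile(
    matrix: QuantMatrix,
    meta: SampleMetadata,
    axis: str,
    levels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-protein missingness magnitude within each level of ``axis``.

    Returns a long-format frame with columns
    ``protein_id, axis, level, missing_count, n_samples, alpha``; one row per
    (protein, level).  Denominators are the per-level sample counts.  By
    default only levels present in the metadata are profiled (alpha for an
    absent stratum is undefined, never 0); requesting an empty level
    explicitly raises.
    """
    matrix, meta = align(matrix, meta)
    mask = matrix.missing_mask()
    present = set(meta.table[axis])
    if levels is None:
        levels = tuple(lv for lv in levels_of(axis) if lv in present)
        if not levels:
            raise ValidationError(f"metadata has no levels on axis {axis!r}")
    blocks = []
    for level in levels:
        samples = meta.samples_where(axis, level)
        if len(samples) == 0:
            raise ValidationError(f"stratum {axis}={level} contains no samples")
        counts = mask.loc[:, samples].sum(axis=1).astype(int)
        blocks.append(
            pd.DataFrame(
                {
                    "protein_id": matrix.protein_ids,
                    "axis": axis,
                    "level": level,
                    "missing_count": counts.to_numpy(),
                    "n_samples": len(samples),
                    "alpha": counts.to_numpy() / len(samples),
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)


def missing_share(counts: Mapping[str, int] | pd.Series) -> pd.Series:
    """Each level's share of a protein's total missingness (shares sum to 1).

    This is the "% of total missingness found in <level>" summary used when
    describing an outlier protein across groups; undefined when every level
    has zero missing values.
    """
    series = pd.Series(counts, dtype=float)
    if (series < 0).any():
        raise ValidationError("missing counts must be non-negative")
    total = series.sum()
    if total == 0:
        raise ValidationError("missing share is undefined when all counts are zero")
    return series / total


def apply_threshold(
    matrix: QuantMatrix, spec: ThresholdSpec = ThresholdSpec()
) -> tuple[QuantMatrix, list[str]]:
    """Filter proteins by total observation count; returns (filtered, removed ids)."""
    n = matrix.n_samples
    observed = (~matrix.missing_mask()).sum(axis=1)
    keep = observed >= spec.min_observed(n)
    removed = matrix.protein_ids[~keep].tolist()
    return QuantMatrix(matrix.values.loc[keep]), removed


def missingness_histogram(matrix: QuantMatrix) -> pd.Series:
    """Distribution of per-protein total missing counts.

    Index = missing-count value, values = number of proteins; the total mass
    equals the protein count.  Used to inspect the inflated low-observation
    mode that motivates a discrete threshold choice.
    """
    counts = matrix.missing_mask().sum(axis=1).astype(int)
    hist = counts.value_counts().sort_index()
    hist.index.name = "missing_count"
    hist.name = "n_proteins"
    return hist
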