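"""Supporting checks: LOD/left-censoring assessment and batch-effect handling.

The LOD assessment asks how much of the missingness is explained by low
abundance (left-censoring at the instrument's limit of detection): it
correlates each protein's mean log abundance over its observed cells with
its missing count.  A weakly negative correlation indicates missingness is
not strictly abundance-driven, which is what licenses reading it as
biological signal.

The batch assessment summarizes how samples distribute over measurement
batches and rescales missingness magnitudes by four batch-aware
denominators.  The printed formulas for these adjustments are ambiguous;
the concrete reading implemented here is, per stratum with B contributing
batches (batches containing at least one sample of the stratum):

1. ``alpha_over_batch_sample_sum``      alpha / (total samples, any stratum, in those B batches)
2. ``alpha_over_freq_times_batchcount`` alpha / (mean stratum samples per contributing batch x B)
                                        (the product equals the stratum sample count)
3. ``rawcount_over_freq_times_batchcount`` raw missing count / (same denominator as 2)
4. ``alpha_over_batchcount``            alpha / B

All four are stratum-constant rescalings of alpha (scheme 3 recovers alpha
itself), so residual-band outlier flags are structurally invariant to them;
``batch_sensitivity`` makes that invariance explicit as a Jaccard overlap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import QuantMatrix, SampleMetadata, ValidationError, align, levels_of
from .correlation import (
    BandSpec,
    UndefinedCorrelationError,
    detect_outliers,
    pearson_with_ci,
)

__all__ = [
    "LodAssessment",
    "BATCH_SCHEMES",
    "lod_assessment",
    "batch_summary",
    "apply_batch_adjustment",
    "batch_sensitivity",
]

BATCH_SCHEMES = (
    "alpha_over_batch_sample_sum",
    "alpha_over_freq_times_batchcount",
    "rawcount_over_freq_times_batchcount",
    "alpha_over_batchcount",
)


@dataclass(frozen=True)
class LodAssessment:
    """Correlation between per-protein mean log abundance and missing count.

    ``r`` is ``None`` when the correlation is undefined (e.g. a complete
    matrix, where every missing count is zero).
    """

    scope: str
    r: float | None
    ci_low: float | None
    ci_high: float | None
    n_proteins: int
    excluded_proteins: tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return self.r is not None


def lod_assessment(
    matrix: QuantMatrix,
    meta: SampleMetadata | None = None,
    scope: tuple[str, str] | None = None,
    conf: float = 0.95,
) -> LodAssessment:
    """Assess left-censoring: corr(mean log abundance, missing count).

    ``scope`` restricts to one stratum, e.g. ``("timepoint", "baseline")``;
    ``None`` uses all samples.  The mean log abundance is the natural log of
    a protein's observed cells only (values must be on a positive scale);
    proteins with no observed value in scope are excluded and reported.
    """
    if scope is not None:
        if meta is None:
            raise ValidationError("a stratum scope requires sample metadata")
        matrix, meta = align(matrix, meta)
        axis, level = scope
        matrix = matrix.subset_samples(meta.samples_where(axis, level))
        scope_name = f"{axis}={level}"
    else:
        scope_name = "overall"
    values = matrix.values
    if (values <= 0).any().any():
        raise ValidationError(
            "LOD assessment requires positive abundances (it takes logs itself)"
        )
    observed = values.notna().sum(axis=1)
    excluded = tuple(values.index[observed == 0])
    kept = values.loc[observed > 0]
    mean_log = np.log(kept).mean(axis=1)
    missing_count = kept.isna().sum(axis=1)
    if len(kept) < 4:
        raise ValidationError(
            f"LOD assessment needs >= 4 proteins with observations, got {len(kept)}"
        )
    try:
        res = pearson_with_ci(mean_log, missing_count, conf=conf)
    except UndefinedCorrelationError:
        return LodAssessment(scope_name, None, None, None, len(kept), excluded)
    return LodAssessment(scope_name, res.r, res.ci_low, res.ci_high, res.n, excluded)


def batch_summary(meta: SampleMetadata) -> dict:
    """Sample counts per batch by time point and by group, plus batch spans.

    Returns ``{"by_timepoint": DataFrame, "by_group": DataFrame,
    "batches_per_group": Series, "n_batches": int}``; contingency counts sum
    to the total sample count.
    """
    df = meta.table
    by_tp = pd.crosstab(df["batch"], df["timepoint"]).reindex(
        columns=[t for t in levels_of("timepoint") if t in set(df["timepoint"])]
    )
    by_grp = pd.crosstab(df["batch"], df["group"]).reindex(
        columns=[g for g in levels_of("group") if g in set(df["group"])]
    )
    spans = df.groupby("group")["batch"].nunique()
    return {
        "by_timepoint": by_tp,
        "by_group": by_grp,
        "batches_per_group": spans,
        "n_batches": int(df["batch"].nunique()),
    }


def _stratum_denominators(meta: SampleMetadata, axis: str, level: str) -> dict[str, float]:
    df = meta.table
    in_level = df[axis] == level
    batches = set(df.loc[in_level, "batch"])
    if not batches:
        return {"batch_sample_sum": np.nan, "freq_times_batchcount": np.nan, "batchcount": np.nan}
    n_level = int(in_level.sum())
    return {
        # all samples (any stratum) measured in the contributing batches
        "batch_sample_sum": float(df["batch"].isin(batches).sum()),
        # mean stratum samples per contributing batch x batch count == n_level
        "freq_times_batchcount": float(n_level),
        "batchcount": float(len(batches)),
    }


def apply_batch_adjustment(
    profiles: pd.DataFrame, meta: SampleMetadata, scheme: str
) -> pd.DataFrame:
    """Rescale per-stratum missingness by one of the four batch-aware schemes.

    Returns the profile frame with an ``adjusted`` column; a stratum with no
    samples yields NaN.  Adjusted values are non-negative and zero exactly
    where the numerator (alpha, or the raw missing count) is zero.
    """
    if scheme not in BATCH_SCHEMES:
        raise ValidationError(f"unknown batch scheme {scheme!r}; expected one of {BATCH_SCHEMES}")
    out = profiles.copy()
    adjusted = np.full(len(out), np.nan)
    for (axis, level), idx in out.groupby(["axis", "level"]).groups.items():
        denoms = _stratum_denominators(meta, axis, level)
        rows = out.loc[idx]
        if scheme == "alpha_over_batch_sample_sum":
            adj = rows["alpha"] / denoms["batch_sample_sum"]
        elif scheme == "alpha_over_freq_times_batchcount":
            adj = rows["alpha"] / denoms["freq_times_batchcount"]
        elif scheme == "rawcount_over_freq_times_batchcount":
            adj = rows["missing_count"] / denoms["freq_times_batchcount"]
        else:
            adj = rows["alpha"] / denoms["batchcount"]
        adjusted[out.index.get_indexer(idx)] = adj
    out["adjusted"] = adjusted
    return out


def _flag_set(profiles: pd.DataFrame, axis: str, band: BandSpec, column: str) -> set:
    """(protein, comparison) pairs flagged when outliers are detected on ``column``."""
    work = profiles.copy()
    if column != "alpha":
        work["alpha"] = work[column]
    flags = set()
    for a, b in itertools.combinations(levels_of(axis), 2):
        rep = detect_outliers(work, (a, b), band=band, axis=axis)
        for pid in rep.loc[rep["flagged"], "protein_id"]:
            flags.add((pid, f"{a}-{b}"))
    return flags


def batch_sensitivity(
    profiles: pd.DataFrame,
    meta: SampleMetadata,
    band: BandSpec = BandSpec(),
    axis: str = "group",
) -> pd.DataFrame:
    """Jaccard overlap of outlier flag sets under each batch scheme vs unadjusted.

    Empty-vs-empty overlap is 1.0 by convention.  Also reports each group's
    batch span so group-batch confounding (a group confined to few batches)
    is visible alongside the overlap.
    """
    base_flags = _flag_set(profiles, axis, band, "alpha")
    spans = batch_summary(meta)["batches_per_group"]
    rows = []
    for scheme in BATCH_SCHEMES:
        adj = apply_batch_adjustment(profiles, meta, scheme)
        flags = _flag_set(adj, axis, band, "adjusted")
        union = base_flags | flags
        jaccard = 1.0 if not union else len(base_flags & flags) / len(union)
        rows.append(
            {
                "scheme": scheme,
                "n_flagged_unadjusted": len(base_flags),
                "n_flagged_adjusted": len(flags),
                "jaccard_vs_unadjusted": jaccard,
                "min_batches_per_group": int(spans.min()),
            }
        )
    return pd.DataFrame(rows)
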