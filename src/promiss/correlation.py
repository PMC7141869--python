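"""Cross-stratum correlation of missingness and residual-band outlier detection.

Per-protein missingness magnitudes (alpha) from two strata are compared by
Pearson correlation with a Fisher-z confidence interval.  Between time
points alpha is expected to correlate strongly (technique reproducibility);
between disease-activity groups less so, and proteins far from the fitted
cross-stratum regression line are candidate informative-missingness
biomarkers.  The visual "shaded band parallel to the regression line" is
made algorithmic as a residual band of half-width ``k`` residual standard
deviations (default k = 2.5) around the ordinary-least-squares line.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ValidationError, levels_of

__all__ = [
    "UndefinedCorrelationError",
    "CorrelationResult",
    "BandSpec",
    "pearson_with_ci",
    "fisher_ci",
    "correlate_axis",
    "correlations_frame",
    "detect_outliers",
    "cross_axis_screen",
]

_VAR_EPS = 1e-12
_ATANH_CAP = 20.0  # tanh(20) == 1.0 to double precision; caps atanh(+-1)


class UndefinedCorrelationError(ValidationError):
    """A correlation was requested on degenerate input (zero variance or n < 4)."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r between two per-protein alpha vectors with a Fisher-z CI."""

    stratum_a: str
    stratum_b: str
    r: float
    ci_low: float
    ci_high: float
    n: int
    conf: float = 0.95


@dataclass(frozen=True)
class BandSpec:
    """Residual band: half-width ``k`` x SD(residuals), or an absolute alpha offset."""

    k: float = 2.5
    absolute: float | None = None

    def halfwidth(self, residual_sd: float) -> float:
        if self.absolute is not None:
            return float(self.absolute)
        return self.k * residual_sd


def fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    ``tanh(atanh(r) +- z_{1-(1-conf)/2} / sqrt(n - 3))``, with ``atanh``
    capped at a large finite value so r = +-1 yields a degenerate interval
    at +-1 instead of overflowing.
    """
    if n < 4:
        raise UndefinedCorrelationError(f"Fisher CI requires n >= 4, got n={n}")
    z = np.clip(np.arctanh(np.clip(r, -1.0, 1.0)), -_ATANH_CAP, _ATANH_CAP)
    half = stats.norm.ppf(1 - (1 - conf) / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_with_ci(
    x: Sequence[float],
    y: Sequence[float],
    conf: float = 0.95,
    stratum_a: str = "x",
    stratum_b: str = "y",
) -> CorrelationResult:
    """Sample Pearson correlation of two equal-length vectors with Fisher-z CI.

    Raises :class:`UndefinedCorrelationError` for n < 4 or (near-)zero
    variance in either vector — a degenerate correlation is reported as
    undefined, never as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"vectors must be 1-D and equal length, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 4:
        raise UndefinedCorrelationError(f"correlation requires n >= 4, got n={n}")
    if x.var(ddof=0) < _VAR_EPS or y.var(ddof=0) < _VAR_EPS:
        raise UndefinedCorrelationError("correlation undefined: zero variance input")
    r = float(stats.pearsonr(x, y).statistic)
    lo, hi = fisher_ci(r, n, conf)
    return CorrelationResult(stratum_a, stratum_b, r, lo, hi, n, conf)


def _alpha_wide(profiles: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Pivot a long profile frame to proteins x levels of one axis."""
    sub = profiles[profiles["axis"] == axis]
    if sub.empty:
        raise ValidationError(f"no profiles for axis {axis!r}")
    wide = sub.pivot(index="protein_id", columns="level", values="alpha")
    missing_levels = [lv for lv in levels_of(axis) if lv not in wide.columns]
    if missing_levels:
        raise ValidationError(f"profiles lack levels {missing_levels} on axis {axis!r}")
    if wide.isna().any().any():
        raise ValidationError("profile frame has proteins without all strata")
    return wide[list(levels_of(axis))]


def correlate_axis(
    profiles: pd.DataFrame, axis: str, conf: float = 0.95, on: str = "alpha"
) -> list[CorrelationResult]:
    """All pairwise cross-stratum correlations along one axis.

    Three results per axis (baseline-3m, baseline-6m, 3m-6m, or HD-2HD,
    HD-LD, 2HD-LD).  ``on='missing_count'`` correlates raw counts instead of
    alpha (for sensitivity checks); the default follows the normalized
    missing count.
    """
    if on not in ("alpha", "missing_count"):
        raise ValidationError(f"on must be 'alpha' or 'missing_count', got {on!r}")
    sub = profiles[profiles["axis"] == axis]
    if on == "alpha":
        wide = _alpha_wide(profiles, axis)
    else:
        wide = sub.pivot(index="protein_id", columns="level", values="missing_count")
        wide = wide[list(levels_of(axis))]
    results = []
    for a, b in itertools.combinations(levels_of(axis), 2):
        results.append(
            pearson_with_ci(wide[a], wide[b], conf=conf, stratum_a=a, stratum_b=b)
        )
    return results


def correlations_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Tidy frame (stratum_a, stratum_b, r, ci_low, ci_high, n) for report output."""
    return pd.DataFrame(
        [
            {
                "stratum_a": c.stratum_a,
                "stratum_b": c.stratum_b,
                "r": c.r,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "n": c.n,
            }
            for c in results
        ]
    )


def detect_outliers(
    profiles: pd.DataFrame,
    comparison: tuple[str, str],
    band: BandSpec = BandSpec(),
    axis: str | None = None,
) -> pd.DataFrame:
    """Flag proteins far from the cross-stratum regression of alpha_b on alpha_a.

    Fits ordinary least squares of the second stratum's alpha on the first's
    over all proteins; the signed residual is ``alpha_b - fitted`` and a
    protein is flagged when ``|residual| > band halfwidth``.  ``direction``
    names the stratum with excess missingness relative to the trend.

    Returns one row per protein: ``protein_id, stratum_a, stratum_b,
    alpha_a, alpha_b, residual, band_halfwidth, flagged, direction``.
    """
    level_a, level_b = comparison
    if axis is None:
        axis = _infer_axis(level_a, level_b)
    wide = _alpha_wide(profiles, axis)
    if len(wide) < 10:
        raise ValidationError(
            f"outlier detection needs >= 10 proteins, got {len(wide)}"
        )
    x = wide[level_a].to_numpy()
    y = wide[level_b].to_numpy()

    if x.var(ddof=0) < _VAR_EPS:
        warnings.warn(
            f"degenerate fit for {level_a} vs {level_b}: no variance in alpha; "
            "no outliers flagged",
            stacklevel=2,
        )
        slope, intercept = 0.0, float(y.mean())
    else:
        slope, intercept = np.polyfit(x, y, 1)
    residual = y - (slope * x + intercept)
    sd = float(residual.std(ddof=1)) if len(residual) > 1 else 0.0
    halfwidth = band.halfwidth(sd)
    # tolerance keeps exactly-collinear data (residuals ~1e-16) unflagged
    flagged = np.abs(residual) > halfwidth + 1e-10
    return pd.DataFrame(
        {
            "protein_id": wide.index,
            "stratum_a": level_a,
            "stratum_b": level_b,
            "alpha_a": x,
            "alpha_b": y,
            "residual": residual,
            "band_halfwidth": halfwidth,
            "flagged": flagged,
            "direction": np.where(residual > 0, level_b, level_a),
        }
    ).reset_index(drop=True)


def _infer_axis(level_a: str, level_b: str) -> str:
    for axis in ("timepoint", "group"):
        if {level_a, level_b} <= set(levels_of(axis)):
            return axis
    raise ValidationError(f"levels {level_a!r}, {level_b!r} are not on a single axis")


def all_outlier_reports(
    profiles: pd.DataFrame, axis: str, band: BandSpec = BandSpec()
) -> pd.DataFrame:
    """Concatenated outlier reports for the three pairwise comparisons of one axis."""
    reports = [
        detect_outliers(profiles, (a, b), band=band, axis=axis)
        for a, b in itertools.combinations(levels_of(axis), 2)
    ]
    return pd.concat(reports, ignore_index=True)


def cross_axis_screen(
    group_reports: pd.DataFrame,
    time_reports: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Candidate-biomarker screen: group-axis outlier, time-axis stable.

    A protein qualifies when it is flagged in at least one disease-group
    comparison and in none of the time-point comparisons — group-dependent
    but time-stable missingness, the discriminating-protein criterion.
    Per-level alphas are attached when ``profiles`` is given.
    """
    g_flags = group_reports.groupby("protein_id")["flagged"].sum()
    t_flags = time_reports.groupby("protein_id")["flagged"].sum()
    combined = pd.DataFrame(
        {"n_group_flags": g_flags, "n_time_flags": t_flags}
    ).fillna(0).astype(int)
    keep = combined[(combined["n_group_flags"] >= 1) & (combined["n_time_flags"] == 0)]

    flagged_rows = group_reports[group_reports["flagged"]]
    comparisons = (
        flagged_rows.assign(
            comparison=flagged_rows["stratum_a"] + "-" + flagged_rows["stratum_b"]
        )
        .groupby("protein_id")["comparison"]
        .agg(";".join)
    )
    out = keep.copy()
    out["group_comparisons_flagged"] = comparisons.reindex(keep.index).fillna("")
    if profiles is not None:
        for axis in ("group", "timepoint"):
            if not (profiles["axis"] == axis).any():
                continue
            wide = _alpha_wide(profiles, axis)
            for level in levels_of(axis):
                out[f"alpha_{level}"] = wide[level].reindex(keep.index)
    out.index.name = "protein_id"
    return out.reset_index()
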