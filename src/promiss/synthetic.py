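"""Synthetic longitudinal DIA-like cohort generator with ground truth.

Emulates the statistical structure the missingness analysis assumes, so the
whole pipeline is testable without access to any clinical dataset:

* 64 participants in three disease-activity groups (HD 12, 2HD 20, LD 32)
  followed at baseline / 3 months / 6 months with attrition to 58/47/44
  samples;
* several hundred proteins, most carrying a time-stable per-protein
  missingness propensity with a broad spread (this is what makes alpha
  correlate strongly across time points), plus a block of rarely detected
  proteins that the observation filter removes;
* a weak abundance-driven (left-censoring-like) missingness component via a
  logistic term in the protein's mean log abundance;
* a small set of planted "informative" proteins whose missingness
  probability depends on the disease-activity group and is constant in time;
* twelve measurement batches with group-batch imbalance (each participant's
  samples run in one batch).

Cell missingness probability is additive-clamped across mechanisms:
``p = clamp(propensity + lod_term + timepoint_offset, 0, 1)`` for background
proteins; planted proteins use their configured per-group rate directly; the
rarely-detected block uses a per-protein constant.  The per-timepoint
offsets are solved by bisection so the mean probability over background
proteins equals the configured per-timepoint rate exactly.

Everything is deterministic given the seed, and the returned truth object
stores the full protein x sample probability matrix — an exact oracle for
downstream recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_data import GROUPS, TIMEPOINTS, QuantMatrix, SampleMetadata, ValidationError

__all__ = ["SimulationConfig", "SimulationTruth", "simulate", "empirical_rates"]


def _default_groups() -> dict[str, int]:
    return {"HD": 12, "2HD": 20, "LD": 32}


def _default_attrition() -> dict[str, int]:
    return {"baseline": 58, "3m": 47, "6m": 44}


def _default_rates() -> dict[str, float]:
    return {"baseline": 0.39, "3m": 0.31, "6m": 0.30}


def _default_informative_rates() -> dict[str, float]:
    return {"HD": 0.32, "2HD": 0.30, "LD": 0.76}


def _default_batches() -> dict[str, tuple[int, ...]]:
    # HD confined to 2 batches, 2HD spread over 8, LD over 10; union = 12
    return {
        "HD": (1, 2),
        "2HD": tuple(range(3, 11)),
        "LD": tuple(range(3, 13)),
    }


@dataclass
class SimulationConfig:
    """Cohort and missingness-mechanism parameters (defaults = study conditions)."""

    n_participants_per_group: Mapping[str, int] = field(default_factory=_default_groups)
    samples_per_timepoint: Mapping[str, int] = field(default_factory=_default_attrition)
    n_proteins: int = 742
    #: proteins drawn from the detectable population; the remainder form the
    #: rarely-detected block the observation filter is meant to remove
    n_detectable: int = 565
    #: target mean missingness among detectable background proteins, per timepoint
    missing_rate_per_timepoint: Mapping[str, float] = field(default_factory=_default_rates)
    #: spread of the time-stable per-protein missingness propensity
    propensity_sd: float = 0.26
    #: weight of the abundance-dependent (pseudo-LOD) censoring term
    lod_strength: float = 0.40
    #: pseudo-LOD centre, in abundance-SD units below the mean log abundance
    lod_center_offset: float = -1.0
    lod_scale: float = 0.5
    n_informative: int = 8
    informative_rates: Mapping[str, float] = field(default_factory=_default_informative_rates)
    n_batches: int = 12
    batch_allocation: Mapping[str, tuple[int, ...]] = field(default_factory=_default_batches)
    abundance_log_mean: float = 14.0
    abundance_log_sd: float = 1.5
    within_protein_sd: float = 0.5
    low_detection_rate_range: tuple[float, float] = (0.92, 0.995)
    low_detection_abundance_shift: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_participants_per_group.items():
            if g not in GROUPS:
                raise ValidationError(f"unknown group {g!r} in config")
            if n <= 0:
                raise ValidationError(f"group size for {g} must be positive, got {n}")
        total = sum(self.n_participants_per_group.values())
        for t, n in self.samples_per_timepoint.items():
            if t not in TIMEPOINTS:
                raise ValidationError(f"unknown timepoint {t!r} in config")
            if not 0 < n <= total:
                raise ValidationError(
                    f"retention at {t} must be in 1..{total} participants, got {n}"
                )
        if set(self.samples_per_timepoint) != set(TIMEPOINTS):
            raise ValidationError("samples_per_timepoint must cover all three timepoints")
        for label, rates in (
            ("missing_rate_per_timepoint", self.missing_rate_per_timepoint.values()),
            ("informative_rates", self.informative_rates.values()),
            ("low_detection_rate_range", self.low_detection_rate_range),
        ):
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValidationError(f"{label} must lie in [0, 1]")
        if not 0 < self.n_detectable <= self.n_proteins:
            raise ValidationError("need 0 < n_detectable <= n_proteins")
        if not 0 <= self.n_informative <= self.n_detectable:
            raise ValidationError("need 0 <= n_informative <= n_detectable")
        if self.lod_strength < 0 or self.propensity_sd <= 0:
            raise ValidationError("lod_strength must be >= 0 and propensity_sd > 0")
        for g in self.n_participants_per_group:
            batches = self.batch_allocation.get(g)
            if not batches:
                raise ValidationError(f"no batch allocation for group {g}")
            if any(not 1 <= b <= self.n_batches for b in batches):
                raise ValidationError(f"batch ids for {g} outside 1..{self.n_batches}")


@dataclass(frozen=True)
class SimulationTruth:
    """Exact generating quantities: planted ids, per-protein parameters and the
    full protein x sample missingness-probability matrix."""

    informative_protein_ids: tuple[str, ...]
    protein_params: pd.DataFrame  # protein_id, kind, log_abundance_mean, propensity, lod_term
    probabilities: pd.DataFrame  # proteins x samples
    timepoint_offsets: dict[str, float]
    informative_rates: dict[str, float]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (largest remainder)."""
    quota = weights / weights.sum() * total
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    for i in np.argsort(-remainder)[: total - alloc.sum()]:
        alloc[i] += 1
    return alloc


def _solve_offset(base: np.ndarray, target: float) -> float:
    """Bisection for delta with mean(clip(base + delta, 0, 1)) == target."""
    lo, hi = -2.0, 2.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if np.clip(base + mid, 0.0, 1.0).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def simulate(config: SimulationConfig) -> tuple[QuantMatrix, SampleMetadata, SimulationTruth]:
    """Generate a cohort (matrix, metadata, truth); deterministic given the seed."""
    rng = np.random.default_rng(config.seed)

    # --- participants, groups, batches -------------------------------------
    participants: list[str] = []
    part_group: dict[str, str] = {}
    part_batch: dict[str, int] = {}
    pid = 0
    for g in GROUPS:
        n = config.n_participants_per_group.get(g, 0)
        batches = config.batch_allocation[g] if n else ()
        for i in range(n):
            pid += 1
            name = f"P{pid:03d}"
            participants.append(name)
            part_group[name] = g
            part_batch[name] = batches[i % len(batches)]

    # --- attrition: whole samples retained at random within group ----------
    group_sizes = np.array([config.n_participants_per_group.get(g, 0) for g in GROUPS])
    by_group = {g: [p for p in participants if part_group[p] == g] for g in GROUPS}
    sample_rows: list[tuple[str, str, str, str, int]] = []  # sample, participant, tp, group, batch
    for t in TIMEPOINTS:
        alloc = _largest_remainder(group_sizes.astype(float), config.samples_per_timepoint[t])
        for g, n_keep in zip(GROUPS, alloc):
            pool = by_group[g]
            if n_keep > len(pool):
                raise ValidationError(
                    f"retention {n_keep} at {t} exceeds group {g} size {len(pool)}"
                )
            kept = rng.choice(pool, size=n_keep, replace=False)
            for p in sorted(kept):
                sample_rows.append((f"{p}_{t}", p, t, g, part_batch[p]))
    meta_df = pd.DataFrame(
        sample_rows, columns=["sample_id", "participant_id", "timepoint", "group", "batch"]
    ).set_index("sample_id")
    meta = SampleMetadata(meta_df)

    # --- protein parameters -------------------------------------------------
    P = config.n_proteins
    protein_ids = np.array([f"PROT{i + 1:04d}" for i in range(P)])
    order = rng.permutation(P)
    detect_idx = np.sort(order[: config.n_detectable])
    junk_idx = np.sort(order[config.n_detectable :])
    informative_idx = np.sort(detect_idx[rng.permutation(config.n_detectable)[: config.n_informative]])

    mu = rng.normal(config.abundance_log_mean, config.abundance_log_sd, size=P)
    mu[junk_idx] += config.low_detection_abundance_shift

    # time-stable propensity with broad spread: Beta matched to mean/sd
    mean_target = float(np.mean(list(config.missing_rate_per_timepoint.values())))
    m_bar = float(np.clip(mean_target - 0.4 * config.lod_strength, 0.05, 0.95))
    var = min(config.propensity_sd**2, 0.9 * m_bar * (1 - m_bar))
    shape_sum = m_bar * (1 - m_bar) / var - 1
    propensity = rng.beta(m_bar * shape_sum, (1 - m_bar) * shape_sum, size=P)

    lod_center = config.abundance_log_mean + config.lod_center_offset * config.abundance_log_sd
    lod_term = config.lod_strength * expit(
        -(mu - lod_center) / (config.lod_scale * config.abundance_log_sd)
    )

    junk_rate = rng.uniform(*config.low_detection_rate_range, size=len(junk_idx))

    # Per-timepoint offsets calibrated on detectable background proteins.
    # Two passes: the configured rates describe the analysis set, i.e. the
    # proteins that survive the observation filter, so after a first solve the
    # near-saturated tail (expected missingness > ~0.9, which the default
    # 10%-observations filter removes) is dropped and the offsets re-solved.
    informative_set = set(informative_idx)
    background_idx = np.array([i for i in detect_idx if i not in informative_set])
    base = propensity[background_idx] + lod_term[background_idx]
    offsets = {
        t: _solve_offset(base, config.missing_rate_per_timepoint[t]) for t in TIMEPOINTS
    }
    expected = np.mean(
        [np.clip(base + offsets[t], 0.0, 1.0) for t in TIMEPOINTS], axis=0
    )
    retainable = base[expected <= 0.88]
    if len(retainable) >= 20:
        offsets = {
            t: _solve_offset(retainable, config.missing_rate_per_timepoint[t])
            for t in TIMEPOINTS
        }

    # --- probability matrix -------------------------------------------------
    S = len(meta_df)
    prob = np.empty((P, S))
    tp_arr = meta_df["timepoint"].to_numpy()
    grp_arr = meta_df["group"].to_numpy()
    for j in range(S):
        col = np.clip(propensity + lod_term + offsets[tp_arr[j]], 0.0, 1.0)
        col[informative_idx] = config.informative_rates[grp_arr[j]]
        col[junk_idx] = junk_rate
        prob[:, j] = col

    # --- draws ---------------------------------------------------------------
    mask = rng.random((P, S)) < prob
    log_values = rng.normal(mu[:, None], config.within_protein_sd, size=(P, S))
    values = np.exp(log_values)
    values[mask] = np.nan

    matrix = QuantMatrix(
        pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                     columns=meta_df.index)
    )
    kind = np.full(P, "background", dtype=object)
    kind[junk_idx] = "low_detection"
    kind[informative_idx] = "informative"
    truth = SimulationTruth(
        informative_protein_ids=tuple(protein_ids[informative_idx]),
        protein_params=pd.DataFrame(
            {
                "protein_id": protein_ids,
                "kind": kind,
                "log_abundance_mean": mu,
                "propensity": propensity,
                "lod_term": lod_term,
            }
        ),
        probabilities=pd.DataFrame(
            prob, index=pd.Index(protein_ids, name="protein_id"), columns=meta_df.index
        ),
        timepoint_offsets=offsets,
        informative_rates=dict(config.informative_rates),
    )
    return matrix, meta, truth


def empirical_rates(
    matrix: QuantMatrix, meta: SampleMetadata, truth: SimulationTruth
) -> pd.DataFrame:
    """Realized per-group missingness rate for each planted informative protein.

    Rates converge to the configured per-group probabilities as group sizes
    grow; a group with no samples yields an explicit NaN rate.
    """
    mask = matrix.missing_mask()
    rows = []
    for pid in truth.informative_protein_ids:
        for g in GROUPS:
            samples = meta.table.index[meta.table["group"] == g]
            n = len(samples)
            miss = int(mask.loc[pid, samples].sum()) if n else 0
            rows.append(
                {
                    "protein_id": pid,
                    "group": g,
                    "missing_count": miss,
                    "n_samples": n,
                    "rate": miss / n if n else np.nan,
                    "true_rate": truth.informative_rates[g],
                }
            )
    return pd.DataFrame(rows)
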