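"""Containers, readers and validation for quantification matrices and sample metadata.

The analysis operates on two tables: a wide protein x sample matrix of
relative abundances in which missing cells are explicit (never zero), and a
per-sample metadata table assigning each sample to a participant, a
collection time point, a disease-activity group and a mass-spectrometry
batch.  Both are thin, validated wrappers around :class:`pandas.DataFrame`;
inside the matrix, ``NaN`` is the missing marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "GROUPS",
    "DEFAULT_MISSING_TOKENS",
    "ValidationError",
    "QuantMatrix",
    "SampleMetadata",
    "read_quant_matrix",
    "write_quant_matrix",
    "read_metadata",
    "write_metadata",
    "align",
]

#: Canonical collection time points, in temporal order.
TIMEPOINTS: tuple[str, ...] = ("baseline", "3m", "6m")

#: Canonical disease-activity groups: high, secondary-high (low at 3 months,
#: worsening by 6 months) and low disease activity.
GROUPS: tuple[str, ...] = ("HD", "2HD", "LD")

#: On-disk cell contents treated as missing (case-sensitive; configurable).
DEFAULT_MISSING_TOKENS: frozenset[str] = frozenset({"", "NA"})

_TIMEPOINT_ALIASES: Mapping[str, str] = {
    "baseline": "baseline",
    "bl": "baseline",
    "0m": "baseline",
    "3m": "3m",
    "m3": "3m",
    "3months": "3m",
    "6m": "6m",
    "m6": "6m",
    "6months": "6m",
}

_GROUP_ALIASES: Mapping[str, str] = {
    "hd": "HD",
    "high": "HD",
    "2hd": "2HD",
    "hd2": "2HD",
    "2°hd": "2HD",
    "ld": "LD",
    "low": "LD",
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dups = labels[labels.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


@dataclass(frozen=True)
class QuantMatrix:
    """Protein x sample relative-quantification matrix with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with sample ids as columns.  Cells
        are finite floats or ``NaN`` (the missing marker).  Zeros are valid
        observed measurements and are never conflated with missingness.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index, "protein ids")
        _check_unique(df.columns, "sample ids")
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric cell in quant matrix: {exc}") from exc
        arr = df.to_numpy()
        if np.isinf(arr).any():
            i, j = np.argwhere(np.isinf(arr))[0]
            raise ValidationError(
                f"non-finite value at protein {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        df.index.name = "protein_id"
        df.columns.name = "sample_id"
        object.__setattr__(self, "values", df)

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean protein x sample frame, ``True`` where the cell is missing."""
        return self.values.isna()

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_proteins(self, protein_ids: Iterable[str]) -> "QuantMatrix":
        return QuantMatrix(self.values.loc[list(protein_ids)])

    def subset_samples(self, sample_ids: Iterable[str]) -> "QuantMatrix":
        return QuantMatrix(self.values.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations: participant, time point, group and batch.

    Indexed by sample id with columns ``participant_id``, ``timepoint``
    (one of :data:`TIMEPOINTS`), ``group`` (one of :data:`GROUPS`) and
    integer ``batch``.  A participant appears at most once per time point
    and belongs to exactly one group across all of their samples.
    """

    table: pd.DataFrame

    _REQUIRED = ("participant_id", "timepoint", "group", "batch")

    def __post_init__(self) -> None:
        df = self.table
        missing_cols = [c for c in self._REQUIRED if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"metadata is missing columns: {missing_cols}")
        _check_unique(df.index, "sample ids")
        df = df.copy()
        df.index.name = "sample_id"

        bad_tp = sorted(set(df["timepoint"]) - set(TIMEPOINTS))
        if bad_tp:
            raise ValidationError(
                f"unknown timepoint labels {bad_tp}; expected one of {list(TIMEPOINTS)}"
            )
        bad_grp = sorted(set(df["group"]) - set(GROUPS))
        if bad_grp:
            raise ValidationError(
                f"unknown group labels {bad_grp}; expected one of {list(GROUPS)}"
            )
        try:
            df["batch"] = df["batch"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"batch must be an integer: {exc}") from exc
        if (df["batch"] < 1).any():
            raise ValidationError("batch ids must be >= 1")

        dup = df.duplicated(subset=["participant_id", "timepoint"])
        if dup.any():
            pairs = df.loc[dup, ["participant_id", "timepoint"]].values.tolist()[:5]
            raise ValidationError(f"participant measured twice at one timepoint: {pairs}")

        n_groups = df.groupby("participant_id")["group"].nunique()
        unstable = n_groups[n_groups > 1].index.tolist()
        if unstable:
            raise ValidationError(
                f"participants assigned to more than one group: {unstable[:5]}"
            )
        object.__setattr__(self, "table", df)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def samples_where(self, axis: str, level: str) -> pd.Index:
        """Sample ids belonging to one stratum (a level of one axis)."""
        levels = levels_of(axis)
        if level not in levels:
            raise ValidationError(f"level {level!r} not on axis {axis!r} ({levels})")
        return self.table.index[self.table[axis] == level]

    def reorder(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)])


def levels_of(axis: str) -> tuple[str, ...]:
    """Canonical stratum levels for a grouping axis (``timepoint`` or ``group``)."""
    if axis == "timepoint":
        return TIMEPOINTS
    if axis == "group":
        return GROUPS
    raise ValidationError(f"unknown axis {axis!r}; expected 'timepoint' or 'group'")


def read_quant_matrix(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    sep: str | None = None,
) -> QuantMatrix:
    """Read a wide delimited quant matrix (first column protein ids, header sample ids).

    Cells equal to any of ``missing_tokens`` become the missing marker; every
    other cell must parse as a finite real, otherwise a
    :class:`ValidationError` names the offending row and column.
    """
    path = Path(path)
    tokens = set(missing_tokens)
    raw = pd.read_csv(
        path, sep=_infer_sep(path, sep), index_col=0, dtype=str, keep_default_na=False
    )
    _check_unique(raw.index, "protein ids")
    _check_unique(raw.columns, "sample ids")
    stripped = raw.apply(lambda col: col.str.strip())
    token_mask = stripped.isin(tokens)
    numeric = stripped.mask(token_mask).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~token_mask
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"unparseable cell {stripped.iat[i, j]!r} at protein "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    return QuantMatrix(numeric)


def write_quant_matrix(
    matrix: QuantMatrix,
    path: str | Path,
    missing_token: str = "NA",
    sep: str | None = None,
) -> None:
    """Write a quant matrix; missing cells are emitted as ``missing_token``.

    Values are written at full float precision so a write -> read round trip
    is lossless for both values and the missing mask.
    """
    path = Path(path)
    matrix.values.to_csv(path, sep=_infer_sep(path, sep), na_rep=missing_token)


def read_metadata(path: str | Path, sep: str | None = None) -> SampleMetadata:
    """Read the sample metadata CSV/TSV (columns sample_id, participant_id,
    timepoint, group, batch).  Time point and group labels accept
    case-insensitive aliases (``m3``/``3m``, ``HD2``/``2HD`` ...)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str, keep_default_na=False)
    required = ["sample_id", "participant_id", "timepoint", "group", "batch"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"metadata file is missing columns: {missing_cols}")

    def _norm(series: pd.Series, aliases: Mapping[str, str], what: str) -> pd.Series:
        lowered = series.str.strip().str.lower()
        unknown = sorted(set(lowered) - set(aliases))
        if unknown:
            raise ValidationError(f"unknown {what} labels: {unknown}")
        return lowered.map(aliases)

    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].str.strip().to_numpy(),
            "timepoint": _norm(df["timepoint"], _TIMEPOINT_ALIASES, "timepoint").to_numpy(),
            "group": _norm(df["group"], _GROUP_ALIASES, "group").to_numpy(),
            "batch": df["batch"].to_numpy(),
        },
        index=pd.Index(df["sample_id"].str.strip(), name="sample_id"),
    )
    return SampleMetadata(out)


def write_metadata(meta: SampleMetadata, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    meta.table.to_csv(path, sep=_infer_sep(path, sep))


def align(matrix: QuantMatrix, meta: SampleMetadata) -> tuple[QuantMatrix, SampleMetadata]:
    """Harmonize sample order between matrix and metadata.

    Any sample present in exactly one of the two inputs is an error (silently
    dropping samples would corrupt missingness denominators).  Returns the
    pair with metadata rows in the matrix's column order; idempotent.
    """
    m_ids = set(matrix.sample_ids)
    t_ids = set(meta.sample_ids)
    only_matrix = sorted(m_ids - t_ids)
    only_meta = sorted(t_ids - m_ids)
    if only_matrix or only_meta:
        raise ValidationError(
            "sample sets differ between matrix and metadata; "
            f"matrix-only={only_matrix[:10]}, metadata-only={only_meta[:10]}"
        )
    if not m_ids:
        raise ValidationError("no samples in common between matrix and metadata")
    return matrix, meta.reorder(matrix.sample_ids)
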