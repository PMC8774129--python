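"""Expression-matrix I/O, marker panels, and reproducible cohort splitting.

Expression values are TPM (Transcripts Per Million): non-negative,
within-sample normalized abundances. A deliberate design rule of this
package is that values are carried through *as printed* — no filtering,
no model-based normalization, no log transform on read — because the
screening models downstream are meant to accept raw real-world TPM.
An optional ``log1p`` flag exists at model-training time only.

The splitting convention reproduces the study design this package
implements: the test set takes ``ceil(test_frac * N)`` samples and the
validation set ``ceil(val_frac * (N - |test|))`` of the remainder, so a
9057-sample cohort at 20%/20% yields 1812 / 1449 / 5796 samples exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NORMAL_LABEL = "normal"
"""Reserved label for non-cancer control samples."""


class ExpressionParseError(ValueError):
    """A file violated the expression/panel TSV contract."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples-by-features table of non-negative TPM values.

    Parameters
    ----------
    data
        DataFrame with unique sample identifiers as the index and unique
        feature identifiers as columns. All values must be finite and >= 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ExpressionParseError(f"duplicate sample identifier: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ExpressionParseError(f"duplicate feature identifier: {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ExpressionParseError("expression values must be numeric")
        if values.size:
            if not np.isfinite(values).all():
                raise ExpressionParseError("expression values must be finite")
            if (values < 0).any():
                r, c = np.argwhere(values < 0)[0]
                raise ExpressionParseError(
                    f"negative TPM value at sample {idx[r]!r}, feature {cols[c]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def restrict_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy keeping only ``feature_ids``, in the given order."""
        missing = [f for f in feature_ids if f not in self.data.columns]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(feature_ids)].copy())

    def take_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.iloc[list(indices)].copy())


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/validation/test partition of sample indices."""

    test_idx: np.ndarray
    val_idx: np.ndarray
    train_idx: np.ndarray
    seed: int
    fractions: tuple[float, float]

    def __post_init__(self) -> None:
        parts = [np.asarray(p, dtype=int) for p in
                 (self.test_idx, self.val_idx, self.train_idx)]
        object.__setattr__(self, "test_idx", parts[0])
        object.__setattr__(self, "val_idx", parts[1])
        object.__setattr__(self, "train_idx", parts[2])
        combined = np.concatenate(parts)
        if len(np.unique(combined)) != len(combined):
            raise ValueError("split index sets are not pairwise disjoint")
        if not np.array_equal(np.sort(combined), np.arange(len(combined))):
            raise ValueError("split does not cover 0..N-1 exactly")

    @property
    def n_samples(self) -> int:
        return len(self.test_idx) + len(self.val_idx) + len(self.train_idx)

    def sizes(self) -> tuple[int, int, int]:
        """(test, validation, train) sizes."""
        return len(self.test_idx), len(self.val_idx), len(self.train_idx)


def split_samples(
    n_samples: int,
    test_frac: float = 0.2,
    val_frac: float = 0.2,
    seed: int = 0,
    labels: Sequence[str] | None = None,
    stratify: bool = False,
) -> DataSplit:
    """Randomly partition ``n_samples`` indices into test/validation/train.

    Sizes follow the ceiling convention: ``|test| = ceil(test_frac * N)``
    and ``|val| = ceil(val_frac * (N - |test|))``; the remainder trains.
    Membership is a uniform random permutation, deterministic per seed.
    Stratification by class label is available but off by default (the
    study design splits sample-wise without stratification).
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples to split")
    if not (0 < test_frac < 1 and 0 < val_frac < 1):
        raise ValueError("fractions must lie strictly in (0, 1)")

    n_test = math.ceil(test_frac * n_samples)
    n_val = math.ceil(val_frac * (n_samples - n_test))
    n_train = n_samples - n_test - n_val
    if min(n_test, n_val, n_train) < 1:
        raise ValueError(
            f"fractions ({test_frac}, {val_frac}) leave an empty set "
            f"for N={n_samples}"
        )

    if stratify:
        if labels is None:
            raise ValueError("stratify=True requires labels")
        labels = np.asarray(labels)
        if len(labels) != n_samples:
            raise ValueError("labels length must equal n_samples")
        rng = np.random.default_rng(seed)
        test_parts, val_parts, train_parts = [], [], []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            perm = rng.permutation(idx)
            k_t = math.ceil(test_frac * len(idx))
            k_v = math.ceil(val_frac * (len(idx) - k_t))
            test_parts.append(perm[:k_t])
            val_parts.append(perm[k_t:k_t + k_v])
            train_parts.append(perm[k_t + k_v:])
        return DataSplit(
            np.sort(np.concatenate(test_parts)),
            np.sort(np.concatenate(val_parts)),
            np.sort(np.concatenate(train_parts)),
            seed=seed,
            fractions=(test_frac, val_frac),
        )

    perm = np.random.default_rng(seed).permutation(n_samples)
    return DataSplit(
        np.sort(perm[:n_test]),
        np.sort(perm[n_test:n_test + n_val]),
        np.sort(perm[n_test + n_val:]),
        seed=seed,
        fractions=(test_frac, val_frac),
    )


# ---------------------------------------------------------------------------
# marker panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered biomarker list with per-feature frequency scores.

    ``entries`` is ordered by non-increasing frequency score with ties
    broken by ascending feature identifier; the frequency score is the
    fraction of resampling runs in which the feature was selected.
    ``stable_ids`` optionally flags the "final biomarker" subset that met
    the consistency threshold during stability selection.
    """

    entries: tuple[tuple[str, float], ...]
    provenance: str = ""
    stable_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        prev: tuple[float, str] | None = None
        for fid, score in self.entries:
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"frequency score out of [0,1] for {fid!r}: {score}")
            if fid in seen:
                raise ValueError(f"duplicate feature in panel: {fid!r}")
            seen.add(fid)
            key = (-score, fid)
            if prev is not None and key < prev:
                raise ValueError(
                    "panel entries must be ordered by non-increasing score, "
                    f"ties by ascending feature_id (violated at {fid!r})"
                )
            prev = key

    @classmethod
    def from_scores(
        cls,
        scores: dict[str, float] | pd.Series,
        provenance: str = "",
        stable_ids: Iterable[str] = (),
    ) -> "MarkerPanel":
        """Build a canonically ordered panel from a feature -> score mapping."""
        items = sorted(dict(scores).items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(tuple((f, float(s)) for f, s in items), provenance,
                   frozenset(stable_ids))

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries])

    def top(self, k: int) -> list[str]:
        """The first ``k`` ranked feature identifiers."""
        if not (1 <= k <= len(self.entries)):
            raise ValueError(f"k must be in 1..{len(self.entries)}, got {k}")
        return self.feature_ids[:k]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class IntersectionReport:
    """Outcome of matching a marker panel against a cohort's features."""

    n_matched: int
    missing: tuple[str, ...]

    @property
    def n_missing(self) -> int:
        return len(self.missing)


def intersect_markers(
    matrix: ExpressionMatrix, panel: MarkerPanel
) -> tuple[ExpressionMatrix, MarkerPanel, IntersectionReport]:
    """Restrict a cohort to the panel features it actually measures.

    External cohorts (different platform or annotation) typically expose
    only a subset of a panel's identifiers; this keeps the measurable
    subset in panel order, preserving frequency scores, and reports what
    was lost. Identifiers are matched as exact strings.
    """
    present = set(matrix.feature_ids)
    matched = [(f, s) for f, s in panel.entries if f in present]
    missing = tuple(f for f, _ in panel.entries if f not in present)
    if not matched:
        raise ValueError(
            "no panel feature is measured in this cohort; external "
            "validation is impossible without at least one shared marker"
        )
    matched_panel = MarkerPanel(
        tuple(matched),
        provenance=panel.provenance,
        stable_ids=panel.stable_ids & {f for f, _ in matched},
    )
    restricted = matrix.restrict_features([f for f, _ in matched])
    return restricted, matched_panel, IntersectionReport(len(matched), missing)


# ---------------------------------------------------------------------------
# file formats (all plain TSV)
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Parse an expression TSV: header ``sample_id\\t<feature ids...>``,
    then one row per sample. Values are returned exactly as printed —
    never normalized or transformed on read."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)

    def to_float(col: pd.Series) -> pd.Series:
        # python float() is correctly rounded; pandas' fast parser is not
        def one(v):
            try:
                return float(v)
            except (TypeError, ValueError):
                return np.nan
        return col.map(one, na_action="ignore")

    numeric = raw.apply(to_float)
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ExpressionParseError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at line {r + 2}, "
            f"column {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ExpressionParseError(
            f"{path}: missing value at line {r + 2}, column {raw.columns[c]!r}"
        )
    neg = numeric.to_numpy() < 0
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise ExpressionParseError(
            f"{path}: negative value at line {r + 2}, column {raw.columns[c]!r}"
        )
    try:
        return ExpressionMatrix(numeric)
    except ExpressionParseError as exc:
        raise ExpressionParseError(f"{path}: {exc}") from None


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "sample_id"
    # %.17g guarantees binary round-trip of every double
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_labels(path: str | Path) -> pd.Series:
    """Parse a labels TSV (columns sample_id, label) into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise ExpressionParseError(
            f"{path}: expected header 'sample_id\\tlabel', got {list(df.columns)}"
        )
    return pd.Series(df["label"].to_numpy(), index=df["sample_id"], name="label")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": labels.index, "label": labels.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    """Write a panel TSV with columns feature_id, frequency_score, rank."""
    df = pd.DataFrame(
        {
            "feature_id": panel.feature_ids,
            "frequency_score": [repr(float(s)) for s in panel.scores],
            "rank": np.arange(1, len(panel) + 1),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_marker_panel(path: str | Path, provenance: str = "") -> MarkerPanel:
    """Read a panel TSV, re-validating the ordering invariant."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str},
                     float_precision="round_trip")
    required = {"feature_id", "frequency_score"}
    if not required <= set(df.columns):
        raise ExpressionParseError(
            f"{path}: panel file must have columns {sorted(required)}"
        )
    entries = tuple(
        (str(f), float(s)) for f, s in zip(df["feature_id"], df["frequency_score"])
    )
    try:
        return MarkerPanel(entries, provenance=provenance)
    except ValueError as exc:
        raise ExpressionParseError(f"{path}: {exc}") from None
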