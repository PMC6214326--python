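"""Feature-table cleaning: imputation, normalization, correlation filtering.

The clustering pipeline consumes a numeric samples x features table. Raw
phenotype-style tables typically carry a small number of missing entries and
a handful of redundant (highly correlated) instrument scores; this module
fills the gaps (column-mean or cross-feature regression imputation), rescales
every feature to [0, 1] using known instrument score ranges where available,
and greedily drops one member of each feature pair whose absolute Pearson
correlation exceeds a threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "impute_mean",
    "impute_regression",
    "normalize_features",
    "correlation_filter",
    "read_table",
    "write_table",
]

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", "N/A")


@dataclass
class FeatureTable:
    """Numeric samples x features matrix with an explicit missingness mask.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float array. Entries flagged in
        ``missing_mask`` are placeholders and must never be interpreted.
    missing_mask
        Boolean array of the same shape; ``True`` marks a missing cell.
    feature_names
        Unique column identifiers.
    feature_ranges
        Optional per-feature ``(min, max)`` known score bounds used for
        normalization (e.g. instrument score ranges).
    sample_ids
        Optional row identifiers; defaults to ``"s0" .. "s{n-1}"``.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    feature_names: list[str]
    feature_ranges: dict[str, tuple[float, float]] | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("values and missing_mask must have identical shape")
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match number of columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must match number of rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def column(self, feature: str) -> int:
        try:
            return self.feature_names.index(feature)
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            feature_names=list(self.feature_names),
            feature_ranges=dict(self.feature_ranges) if self.feature_ranges else None,
            sample_ids=list(self.sample_ids),
        )

    def to_dataframe(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, columns=self.feature_names, index=self.sample_ids)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_ranges: Mapping[str, tuple[float, float]] | None = None,
    ) -> "FeatureTable":
        values = df.to_numpy(dtype=float)
        return cls(
            values=np.nan_to_num(values, nan=0.0),
            missing_mask=np.isnan(values),
            feature_names=[str(c) for c in df.columns],
            feature_ranges=dict(feature_ranges) if feature_ranges else None,
            sample_ids=[str(i) for i in df.index],
        )


def impute_mean(table: FeatureTable, feature: str) -> FeatureTable:
    """Replace missing entries of one column by the mean of its observed entries."""
    j = table.column(feature)
    out = table.copy()
    mask = out.missing_mask[:, j]
    if not mask.any():
        return out
    observed = out.values[~mask, j]
    if observed.size == 0:
        raise ValueError(f"feature {feature!r} has no observed values to impute from")
    out.values[mask, j] = observed.mean()
    out.missing_mask[:, j] = False
    return out


def impute_regression(
    table: FeatureTable, target_features: Sequence[str]
) -> FeatureTable:
    """Impute listed columns by ordinary least squares on all other features.

    For each target, a linear model with intercept is fit on the rows where the
    target is observed; gaps in predictor columns are mean-filled for the fit
    only. Predictions are clipped to the target's known score range when one is
    supplied. A rank-deficient design falls back to :func:`impute_mean`.
    """
    out = table.copy()
    for feature in target_features:
        j = out.column(feature)
        mask = out.missing_mask[:, j]
        if not mask.any():
            continue
        predictors = [i for i in range(out.n_features) if i != j]
        # mean-fill predictor gaps for the fit only
        P = out.values[:, predictors].copy()
        pm = out.missing_mask[:, predictors]
        for c in range(P.shape[1]):
            col_mask = pm[:, c]
            if col_mask.any():
                obs = P[~col_mask, c]
                P[col_mask, c] = obs.mean() if obs.size else 0.0
        fit_rows = ~mask
        design = np.column_stack([np.ones(fit_rows.sum()), P[fit_rows]])
        if (
            fit_rows.sum() < design.shape[1]
            or np.linalg.matrix_rank(design) < design.shape[1]
        ):
            logger.warning(
                "rank-deficient regression design for %r; falling back to mean "
                "imputation",
                feature,
            )
            out = impute_mean(out, feature)
            continue
        beta, *_ = np.linalg.lstsq(design, out.values[fit_rows, j], rcond=None)
        pred = np.column_stack([np.ones(mask.sum()), P[mask]]) @ beta
        if out.feature_ranges and feature in out.feature_ranges:
            lo, hi = out.feature_ranges[feature]
            pred = np.clip(pred, lo, hi)
        out.values[mask, j] = pred
        out.missing_mask[:, j] = False
    return out


def normalize_features(table: FeatureTable) -> FeatureTable:
    """Map every feature to [0, 1] by its known score range.

    Falls back (with a log message) to the observed min/max of a column when no
    range is supplied. A constant column maps to 0. A supplied range with
    ``max <= min`` is rejected.
    """
    if not table.is_complete():
        raise ValueError("normalize_features requires a complete table; impute first")
    out = table.copy()
    ranges = out.feature_ranges or {}
    new_ranges: dict[str, tuple[float, float]] = {}
    for j, name in enumerate(out.feature_names):
        col = out.values[:, j]
        if name in ranges:
            lo, hi = ranges[name]
            if hi <= lo:
                raise ValueError(f"invalid range for {name!r}: ({lo}, {hi})")
        else:
            lo, hi = float(col.min()), float(col.max())
            logger.info("no score range for %r; using observed (%g, %g)", name, lo, hi)
        if hi == lo:
            out.values[:, j] = 0.0
        else:
            out.values[:, j] = (col - lo) / (hi - lo)
        new_ranges[name] = (0.0, 1.0)
    out.feature_ranges = new_ranges
    return out


def _abs_corr(values: np.ndarray) -> np.ndarray:
    """|Pearson r| matrix with zero-variance columns contributing 0, zero diag."""
    d = values.shape[1]
    std = values.std(axis=0)
    degenerate = std == 0
    if degenerate.any():
        logger.warning(
            "zero-variance columns at positions %s; their correlations treated as 0",
            np.flatnonzero(degenerate).tolist(),
        )
    safe = values.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(safe, rowvar=False)
    corr = np.abs(np.nan_to_num(corr, nan=0.0))
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 0.0)
    return corr


def correlation_filter(
    table: FeatureTable, threshold: float = 0.8
) -> tuple[FeatureTable, list[str]]:
    """Iteratively drop one feature of every pair with ``|r| > threshold``.

    While any remaining pair exceeds the threshold, the most-correlated pair is
    located and the member with the larger mean absolute correlation to all
    remaining features is removed (ties broken toward the later column).
    Returns the reduced table and the removal list in order.
    """
    if not table.is_complete():
        raise ValueError("correlation_filter requires a complete table")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if table.n_features < 2:
        raise ValueError("need at least two features")
    keep = list(range(table.n_features))
    removed: list[str] = []
    while len(keep) >= 2:
        corr = _abs_corr(table.values[:, keep])
        iu = np.triu_indices(len(keep), k=1)
        if corr[iu].size == 0 or corr[iu].max() <= threshold:
            break
        flat = corr[iu]
        best = int(np.argmax(flat))  # argmax is first-in-order: earliest (i, j)
        i, j = int(iu[0][best]), int(iu[1][best])
        mean_i = corr[i].sum() / (len(keep) - 1)
        mean_j = corr[j].sum() / (len(keep) - 1)
        drop_local = j if mean_j >= mean_i else i  # tie -> later column
        removed.append(table.feature_names[keep[drop_local]])
        del keep[drop_local]
    kept_names = [table.feature_names[i] for i in keep]
    ranges = None
    if table.feature_ranges:
        ranges = {n: table.feature_ranges[n] for n in kept_names if n in table.feature_ranges}
    reduced = FeatureTable(
        values=table.values[:, keep].copy(),
        missing_mask=table.missing_mask[:, keep].copy(),
        feature_names=kept_names,
        feature_ranges=ranges,
        sample_ids=list(table.sample_ids),
    )
    return reduced, removed


def read_table(
    path: str | Path,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    ranges_path: str | Path | None = None,
    sep: str | None = None,
) -> FeatureTable:
    """Read a delimited text table (CSV/TSV inferred from suffix) into a FeatureTable.

    ``ranges_path`` may point to a JSON sidecar mapping feature name to
    ``[min, max]`` known score range.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(missing_tokens),
                     keep_default_na=False)
    ranges = None
    if ranges_path is not None:
        with open(ranges_path) as fh:
            raw = json.load(fh)
        ranges = {k: (float(v[0]), float(v[1])) for k, v in raw.items()}
    return FeatureTable.from_dataframe(df, feature_ranges=ranges)


def write_table(
    table: FeatureTable,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write a FeatureTable to CSV plus an optional JSON provenance sidecar."""
    path = Path(path)
    table.to_dataframe().to_csv(path, index_label="sample_id")
    if provenance is not None:
        with open(path.with_suffix(".provenance.json"), "w") as fh:
            json.dump(dict(provenance), fh, indent=2, default=str)
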