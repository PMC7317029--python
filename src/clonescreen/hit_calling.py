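"""Hit selection: per-category median +/- IQR rule over line mean scores.

A line is an enhancer in a category if its mean score lies strictly above
median + IQR of that category's distribution of line means, and a suppressor
if strictly below median - IQR.  Ties at a bound are not hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .score_db import LineScoreMatrix

QUANTILE_METHODS = ("linear", "lower", "higher", "nearest", "midpoint",
                    "inverted_cdf", "averaged_inverted_cdf",
                    "closest_observation", "interpolated_inverted_cdf",
                    "hazen", "weibull", "median_unbiased", "normal_unbiased")


@dataclass
class CategoryThresholds:
    category: str
    median: float
    iqr: float  # Q3 - Q1

    def __post_init__(self):
        if self.iqr < 0:
            raise InvalidArgumentError("IQR must be non-negative")

    @property
    def lower(self) -> float:
        return self.median - self.iqr

    @property
    def upper(self) -> float:
        return self.median + self.iqr


@dataclass
class HitTable:
    """Directional hit calls per (line, category) with audit thresholds."""

    calls: pd.DataFrame        # line_id, gene_id, category, mean, call
    thresholds: dict           # category -> CategoryThresholds
    line_to_gene: dict

    def counts(self) -> pd.DataFrame:
        """Per-category enhancer/suppressor counts and hit score ranges."""
        rows = []
        for cat, grp in self.calls.groupby("category", sort=True):
            enh = grp.loc[grp["call"] == "enhancer", "mean"]
            sup = grp.loc[grp["call"] == "suppressor", "mean"]
            th = self.thresholds[cat]
            rows.append({
                "category": cat,
                "n_enhancers": len(enh), "n_suppressors": len(sup),
                "enh_min": enh.min() if len(enh) else np.nan,
                "enh_max": enh.max() if len(enh) else np.nan,
                "sup_min": sup.min() if len(sup) else np.nan,
                "sup_max": sup.max() if len(sup) else np.nan,
                "median": th.median, "iqr": th.iqr,
                "lower": th.lower, "upper": th.upper,
            })
        return pd.DataFrame(rows)

    def hits(self, category: str, direction: str) -> pd.DataFrame:
        sel = self.calls[(self.calls["category"] == category)
                         & (self.calls["call"] == direction)]
        return sel.sort_values("mean", ascending=(direction == "suppressor"))

    def to_frame(self) -> pd.DataFrame:
        df = self.calls.copy()
        df["lower"] = df["category"].map(lambda c: self.thresholds[c].lower)
        df["upper"] = df["category"].map(lambda c: self.thresholds[c].upper)
        return df


def category_thresholds(matrix: LineScoreMatrix, category: str,
                        quantile_method: str = "linear") -> CategoryThresholds:
    """Median and IQR of a category's line means (lethal lines never appear
    in a LineScoreMatrix, so all rows enter the distribution)."""
    if category not in matrix.matrix.columns:
        raise InvalidArgumentError(f"unknown category: {category!r}")
    if quantile_method not in QUANTILE_METHODS:
        raise InvalidArgumentError(f"unknown quantile method: {quantile_method!r}")
    vals = matrix.matrix[category].to_numpy(dtype=float)
    if len(vals) < 4:
        raise InvalidArgumentError(
            f"category {category!r} has {len(vals)} lines; need >= 4")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method=quantile_method)
    return CategoryThresholds(category=category, median=float(med),
                              iqr=float(q3 - q1))


def call_hits(matrix: LineScoreMatrix, categories=None,
              quantile_method: str = "linear") -> HitTable:
    """Call enhancers/suppressors per category by the strict median+/-IQR rule."""
    if categories is None:
        categories = list(matrix.matrix.columns)
    thresholds = {}
    frames = []
    for cat in categories:
        th = category_thresholds(matrix, cat, quantile_method)
        thresholds[cat] = th
        means = matrix.matrix[cat]
        call = np.where(means > th.upper, "enhancer",
                        np.where(means < th.lower, "suppressor", "none"))
        frames.append(pd.DataFrame({
            "line_id": means.index,
            "gene_id": [matrix.line_to_gene[l] for l in means.index],
            "category": cat,
            "mean": means.to_numpy(dtype=float),
            "call": call,
        }))
    return HitTable(calls=pd.concat(frames, ignore_index=True),
                    thresholds=thresholds, line_to_gene=matrix.line_to_gene)


def combine_hits(hits: HitTable, categories, direction: str) -> pd.DataFrame:
    """Union of genes with the requested call in any listed category.

    Returns one row per gene with the set of categories in which it was called
    (kept for multi-color node annotation in the network stage).
    """
    categories = list(categories)
    if not categories:
        raise InvalidArgumentError("empty category list")
    if direction not in ("enhancer", "suppressor"):
        raise InvalidArgumentError(f"unknown direction: {direction!r}")
    missing = set(categories) - set(hits.calls["category"])
    if missing:
        raise InvalidArgumentError(f"categories absent from hit table: {sorted(missing)}")
    sel = hits.calls[(hits.calls["category"].isin(categories))
                     & (hits.calls["call"] == direction)]
    by_gene: dict[str, set] = {}
    for _, r in sel.iterrows():
        by_gene.setdefault(r["gene_id"], set()).add(r["category"])
    return pd.DataFrame(
        [{"gene_id": g, "categories": tuple(sorted(cs))}
         for g, cs in sorted(by_gene.items())]
    )
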