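"""Knockdown-vs-control differential expression filtering.

Input is a genes x samples matrix of log2 intensities plus a sample sheet
assigning each sample to a condition.  Per gene, a two-sided unequal-variance
t-test compares the knockdown samples with the pooled controls (or each
control separately), and the signed linear fold change is computed on
anti-logged group means.  The pass rule is raw ``p < p_thresh`` together with
``fc >= fc_thresh or fc <= -fc_thresh`` (inclusive bounds on |fc|); no
multiple-testing correction enters the rule, though BH q-values are emitted
for context.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .exceptions import InvalidArgumentError


def fold_change(mean_kd: float, mean_ctrl: float) -> float:
    """Signed linear fold change: r if r >= 1 else -1/r, r = kd/ctrl."""
    if mean_kd <= 0 or mean_ctrl <= 0:
        raise InvalidArgumentError("group means must be positive")
    r = mean_kd / mean_ctrl
    return r if r >= 1.0 else -1.0 / r


def de_test(expr: pd.DataFrame, groups, kd_label: str = "kd",
            per_control: bool = False) -> pd.DataFrame:
    """Per-gene Welch t-test of knockdown vs control samples on log2 values.

    Parameters
    ----------
    expr
        Genes x samples matrix of log2 intensities.
    groups
        Sequence of condition labels aligned with ``expr`` columns, or a
        sample sheet DataFrame with ``sample``/``condition`` columns.
    kd_label
        Condition treated as knockdown; all other conditions are controls.
    per_control
        If True, test against each control condition separately and report
        the worst (largest) p; default pools all control samples.

    Returns a DataFrame indexed by gene with ``mean_kd, mean_ctrl, fc, p, q``
    and a ``flag`` column ('zero-variance' where both groups are constant and
    equal, in which case p = 1).
    """
    if isinstance(groups, pd.DataFrame):
        lut = dict(zip(groups["sample"], groups["condition"]))
        labels = np.array([lut[c] for c in expr.columns])
    else:
        labels = np.asarray(list(groups))
        if len(labels) != expr.shape[1]:
            raise InvalidArgumentError("group labels do not match sample count")
    kd_mask = labels == kd_label
    if kd_mask.sum() < 2 or (~kd_mask).sum() < 2:
        raise InvalidArgumentError("need >= 2 samples per group")

    X = expr.to_numpy(dtype=float)
    kd = X[:, kd_mask]
    ctrl = X[:, ~kd_mask]

    if per_control:
        pvals = np.zeros(len(expr))
        for cond in np.unique(labels[~kd_mask]):
            sub = X[:, labels == cond]
            if sub.shape[1] < 2:
                raise InvalidArgumentError(
                    f"control condition {cond!r} has < 2 samples")
            p = stats.ttest_ind(kd, sub, axis=1, equal_var=False).pvalue
            pvals = np.maximum(pvals, np.nan_to_num(p, nan=1.0))
    else:
        pvals = stats.ttest_ind(kd, ctrl, axis=1, equal_var=False).pvalue

    zero_var = (kd.std(axis=1) == 0) & (ctrl.std(axis=1) == 0)
    equal_mean = np.isclose(kd.mean(axis=1), ctrl.mean(axis=1))
    degenerate = zero_var & equal_mean
    pvals = np.where(degenerate, 1.0, pvals)
    pvals = np.nan_to_num(pvals, nan=1.0)

    mean_kd = kd.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    ratio = np.exp2(mean_kd) / np.exp2(mean_ctrl)
    fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)

    return pd.DataFrame({
        "mean_kd": mean_kd, "mean_ctrl": mean_ctrl, "fc": fc,
        "p": pvals, "q": bh_adjust(pvals),
        "flag": np.where(degenerate, "zero-variance", ""),
    }, index=expr.index)


def de_filter(results: pd.DataFrame, p_thresh: float = 0.01,
              fc_thresh: float = 1.5) -> pd.DataFrame:
    """Genes passing ``p < p_thresh`` and ``|fc| >= fc_thresh`` (inclusive),
    sorted by |fc| descending; up/down counts in DataFrame attrs."""
    if len(results) == 0:
        return results.iloc[0:0].copy()
    passes = (results["p"] < p_thresh) & (results["fc"].abs() >= fc_thresh)
    out = results.loc[passes].copy()
    out = out.reindex(out["fc"].abs().sort_values(ascending=False).index)
    out.attrs["n_up"] = int((out["fc"] > 0).sum())
    out.attrs["n_down"] = int((out["fc"] < 0).sum())
    return out


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples log2 matrix TSV (gene ids in the first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_samples(path) -> pd.DataFrame:
    """Read a sample sheet TSV with ``sample`` and ``condition`` columns."""
    return pd.read_csv(path, sep="\t", dtype=str)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t")
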