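"""Quality control for the score database.

Three analyses: correlation of qualitative scores with matched quantitative
measurements, between-scorer agreement, and concordance of independent RNAi
line pairs targeting the same gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyInputError, InvalidArgumentError
from .score_db import LineScoreMatrix, ScoreTable


@dataclass
class ConcordanceReport:
    """Per-gene RNAi-pair concordance plus the overall fraction."""

    table: pd.DataFrame  # gene_id, line_a, line_b, rho, p, concordant, flag
    n_genes_two_lines: int
    n_concordant: int
    alpha: float

    @property
    def fraction(self) -> float:
        if self.n_genes_two_lines == 0:
            return float("nan")
        return self.n_concordant / self.n_genes_two_lines


def qual_quant_correlation(qual_means, quant_values) -> pd.DataFrame:
    """Per-category Spearman correlation of qualitative vs quantitative values.

    Both arguments are mappings ``category -> vector`` of matched per-animal
    values.  Ties are handled by midranks (scipy's default).
    """
    out = []
    for cat in qual_means:
        if cat not in quant_values:
            raise InvalidArgumentError(f"category {cat!r} missing from quant_values")
        x = np.asarray(qual_means[cat], dtype=float)
        y = np.asarray(quant_values[cat], dtype=float)
        if len(x) != len(y):
            raise InvalidArgumentError(
                f"length mismatch for category {cat!r}: {len(x)} vs {len(y)}")
        if len(x) < 3:
            raise InvalidArgumentError(
                f"category {cat!r} needs >= 3 paired values, got {len(x)}")
        rho, p = stats.spearmanr(x, y)
        out.append({"category": cat, "rho": rho, "p": p, "n": len(x)})
    return pd.DataFrame(out)


def scorer_agreement(table: ScoreTable) -> pd.DataFrame:
    """Spearman agreement between the two scorers, per category and overall.

    For each category, paired vectors are built over (line, animal) cells
    scored by both scorers; single-scorer cells are excluded and counted.
    The overall row pools all categories.
    """
    df = table.rows
    scorers = sorted(df["scorer_id"].unique())
    if len(scorers) < 2:
        raise EmptyInputError("need two scorers for agreement analysis")
    wide = df.pivot_table(index=["line_id", "animal_id", "category"],
                          columns="scorer_id", values="score")
    s1, s2 = scorers[0], scorers[1]
    paired = wide.dropna(subset=[s1, s2])
    n_excluded = len(wide) - len(paired)
    if len(paired) == 0:
        raise EmptyInputError("no doubly-scored cells")
    rows = []
    for cat, grp in paired.groupby(level="category", sort=True):
        if len(grp) < 3 or grp[s1].nunique() < 2 or grp[s2].nunique() < 2:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = stats.spearmanr(grp[s1], grp[s2])
        rows.append({"category": cat, "rho": rho, "p": p, "n_cells": len(grp),
                     "n_single_scorer": 0})
    rho_all, p_all = stats.spearmanr(paired[s1], paired[s2])
    rows.append({"category": "__overall__", "rho": rho_all, "p": p_all,
                 "n_cells": len(paired), "n_single_scorer": n_excluded})
    return pd.DataFrame(rows)


def _pair_concordance(a: np.ndarray, b: np.ndarray, n_perm: int, alpha: float,
                      rng: np.random.Generator):
    """Spearman rho and one-sided (positive) permutation p for one line pair."""
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan"), float("nan"), False, "degenerate"
    rho = stats.spearmanr(a, b).statistic
    perm_rhos = np.empty(n_perm)
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    for i in range(n_perm):
        perm_rhos[i] = np.corrcoef(ra, rng.permutation(rb))[0, 1]
    p = (1 + int(np.sum(perm_rhos >= rho))) / (n_perm + 1)
    return rho, p, bool(rho > 0 and p < alpha), ""


def rnai_pair_concordance(matrix: LineScoreMatrix, n_perm: int = 10_000,
                          alpha: float = 0.05, seed: int = 0) -> ConcordanceReport:
    """Concordance of category profiles between independent lines per gene.

    Concordant means significantly positively correlated profiles (Spearman
    rho > 0 with one-sided permutation p < ``alpha``, permuting category
    entries of one profile).  Genes with more than two lines contribute all
    unordered pairs (flagged); such a gene counts concordant if all its pairs
    do.  Constant (degenerate) profiles are non-concordant, never errors.
    """
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be >= 100")
    gene_lines: dict[str, list] = {}
    for line in matrix.matrix.index:
        gene_lines.setdefault(matrix.line_to_gene[line], []).append(line)
    multi = {g: sorted(ls) for g, ls in gene_lines.items() if len(ls) >= 2}
    if not multi:
        raise EmptyInputError("no gene is covered by two or more lines")
    rng = np.random.default_rng(seed)
    rows = []
    gene_ok: dict[str, bool] = {}
    for gene in sorted(multi):
        lines = multi[gene]
        flag_multi = ">2 lines" if len(lines) > 2 else ""
        ok_all = True
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                a = matrix.matrix.loc[lines[i]].to_numpy(dtype=float)
                b = matrix.matrix.loc[lines[j]].to_numpy(dtype=float)
                rho, p, conc, flag = _pair_concordance(a, b, n_perm, alpha, rng)
                ok_all &= conc
                rows.append({"gene_id": gene, "line_a": lines[i],
                             "line_b": lines[j], "rho": rho, "p": p,
                             "concordant": conc,
                             "flag": "; ".join(f for f in (flag, flag_multi) if f)})
        gene_ok[gene] = ok_all
    table = pd.DataFrame(rows)
    return ConcordanceReport(table=table, n_genes_two_lines=len(multi),
                             n_concordant=sum(gene_ok.values()), alpha=alpha)
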