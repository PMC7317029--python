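"""Data model, validation, I/O and aggregation for the phenotype score database.

The score database is long-form: one row per animal x RNAi line x scorer x
category, with an integer score on a small symmetric ordinal scale (default
-2..+2, 0 = indistinguishable from the sensitized baseline).  Lines whose
knockdown is lethal carry no score rows and are tracked separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import DEFAULT_CATEGORIES, validate_registry
from .exceptions import EmptyInputError, InvalidArgumentError, ValidationError

SCORE_COLUMNS = ["line_id", "gene_id", "animal_id", "scorer_id", "category", "score"]

#: Default ordinal scale (inclusive bounds).
DEFAULT_SCALE = (-2, 2)

#: Declared minimum number of animals per line (warn, do not fail, below it).
MIN_ANIMALS = 5


@dataclass
class ScoreTable:
    """Validated long-form score database.

    Parameters
    ----------
    rows
        DataFrame with columns ``line_id gene_id animal_id scorer_id category
        score``; one row per observation.
    lethal_lines
        Line ids whose knockdown was lethal; these must have no score rows.
    scale
        Inclusive ``(min_score, max_score)`` bounds of the ordinal scale.
    categories
        The category registry in force (default: the shipped 33-entry list).
    """

    rows: pd.DataFrame
    lethal_lines: set = field(default_factory=set)
    scale: tuple = DEFAULT_SCALE
    categories: tuple = DEFAULT_CATEGORIES

    def __post_init__(self):
        self.categories = validate_registry(self.categories)
        self.lethal_lines = set(self.lethal_lines)
        self.validate()

    def validate(self) -> None:
        lo, hi = self.scale
        if not (lo < 0 < hi):
            raise ValidationError(f"scale must straddle 0, got {self.scale}")
        df = self.rows
        missing = [c for c in SCORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"score table missing columns: {missing}")
        bad = df.index[(df["score"] < lo) | (df["score"] > hi)]
        if len(bad):
            r = df.loc[bad[0]]
            raise ValidationError(
                f"score {r['score']} out of range [{lo},{hi}] at row {bad[0]} "
                f"(line {r['line_id']}, category {r['category']!r})"
            )
        dup = df.duplicated(subset=["line_id", "animal_id", "scorer_id", "category"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            r = df.iloc[i]
            raise ValidationError(
                f"duplicate (line, animal, scorer, category) key at row {df.index[i]}: "
                f"({r['line_id']}, {r['animal_id']}, {r['scorer_id']}, {r['category']!r})"
            )
        unknown = set(df["category"]) - set(self.categories)
        if unknown:
            raise ValidationError(f"categories not in registry: {sorted(unknown)}")
        scored_lethals = set(df["line_id"]) & self.lethal_lines
        if scored_lethals:
            raise ValidationError(
                f"lethal lines have score rows: {sorted(scored_lethals)[:5]}"
            )
        # each line maps to exactly one gene
        n_genes = df.groupby("line_id")["gene_id"].nunique()
        multi = n_genes[n_genes > 1]
        if len(multi):
            raise ValidationError(
                f"line(s) mapped to more than one gene: {list(multi.index[:5])}"
            )

    @property
    def line_to_gene(self) -> dict:
        return dict(
            self.rows.drop_duplicates("line_id").set_index("line_id")["gene_id"]
        )

    def animals_per_line(self) -> pd.Series:
        """Number of distinct animals scored per line."""
        return self.rows.groupby("line_id")["animal_id"].nunique()

    def line_ids(self) -> list:
        return sorted(set(self.rows["line_id"]))


@dataclass
class LineScoreMatrix:
    """Mean score per (RNAi line x category).

    ``matrix`` rows are lines, columns are the categories of the registry in
    order.  Cells with no observations are 0-filled and recorded in ``filled``.
    """

    matrix: pd.DataFrame
    line_to_gene: dict
    n_animals: pd.Series
    scale: tuple = DEFAULT_SCALE
    filled: pd.DataFrame | None = None  # boolean mask: True where 0-filled

    def __post_init__(self):
        lo, hi = self.scale
        vals = self.matrix.to_numpy(dtype=float)
        if np.any((vals < lo) | (vals > hi)):
            raise ValidationError("matrix values outside ordinal scale bounds")
        unmapped = set(self.matrix.index) - set(self.line_to_gene)
        if unmapped:
            raise ValidationError(f"lines without a gene mapping: {sorted(unmapped)[:5]}")
        low = self.n_animals[self.n_animals < MIN_ANIMALS]
        if len(low):
            warnings.warn(
                f"{len(low)} line(s) below the declared minimum of "
                f"{MIN_ANIMALS} animals",
                stacklevel=2,
            )

    @property
    def genes(self) -> list:
        return sorted(set(self.line_to_gene.values()))


def read_scores(path, scale=DEFAULT_SCALE, categories=None) -> ScoreTable:
    """Read a score TSV (columns ``line_id gene_id animal_id scorer_id category
    score lethal``) into a validated :class:`ScoreTable`.

    Lethal lines are rows with ``lethal`` true; such rows carry no score (the
    score field is ignored) and serve only to register the line.
    """
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "gene_id": str,
                                            "animal_id": str, "scorer_id": str})
    if "lethal" in df.columns:
        lethal_mask = df["lethal"].astype(str).str.lower().isin(["1", "true", "yes"])
        lethal_lines = set(df.loc[lethal_mask, "line_id"])
        df = df.loc[~lethal_mask].drop(columns=["lethal"])
    else:
        lethal_lines = set()
    df["score"] = pd.to_numeric(df["score"])
    if categories is None:
        categories = DEFAULT_CATEGORIES
        extra = set(df["category"]) - set(categories)
        if extra:  # user table with its own registry
            categories = tuple(categories) + tuple(sorted(extra))
    return ScoreTable(df.reset_index(drop=True), lethal_lines=lethal_lines,
                      scale=scale, categories=categories)


def write_scores(table: ScoreTable, path) -> None:
    """Write a :class:`ScoreTable` to TSV (round-trips with :func:`read_scores`)."""
    df = table.rows.copy()
    df["lethal"] = False
    if table.lethal_lines:
        gene_of = table.line_to_gene
        lethal = pd.DataFrame({
            "line_id": sorted(table.lethal_lines),
            "gene_id": [gene_of.get(l, "NA") for l in sorted(table.lethal_lines)],
            "animal_id": "NA", "scorer_id": "NA",
            "category": table.categories[0], "score": 0, "lethal": True,
        })
        df = pd.concat([df, lethal], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)


def aggregate(table: ScoreTable) -> LineScoreMatrix:
    """Mean score per (line, category), pooling animals and scorers equally.

    Missing (line, category) combinations are 0-filled (no phenotype change)
    and flagged in the returned object's ``filled`` mask.
    """
    if len(table.rows) == 0:
        raise EmptyInputError("score table has no rows")
    piv = table.rows.pivot_table(index="line_id", columns="category",
                                 values="score", aggfunc="mean")
    cats_present = [c for c in table.categories]
    piv = piv.reindex(columns=cats_present)
    filled = piv.isna()
    piv = piv.fillna(0.0)
    piv = piv.sort_index()
    filled = filled.sort_index()
    return LineScoreMatrix(
        matrix=piv,
        line_to_gene=table.line_to_gene,
        n_animals=table.animals_per_line().reindex(piv.index),
        scale=table.scale,
        filled=filled,
    )


def gene_level(matrix: LineScoreMatrix, rule: str = "mean") -> pd.DataFrame:
    """Roll line-level means up to one row per gene.

    ``mean`` averages a gene's lines per category; ``best-line`` takes, per
    category, the value of largest absolute magnitude among the gene's lines.
    """
    if rule not in ("mean", "best-line"):
        raise InvalidArgumentError(f"unknown gene_level rule: {rule!r}")
    genes = pd.Series({l: matrix.line_to_gene[l] for l in matrix.matrix.index})
    if rule == "mean":
        return matrix.matrix.groupby(genes).mean().sort_index()

    def best(col: pd.Series) -> pd.Series:
        idx = col.abs().groupby(genes).idxmax()
        return pd.Series(col.loc[idx].to_numpy(), index=idx.index)

    out = pd.DataFrame({c: best(matrix.matrix[c]) for c in matrix.matrix.columns})
    out.index.name = "gene_id"
    return out.sort_index()


def read_matrix(path) -> pd.DataFrame:
    """Read a line x category matrix TSV (lines as rows)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: LineScoreMatrix | pd.DataFrame, path) -> None:
    df = matrix.matrix if isinstance(matrix, LineScoreMatrix) else matrix
    df.to_csv(path, sep="\t")


def read_line_map(path) -> tuple[dict, set]:
    """Read a line->gene map TSV with columns ``line_id gene_id [lethal]``.

    Returns (line_to_gene, lethal_lines).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    lethal = set()
    if "lethal" in df.columns:
        mask = df["lethal"].astype(str).str.lower().isin(["1", "true", "yes"])
        lethal = set(df.loc[mask, "line_id"])
    return dict(zip(df["line_id"], df["gene_id"])), lethal
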