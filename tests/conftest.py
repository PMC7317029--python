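import numpy as np
import pandas as pd
import pytest

from clonescreen import score_db as sdb
from clonescreen import synthetic


def make_score_rows(entries):
    """entries: (line, gene, animal, scorer, category, score) tuples."""
    return pd.DataFrame(entries, columns=sdb.SCORE_COLUMNS)


@pytest.fixture
def two_line_table():
    """Two lines of one gene plus one single-line gene, one animal, two scorers."""
    rows = []
    for line, gene in [("L1", "gA"), ("L2", "gA"), ("L3", "gB")]:
        for scorer in ("scorer1", "scorer2"):
            for cat, score in [("invasion", 1), ("multilayering", 0)]:
                rows.append((line, gene, f"{line}-an1", scorer, cat, score))
    return sdb.ScoreTable(make_score_rows(rows))


@pytest.fixture(scope="session")
def synth_screen():
    """Medium synthetic screen shared by recovery tests (planted effects 1.2)."""
    table, truth = synthetic.gen_score_db(
        n_genes=120, frac_two_lines=0.5, n_categories=10, n_animals=5,
        effect_size=1.2, scorer_sd=0.3, seed=11, frac_hits=0.1)
    return table, truth


@pytest.fixture(scope="session")
def synth_matrix(synth_screen):
    table, _ = synth_screen
    return sdb.aggregate(table)


def line_matrix(values, categories=None, genes=None, scale=(-2, 2)):
    """Build a LineScoreMatrix from a 2-D array of line x category means."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    lines = [f"L{i}" for i in range(1, n + 1)]
    cats = categories or [f"cat{j}" for j in range(1, m + 1)]
    gene_map = genes or {l: f"g{l}" for l in lines}
    df = pd.DataFrame(values, index=lines, columns=cats)
    return sdb.LineScoreMatrix(matrix=df, line_to_gene=gene_map,
                               n_animals=pd.Series(5, index=lines),
                               scale=scale)
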