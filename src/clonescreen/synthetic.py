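"""Seeded generators for every input the pipeline consumes, with known truth.

All generators take an explicit integer seed and use a local
``numpy.random.Generator``; no global RNG state is touched, so identical seeds
give byte-identical outputs.

Models
------
Score database
    A continuous Gaussian latent score per animal (planted gene effect plus
    animal-level noise), observed independently by each scorer with additional
    scorer noise, then rounded and clipped to the ordinal scale.
Tracks
    Persistent random walk: the step direction is a convex blend of the
    previous direction and a fresh uniform random unit vector, weighted by the
    persistence parameter; persistence 1 is an exactly straight line,
    persistence 0 an uncorrelated random walk.
Interactome
    Vertex-disjoint dense complexes planted among hit genes, linker genes
    wired to >=2 hits, and independent background edges.
Expression
    Gene-level log2 intensities around a Gaussian baseline; planted genes are
    shifted by log2(fc) with random sign in the knockdown group.  Two control
    conditions ("unt", "nonT") are emitted to mirror the pooled-control
    contrast used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import DEFAULT_CATEGORIES
from .exceptions import InvalidArgumentError
from .score_db import DEFAULT_SCALE, ScoreTable

EDGE_TYPES = ("genetic", "physical", "interolog")


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass
class ScreenTruth:
    """Ground truth for a generated score database."""

    gene_effects: dict  # gene -> {category: signed effect on latent scale}
    lethal_genes: set
    pair_map: dict      # gene -> [line ids]
    seed: int

    def __post_init__(self):
        lines = [l for ls in self.pair_map.values() for l in ls]
        if len(lines) != len(set(lines)):
            raise InvalidArgumentError("line ids shared between genes")
        for g, effs in self.gene_effects.items():
            for c, e in effs.items():
                if not math.isfinite(e):
                    raise InvalidArgumentError(f"non-finite effect for {g}/{c}")

    def planted(self, direction: str | None = None) -> set:
        """Genes planted with any effect (optionally 'enhancer'/'suppressor')."""
        out = set()
        for g, effs in self.gene_effects.items():
            for e in effs.values():
                if direction is None or \
                        (direction == "enhancer" and e > 0) or \
                        (direction == "suppressor" and e < 0):
                    out.add(g)
        return out


@dataclass
class TrackTruth:
    track_id: str
    directional: bool
    n_spots: int
    speed_um_min: float


@dataclass
class InteractomeTruth:
    complexes: list            # list of frozenset of hit genes
    linkers: set
    background_nodes: set
    seed: int


@dataclass
class ExpressionTruth:
    de_signs: dict = field(default_factory=dict)  # gene -> +1/-1
    seed: int = 0

    @property
    def de_genes(self) -> set:
        return set(self.de_signs)


# ---------------------------------------------------------------------------
# Score database
# ---------------------------------------------------------------------------

def _category_names(n_categories: int) -> tuple:
    if n_categories <= len(DEFAULT_CATEGORIES):
        return DEFAULT_CATEGORIES[:n_categories]
    extra = tuple(f"category {i:02d}" for i in range(len(DEFAULT_CATEGORIES) + 1,
                                                     n_categories + 1))
    return DEFAULT_CATEGORIES + extra


def gen_score_db(
    n_genes: int,
    frac_two_lines: float,
    n_categories: int,
    n_animals: int,
    effect_size: float,
    scorer_sd: float,
    seed: int,
    *,
    animal_sd: float = 0.0,
    frac_hits: float = 0.1,
    n_hit_categories: int = 1,
    frac_lethal: float = 0.0,
    scale: tuple = DEFAULT_SCALE,
) -> tuple[ScoreTable, ScreenTruth]:
    """Generate a blinded two-scorer score database with planted hit effects.

    ``round(frac_hits * n_genes)`` genes are planted with an effect of
    ``+/-effect_size`` (random sign per category) in ``n_hit_categories``
    distinct randomly chosen categories each; both RNAi lines of a gene share
    its effects.
    """
    if n_genes < 1 or n_categories < 1 or n_animals < 1:
        raise InvalidArgumentError("counts must be positive")
    if not (0.0 <= frac_two_lines <= 1.0):
        raise InvalidArgumentError("frac_two_lines must lie in [0, 1]")
    if scorer_sd < 0 or animal_sd < 0:
        raise InvalidArgumentError("noise SDs must be non-negative")
    rng = np.random.default_rng(seed)
    cats = _category_names(n_categories)
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]

    n_two = int(round(frac_two_lines * n_genes))
    two_line_genes = set(rng.choice(genes, size=n_two, replace=False))
    pair_map = {}
    for g in genes:
        pair_map[g] = [f"{g}-a", f"{g}-b"] if g in two_line_genes else [f"{g}-a"]

    n_lethal = int(round(frac_lethal * n_genes))
    lethal_genes = set(rng.choice(genes, size=n_lethal, replace=False)) \
        if n_lethal else set()
    scored_genes = [g for g in genes if g not in lethal_genes]

    n_planted = int(round(frac_hits * len(scored_genes)))
    planted_genes = rng.choice(scored_genes, size=n_planted, replace=False) \
        if n_planted else np.array([], dtype=object)
    if not (1 <= n_hit_categories <= n_categories):
        raise InvalidArgumentError("n_hit_categories out of range")
    gene_effects: dict = {}
    for g in planted_genes:
        chosen = rng.choice(n_categories, size=n_hit_categories, replace=False)
        gene_effects[g] = {
            cats[int(ci)]: (1.0 if rng.random() < 0.5 else -1.0) * effect_size
            for ci in sorted(chosen)}

    lo, hi = scale
    records = {k: [] for k in
               ("line_id", "gene_id", "animal_id", "scorer_id", "category", "score")}
    cat_idx = {c: i for i, c in enumerate(cats)}
    for g in scored_genes:
        eff = np.zeros(n_categories)
        for c, e in gene_effects.get(g, {}).items():
            eff[cat_idx[c]] = e
        for line in pair_map[g]:
            # animal latent per (animal, category)
            latent = eff[None, :] + rng.normal(0.0, animal_sd,
                                               size=(n_animals, n_categories)) \
                if animal_sd > 0 else np.broadcast_to(eff, (n_animals, n_categories))
            for s, scorer in enumerate(("scorer1", "scorer2")):
                obs = latent + rng.normal(0.0, scorer_sd,
                                          size=(n_animals, n_categories)) \
                    if scorer_sd > 0 else latent
                obs = np.clip(np.rint(obs), lo, hi).astype(int)
                for a in range(n_animals):
                    records["line_id"].extend([line] * n_categories)
                    records["gene_id"].extend([g] * n_categories)
                    records["animal_id"].extend([f"{line}-an{a + 1}"] * n_categories)
                    records["scorer_id"].extend([scorer] * n_categories)
                    records["category"].extend(cats)
                    records["score"].extend(obs[a].tolist())

    rows = pd.DataFrame(records)
    lethal_lines = {l for g in lethal_genes for l in pair_map[g]}
    table = ScoreTable(rows, lethal_lines=lethal_lines, scale=scale, categories=cats)
    truth = ScreenTruth(gene_effects=gene_effects, lethal_genes=lethal_genes,
                        pair_map=pair_map, seed=seed)
    return table, truth


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def gen_tracks(
    n_directional: int,
    n_random: int,
    dt_min: float = 3.0,
    duration_min: float = 30.0,
    speed_um_min: float = 1.0,
    persistence: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[TrackTruth]]:
    """Simulate directional (persistent) and random 3-D cell tracks.

    Returns a long-form DataFrame with columns ``track_id, genotype, t_min,
    x_um, y_um, z_um, n_actin_spots`` (11 time points for the default 3-min
    sampling over 30 min) and the per-track truth list.
    """
    if speed_um_min < 0:
        raise InvalidArgumentError("speed must be non-negative")
    if not (0.0 <= persistence <= 1.0):
        raise InvalidArgumentError("persistence must lie in [0, 1]")
    if dt_min <= 0 or duration_min <= 0:
        raise InvalidArgumentError("dt and duration must be positive")
    n_steps = duration_min / dt_min
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise InvalidArgumentError("duration must be divisible by dt")
    n_steps = int(round(n_steps))
    rng = np.random.default_rng(seed)

    frames = []
    truths = []
    specs = [("directional", persistence, 3)] * n_directional + \
            [("random", 0.0, 1)] * n_random
    for i, (genotype, p, n_spots) in enumerate(specs):
        tid = f"{genotype[:3]}{i + 1:04d}"
        d = _random_unit(rng)
        pos = np.zeros((n_steps + 1, 3))
        step = speed_um_min * dt_min
        for t in range(1, n_steps + 1):
            if p < 1.0:
                blended = p * d + (1.0 - p) * _random_unit(rng)
                nrm = np.linalg.norm(blended)
                d = blended / nrm if nrm > 1e-12 else _random_unit(rng)
            pos[t] = pos[t - 1] + step * d
        frames.append(pd.DataFrame({
            "track_id": tid,
            "genotype": genotype,
            "t_min": np.arange(n_steps + 1) * dt_min,
            "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
            "n_actin_spots": n_spots,
        }))
        truths.append(TrackTruth(tid, genotype == "directional", n_spots,
                                 speed_um_min))
    cols = ["track_id", "genotype", "t_min", "x_um", "y_um", "z_um",
            "n_actin_spots"]
    if not frames:
        return pd.DataFrame(columns=cols), []
    return pd.concat(frames, ignore_index=True), truths


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

def gen_interactome(
    hit_genes,
    lethal_genes,
    background_genes: int,
    planted_complexes,
    p_background: float,
    n_linkers: int,
    seed: int,
) -> tuple[pd.DataFrame, InteractomeTruth]:
    """Generate a typed interaction edge table with planted dense complexes.

    Planted complexes are vertex-disjoint subgraphs among hit genes meeting at
    least the requested density; linkers are fresh non-hit genes wired to two
    distinct hits; background edges are Bernoulli(p_background) over all other
    node pairs (linkers excluded, to keep their degree structure exact).
    """
    hit_genes = sorted(set(hit_genes))
    lethal_genes = sorted(set(lethal_genes))
    if set(hit_genes) & set(lethal_genes):
        raise InvalidArgumentError("hit and lethal sets overlap")
    if not (0.0 <= p_background <= 1.0):
        raise InvalidArgumentError("p_background must lie in [0, 1]")
    total_planted = sum(s for s, _ in planted_complexes)
    if total_planted > len(hit_genes):
        raise InvalidArgumentError(
            f"planted complex sizes ({total_planted}) exceed hit genes "
            f"({len(hit_genes)})")
    for size, density in planted_complexes:
        if size < 3:
            raise InvalidArgumentError("planted complex size must be >= 3")
        if not (0.0 < density <= 1.0):
            raise InvalidArgumentError("planted density must lie in (0, 1]")
    if n_linkers < 0 or background_genes < 0:
        raise InvalidArgumentError("counts must be non-negative")

    rng = np.random.default_rng(seed)
    edges: dict[tuple, tuple] = {}  # (a,b) sorted -> (type, source)

    def add_edge(a, b, source):
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        if key not in edges:
            edges[key] = (EDGE_TYPES[int(rng.integers(3))], source)

    # planted complexes: disjoint random hit subsets
    pool = list(rng.permutation(hit_genes))
    complexes = []
    for size, density in planted_complexes:
        members = sorted(pool[:size])
        pool = pool[size:]
        pairs = [(members[i], members[j])
                 for i in range(size) for j in range(i + 1, size)]
        if density >= 1.0:
            chosen = pairs
        else:
            m = max(size - 1, math.ceil(density * len(pairs)))
            idx = rng.choice(len(pairs), size=m, replace=False)
            chosen = [pairs[k] for k in idx]
        for a, b in chosen:
            add_edge(a, b, "planted")
        complexes.append(frozenset(members))

    # linkers
    linkers = set()
    for i in range(n_linkers):
        name = f"linker{i + 1:03d}"
        linkers.add(name)
        anchors = rng.choice(hit_genes, size=2, replace=False)
        for h in anchors:
            add_edge(name, h, "linker")

    # background
    bg_nodes = {f"bg{i + 1:04d}" for i in range(background_genes)}
    if p_background > 0:
        nodes = sorted(set(hit_genes) | set(lethal_genes) | bg_nodes)
        n = len(nodes)
        iu = np.triu_indices(n, k=1)
        mask = rng.random(len(iu[0])) < p_background
        for a_i, b_i in zip(iu[0][mask], iu[1][mask]):
            add_edge(nodes[a_i], nodes[b_i], "background")

    df = pd.DataFrame(
        [(a, b, t, s) for (a, b), (t, s) in sorted(edges.items())],
        columns=["gene_a", "gene_b", "type", "source"],
    )
    truth = InteractomeTruth(complexes=complexes, linkers=linkers,
                             background_nodes=bg_nodes, seed=seed)
    return df, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gen_expression(
    n_genes: int,
    n_per_group: int,
    n_de: int,
    fc: float,
    sd_log2: float,
    seed: int,
    *,
    base_mean: float = 7.0,
    base_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Generate a log2 expression matrix with planted fold changes.

    Emits one knockdown condition (``kd``) and two control conditions
    (``unt``, ``nonT``) of ``n_per_group`` samples each.  Planted genes are
    shifted by ``log2(fc)`` with a random sign in the knockdown samples.

    Returns ``(expr, sample_sheet, truth)`` where ``expr`` is genes x samples
    and ``sample_sheet`` has columns ``sample, condition``.
    """
    if n_per_group < 2:
        raise InvalidArgumentError("n_per_group must be >= 2 (variance undefined)")
    if n_de > n_genes or n_de < 0:
        raise InvalidArgumentError("n_de must lie in [0, n_genes]")
    if fc < 1.0:
        raise InvalidArgumentError("fc must be >= 1")
    if sd_log2 < 0:
        raise InvalidArgumentError("sd_log2 must be non-negative")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(1, n_genes + 1)]
    conditions = (["kd"] * n_per_group + ["unt"] * n_per_group
                  + ["nonT"] * n_per_group)
    samples = [f"{c}_{i % n_per_group + 1}" for i, c in enumerate(conditions)]
    baseline = rng.normal(base_mean, base_sd, size=n_genes)
    vals = baseline[:, None] + rng.normal(0.0, sd_log2,
                                          size=(n_genes, len(samples)))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else \
        np.array([], dtype=int)
    signs = np.where(rng.random(n_de) < 0.5, -1.0, 1.0)
    shift = math.log2(fc)
    for idx, sign in zip(de_idx, signs):
        vals[idx, :n_per_group] += sign * shift
    expr = pd.DataFrame(vals, index=pd.Index(genes, name="gene_id"),
                        columns=samples)
    sheet = pd.DataFrame({"sample": samples, "condition": conditions})
    truth = ExpressionTruth(
        de_signs={genes[i]: int(s) for i, s in zip(de_idx, signs)}, seed=seed)
    return expr, sheet, truth
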