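import numpy as np
import pandas as pd
import pytest

from clonescreen import score_db as sdb
from clonescreen import synthetic, tracks as trk
from clonescreen.exceptions import InvalidArgumentError


class TestGenScoreDb:
    def test_screen_scale_line_counts(self):
        table, truth = synthetic.gen_score_db(
            n_genes=497, frac_two_lines=256 / 497, n_categories=33,
            n_animals=5, effect_size=1.0, scorer_sd=0.2, seed=0)
        n_lines = sum(len(v) for v in truth.pair_map.values())
        assert n_lines == 497 + 256 == 753
        # every scored line has 5 animals x 2 scorers
        per_line = table.rows.groupby("line_id").apply(
            lambda g: (g["animal_id"].nunique(), g["scorer_id"].nunique()),
            include_groups=False)
        assert all(v == (5, 2) for v in per_line)

    def test_no_signal_no_noise_zero(self):
        table, _ = synthetic.gen_score_db(20, 0.5, 4, 2, 0.0, 0.0, seed=1,
                                          frac_hits=0.0)
        assert (table.rows["score"] == 0).all()

    def test_seed_determinism(self):
        a, _ = synthetic.gen_score_db(30, 0.5, 5, 3, 1.0, 0.3, seed=5)
        b, _ = synthetic.gen_score_db(30, 0.5, 5, 3, 1.0, 0.3, seed=5)
        c, _ = synthetic.gen_score_db(30, 0.5, 5, 3, 1.0, 0.3, seed=6)
        pd.testing.assert_frame_equal(a.rows, b.rows)
        assert not a.rows.equals(c.rows)

    def test_two_lines_share_effect(self):
        _, truth = synthetic.gen_score_db(40, 1.0, 6, 3, 1.5, 0.1, seed=2,
                                          frac_hits=0.5)
        for g, lines in truth.pair_map.items():
            assert len(lines) == 2  # frac_two_lines = 1
        assert truth.planted() == set(truth.gene_effects)

    def test_lethal_genes_have_no_scores(self):
        table, truth = synthetic.gen_score_db(40, 0.5, 4, 2, 1.0, 0.2, seed=3,
                                              frac_lethal=0.25)
        assert len(truth.lethal_genes) == 10
        scored_genes = set(table.rows["gene_id"])
        assert scored_genes.isdisjoint(truth.lethal_genes)
        assert table.lethal_lines == {
            l for g in truth.lethal_genes for l in truth.pair_map[g]}

    def test_invalid_args(self):
        with pytest.raises(InvalidArgumentError):
            synthetic.gen_score_db(0, 0.5, 4, 2, 1.0, 0.2, seed=0)
        with pytest.raises(InvalidArgumentError):
            synthetic.gen_score_db(10, 1.5, 4, 2, 1.0, 0.2, seed=0)
        with pytest.raises(InvalidArgumentError):
            synthetic.gen_score_db(10, 0.5, 4, 0, 1.0, 0.2, seed=0)

    def test_generated_table_passes_validation(self):
        # construction-time ScoreTable validation doubles as the invariant
        table, _ = synthetic.gen_score_db(25, 0.4, 33, 5, 1.2, 0.3, seed=9)
        table.validate()
        m = sdb.aggregate(table)
        assert m.matrix.shape[1] == 33


class TestGenTracks:
    def test_point_count(self):
        df, truths = synthetic.gen_tracks(3, 2, dt_min=3, duration_min=30,
                                          seed=0)
        for _, grp in df.groupby("track_id"):
            assert len(grp) == 11
        assert sum(t.directional for t in truths) == 3

    def test_persistence_one_straight(self):
        df, _ = synthetic.gen_tracks(5, 0, 3, 30, 1.0, persistence=1.0, seed=1)
        for t in trk.tracks_from_frame(df):
            assert trk.track_stats(t).straightness == 1.0

    def test_monte_carlo_straightness_ordering(self):
        def mean_straightness(p, n, seed):
            df, _ = synthetic.gen_tracks(n, 0, 3, 30, 1.0, p, seed)
            return np.mean([trk.track_stats(t).straightness
                            for t in trk.tracks_from_frame(df)])
        s0 = mean_straightness(0.0, 800, 2)
        s9 = mean_straightness(0.9, 800, 2)
        assert s0 < s9

    def test_duration_divisibility(self):
        with pytest.raises(InvalidArgumentError):
            synthetic.gen_tracks(1, 1, dt_min=4, duration_min=30)

    def test_negative_speed(self):
        with pytest.raises(InvalidArgumentError):
            synthetic.gen_tracks(1, 1, speed_um_min=-1.0)

    def test_determinism(self):
        a, _ = synthetic.gen_tracks(4, 4, seed=7)
        b, _ = synthetic.gen_tracks(4, 4, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestGenInteractome:
    def test_five_clique_exact(self):
        edges, truth = synthetic.gen_interactome(
            [f"h{i}" for i in range(8)], set(), 0,
            planted_complexes=[(5, 1.0)], p_background=0.0, n_linkers=0,
            seed=0)
        assert len(edges) == 10
        members = truth.complexes[0]
        got = {frozenset((a, b)) for a, b in zip(edges["gene_a"],
                                                 edges["gene_b"])}
        expect = {frozenset((a, b)) for a in members for b in members if a < b}
        assert got == expect

    def test_linkers_degree_two_into_hits(self):
        hits = [f"h{i}" for i in range(6)]
        edges, truth = synthetic.gen_interactome(
            hits, set(), 0, planted_complexes=[], p_background=0.0,
            n_linkers=3, seed=1)
        assert len(truth.linkers) == 3
        non_hits = set(edges["gene_a"]) | set(edges["gene_b"]) - set(hits)
        for linker in truth.linkers:
            deg = ((edges["gene_a"] == linker) | (edges["gene_b"] == linker)).sum()
            assert deg >= 2

    def test_size_exceeding_hits_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synthetic.gen_interactome(["h1", "h2", "h3"], set(), 0,
                                      [(4, 1.0)], 0.0, 0, seed=0)

    def test_density_at_least_requested(self):
        edges, truth = synthetic.gen_interactome(
            [f"h{i}" for i in range(12)], set(), 0,
            planted_complexes=[(6, 0.6)], p_background=0.0, n_linkers=0,
            seed=2)
        members = truth.complexes[0]
        n_pairs = 6 * 5 // 2
        assert len(edges) >= np.ceil(0.6 * n_pairs)

    def test_edge_types_from_registry(self):
        edges, _ = synthetic.gen_interactome(
            [f"h{i}" for i in range(10)], {"let1"}, 5, [(4, 1.0)], 0.3, 2,
            seed=3)
        assert set(edges["type"]) <= set(synthetic.EDGE_TYPES)

    def test_determinism(self):
        a, _ = synthetic.gen_interactome([f"h{i}" for i in range(10)], set(),
                                         5, [(4, 1.0)], 0.2, 2, seed=4)
        b, _ = synthetic.gen_interactome([f"h{i}" for i in range(10)], set(),
                                         5, [(4, 1.0)], 0.2, 2, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestGenExpression:
    def test_no_de_empty_truth(self):
        _, _, truth = synthetic.gen_expression(50, 2, 0, 2.0, 0.2, seed=0)
        assert truth.de_genes == set()

    def test_fc_one_no_shift(self):
        expr1, _, t1 = synthetic.gen_expression(50, 3, 5, 1.0, 0.2, seed=1)
        assert len(t1.de_genes) == 5
        # shift log2(1) = 0: planted genes' kd means equal ctrl means in
        # expectation; check the planted shift is exactly zero by regenerating
        # without planting under the same seed
        expr0, _, _ = synthetic.gen_expression(50, 3, 5, 1.0, 0.2, seed=1)
        pd.testing.assert_frame_equal(expr1, expr0)

    def test_group_structure(self):
        expr, sheet, _ = synthetic.gen_expression(10, 3, 2, 2.0, 0.1, seed=2)
        assert list(expr.columns) == list(sheet["sample"])
        assert sheet["condition"].value_counts().to_dict() == {
            "kd": 3, "unt": 3, "nonT": 3}

    def test_invalid_args(self):
        with pytest.raises(InvalidArgumentError):
            synthetic.gen_expression(10, 1, 2, 2.0, 0.1, seed=0)
        with pytest.raises(InvalidArgumentError):
            synthetic.gen_expression(10, 3, 20, 2.0, 0.1, seed=0)
        with pytest.raises(InvalidArgumentError):
            synthetic.gen_expression(10, 3, 2, 0.5, 0.1, seed=0)

    def test_determinism(self):
        a, _, _ = synthetic.gen_expression(40, 3, 5, 2.0, 0.2, seed=5)
        b, _, _ = synthetic.gen_expression(40, 3, 5, 2.0, 0.2, seed=5)
        pd.testing.assert_frame_equal(a, b)
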