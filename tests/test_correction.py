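"""HTD-DAG and TPR-DAG engines: exact unit cases, oracles, and invariants."""

import numpy as np
import pandas as pd
import pytest

from hierdag import (
    OntologyDAG,
    TprConfig,
    check_consistency,
    compute_levels,
    fit_adaptive_thresholds,
    htd_correct,
    min_distance_levels,
    select_positive_children,
    tpr_correct,
    tpr_node_update,
    tune_weight,
)

from conftest import random_dag, random_scores

ALL_VARIANT_CONFIGS = [
    TprConfig(variant="T", constant_threshold=0.5),
    TprConfig(variant="AT"),
    TprConfig(variant="TF"),
    TprConfig(variant="W", weight=0.5, child_strategy_for_w="TF"),
    TprConfig(variant="D", constant_threshold=0.5),
]


def naive_tpr(dag, levels, flat, config, thresholds=None):
    """Per-gene reference implementation: dict-based bottom-up pass using the
    exposed single-gene helpers, then the closed-form top-down minimum over
    ancestors.  Independent of the vectorised engine's internals."""
    out = {}
    order = sorted(flat.columns, key=lambda t: (levels[t], list(flat.columns).index(t)))
    for gene in flat.index:
        flat_g = flat.loc[gene].to_dict()
        work = dict(flat_g)
        for term in reversed(order):
            if config.variant == "D":
                group = {
                    d for d in dag.descendants(term)
                    if work[d] > config.constant_threshold
                }
                work[term] = tpr_node_update(
                    flat_g[term], [work[d] for d in group],
                    TprConfig(variant="T", constant_threshold=config.constant_threshold),
                )
            else:
                pos = select_positive_children(
                    term, dag, work, flat_g, config, adaptive_thresholds=thresholds
                )
                work[term] = tpr_node_update(
                    flat_g[term], [work[c] for c in pos], config
                )
        # top-down closed form: min over self and ancestors of the bottom-up value
        out[gene] = {
            t: min([work[t]] + [work[a] for a in dag.ancestors(t)])
            for t in flat.columns
        }
    return pd.DataFrame.from_dict(out, orient="index").loc[
        flat.index, flat.columns
    ]


class TestHtd:
    def test_parent_caps_child(self):
        dag = OntologyDAG.from_edges([("p", "c")])
        levels = compute_levels(dag)
        flat = pd.DataFrame([[0.3, 0.7]], index=["g"], columns=["p", "c"])
        corrected = htd_correct(dag, levels, flat)
        assert corrected.loc["g", "p"] == 0.3
        assert corrected.loc["g", "c"] == 0.3

    def test_consistent_matrix_unchanged(self, chain_dag):
        levels = compute_levels(chain_dag)
        flat = pd.DataFrame([[0.9, 0.5, 0.2]], index=["g"],
                            columns=["root", "a", "b"])
        pd.testing.assert_frame_equal(htd_correct(chain_dag, levels, flat), flat)

    def test_idempotent(self, rng):
        dag = random_dag(rng, 30)
        levels = compute_levels(dag)
        flat = random_scores(rng, dag, 10)
        once = htd_correct(dag, levels, flat)
        twice = htd_correct(dag, levels, once)
        pd.testing.assert_frame_equal(once, twice)

    @pytest.mark.parametrize("seed", range(5))
    def test_min_over_ancestors_closed_form(self, seed):
        rng = np.random.default_rng(300 + seed)
        dag = random_dag(rng, 50)
        levels = compute_levels(dag)
        flat = random_scores(rng, dag, 12)
        corrected = htd_correct(dag, levels, flat)
        for term in dag.terms:
            group = [term] + sorted(dag.ancestors(term))
            expected = flat[group].min(axis=1)
            np.testing.assert_array_equal(corrected[term].to_numpy(),
                                          expected.to_numpy())

    def test_rejects_min_distance_levels(self):
        dag = OntologyDAG.from_edges(
            [("root", "a"), ("root", "x"), ("x", "b"), ("a", "d"), ("b", "d")]
        )
        flat = pd.DataFrame(
            [[1.0, 1.0, 0.1, 0.8, 0.9]], index=["g"],
            columns=["root", "a", "x", "d", "b"],
        )
        with pytest.raises(ValueError, match="max-distance"):
            htd_correct(dag, min_distance_levels(dag), flat)

    def test_min_distance_levels_break_consistency(self):
        """Shortest-path levels process a term before a deeper parent has been
        lowered, leaving a true-path violation; longest-path levels do not."""
        dag = OntologyDAG.from_edges(
            [("root", "a"), ("root", "x"), ("x", "b"), ("a", "d"), ("b", "d")]
        )
        flat = pd.DataFrame(
            [[1.0, 1.0, 0.1, 0.8, 0.9]], index=["g"],
            columns=["root", "a", "x", "d", "b"],
        )
        bad = htd_correct(dag, min_distance_levels(dag), flat,
                          validate_levels=False)
        assert len(check_consistency(dag, bad)) >= 1
        good = htd_correct(dag, compute_levels(dag), flat)
        assert check_consistency(dag, good) == []

    def test_range_preserved(self, rng):
        dag = random_dag(rng, 40)
        flat = random_scores(rng, dag, 8)
        corrected = htd_correct(dag, compute_levels(dag), flat)
        assert corrected.to_numpy().min() >= 0.0
        assert corrected.to_numpy().max() <= 1.0

    def test_out_of_range_scores_fatal(self, chain_dag):
        flat = pd.DataFrame([[1.2, 0.5, 0.1]], index=["g"],
                            columns=["root", "a", "b"])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            htd_correct(chain_dag, compute_levels(chain_dag), flat)


class TestPositiveChildren:
    @pytest.fixture
    def star(self):
        return OntologyDAG.from_edges(
            [("i", "c1"), ("i", "c2"), ("i", "c3")]
        )

    def test_threshold_free_strict(self, star):
        work = {"c1": 0.4, "c2": 0.5, "c3": 0.9}
        flat = {"i": 0.5}
        pos = select_positive_children("i", star, work, flat, TprConfig(variant="TF"))
        assert pos == {"c3"}  # ties with the parent's flat score are negative

    def test_constant_threshold_strict(self, star):
        work = {"c1": 0.4, "c2": 0.5, "c3": 0.9}
        pos = select_positive_children(
            "i", star, work, {"i": 0.0},
            TprConfig(variant="T", constant_threshold=0.5),
        )
        assert pos == {"c3"}

    def test_adaptive_threshold_requires_training(self, star):
        with pytest.raises(ValueError, match="training"):
            select_positive_children(
                "i", star, {"c1": 1.0, "c2": 1.0, "c3": 1.0}, {"i": 0.0},
                TprConfig(variant="AT"),
            )

    def test_adaptive_threshold_from_fit(self, star):
        thresholds = {"c1": 0.2, "c2": 0.6, "c3": 0.95}
        work = {"c1": 0.4, "c2": 0.5, "c3": 0.9}
        pos = select_positive_children(
            "i", star, work, {"i": 0.0}, TprConfig(variant="AT"),
            adaptive_thresholds=thresholds,
        )
        assert pos == {"c1"}


class TestAdaptiveThresholdFit:
    def test_perfect_separation_picks_grid_optimum(self):
        """Labels separated exactly at 0.55: every grid point in [0.55, 0.75)
        classifies perfectly, and the smallest such point is returned."""
        genes = [f"g{i}" for i in range(10)]
        scores = pd.DataFrame(
            {"j": np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.55, 0.8, 0.85, 0.9, 1.0])},
            index=genes,
        )
        labels = pd.DataFrame({"j": [0, 0, 0, 0, 0, 0, 1, 1, 1, 1]}, index=genes)
        grid = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))
        fitted = fit_adaptive_thresholds(scores, labels, grid)

        # exhaustive oracle over the same grid
        def f1_at(t):
            pred = scores["j"].to_numpy() > t
            y = labels["j"].to_numpy(dtype=bool)
            tp = (pred & y).sum()
            return 0.0 if pred.sum() + y.sum() == 0 else 2 * tp / (pred.sum() + y.sum())

        best = min(t for t in grid if f1_at(t) == max(f1_at(t) for t in grid))
        assert fitted["j"] == best == 0.55

    def test_matches_exhaustive_grid_oracle_random(self, rng):
        genes = [f"g{i}" for i in range(30)]
        terms = ["a", "b", "c"]
        scores = pd.DataFrame(rng.random((30, 3)), index=genes, columns=terms)
        labels = pd.DataFrame(rng.integers(0, 2, (30, 3)), index=genes,
                              columns=terms)
        grid = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))
        fitted = fit_adaptive_thresholds(scores, labels, grid)
        for term in terms:
            y = labels[term].to_numpy(dtype=bool)
            s = scores[term].to_numpy()

            def f1(t):
                pred = s > t
                denom = pred.sum() + y.sum()
                return 0.0 if denom == 0 else 2 * (pred & y).sum() / denom

            scores_by_t = [f1(t) for t in grid]
            assert f1(fitted[term]) == max(scores_by_t)
            # smallest grid point on ties
            assert fitted[term] == grid[int(np.argmax(scores_by_t))]


class TestNodeUpdate:
    def test_average_with_one_positive(self):
        assert tpr_node_update(0.2, [0.8], TprConfig(variant="TF")) == 0.5

    def test_no_positives_returns_flat(self):
        assert tpr_node_update(0.7, [], TprConfig(variant="TF")) == 0.7

    def test_weighted_w1_is_flat(self):
        cfg = TprConfig(variant="W", weight=1.0)
        assert tpr_node_update(0.3, [0.9, 0.1], cfg) == pytest.approx(0.3)

    def test_weighted_w0_is_children_mean(self):
        cfg = TprConfig(variant="W", weight=0.0)
        assert tpr_node_update(0.9, [0.1, 0.3], cfg) == pytest.approx(0.2)

    def test_weighted_empty_positives_returns_flat(self):
        cfg = TprConfig(variant="W", weight=0.3)
        assert tpr_node_update(0.6, [], cfg) == 0.6

    def test_result_in_unit_interval(self, rng):
        for _ in range(100):
            flat = rng.random()
            vals = rng.random(rng.integers(0, 5))
            for cfg in ALL_VARIANT_CONFIGS:
                if cfg.variant == "D":
                    continue
                assert 0.0 <= tpr_node_update(flat, vals, cfg) <= 1.0


class TestTprCorrect:
    @pytest.mark.parametrize("config", ALL_VARIANT_CONFIGS,
                             ids=lambda c: c.variant)
    def test_output_consistent(self, config, small_instance):
        dag, levels, ann, flat = small_instance
        corrected = tpr_correct(dag, levels, flat, config,
                                training_annotations=ann)
        assert check_consistency(dag, corrected) == []

    @pytest.mark.parametrize("config", ALL_VARIANT_CONFIGS,
                             ids=lambda c: c.variant)
    def test_range_preserved(self, config, small_instance):
        dag, levels, ann, flat = small_instance
        corrected = tpr_correct(dag, levels, flat, config,
                                training_annotations=ann)
        values = corrected.to_numpy()
        assert values.min() >= 0.0 and values.max() <= 1.0

    def test_w1_bit_identical_to_htd(self, small_instance):
        dag, levels, _, flat = small_instance
        cfg = TprConfig(variant="W", weight=1.0)
        tpr = tpr_correct(dag, levels, flat, cfg)
        htd = htd_correct(dag, levels, flat)
        assert np.array_equal(tpr.to_numpy(), htd.to_numpy())

    @pytest.mark.parametrize("seed", range(5))
    def test_tf_dominates_htd_entrywise(self, seed):
        rng = np.random.default_rng(400 + seed)
        dag = random_dag(rng, 40)
        levels = compute_levels(dag)
        flat = random_scores(rng, dag, 15)
        tf = tpr_correct(dag, levels, flat, TprConfig(variant="TF"))
        htd = htd_correct(dag, levels, flat)
        assert (tf.to_numpy() >= htd.to_numpy() - 1e-12).all()

    def test_tf_sensitivity_dominates_htd(self, small_instance):
        """Per-term sensitivity of TPR-TF ≥ HTD at every decision threshold."""
        dag, levels, ann, flat = small_instance
        tf = tpr_correct(dag, levels, flat, TprConfig(variant="TF"))
        htd = htd_correct(dag, levels, flat)
        labels = ann.to_numpy(dtype=bool)
        for tau in np.arange(0.0, 1.01, 0.05):
            sn_tf = ((tf.to_numpy() > tau) & labels).sum(axis=0)
            sn_htd = ((htd.to_numpy() > tau) & labels).sum(axis=0)
            assert (sn_tf >= sn_htd).all()

    def test_leaf_only_dag_direct_recursion(self):
        """Star ontology: leaves untouched by the bottom-up pass; the root is
        the average of its flat score with the positive leaves; top-down then
        caps the leaves at the updated root."""
        dag = OntologyDAG.from_edges([("r", "l1"), ("r", "l2"), ("r", "l3")])
        levels = compute_levels(dag)
        flat = pd.DataFrame([[0.4, 0.9, 0.3, 0.8]], index=["g"],
                            columns=["r", "l1", "l2", "l3"])
        corrected = tpr_correct(dag, levels, flat, TprConfig(variant="TF"))
        # positives of r under TF: l1 (0.9) and l3 (0.8) exceed flat 0.4
        expected_root = (0.4 + 0.9 + 0.8) / 3
        assert corrected.loc["g", "r"] == pytest.approx(expected_root)
        assert corrected.loc["g", "l1"] == pytest.approx(expected_root)
        assert corrected.loc["g", "l2"] == pytest.approx(0.3)
        assert corrected.loc["g", "l3"] == pytest.approx(expected_root)

    @pytest.mark.parametrize("config", ALL_VARIANT_CONFIGS,
                             ids=lambda c: c.variant)
    def test_engine_matches_naive_per_gene_oracle(self, config):
        rng = np.random.default_rng(777)
        dag = random_dag(rng, 25)
        levels = compute_levels(dag)
        flat = random_scores(rng, dag, 6)
        thresholds = None
        kwargs = {}
        if config.selection_strategy == "AT":
            labels = pd.DataFrame(
                rng.integers(0, 2, flat.shape), index=flat.index,
                columns=flat.columns,
            )
            thresholds = fit_adaptive_thresholds(flat, labels)
            kwargs["training_annotations"] = labels
            kwargs["training_scores"] = flat
        engine = tpr_correct(dag, levels, flat, config, **kwargs)
        reference = naive_tpr(dag, levels, flat, config, thresholds=thresholds)
        np.testing.assert_allclose(engine.to_numpy(), reference.to_numpy(),
                                   atol=1e-12)

    def test_top_down_block_idempotent(self, small_instance):
        dag, levels, ann, flat = small_instance
        corrected = tpr_correct(dag, levels, flat, TprConfig(variant="TF"))
        again = htd_correct(dag, levels, corrected)
        pd.testing.assert_frame_equal(corrected, again)

    def test_ancestor_dominance_all_variants(self, small_instance):
        """Corrected scores never exceed any ancestor's corrected score."""
        dag, levels, ann, flat = small_instance
        for config in ALL_VARIANT_CONFIGS:
            corrected = tpr_correct(dag, levels, flat, config,
                                    training_annotations=ann)
            values = corrected.to_numpy()
            col = {t: j for j, t in enumerate(corrected.columns)}
            for term in dag.terms:
                for anc in dag.ancestors(term):
                    assert (values[:, col[anc]] >= values[:, col[term]] - 1e-9).all()


class TestTuneWeight:
    def test_single_grid_point_returned(self, small_instance):
        dag, levels, ann, flat = small_instance
        assert tune_weight(dag, levels, flat, ann, weight_grid=[0.4]) == 0.4

    def test_deterministic_under_seed(self, small_instance):
        dag, levels, ann, flat = small_instance
        grid = (0.2, 0.5, 0.8)
        w1 = tune_weight(dag, levels, flat, ann, weight_grid=grid, seed=3)
        w2 = tune_weight(dag, levels, flat, ann, weight_grid=grid, seed=3)
        assert w1 == w2

    def test_matches_exhaustive_cv_curve(self, small_instance):
        """The returned weight maximises the mean fold Fmax computed by an
        explicit loop over folds and grid points."""
        from hierdag.metrics import fmax

        dag, levels, ann, flat = small_instance
        grid = (0.1, 0.5, 0.9)
        seed, n_folds = 11, 3
        selected = tune_weight(dag, levels, flat, ann, weight_grid=grid,
                               n_folds=n_folds, seed=seed)

        genes = list(flat.index)
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(genes))
        fold_assign = np.empty(len(genes), dtype=int)
        fold_assign[order] = np.arange(len(genes)) % n_folds
        non_root = [t for t in flat.columns if t != dag.root]
        curve = []
        for w in grid:
            cfg = TprConfig(variant="W", weight=w, child_strategy_for_w="TF")
            fold_scores = []
            for fold in range(n_folds):
                held = [g for g, f in zip(genes, fold_assign) if f == fold]
                corrected = tpr_correct(dag, levels, flat.loc[held], cfg,
                                        training_annotations=ann)
                f, *_ = fmax(corrected[non_root], ann.loc[held, non_root])
                fold_scores.append(f)
            curve.append(np.mean(fold_scores))
        assert selected == grid[int(np.argmax(curve))]

    def test_too_few_genes_fatal(self, chain_dag):
        levels = compute_levels(chain_dag)
        flat = pd.DataFrame([[1.0, 0.5, 0.2]], index=["g"],
                            columns=["root", "a", "b"])
        ann = pd.DataFrame([[1, 1, 0]], index=["g"], columns=["root", "a", "b"])
        with pytest.raises(ValueError, match="fold"):
            tune_weight(chain_dag, levels, flat, ann, weight_grid=(0.2, 0.8),
                        n_folds=3)
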