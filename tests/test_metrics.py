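"""CAFA metrics against exhaustive oracles, pair matching, summaries."""

import numpy as np
import pandas as pd
import pytest

from gofuse.metrics import (
    TAU_GRID,
    evaluate,
    example_f1,
    fmax,
    frequency_sweep,
    improvement_summary,
    load_reference_table,
    matching_rate_from_counts,
    method_row_means,
    micro_aupr,
    micro_mcc,
    pair_matching_rate,
    retained_fraction,
)


def fmax_oracle(scores, labels):
    """Exhaustive grid enumeration with explicit per-protein loops."""
    best, best_tau = 0.0, float(TAU_GRID[0])
    n, gamma = scores.shape
    for tau in TAU_GRID:
        precisions, recalls = [], []
        for i in range(n):
            pred = {j for j in range(gamma) if scores[i, j] >= tau}
            true = {j for j in range(gamma) if labels[i, j]}
            if pred:
                precisions.append(len(pred & true) / len(pred))
            if true:
                recalls.append(len(pred & true) / len(true))
        pr = sum(precisions) / len(precisions) if precisions else 0.0
        rc = sum(recalls) / len(recalls) if recalls else 0.0
        f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
        if f > best:
            best, best_tau = f, float(tau)
    return best, best_tau


def aupr_oracle(scores, labels):
    """Step-integration average precision, written independently."""
    order = np.argsort(-scores.ravel(), kind="stable")
    y = labels.ravel()[order]
    tp = 0
    total_pos = int(y.sum())
    area = 0.0
    for k, yk in enumerate(y, start=1):
        if yk:
            tp += 1
            area += tp / k
    return area / total_pos


def mcc_oracle(scores, labels, tau=0.5):
    pred = (scores >= tau).ravel()
    true = labels.ravel() > 0
    tp = float((pred & true).sum())
    tn = float((~pred & ~true).sum())
    fp = float((pred & ~true).sum())
    fn = float((~pred & true).sum())
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if denom == 0 else (tp * tn - fp * fn) / denom


class TestFmax:
    def test_perfect_predictor(self):
        y = np.array([[1, 0, 1], [0, 1, 0]])
        f, tau = fmax(y.astype(float), y)
        assert f == 1.0
        # and indeed every swept τ achieves F = 1 for 0/1 scores
        for t in (0.01, 0.5, 1.0):
            pred = y.astype(float) >= t
            assert np.array_equal(pred, y > 0)

    def test_all_zero_scores(self):
        y = np.array([[1, 0], [0, 1]])
        f, _ = fmax(np.zeros((2, 2)), y)
        assert f == 0.0

    def test_hand_instance_matches_oracle(self):
        scores = np.array(
            [[0.9, 0.4, 0.1, 0.6], [0.2, 0.8, 0.55, 0.0], [0.7, 0.7, 0.3, 0.45]]
        )
        labels = np.array([[1, 0, 0, 1], [0, 1, 1, 0], [1, 1, 0, 0]])
        assert fmax(scores, labels) == pytest.approx(fmax_oracle(scores, labels))

    @pytest.mark.parametrize("seed", range(25))
    def test_randomized_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 10))
        gamma = int(rng.integers(1, 8))
        scores = rng.random((n, gamma))
        labels = rng.random((n, gamma)) < 0.4
        if not labels.any():
            labels[0, 0] = True
        f, tau = fmax(scores, labels)
        fo, tau_o = fmax_oracle(scores, labels)
        assert f == pytest.approx(fo, abs=1e-12)
        assert tau == pytest.approx(tau_o)

    def test_no_true_labels_errors(self):
        with pytest.raises(ValueError, match="recall"):
            fmax(np.ones((2, 2)), np.zeros((2, 2)))

    def test_protein_permutation_invariance(self, rng):
        scores = rng.random((8, 5))
        labels = (rng.random((8, 5)) < 0.4).astype(int)
        labels[0, 0] = 1
        perm = rng.permutation(8)
        assert fmax(scores, labels) == fmax(scores[perm], labels[perm])

    def test_monotone_rank_preserving_transform_invariance(self, rng):
        """Remapping score values monotonically onto other grid points
        preserves every induced binarization, hence Fmax."""
        values = np.sort(rng.choice(TAU_GRID[5:-5], size=6, replace=False))
        remapped = np.sort(rng.choice(TAU_GRID[5:-5], size=6, replace=False))
        idx = rng.integers(0, 6, size=(7, 4))
        labels = (rng.random((7, 4)) < 0.5).astype(int)
        labels[0, 0] = 1
        assert fmax(values[idx], labels)[0] == pytest.approx(
            fmax(remapped[idx], labels)[0]
        )


class TestPointMetrics:
    def test_perfect_scores(self):
        y = np.array([[1, 0], [0, 1], [1, 1]])
        s = y.astype(float)
        assert example_f1(s, y) == 1.0
        assert micro_aupr(s, y) == 1.0
        assert micro_mcc(s, y) == 1.0

    def test_mcc_zero_without_association(self):
        # balanced flips: prediction independent of truth
        labels = np.array([[1, 0], [1, 0]])
        scores = np.array([[0.9, 0.9], [0.1, 0.1]])
        assert micro_mcc(scores, labels) == pytest.approx(0.0)

    def test_empty_prediction_and_truth_convention(self):
        labels = np.array([[0, 0], [1, 0]])
        scores = np.array([[0.1, 0.2], [0.9, 0.1]])
        # protein 0: nothing predicted, nothing true -> F1 contribution 1
        assert example_f1(scores, labels) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_match_secondary_oracles(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random((5, 6))
        labels = (rng.random((5, 6)) < 0.4).astype(int)
        if not labels.any():
            labels[0, 0] = 1
        assert micro_aupr(scores, labels) == pytest.approx(
            aupr_oracle(scores, labels), abs=1e-12
        )
        assert micro_mcc(scores, labels) == pytest.approx(
            mcc_oracle(scores, labels), abs=1e-12
        )

    def test_random_scorer_aupr_near_positive_rate(self):
        rng = np.random.default_rng(0)
        labels = (rng.random((200, 20)) < 0.3).astype(int)
        scores = rng.random((200, 20))
        rate = labels.mean()
        assert micro_aupr(scores, labels) == pytest.approx(rate, abs=0.03)

    def test_report_invariants(self, rng):
        scores = rng.random((10, 6))
        labels = (rng.random((10, 6)) < 0.4).astype(int)
        labels[0, 0] = 1
        report = evaluate(scores, labels)
        assert 0 <= report.fmax <= 1
        for pr, rc in zip(report.precision, report.recall):
            f = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
            assert report.fmax >= f - 1e-12
        assert 0 <= report.aupr <= 1
        assert -1 <= report.mcc <= 1


class TestPairMatching:
    def test_identical_positive_sets_pair_up(self):
        labels = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        scores = labels.astype(float) * 0.9
        conf = {("A", "B"): 95.0}
        result = pair_matching_rate(
            scores, labels, conf, ["A", "B", "C"]
        )
        assert result.n_selected == 1
        assert result.selection.pairs[0][:2] == ("A", "B")
        assert result.selection.pairs[0][2] == 1.0
        assert result.n_matched == 1 and result.rate == 1.0

    def test_empty_confidence_table(self):
        labels = np.array([[1, 1], [1, 1]])
        scores = labels.astype(float)
        result = pair_matching_rate(scores, labels, {}, ["A", "B"])
        assert result.n_selected == 1 and result.n_matched == 0

    def test_low_precision_proteins_excluded(self):
        labels = np.array([[1, 0, 0, 0], [1, 1, 1, 1]])
        scores = np.array([[0.9, 0.9, 0.9, 0.9], [0.9, 0.9, 0.9, 0.9]])
        # protein 0 precision 0.25 < 0.75 -> no pair possible
        result = pair_matching_rate(scores, labels, {}, ["A", "B"])
        assert result.n_selected == 0 and result.rate is None

    def test_published_counts_reproduce_rate(self):
        counts = load_reference_table("ppi_pair_counts")
        result = matching_rate_from_counts(counts)
        assert result.n_selected == 578
        assert result.n_matched == 403
        assert round(100 * result.rate, 2) == 69.72


class TestSummaries:
    def test_mean_fmax_improvement(self):
        table = load_reference_table("plm_benchmark_fmax")
        assert improvement_summary(table) == pytest.approx(14.66, abs=0.005)

    def test_identical_columns_give_zero(self):
        table = pd.DataFrame({"base": [1.0, 2.0], "enhanced": [1.0, 2.0]})
        assert improvement_summary(table) == 0.0

    def test_unpaired_cell_errors(self):
        table = pd.DataFrame(
            {"model": ["m"], "aspect": ["BP"], "base": [1.0], "enhanced": [np.nan]}
        )
        with pytest.raises(ValueError, match="'m'"):
            improvement_summary(table)

    def test_strongest_model_row_means(self):
        fmax_table = load_reference_table("plm_benchmark_fmax")
        f1_table = load_reference_table("plm_benchmark_f1")
        assert method_row_means(fmax_table, "PGLM") == pytest.approx(71.18, abs=0.005)
        assert method_row_means(f1_table, "PGLM") == pytest.approx(52.29, abs=0.005)

    def test_retained_fraction(self):
        counts = load_reference_table("go_term_counts")
        assert retained_fraction(counts) == pytest.approx(32.27, abs=0.005)


class TestFrequencySweep:
    def test_threshold_zero_retains_everything(self, small_cohort):
        from gofuse.model import ModuleSwitches, TrainConfig

        cohort, graphs = small_cohort
        table = frequency_sweep(
            cohort, graphs["BP"], [0],
            train_config=TrainConfig(epochs=1, seed=0),
            switches=ModuleSwitches(text=False),
        )
        assert table.loc[0, "gamma_retained"] == graphs["BP"].gamma

    def test_retained_counts_match_hand_counts(self, small_cohort):
        from gofuse.model import ModuleSwitches, TrainConfig

        cohort, graphs = small_cohort
        freqs = cohort.labels["BP"].sum(axis=0)
        thresholds = [0, 10, 25]
        table = frequency_sweep(
            cohort, graphs["BP"], thresholds,
            train_config=TrainConfig(epochs=1, seed=0),
            switches=ModuleSwitches(text=False),
        )
        for row, t in zip(table.itertuples(), thresholds):
            assert row.gamma_retained == int((freqs >= t).sum())

    def test_emptying_threshold_recorded_invalid(self, small_cohort):
        from gofuse.model import ModuleSwitches, TrainConfig

        cohort, graphs = small_cohort
        table = frequency_sweep(
            cohort, graphs["BP"], [0, 10_000],
            train_config=TrainConfig(epochs=1, seed=0),
            switches=ModuleSwitches(text=False),
        )
        assert table.loc[1, "valid"] == False  # noqa: E712
        assert table.loc[0, "valid"] == True  # noqa: E712

    def test_pruning_rare_noise_terms_does_not_hurt(self):
        """Ten rare label-noise terms attached to a clean cohort: Fmax at
        a moderate pruning threshold must be at least Fmax without pruning
        (tolerance 0.02; measured once at this seed and frozen)."""
        from gofuse.model import ModuleSwitches, TrainConfig
        from gofuse.ontology import GoGraph, GoTerm
        from gofuse.simulate import SimConfig, generate_cohort

        cohort, graphs = generate_cohort(
            SimConfig(n_proteins=120, gamma_per_aspect=12, seed=5, aspects=("BP",))
        )
        graph = graphs["BP"]
        rng = np.random.default_rng(5)
        noise_terms = [GoTerm(id=f"GO:1900{i:03d}", aspect="BP") for i in range(10)]
        root = graph.terms[0].id
        noisy_graph = GoGraph(
            terms=graph.terms + noise_terms,
            edges=graph.edges | {(t.id, root, "is_a") for t in noise_terms},
            aspect="BP",
        )
        extra = pd.DataFrame(
            [
                (cohort.protein_ids[int(rng.integers(cohort.n))], t.id, "BP")
                for t in noise_terms
                for _ in range(2)
            ],
            columns=["protein_id", "go_id", "aspect"],
        )
        cohort.annotations = pd.concat([cohort.annotations, extra], ignore_index=True)
        table = frequency_sweep(
            cohort, noisy_graph, [0, 5],
            train_config=TrainConfig(epochs=5, seed=0),
            switches=ModuleSwitches(text=False),
            seed=0,
        )
        f0, f5 = table["fmax"].tolist()
        assert table["gamma_retained"].tolist()[0] == 22
        assert f5 >= f0 - 0.02
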