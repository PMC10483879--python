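"""Metrics (Sn/Sp/BACC/MCC/AUC) and the stability experiment harnesses."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from idrfuse.errors import ContractError, DataError, ParameterError
from idrfuse.evaluation import (
    ConfusionCounts,
    auc,
    compute_metrics,
    confusion_counts,
    evaluate_tracks,
    ratio_sweep,
    resample_compare,
)
from idrfuse.simulate import (
    DisorderCompositionSpec,
    PredictorSpec,
    simulate_predictor,
    simulate_proteins,
)


class TestConfusionCounts:
    def test_perfect_predictions(self):
        labels = np.array([1, 0, 1, 0])
        counts = confusion_counts(labels.astype(float), labels)
        assert (counts.fp, counts.fn) == (0, 0)
        assert (counts.tp, counts.tn) == (2, 2)

    def test_all_zero_probabilities_all_positive_labels(self):
        counts = confusion_counts(np.zeros(7), np.ones(7, int))
        assert (counts.tp, counts.fn) == (0, 7)

    def test_matches_enumeration_oracle(self, rng):
        probs = rng.random(200)
        labels = (rng.random(200) < 0.3).astype(int)
        counts = confusion_counts(probs, labels, threshold=0.4)
        tp = fp = tn = fn = 0
        for p, y in zip(probs, labels):
            call = p >= 0.4
            if call and y:
                tp += 1
            elif call and not y:
                fp += 1
            elif not call and y:
                fn += 1
            else:
                tn += 1
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)
        assert counts.total == 200

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            confusion_counts(np.zeros(3), np.zeros(4, int))


class TestComputeMetrics:
    def test_chance_level_symmetry(self):
        report = compute_metrics(ConfusionCounts(tp=5, fn=5, tn=8, fp=8))
        assert report.sn == report.sp == report.bacc == 0.5
        assert report.mcc == pytest.approx(0.0)

    def test_perfect_counts(self):
        report = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=20, fn=0))
        assert report.sn == report.sp == report.bacc == 1.0
        assert report.mcc == pytest.approx(1.0)

    def test_direct_formula_case(self):
        # (TP, FP, TN, FN) = (3, 1, 4, 2): MCC = (12 - 2)/sqrt(4*5*5*6)
        report = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert report.sn == pytest.approx(3 / 5)
        assert report.sp == pytest.approx(4 / 5)
        assert report.bacc == pytest.approx(0.7)
        assert report.mcc == pytest.approx(10 / np.sqrt(600))

    def test_bacc_identity_holds_everywhere(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            report = compute_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert report.bacc == pytest.approx((report.sn + report.sp) / 2)

    def test_mcc_sign_flips_on_inversion(self, rng):
        tp, fp, tn, fn = 12, 3, 11, 4
        direct = compute_metrics(ConfusionCounts(tp, fp, tn, fn)).mcc
        inverted = compute_metrics(ConfusionCounts(fn, tn, fp, tp)).mcc
        assert inverted == pytest.approx(-direct)

    def test_zero_denominator_flagged_not_coerced(self):
        report = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert np.isnan(report.sn)
        assert "Sn" in report.undefined


class TestAuc:
    def test_perfect_ranking(self):
        y = np.array([0, 1, 0, 1])
        assert auc(y.astype(float), y) == 1.0

    def test_all_ties_give_half(self):
        assert auc(np.full(10, 0.3), np.array([0, 1] * 5)) == 0.5

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 60))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # induces ties
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            expected = (wins + 0.5 * ties) / (pos.size * neg.size)
            assert auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_complement_identity_for_tie_free_scores(self, rng):
        scores = rng.permutation(50) / 50.0
        labels = (rng.random(50) < 0.5).astype(int)
        labels[:2] = [0, 1]
        assert auc(scores, labels) + auc(scores, 1 - labels) == pytest.approx(1.0)

    def test_single_class_undefined(self):
        with pytest.raises(DataError):
            auc(np.random.rand(5), np.ones(5, int))


def make_specialist_data(seed, n_sdr=24, n_ldr=8):
    """A dataset with an SDR specialist, an LDR specialist and their average."""
    records = simulate_proteins(DisorderCompositionSpec(
        n_ldr=n_ldr, n_sdr=n_sdr, length_range=(50, 90), seed=seed))
    labels = [r.labels for r in records]
    from idrfuse.features import classify_protein
    rng_seed = 1000 + seed
    sdr_spec = PredictorSpec(auc=0.95, auc_by_class={"LDR_protein": 0.55})
    ldr_spec = PredictorSpec(auc=0.95, auc_by_class={"SDR_protein": 0.55})
    sdr_tracks, ldr_tracks, fused_tracks = [], [], []
    for k, y in enumerate(labels):
        cls = classify_protein(y)
        a = simulate_predictor(y, PredictorSpec(auc=sdr_spec.target_for(cls)),
                               seed=rng_seed + 2 * k)
        b = simulate_predictor(y, PredictorSpec(auc=ldr_spec.target_for(cls)),
                               seed=rng_seed + 2 * k + 1)
        sdr_tracks.append(a.probabilities)
        ldr_tracks.append(b.probabilities)
        fused_tracks.append((a.probabilities + b.probabilities) / 2)
    return labels, {"sdr_specialist": sdr_tracks, "ldr_specialist": ldr_tracks,
                    "fused": fused_tracks}


class TestRatioSweep:
    def test_single_step_is_whole_dataset(self, rng):
        labels, methods = make_specialist_data(seed=0)
        table = ratio_sweep(labels, methods, steps=1)
        assert set(table["step"]) == {0}
        whole = evaluate_tracks(methods["fused"], labels)
        row = table[table["method"] == "fused"].iloc[0]
        assert row["auc"] == pytest.approx(whole.auc)

    def test_final_step_has_no_sdr_proteins(self):
        labels, methods = make_specialist_data(seed=1)
        table = ratio_sweep(labels, methods, steps=5, seed=0)
        last = table[table["step"] == 4].iloc[0]
        assert last["sdr_fraction"] == 0.0

    def test_sweep_without_sdr_proteins_degenerates_with_warning(self):
        labels, methods = make_specialist_data(seed=2, n_sdr=0, n_ldr=6)
        with pytest.warns(UserWarning):
            table = ratio_sweep(labels, methods, steps=5)
        assert set(table["step"]) == {0}

    def test_sdr_specialist_declines_along_sweep(self):
        for seed in range(5):
            labels, methods = make_specialist_data(seed=10 + seed)
            table = ratio_sweep(labels, {"sdr_specialist": methods["sdr_specialist"]},
                                steps=11, seed=seed)
            aucs = table.sort_values("step")["auc"].to_numpy()
            rho, _ = spearmanr(np.arange(11), aucs)
            assert rho < 0


class TestResampleCompare:
    def test_full_dataset_single_repeat_equals_whole_evaluation(self):
        labels, methods = make_specialist_data(seed=3)
        table, _wins = resample_compare(labels, methods, n_proteins=len(labels),
                                        repeats=1, seed=0)
        whole = evaluate_tracks(methods["fused"], labels)
        got = table[table["method"] == "fused"]["auc"].iloc[0]
        assert got == pytest.approx(whole.auc)

    def test_identical_methods_all_ties(self):
        labels, methods = make_specialist_data(seed=4)
        twins = {"a": methods["fused"], "b": methods["fused"]}
        _table, wins = resample_compare(labels, twins, n_proteins=10, repeats=8, seed=0)
        assert wins.loc["a", "b"] == 0 and wins.loc["b", "a"] == 0

    def test_dominant_method_wins_nearly_always(self):
        records = simulate_proteins(DisorderCompositionSpec(
            n_ldr=6, n_sdr=18, length_range=(50, 90), seed=9))
        labels = [r.labels for r in records]
        rng = np.random.default_rng(42)
        good = [np.clip(y + rng.normal(0, 0.1, y.size), 0, 1) for y in labels]
        noise = [rng.random(y.size) for y in labels]
        _table, wins = resample_compare(labels, {"good": good, "noise": noise},
                                        n_proteins=12, repeats=50, seed=7)
        assert wins.loc["good", "noise"] >= 49

    def test_oversampling_rejected(self):
        labels, methods = make_specialist_data(seed=5)
        with pytest.raises(ParameterError):
            resample_compare(labels, methods, n_proteins=len(labels) + 1)
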