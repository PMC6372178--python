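import itertools
import math

import numpy as np
import pytest

from dcehist import (
    FeatureRecord,
    auc_rank_sum,
    roc_with_youden,
    spearman_corr,
    summarize_tables,
    wilcoxon_signed_rank,
)
from dcehist.io import FEATURE_NAMES


def _exact_wilcoxon_p(diffs):
    """Oracle: enumerate all 2^n sign assignments of the rank statistic."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1  # no ties assumed
    w_plus = int(ranks[d > 0].sum())
    sums = [sum(subset) for r in range(n + 1) for subset in itertools.combinations(ranks, r)]
    sums = np.array(sums)
    p_le = np.mean(sums <= w_plus)
    p_ge = np.mean(sums >= w_plus)
    return min(1.0, 2.0 * min(p_le, p_ge))


def _brute_force_auc(pos, neg):
    """Oracle: fraction of (positive, negative) pairs won, ties credited 1/2."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestWilcoxon:
    def test_identical_vectors_give_p_one(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_five_positive_differences_exact(self):
        # all 5 differences positive: two-sided exact p = 2/2^5 = 0.0625
        p = wilcoxon_signed_rank([2, 4, 6, 8, 10], [1, 2, 3, 4, 5])
        assert p == pytest.approx(0.0625)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.3, 1, 10)
        y = rng.normal(0.0, 1, 10)
        assert wilcoxon_signed_rank(x, y) == pytest.approx(_exact_wilcoxon_p(x - y))

    def test_invariant_under_positive_affine_transform(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(1, 1, 12), rng.normal(0, 1, 12)
        p = wilcoxon_signed_rank(x, y)
        assert wilcoxon_signed_rank(3.2 * x + 7, 3.2 * y + 7) == pytest.approx(p)

    def test_ties_fall_back_to_corrected_normal(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        y = x - np.array([1, 1, 1, 1, 2, 2, 2, 2.0])  # tied |differences|
        p = wilcoxon_signed_rank(x, y)
        assert 0 < p < 0.05


class TestSpearman:
    def test_monotone_relations(self):
        x = np.arange(10.0)
        assert spearman_corr(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert spearman_corr(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_tied_data_average_rank_oracle(self):
        # ranks of [1,2,2,3] -> [1, 2.5, 2.5, 4]; ranks of y strictly
        # increasing -> [1,2,3,4]; Pearson of those rank vectors:
        # cov = 4.5, var_x = 4.5, var_y = 5 -> rho = 4.5/sqrt(22.5)
        rho, _ = spearman_corr([1, 2, 2, 3], [10, 20, 25, 30])
        assert rho == pytest.approx(4.5 / math.sqrt(22.5))

    def test_constant_vector_undefined(self):
        with pytest.warns(UserWarning):
            rho, p = spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)


class TestRocYouden:
    def test_tie_credit_half(self):
        res = roc_with_youden([3, 4, 5], [1, 2, 3])
        assert res.auc == pytest.approx(8.5 / 9)
        assert res.direction == "high"

    def test_perfect_separation(self):
        res = roc_with_youden([10, 11, 12], [1, 2, 3])
        assert res.auc == 1.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert res.accuracy == 100.0
        assert 3 < res.threshold < 10  # midpoint between the groups

    def test_identical_groups_are_chance(self):
        res = roc_with_youden([1, 2, 3], [1, 2, 3])
        assert res.auc == pytest.approx(0.5)

    def test_constant_equal_groups_warn(self):
        with pytest.warns(UserWarning):
            res = roc_with_youden([2, 2], [2, 2, 2])
        assert res.auc == 0.5 and res.threshold == 2.0

    def test_cancer_low_polarity_detected(self):
        res = roc_with_youden([1, 2, 3], [10, 11, 12])
        assert res.direction == "low" and res.auc == 1.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    @pytest.mark.parametrize("seed", range(6))
    def test_auc_equals_brute_force_pair_fraction(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 8, rng.integers(3, 13)).astype(float)
        neg = rng.integers(0, 8, rng.integers(3, 13)).astype(float)
        expected = _brute_force_auc(pos, neg)
        res = roc_with_youden(pos, neg)
        assert res.auc == pytest.approx(max(expected, 1 - expected))
        assert auc_rank_sum(pos, neg) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(6))
    def test_youden_threshold_is_exhaustively_optimal(self, seed):
        rng = np.random.default_rng(100 + seed)
        pos = rng.normal(1, 1, 10)
        neg = rng.normal(0, 1, 12)
        res = roc_with_youden(pos, neg)
        pooled = np.unique(np.concatenate([pos, neg]))
        candidates = np.concatenate([[pooled[0] - 1], 0.5 * (pooled[:-1] + pooled[1:]),
                                     [pooled[-1] + 1]])
        def j_at(thr):
            if res.direction == "high":
                return np.mean(pos >= thr) + np.mean(neg < thr) - 1
            return np.mean(pos <= thr) + np.mean(neg > thr) - 1
        j_best = max(j_at(t) for t in candidates)
        achieved = res.sensitivity / 100 + res.specificity / 100 - 1
        assert achieved == pytest.approx(j_best)


def _make_records(n_pairs=8, zone="TZ", diameters=(7.5, 10.0), separated_param="p50",
                  shift=5.0, seed=0):
    """Paired records where exactly one parameter separates the groups."""
    rng = np.random.default_rng(seed)
    cancer_label, benign_label = ("CTZ", "NTZ") if zone == "TZ" else ("CPZ", "NPZ")
    records = []
    for i in range(n_pairs):
        for diam in diameters:
            for map_name in ("MWS", "DPS"):
                base = {name: float(rng.normal(0, 1)) for name in FEATURE_NAMES}
                cancer = dict(base)
                cancer[separated_param] = base[separated_param] + shift
                records.append(FeatureRecord(f"P{i:02d}", cancer_label, diam, map_name,
                                             cancer, gleason=6 + i % 3))
                benign = {name: float(rng.normal(0, 1)) for name in FEATURE_NAMES}
                records.append(FeatureRecord(f"P{i:02d}", benign_label, diam, map_name, benign))
    return records


class TestSummarizeTables:
    def test_grid_and_roc_selection(self):
        records = _make_records()
        report = summarize_tables(records)
        # full grid: 1 zone x 2 maps x 2 diameters x 14 parameters
        assert len(report["comparisons"]) == 2 * 2 * 14
        roc_params = {(r["map"], r["parameter"]) for r in report["roc"]}
        assert ("MWS", "p50") in roc_params and ("DPS", "p50") in roc_params
        assert all(r["diameter_mm"] == 10.0 for r in report["roc"])  # protocol diameter
        p50 = [c for c in report["comparisons"] if c["parameter"] == "p50"]
        assert all(c["wilcoxon_p"] < 0.05 for c in p50)
        assert all(c["cancer_mean"] > c["benign_mean"] for c in p50)

    def test_group_summaries_match_pandas_oracle(self):
        records = _make_records()
        report = summarize_tables(records)
        from dcehist.io import records_to_frame

        df = records_to_frame(records)
        for comp in report["comparisons"][:20]:
            sub = df[(df["map"] == comp["map"]) & (df["diameter_mm"] == comp["diameter_mm"])]
            cancer = sub[sub["label"] == "CTZ"][comp["parameter"]]
            assert comp["cancer_mean"] == pytest.approx(cancer.mean())
            assert comp["cancer_sd"] == pytest.approx(cancer.std(ddof=1))

    def test_unpaired_records_dropped(self):
        records = _make_records(n_pairs=6)
        # remove one patient's benign records -> that patient is unpaired
        records = [r for r in records if not (r.patient_id == "P00" and r.label == "NTZ")]
        report = summarize_tables(records)
        assert all(c["n_pairs"] == 5 for c in report["comparisons"])

    def test_identical_groups_yield_null_results(self):
        rng = np.random.default_rng(1)
        records = []
        for i in range(8):
            feats = {name: float(rng.normal(0, 1)) for name in FEATURE_NAMES}
            for label in ("CTZ", "NTZ"):
                records.append(FeatureRecord(f"P{i}", label, 10.0, "MWS", feats))
        report = summarize_tables(records)  # all differences zero -> p = 1
        assert all(c["wilcoxon_p"] == 1.0 for c in report["comparisons"])
        assert report["roc"] == []

    def test_spearman_rows_follow_significant_parameters(self):
        records = _make_records()
        report = summarize_tables(records)
        sp = {(r["map"], r["parameter"]) for r in report["spearman"]}
        assert sp == {(r["map"], r["parameter"]) for r in report["roc"]}

    def test_fdr_extension_column(self):
        report = summarize_tables(_make_records(), fdr=True)
        assert all("wilcoxon_p_fdr_extension" in c for c in report["comparisons"])
        for c in report["comparisons"]:
            if np.isfinite(c["wilcoxon_p"]):
                assert c["wilcoxon_p_fdr_extension"] >= c["wilcoxon_p"] - 1e-12
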