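import itertools
import math

import numpy as np
import pytest
from scipy import stats

from corpus_fidelity import (
    ComparisonConfig,
    CorpusComparison,
    compare_corpora,
    holm_adjust,
    mann_whitney_u,
)
from conftest import make_corpus


def enumeration_oracle(x, y):
    """Exhaustive oracle for tie-free samples: distribution of U over all
    C(n1+n2, n1) placements of the first sample among the pooled ranks."""
    n1, n2 = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    pooled = n1 + n2
    us = []
    for positions in itertools.combinations(range(pooled), n1):
        # ranks are 0..pooled-1; U = sum(ranks of x) - n1(n1-1)/2
        us.append(sum(positions) - n1 * (n1 - 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitneyU:
    def test_complete_separation_anchors_13_vs_20(self):
        x = list(range(100, 113))  # 13 values, all larger
        y = list(range(20))
        top = mann_whitney_u(x, y)
        assert top.u_first_sample == 260.0
        assert top.p_two_sided < 0.001
        bottom = mann_whitney_u(y, x)
        assert bottom.u_first_sample == 0.0
        assert bottom.p_two_sided < 0.001
        assert top.method == "exact"

    def test_small_sample_exact_p(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u_first_sample == 0.0
        assert res.p_two_sided == pytest.approx(1 / 3, abs=1e-9)

    def test_u_convention_sums_to_n1n2(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 10)).tolist()
            y = rng.normal(size=rng.integers(2, 10)).tolist()
            a = mann_whitney_u(x, y)
            b = mann_whitney_u(y, x)
            assert a.u_first_sample + b.u_first_sample == pytest.approx(
                a.n1 * a.n2
            )
            assert 0 <= a.u_first_sample <= a.n1 * a.n2

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            n1, n2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            x = rng.normal(size=n1).tolist()
            y = rng.normal(size=n2).tolist()
            res = mann_whitney_u(x, y)
            u_oracle, p_oracle = enumeration_oracle(x, y)
            assert res.method == "exact"
            assert res.u_first_sample == pytest.approx(u_oracle)
            assert res.p_two_sided == pytest.approx(p_oracle, abs=1e-9)

    def test_exact_close_to_normal_approximation_n15(self, rng):
        for _ in range(20):
            x = rng.normal(size=15).tolist()
            y = rng.normal(size=15).tolist()
            exact = mann_whitney_u(x, y)
            assert exact.method == "exact"
            approx = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            assert exact.p_two_sided == pytest.approx(float(approx.pvalue), abs=0.02)

    def test_ties_use_normal_approximation(self):
        res = mann_whitney_u([1, 1, 2, 3] * 12, [1, 2, 2, 4] * 12)
        assert res.method == "normal_approx"
        assert 0.0 <= res.p_two_sided <= 1.0

    def test_all_ties_degenerate(self):
        res = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.method == "degenerate"
        assert res.p_two_sided == 1.0
        assert res.u_first_sample == 3.0  # n1*n2/2

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def test_holm_adjustment_monotone_and_bounded():
    p = [0.01, 0.04, 0.03, 0.5]
    adj = holm_adjust(p)
    assert all(0 <= a <= 1 for a in adj)
    assert adj[0] == pytest.approx(0.04)
    assert adj[3] == pytest.approx(0.5)


@pytest.fixture(scope="module")
def self_report():
    texts = {
        f"d{i}": f"de patiënt {i} heeft rugpijn en oefent dagelijks "
                 f"met schema nummer {i % 3}"
        for i in range(6)
    }
    ref = make_corpus("pseudonymized", texts)
    syn = make_corpus("synthetic", texts)
    return compare_corpora(ref, syn, folds=3, seed=1)


class TestCompareCorpora:
    def test_self_comparison_is_degenerate(self, self_report):
        assert self_report.corpus_row("inter_corpus_word_jsd")["synthetic"] == 0.0
        assert self_report.corpus_row("bleu_score")["synthetic"] == pytest.approx(100.0)
        for row in self_report.corpus_rows:
            if row.get("p_value") is not None:
                assert row["p_value"] >= 0.9
                assert row.get("u_method") in ("degenerate", "normal_approx", "exact")

    def test_report_schema_stable_and_complete(self, self_report):
        metrics = [r["metric"] for r in self_report.corpus_rows]
        for expected in (
            "corpus_shannon_entropy_char", "corpus_shannon_entropy_word",
            "mean_per_doc_shannon_entropy_char", "mean_per_doc_shannon_entropy_word",
            "inter_corpus_word_jsd", "mean_per_doc_jsd_vs_combined",
            "corpus_avg_bigram_pmi_minfreq3", "mean_per_doc_bigram_pmi",
            "mean_doc_length_chars", "bleu_score", "semantic_f1",
            "classifier_auc", "classifier_auprc",
        ):
            assert expected in metrics
        assert len(self_report.per_document_table) == 12
        assert all(0 <= r["p_value"] <= 1 for r in self_report.corpus_rows
                   if r.get("p_value") is not None)

    def test_deterministic_given_config(self):
        texts_r = {f"r{i}": f"rugpijn nummer {i} bij zitten en lopen" for i in range(5)}
        texts_s = {f"s{i}": f"fictieve klacht {i} bij fietsen" for i in range(5)}
        ref, syn = make_corpus("p", texts_r), make_corpus("s", texts_s)
        a = compare_corpora(ref, syn, folds=3, seed=9)
        b = compare_corpora(ref, syn, folds=3, seed=9)
        assert a.to_dict() == b.to_dict()

    def test_complete_separation_gives_significant_length_test(self, rng):
        vocab = ["rug", "pijn", "zit", "loop"]

        def doc(n):
            return " ".join(vocab[i] for i in rng.integers(0, 4, size=n))

        ref = make_corpus("p", {f"r{i}": doc(300 + int(rng.integers(50)))
                                for i in range(13)})
        syn = make_corpus("s", {f"s{i}": doc(60 + int(rng.integers(20)))
                                for i in range(20)})
        report = compare_corpora(ref, syn, folds=5, seed=3)
        row = report.corpus_row("per_doc_length_chars")
        assert row["u_statistic"] == 260.0
        assert row["p_value"] < 0.001


class TestModelObjects:
    def test_fit_returns_results_with_summary(self, two_small_corpora):
        ref, syn = two_small_corpora
        results = CorpusComparison(ref, syn, folds=2, seed=5).fit()
        text = results.summary()
        assert "bleu_score" in text
        assert "classifier_auc" in text
        assert results.report.config_echo["folds"] == 2

    def test_config_and_overrides_are_exclusive(self, two_small_corpora):
        ref, syn = two_small_corpora
        with pytest.raises(TypeError):
            CorpusComparison(ref, syn, config=ComparisonConfig(), folds=3)

    def test_from_directories(self, tmp_path, two_small_corpora):
        from corpus_fidelity import write_corpus

        ref, syn = two_small_corpora
        write_corpus(ref, tmp_path / "ref")
        write_corpus(syn, tmp_path / "syn")
        model = CorpusComparison.from_directories(
            tmp_path / "ref", tmp_path / "syn", folds=2, seed=1
        )
        results = model.fit()
        assert results.report.config_echo["seed"] == 1

    def test_results_save_round_trip(self, tmp_path, two_small_corpora):
        from corpus_fidelity import read_report

        ref, syn = two_small_corpora
        results = CorpusComparison(ref, syn, folds=2, seed=5).fit()
        paths = results.save(tmp_path)
        assert read_report(paths["json"]).to_dict() == results.report.to_dict()
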