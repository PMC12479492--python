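"""Corpus-versus-corpus statistical comparison and report assembly.

The central entry point is :class:`CorpusComparison`, a model object built
from a reference and a synthetic corpus whose :meth:`~CorpusComparison.fit`
runs the full metric battery — pooled and mean per-document entropies,
inter-corpus and per-document Jensen-Shannon divergence, average bigram PMI,
document lengths, corpus BLEU, greedy embedding matching, and the
machine-discernibility test — and returns a :class:`ComparisonResults`
carrying the per-document table, the corpus-level rows with Mann-Whitney U
statistics and two-sided p-values, and a ``summary()`` table.

Per-document metric lists are compared with the Mann-Whitney U test, the
first sample being the reference corpus.  No multiple-testing correction is
applied by default; a Holm-adjusted column is available on request.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .corpus_io import (
    Corpus,
    MetricReport,
    PER_DOC_FEATURES,
    write_report,
)
from .discernibility import discernibility_test
from .info_metrics import (
    CorpusProfile,
    corpus_profile,
    corpus_word_distribution,
    jensen_shannon_divergence,
)
from .overlap_metrics import corpus_bleu
from .semantic_match import corpus_semantic_score, hash_embedder


@dataclass(frozen=True)
class UTestResult:
    """Mann-Whitney U of the first sample, with a two-sided p-value.

    ``method`` is ``exact`` (tie-free, n1+n2 <= 40), ``normal_approx``
    (continuity and tie corrected) or ``degenerate`` (all observations
    tied across both samples, p fixed at 1).
    """

    u_first_sample: float
    p_two_sided: float
    n1: int
    n2: int
    method: str


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> UTestResult:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    U(x) counts pairs (i, j) with x_i > y_j plus half the tied pairs, so
    U(x) + U(y) = n1*n2.  Exact p by enumeration when the samples are
    tie-free and n1+n2 <= 40, else the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return UTestResult(n1 * n2 / 2.0, 1.0, n1, n2, "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n1 + n2 <= 40:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approx"
    return UTestResult(float(res.statistic), float(min(res.pvalue, 1.0)), n1, n2, method)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p_values[idx]))
        adjusted[idx] = running
    return adjusted


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonConfig:
    """Full parameter set of a comparison run (echoed into the report)."""

    pmi_min_freq: int = 3
    doc_pmi_min_freq: int = 1
    bleu_max_n: int = 4
    bleu_pairing: str = "multi_reference"
    semantic_aggregation: str = "all_pairs"
    embedder_dim: int = 256
    folds: int = 5
    seed: int = 42
    strip_markdown: bool = True
    jsd_sqrt: bool = False
    lowercase_chars: bool = False
    holm: bool = False


class CorpusComparison:
    """Model: holistic fidelity comparison of a synthetic corpus against a
    reference corpus.  ``fit()`` computes everything and returns
    :class:`ComparisonResults`."""

    def __init__(self, reference: Corpus, synthetic: Corpus,
                 config: ComparisonConfig | None = None, **overrides):
        if config is None:
            config = ComparisonConfig(**overrides)
        elif overrides:
            raise TypeError("pass either a ComparisonConfig or keyword overrides, not both")
        self.reference = reference
        self.synthetic = synthetic
        self.config = config

    @classmethod
    def from_directories(cls, reference_dir, synthetic_dir, pattern: str = "*",
                         config: ComparisonConfig | None = None, **overrides):
        from .corpus_io import read_corpus

        cfg = config or ComparisonConfig(**overrides)
        ref = read_corpus(reference_dir, pattern, label="pseudonymized",
                          strip=cfg.strip_markdown)
        syn = read_corpus(synthetic_dir, pattern, label="synthetic",
                          strip=cfg.strip_markdown)
        return cls(ref, syn, config=cfg)

    def fit(self) -> "ComparisonResults":
        cfg = self.config
        ref, syn = self.reference, self.synthetic

        combined_pool = corpus_word_distribution(ref).merge(corpus_word_distribution(syn))
        prof_ref = corpus_profile(
            ref, cfg.pmi_min_freq, doc_pmi_min_freq=cfg.doc_pmi_min_freq,
            pool=combined_pool, jsd_sqrt=cfg.jsd_sqrt, lowercase_chars=cfg.lowercase_chars,
        )
        prof_syn = corpus_profile(
            syn, cfg.pmi_min_freq, doc_pmi_min_freq=cfg.doc_pmi_min_freq,
            pool=combined_pool, jsd_sqrt=cfg.jsd_sqrt, lowercase_chars=cfg.lowercase_chars,
        )

        inter_jsd = jensen_shannon_divergence(
            corpus_word_distribution(ref), corpus_word_distribution(syn),
            sqrt=cfg.jsd_sqrt,
        )
        bleu = corpus_bleu(syn, ref, max_n=cfg.bleu_max_n, pairing=cfg.bleu_pairing)
        semantic = corpus_semantic_score(
            syn, ref, hash_embedder(cfg.seed, cfg.embedder_dim),
            aggregation=cfg.semantic_aggregation,
        )
        disc = discernibility_test(ref, syn, folds=cfg.folds, seed=cfg.seed)

        report = _assemble_report(
            ref, syn, prof_ref, prof_syn, inter_jsd, bleu, semantic, disc, cfg
        )
        return ComparisonResults(self, report, prof_ref, prof_syn, bleu, semantic, disc)


class ComparisonResults:
    """Fitted comparison: report, profiles and component results."""

    def __init__(self, model, report: MetricReport, profile_reference: CorpusProfile,
                 profile_synthetic: CorpusProfile, bleu, semantic, discernibility):
        self.model = model
        self.report = report
        self.profile_reference = profile_reference
        self.profile_synthetic = profile_synthetic
        self.bleu = bleu
        self.semantic = semantic
        self.discernibility = discernibility

    def save(self, out_dir) -> dict:
        return write_report(self.report, out_dir)

    def summary(self) -> str:
        """Plain-text corpus-level comparison table."""
        cfg = self.model.config
        ref_label = self.model.reference.label
        syn_label = self.model.synthetic.label
        lines = [
            f"Corpus fidelity comparison: {ref_label} (n={len(self.model.reference)}) "
            f"vs {syn_label} (n={len(self.model.synthetic)})",
            "=" * 82,
            f"{'metric':<42}{'ref':>11}{'synth':>11}{'U':>8}{'p':>10}",
            "-" * 82,
        ]
        for row in self.report.corpus_rows:
            def _fmt(v, width):
                if v is None:
                    return " " * (width - 1) + "-"
                return f"{v:>{width}.4g}"
            lines.append(
                f"{row['metric']:<42}"
                + _fmt(row.get("reference"), 11)
                + _fmt(row.get("synthetic"), 11)
                + _fmt(row.get("u_statistic"), 8)
                + _fmt(row.get("p_value"), 10)
            )
        lines.append("-" * 82)
        lines.append(
            f"config: pmi_min_freq={cfg.pmi_min_freq}, bleu_max_n={cfg.bleu_max_n}, "
            f"folds={cfg.folds}, seed={cfg.seed}"
        )
        return "\n".join(lines)


def _per_doc_rows(label: str, corpus: Corpus, profile: CorpusProfile) -> list[dict]:
    rows = []
    for doc, p in zip(corpus, profile.per_doc_profiles):
        values = (
            p.size_mb, p.word_count, p.unique_word_count, p.char_length,
            p.char_entropy_bits, p.word_entropy_bits, p.avg_bigram_pmi_bits,
            p.jsd_vs_pool,
        )
        row = {"corpus": label, "id": doc.id}
        row.update({name: v for name, v in zip(PER_DOC_FEATURES, values)})
        rows.append(row)
    return rows


def _u_row(metric: str, ref_vals: list, syn_vals: list) -> dict:
    ref_vals = [v for v in ref_vals if v is not None]
    syn_vals = [v for v in syn_vals if v is not None]
    test = mann_whitney_u(ref_vals, syn_vals)
    return {
        "metric": metric,
        "reference": float(np.mean(ref_vals)),
        "synthetic": float(np.mean(syn_vals)),
        "u_statistic": test.u_first_sample,
        "p_value": test.p_two_sided,
        "u_method": test.method,
    }


def _plain_row(metric: str, reference=None, synthetic=None) -> dict:
    return {"metric": metric, "reference": reference, "synthetic": synthetic,
            "u_statistic": None, "p_value": None}


def _assemble_report(ref: Corpus, syn: Corpus, prof_ref, prof_syn, inter_jsd,
                     bleu, semantic, disc, cfg: ComparisonConfig) -> MetricReport:
    pr, ps = prof_ref.per_doc_profiles, prof_syn.per_doc_profiles
    rows = [
        _plain_row("corpus_shannon_entropy_char",
                   prof_ref.pooled_char_entropy_bits, prof_syn.pooled_char_entropy_bits),
        _plain_row("corpus_shannon_entropy_word",
                   prof_ref.pooled_word_entropy_bits, prof_syn.pooled_word_entropy_bits),
        _u_row("mean_per_doc_shannon_entropy_char",
               [p.char_entropy_bits for p in pr], [p.char_entropy_bits for p in ps]),
        _u_row("mean_per_doc_shannon_entropy_word",
               [p.word_entropy_bits for p in pr], [p.word_entropy_bits for p in ps]),
        _plain_row("inter_corpus_word_jsd", synthetic=inter_jsd),
        _u_row("mean_per_doc_jsd_vs_combined",
               [p.jsd_vs_pool for p in pr], [p.jsd_vs_pool for p in ps]),
        _plain_row(f"corpus_avg_bigram_pmi_minfreq{cfg.pmi_min_freq}",
                   prof_ref.corpus_avg_bigram_pmi_bits, prof_syn.corpus_avg_bigram_pmi_bits),
        _u_row("mean_per_doc_bigram_pmi",
               [p.avg_bigram_pmi_bits for p in pr], [p.avg_bigram_pmi_bits for p in ps]),
        _plain_row("mean_doc_length_chars",
                   prof_ref.mean_doc_length_chars, prof_syn.mean_doc_length_chars),
        _u_row("per_doc_length_chars",
               [p.char_length for p in pr], [p.char_length for p in ps]),
        _plain_row("bleu_score", synthetic=bleu.score),
        _plain_row("semantic_precision", synthetic=semantic.precision),
        _plain_row("semantic_recall", synthetic=semantic.recall),
        _plain_row("semantic_f1", synthetic=semantic.f1),
        _plain_row("classifier_precision", synthetic=disc.precision),
        _plain_row("classifier_recall", synthetic=disc.recall),
        _plain_row("classifier_f1", synthetic=disc.f1),
        _plain_row("classifier_auc", synthetic=disc.auc),
        _plain_row("classifier_auprc", synthetic=disc.auprc),
        _plain_row("classifier_auc_length_only", synthetic=disc.ablation_auc_length_only),
        _plain_row("classifier_auc_tfidf_only", synthetic=disc.ablation_auc_tfidf_only),
    ]
    if cfg.holm:
        p_rows = [r for r in rows if r.get("p_value") is not None]
        adjusted = holm_adjust([r["p_value"] for r in p_rows])
        for r, padj in zip(p_rows, adjusted):
            r["p_holm"] = padj

    per_doc = _per_doc_rows(ref.label, ref, prof_ref) + _per_doc_rows(
        syn.label, syn, prof_syn
    )
    return MetricReport(
        per_document_table=per_doc,
        corpus_rows=rows,
        config_echo={
            **asdict(cfg),
            "pmi_excluded_docs_reference": prof_ref.pmi_excluded_docs,
            "pmi_excluded_docs_synthetic": prof_syn.pmi_excluded_docs,
            "semantic_embedder": semantic.embedder,
            "semantic_pair_count": semantic.pair_count,
            "bleu_brevity_penalty": bleu.brevity_penalty,
            "classifier_top_features": [list(t) for t in disc.top_features],
        },
    )


def compare_corpora(reference: Corpus, synthetic: Corpus,
                    config: ComparisonConfig | None = None, **overrides) -> MetricReport:
    """Functional wrapper: fit a :class:`CorpusComparison` and return its report."""
    results = CorpusComparison(reference, synthetic, config=config, **overrides).fit()
    return results.report
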