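import numpy as np
import pytest

from corpus_fidelity import Corpus, Document


def make_doc(doc_id: str, text: str) -> Document:
    return Document.from_text(id=doc_id, raw_text=text)


def make_corpus(label: str, texts: dict[str, str]) -> Corpus:
    return Corpus(label, [make_doc(i, t) for i, t in texts.items()])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_small_corpora():
    ref = make_corpus(
        "pseudonymized",
        {
            "r1": "de patiënt heeft lage rugpijn en de pijn straalt uit",
            "r2": "de oefeningen gaan goed en de pijn neemt af",
            "r3": "patiënt meldt stijfheid in de ochtend en pijn bij zitten",
        },
    )
    syn = make_corpus(
        "synthetic",
        {
            "s1": "de fictieve patiënt beschrijft rugklachten bij lopen",
            "s2": "oefenschema aangepast en de klachten nemen af",
        },
    )
    return ref, syn
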