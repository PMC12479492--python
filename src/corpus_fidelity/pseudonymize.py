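"""Deterministic rule-based pseudonymization of clinical note text.

Detects e-mail addresses, phone-like digit runs, date formats, elfproef-valid
nine-digit citizen service numbers (BSN) and gazetteer-listed person names,
and replaces them: names by fictive names (chosen deterministically by seed
and consistent within one document), other categories by bracketed
placeholders.  Every replacement is recorded in a character-offset audit log
that replays exactly.

Transparent regex + gazetteer rules are used deliberately: the module is a
testable, offline de-identification stage whose recall on free text is
necessarily below that of a statistical or neural NER system — a documented
limitation, not a hidden one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CATEGORIES = ("name", "address", "phone", "email", "date_of_birth", "bsn",
              "insurance", "financial")


def bsn_is_valid(digits: str) -> bool:
    """Dutch elfproef: sum_{i=1..8} d_i*(10-i) - d_9 divisible by 11,
    excluding the all-zero string.  ``digits`` must be exactly 9 ASCII digits."""
    if len(digits) != 9 or not digits.isascii() or not digits.isdigit():
        raise ValueError("BSN check requires exactly 9 ASCII digits")
    if digits == "000000000":
        return False
    total = sum(int(d) * (9 - i) for i, d in enumerate(digits[:8])) - int(digits[8])
    return total % 11 == 0


@dataclass(frozen=True)
class Replacement:
    category: str
    original_span: tuple[int, int]  # 0-based, half-open, Unicode characters
    original: str
    replacement: str


@dataclass
class ReplacementLog:
    entries: list[Replacement] = field(default_factory=list)

    def replay(self, original_text: str) -> str:
        """Apply the logged replacements right-to-left; reproduces the output."""
        text = original_text
        for e in sorted(self.entries, key=lambda e: e.original_span[0], reverse=True):
            s, t = e.original_span
            text = text[:s] + e.replacement + text[t:]
        return text


_EMAIL_RE = re.compile(r"[\w.+-]+@[\w-]+(?:\.[\w-]+)+")
_PHONE_RE = re.compile(r"(?<![\d\w])(?:\+31[-\s]?|0)\d{1,3}[-\s]?\d{6,8}(?![\d\w])")
_DATE_RE = re.compile(
    r"(?<!\d)(?:\d{1,2}[-/]\d{1,2}[-/]\d{2,4}|\d{4}[-/]\d{1,2}[-/]\d{1,2})(?!\d)"
)
_DIGIT_RUN_RE = re.compile(r"(?<!\d)\d{9}(?!\d)")

_PLACEHOLDER = {
    "email": "[EMAIL]",
    "phone": "[PHONE]",
    "date_of_birth": "[DATE]",
    "bsn": "[BSN]",
    "address": "[ADDRESS]",
    "insurance": "[INSURANCE]",
    "financial": "[FINANCIAL]",
}


def pseudonymize_text(
    text: str,
    fictive_names: Sequence[str],
    seed: int = 0,
    gazetteer: Sequence[str] = (),
) -> tuple[str, ReplacementLog]:
    """Replace personal identifiers in ``text``; returns (new text, audit log).

    ``gazetteer`` lists the true person names to replace; each distinct name
    maps to one fictive name chosen deterministically from ``fictive_names``
    by ``seed``, consistently within the document.  Spans in the log refer to
    the input text and are non-overlapping.
    """
    if not fictive_names:
        raise ValueError("fictive_names must be non-empty")

    matches: list[tuple[int, int, str, str]] = []  # (start, end, category, original)

    def _collect(regex: re.Pattern, category: str) -> None:
        for m in regex.finditer(text):
            matches.append((m.start(), m.end(), category, m.group(0)))

    _collect(_EMAIL_RE, "email")
    _collect(_PHONE_RE, "phone")
    _collect(_DATE_RE, "date_of_birth")
    for m in _DIGIT_RUN_RE.finditer(text):
        if bsn_is_valid(m.group(0)):
            matches.append((m.start(), m.end(), "bsn", m.group(0)))
    for name in gazetteer:
        for m in re.finditer(rf"\b{re.escape(name)}\b", text):
            matches.append((m.start(), m.end(), "name", m.group(0)))

    # earliest-start wins; longer match breaks ties; drop overlaps
    matches.sort(key=lambda t: (t[0], -(t[1] - t[0])))
    selected: list[tuple[int, int, str, str]] = []
    last_end = -1
    for start, end, category, original in matches:
        if start >= last_end:
            selected.append((start, end, category, original))
            last_end = end

    rng = np.random.default_rng(seed)
    name_map: dict[str, str] = {}
    log = ReplacementLog()
    for start, end, category, original in selected:
        if category == "name":
            if original not in name_map:
                name_map[original] = fictive_names[int(rng.integers(len(fictive_names)))]
            repl = name_map[original]
        else:
            repl = _PLACEHOLDER[category]
        log.entries.append(Replacement(category, (start, end), original, repl))

    return log.replay(text), log
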