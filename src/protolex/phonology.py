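"""Spanish orthography-to-phonology conversion.

Orthographic stimuli are converted to phoneme sequences by a deterministic
table of context-sensitive rewrite rules (longest match first, left to
right).  The table is a documented simplification of standard Spanish
spelling-to-sound conventions: digraphs (ch, ll, rr, qu, gu+e/i) map to
single phonemes, accented vowels map to the same phoneme as their plain
counterparts, and ⟨h⟩ is silent.  Accent marks are not carried into the
phonological form; their presence is exposed separately as an orthographic
covariate (`orth_features`), since visually salient non-English characters
⟨á é í ó ú ñ⟩ are modeled as a predictor in their own right.

The default dialect is seseo (⟨c⟩ before front vowels and ⟨z⟩ → /s/);
``dialect="distincion"`` maps them to /θ/ instead.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

START = "⟨"
END = "⟩"

#: characters whose presence defines the accent-character covariate
ACCENT_CHARS = frozenset("áéíóúñ")

_SPANISH_ALPHABET = frozenset("abcdefghijklmnopqrstuvwxyzáéíóúñü")


class ConversionError(ValueError):
    """Raised when no rewrite rule applies at some position."""

    def __init__(self, text: str, position: int):
        self.text = text
        self.position = position
        super().__init__(
            f"no rule applies to character {text[position]!r} "
            f"at position {position} in {text!r}"
        )


@dataclass(frozen=True)
class OrthForm:
    """A lowercase orthographic form restricted to the Spanish alphabet."""

    text: str
    has_accent_char: bool = field(init=False)
    orth_length: int = field(init=False)

    def __post_init__(self):
        text = unicodedata.normalize("NFC", self.text)
        object.__setattr__(self, "text", text)
        if not text:
            raise ValueError("orthographic form must be non-empty")
        bad = set(text) - _SPANISH_ALPHABET
        if bad:
            raise ValueError(f"characters outside the Spanish alphabet: {sorted(bad)}")
        object.__setattr__(self, "has_accent_char", bool(set(text) & ACCENT_CHARS))
        object.__setattr__(self, "orth_length", len(text))


@dataclass(frozen=True)
class PhonForm:
    """A phoneme sequence over a fixed symbol alphabet.

    START/END markers are reserved for language-model padding and never
    appear inside the sequence.
    """

    phonemes: tuple[str, ...]
    source: OrthForm | None = None

    def __post_init__(self):
        if len(self.phonemes) < 1:
            raise ValueError("phonological form must contain at least one phoneme")
        if START in self.phonemes or END in self.phonemes:
            raise ValueError("START/END markers may not appear inside a form")

    @property
    def phon_length(self) -> int:
        return len(self.phonemes)


@dataclass(frozen=True)
class Rule:
    pattern: str
    left_context: str  # string of admissible preceding chars, "" = any, "#" = boundary
    right_context: str
    phonemes: tuple[str, ...]  # may be empty (silent grapheme)
    priority: int = 1


class RuleTable:
    """Ordered grapheme→phoneme rules, applied longest-match-first."""

    def __init__(self, rules: list[Rule], extra_symbols: tuple[str, ...] = ()):
        # longest pattern first, then priority; stable for ties
        self.rules = sorted(rules, key=lambda r: (-len(r.pattern), -r.priority))
        self.extra_symbols = tuple(extra_symbols)

    def alphabet(self) -> frozenset[str]:
        """The phoneme alphabet Σ implied by the table (plus extra symbols)."""
        syms = {p for r in self.rules for p in r.phonemes}
        return frozenset(syms | set(self.extra_symbols))

    def _match(self, text: str, i: int) -> Rule | None:
        for rule in self.rules:
            j = i + len(rule.pattern)
            if text[i:j] != rule.pattern:
                continue
            left = text[i - 1] if i > 0 else "#"
            right = text[j] if j < len(text) else "#"
            if rule.left_context and left not in rule.left_context:
                continue
            if rule.right_context and right not in rule.right_context:
                continue
            return rule
        return None

    def apply(self, text: str) -> tuple[str, ...]:
        out: list[str] = []
        i = 0
        while i < len(text):
            rule = self._match(text, i)
            if rule is None:
                raise ConversionError(text, i)
            out.extend(rule.phonemes)
            i += len(rule.pattern)
        return tuple(out)


def load_rules(
    path: str | Path | None = None,
    dialect: str = "seseo",
    extra_symbols: tuple[str, ...] = (),
) -> RuleTable:
    """Load a rewrite-rule table from TSV.

    Columns: pattern, left_context, right_context, phonemes (space-separated,
    "-" for silence), priority, and an optional dialect marker.  Rows marked
    ``szeta`` emit /s/ under seseo (default) and /θ/ under distinción.
    """
    if dialect not in ("seseo", "distincion"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if path is None:
        src = resources.files("protolex").joinpath("data/spanish_g2p.tsv")
        lines = src.read_text(encoding="utf-8").splitlines()
    else:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    rules = []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        parts += [""] * (6 - len(parts))
        pattern, left, right, phon, prio, var = parts[:6]
        phonemes = tuple(p for p in phon.split() if p != "-")
        if var == "szeta" and dialect == "distincion":
            phonemes = tuple("θ" if p == "s" else p for p in phonemes)
        rules.append(Rule(pattern, left, right, phonemes, int(prio or 1)))
    return RuleTable(rules, extra_symbols=extra_symbols)


def to_phonemes(orth: OrthForm | str, rules: RuleTable) -> PhonForm:
    """Convert an orthographic form to phonemes. Deterministic per table."""
    if isinstance(orth, str):
        orth = OrthForm(orth)
    return PhonForm(rules.apply(orth.text), source=orth)


def orth_features(orth: OrthForm | str) -> tuple[bool, int]:
    """(has_accent_char, orth_length) — the orthographic covariates."""
    if isinstance(orth, str):
        orth = OrthForm(orth)
    return orth.has_accent_char, orth.orth_length
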