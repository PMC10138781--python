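"""Witten-Bell-smoothed trigram models over symbol sequences.

The phonotactic (or orthotactic) score of a form is the length-normalized
average conditional log-probability (base 10) of its symbols under a
trigram model with interpolated Witten-Bell smoothing:

    P(w | h) = (c(hw) + T(h) · P(w | h')) / (c(h·) + T(h))

where h' drops the oldest symbol of the history h, T(h) is the number of
distinct symbols observed after h, and the recursion bottoms out in a
uniform distribution over Σ ∪ {END}.  Each training form is padded as
⟨⟨ … ⟩ (double START, single END), so the first symbol is conditioned on
the word boundary.  A score of −1.2 corresponds to an average conditional
probability of 10^−1.2 ≈ 1/16 per symbol.

Training is type-based by default (each distinct form counts once); a
weights argument supports token- or frequency-weighted counting, used for
morph inventories.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Sequence

from .phonology import START, END

Symbol = str
History = tuple[Symbol, ...]


@dataclass(frozen=True)
class PhonotacticScore:
    """Average conditional log10-probability per symbol; always ≤ 0."""

    value: float
    n_symbols: int


def per_symbol_probability(score: float) -> float:
    """Invert a phonotactic score to the average per-symbol probability."""
    return 10.0 ** score


class WittenBellTrigram:
    """Interpolated Witten-Bell trigram model over a symbol alphabet."""

    def __init__(self, alphabet: frozenset[Symbol], counts, totals, distinct,
                 unit: str = "word", training: str = "type", source: str = ""):
        self.alphabet = frozenset(alphabet)
        self._counts = counts        # history tuple -> {symbol: weight}
        self._totals = totals        # history tuple -> total weight c(h·)
        self._distinct = distinct    # history tuple -> T(h)
        self.unit = unit
        self.training = training
        self.source = source
        self._uniform = 1.0 / (len(self.alphabet) + 1)  # over Σ ∪ {END}

    # -- training ---------------------------------------------------------

    @classmethod
    def train(cls, forms: Iterable[Sequence[Symbol]],
              weights: Sequence[float] | None = None,
              alphabet: frozenset[Symbol] | None = None,
              unit: str = "word", source: str = "") -> "WittenBellTrigram":
        forms = [tuple(f) for f in forms]
        if not forms:
            raise ValueError("training set must contain at least one form")
        if weights is not None:
            weights = list(weights)
            if len(weights) != len(forms):
                raise ValueError("weights must match forms in length")
            if any(w < 0 for w in weights):
                raise ValueError("weights must be nonnegative")
        else:
            weights = [1.0] * len(forms)
        if alphabet is None:
            alphabet = frozenset(s for f in forms for s in f)
        else:
            alphabet = frozenset(alphabet)
            for f in forms:
                for s in f:
                    if s not in alphabet:
                        raise ValueError(f"symbol {s!r} outside alphabet")
        counts: dict[History, dict[Symbol, float]] = defaultdict(Counter)
        for form, w in zip(forms, weights):
            if w == 0:
                continue
            seq = (START, START) + form + (END,)
            for i in range(2, len(seq)):
                sym = seq[i]
                counts[seq[i - 2:i]][sym] += w
                counts[seq[i - 1:i]][sym] += w
                counts[()][sym] += w
        totals = {h: sum(c.values()) for h, c in counts.items()}
        distinct = {h: sum(1 for v in c.values() if v > 0) for h, c in counts.items()}
        training = "type" if all(w == 1 for w in weights) else "weighted"
        return cls(alphabet, dict(counts), totals, distinct,
                   unit=unit, training=training, source=source)

    # -- probabilities ----------------------------------------------------

    def cond_prob(self, history: Sequence[Symbol], symbol: Symbol) -> float:
        """P(symbol | history) with full backoff on unseen histories."""
        if symbol not in self.alphabet and symbol != END:
            raise ValueError(f"symbol {symbol!r} outside alphabet")
        h = tuple(history)[-2:]
        for s in h:
            if s not in self.alphabet and s != START:
                raise ValueError(f"history symbol {s!r} outside alphabet")
        return self._p(h, symbol)

    def _p(self, h: History, w: Symbol) -> float:
        if not h:
            c = self._counts.get((), {})
            t = self._distinct.get((), 0)
            total = self._totals.get((), 0.0)
            # uniform base distribution over Σ ∪ {END}
            return (c.get(w, 0.0) + t * self._uniform) / (total + t) if total + t > 0 \
                else self._uniform
        total = self._totals.get(h, 0.0)
        t = self._distinct.get(h, 0)
        lower = self._p(h[1:], w)
        if total + t == 0:
            return lower  # unseen history: back off fully
        c = self._counts.get(h, {}).get(w, 0.0)
        return (c + t * lower) / (total + t)

    # -- scoring ----------------------------------------------------------

    def score(self, form: Sequence[Symbol], include_end: bool = False) -> PhonotacticScore:
        """Length-normalized base-10 log-probability of a form.

        The END transition is excluded from both the sum and the length by
        default; ``include_end=True`` adds it to both.
        """
        form = tuple(form)
        if not form:
            raise ValueError("cannot score an empty form")
        seq = (START, START) + form + ((END,) if include_end else ())
        total = 0.0
        for i in range(2, len(seq)):
            total += math.log10(self._p(seq[i - 2:i], seq[i]))
        n = len(seq) - 2
        return PhonotacticScore(total / n, n)

    def score_value(self, form: Sequence[Symbol], include_end: bool = False) -> float:
        return self.score(form, include_end=include_end).value

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "alphabet": sorted(self.alphabet),
            "unit": self.unit,
            "training": self.training,
            "source": self.source,
            "counts": {" ".join(h): dict(c) for h, c in self._counts.items()},
        }
        text = json.dumps(payload, ensure_ascii=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "WittenBellTrigram":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        payload = json.loads(text)
        counts = {tuple(h.split(" ")) if h else (): dict(c)
                  for h, c in payload["counts"].items()}
        totals = {h: sum(c.values()) for h, c in counts.items()}
        distinct = {h: sum(1 for v in c.values() if v > 0) for h, c in counts.items()}
        return cls(frozenset(payload["alphabet"]), counts, totals, distinct,
                   unit=payload["unit"], training=payload["training"],
                   source=payload["source"])


def train_trigram(forms: Iterable[Sequence[Symbol]],
                  weights: Sequence[float] | None = None,
                  **kwargs) -> WittenBellTrigram:
    return WittenBellTrigram.train(forms, weights=weights, **kwargs)


def phonotactic_score(model: WittenBellTrigram, form: Sequence[Symbol],
                      include_end: bool = False) -> PhonotacticScore:
    return model.score(form, include_end=include_end)
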