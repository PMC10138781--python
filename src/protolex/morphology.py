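"""Unsupervised morph segmentation by minimum description length.

A morph inventory is learned from word types by greedy recursive binary
splitting.  The objective is a two-part code length:

* lexicon cost — each distinct morph type is encoded symbol by symbol
  under a unigram symbol model, with a geometric length prior (each
  additional symbol costs −log(1 − p_end), ending a morph costs
  −log p_end);
* corpus cost — each morph usage across word types costs −log of the
  morph's relative frequency among all morph tokens.

Words are visited in seeded random order; for each word the learner
compares keeping the string whole against every binary split (recursing
into accepted halves) and accepts a split only if total cost strictly
decreases.  Passes repeat until no split is accepted.  The procedure is
analogous to a naive listener segmenting recurring subsequences out of a
wordform stream without access to meaning.

After learning, token frequencies (word frequency × occurrences within
the word) are attached to morphs for frequency-weighted sampling, and a
unigram Viterbi parser segments arbitrary forms, falling back to
single-symbol morphs at a floor probability so every form receives a
finite parse.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ngram import WittenBellTrigram, PhonotacticScore

Form = tuple[str, ...]


@dataclass
class Segmentation:
    parts: tuple[Form, ...]
    score: float  # log-probability under the unigram morph model

    def __post_init__(self):
        if not self.parts:
            raise ValueError("segmentation must have at least one part")


@dataclass
class MorphInventory:
    """Morph types with usage counts and the final MDL objective."""

    segmentations: dict[Form, tuple[Form, ...]]
    type_counts: Counter  # morph -> number of usages across word types
    token_freq: Counter = field(default_factory=Counter)
    total_cost: float = float("nan")
    cost_history: list[float] = field(default_factory=list)

    @property
    def morphs(self) -> set[Form]:
        return set(self.type_counts)

    def __len__(self) -> int:
        return len(self.type_counts)

    def attach_frequencies(self, word_freqs: Mapping[Form, float]) -> None:
        """Token frequency of a morph = Σ over containing words of
        word frequency × number of occurrences within the word."""
        tf: Counter = Counter()
        for word, parts in self.segmentations.items():
            f = word_freqs.get(word, 0.0)
            for m in parts:
                tf[m] += f
        self.token_freq = tf

    def restrict(self, morphs: Sequence[Form]) -> "MorphInventory":
        """A sub-inventory over the given morph sample (for Monte Carlo)."""
        keep = set(morphs)
        return MorphInventory(
            segmentations={},
            type_counts=Counter({m: self.type_counts[m] for m in keep if m in self.type_counts}),
            token_freq=Counter({m: self.token_freq[m] for m in keep if m in self.token_freq}),
        )

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("morph\ttype_count\ttoken_frequency\n")
            for m in sorted(self.type_counts):
                fh.write(f"{' '.join(m)}\t{self.type_counts[m]}\t{self.token_freq.get(m, 0)}\n")


class _MDLState:
    """Incrementally maintained two-part code length."""

    def __init__(self, symbol_logp: dict[str, float], p_end: float):
        self.symbol_logp = symbol_logp
        self.log_pend = math.log(p_end)
        self.log_cont = math.log(1.0 - p_end)
        self.counts: Counter = Counter()
        self.n_tokens = 0
        self._sum_clogc = 0.0   # Σ_m c_m ln c_m
        self.lex_cost = 0.0

    def _lexcost(self, m: Form) -> float:
        return (-sum(self.symbol_logp[s] for s in m)
                - (len(m) - 1) * self.log_cont - self.log_pend)

    def cost(self) -> float:
        n = self.n_tokens
        corpus = n * math.log(n) - self._sum_clogc if n > 0 else 0.0
        return corpus + self.lex_cost

    def add(self, m: Form, k: int = 1) -> None:
        c = self.counts[m]
        if c > 0:
            self._sum_clogc -= c * math.log(c)
        else:
            self.lex_cost += self._lexcost(m)
        c += k
        self.counts[m] = c
        self._sum_clogc += c * math.log(c)
        self.n_tokens += k

    def remove(self, m: Form, k: int = 1) -> None:
        c = self.counts[m]
        self._sum_clogc -= c * math.log(c)
        c -= k
        self.n_tokens -= k
        if c > 0:
            self.counts[m] = c
            self._sum_clogc += c * math.log(c)
        else:
            del self.counts[m]
            self.lex_cost -= self._lexcost(m)


def learn_morph_inventory(
    word_types: Sequence[Sequence[str]],
    seed: int = 0,
    p_end: float = 0.2,
    max_passes: int = 10,
) -> MorphInventory:
    """Learn a morph inventory from word types by recursive MDL splitting.

    Type-based: each word type contributes once regardless of frequency.
    Deterministic given the seed (which fixes the word-visit order).
    """
    words = [tuple(w) for w in word_types]
    if not words:
        raise ValueError("need at least one word type")
    words = sorted(set(words))

    sym_counts: Counter = Counter(s for w in words for s in w)
    total_syms = sum(sym_counts.values())
    symbol_logp = {s: math.log(c / total_syms) for s, c in sym_counts.items()}

    state = _MDLState(symbol_logp, p_end)
    seg: dict[Form, tuple[Form, ...]] = {w: (w,) for w in words}
    for w in words:
        state.add(w)

    rng = np.random.default_rng(seed)
    history = [state.cost()]

    def place(s: Form) -> tuple[Form, ...]:
        # cost of keeping s whole
        base = state.cost()
        state.add(s)
        whole_delta = state.cost() - base
        state.remove(s)
        best_i = None
        best_delta = whole_delta
        if len(s) > 1:
            for i in range(1, len(s)):
                left, right = s[:i], s[i:]
                state.add(left)
                state.add(right)
                delta = state.cost() - base
                state.remove(left)
                state.remove(right)
                if delta < best_delta - 1e-9:
                    best_delta = delta
                    best_i = i
        if best_i is None:
            state.add(s)
            return (s,)
        parts = place(s[:best_i]) + place(s[best_i:])
        # re-splitting the halves shifts counts, so the realized cost can
        # exceed the jointly evaluated two-part delta; keep whole if so
        if state.cost() - base > whole_delta - 1e-9:
            for m in parts:
                state.remove(m)
            state.add(s)
            return (s,)
        return parts

    for _ in range(max_passes):
        changed = False
        order = rng.permutation(len(words))
        for idx in order:
            w = words[idx]
            old = seg[w]
            c0 = state.cost()
            for m in old:
                state.remove(m)
            new = place(w)
            if state.cost() > c0 + 1e-9:  # strict-decrease acceptance
                for m in new:
                    state.remove(m)
                for m in old:
                    state.add(m)
                new = old
            if new != old:
                changed = True
            seg[w] = new
            c = state.cost()
            assert c <= history[-1] + 1e-6, "MDL objective increased"
            history.append(c)
        if not changed:
            break

    inv = MorphInventory(
        segmentations=seg,
        type_counts=Counter(state.counts),
        total_cost=state.cost(),
        cost_history=history,
    )
    return inv


def viterbi_segment(form: Sequence[str], inv: MorphInventory,
                    floor_factor: float = 0.5) -> Segmentation:
    """Best segmentation of a form under the unigram morph model.

    Maximizes Σ log(token_frequency(m) / total tokens); unseen substrings
    are admitted only as single-symbol fallback morphs at a floor
    probability of ``floor_factor`` × the smallest morph probability, so
    every form receives a finite-score parse.  Ties break toward fewer
    parts.
    """
    form = tuple(form)
    freqs = inv.token_freq if sum(inv.token_freq.values()) > 0 else inv.type_counts
    if not freqs:
        raise ValueError("morph inventory is empty")
    total = sum(freqs.values())
    logp = {m: math.log(f / total) for m, f in freqs.items() if f > 0}
    floor = min(logp.values()) + math.log(floor_factor)

    n = len(form)
    NEG = float("-inf")
    best = [(NEG, 0)] * (n + 1)  # (score, -n_parts)
    back = [0] * (n + 1)
    best[0] = (0.0, 0)
    for j in range(1, n + 1):
        for i in range(j):
            piece = form[i:j]
            lp = logp.get(piece)
            if lp is None:
                if j - i != 1:
                    continue
                lp = floor
            prev = best[i]
            if prev[0] == NEG:
                continue
            cand = (prev[0] + lp, prev[1] - 1)
            if cand[0] > best[j][0] + 1e-12 or (
                    cand[0] >= best[j][0] - 1e-12 and cand[1] > best[j][1]):
                best[j] = cand
                back[j] = i
    parts = []
    j = n
    while j > 0:
        i = back[j]
        parts.append(form[i:j])
        j = i
    parts.reverse()
    return Segmentation(tuple(parts), best[n][0])


def parsed_score(form: Sequence[str], morph_model: WittenBellTrigram,
                 inv: MorphInventory, parse: bool = True,
                 include_end: bool = False) -> PhonotacticScore:
    """Phonotactic score of a form treated as potentially multi-morphemic.

    The form is segmented against the (sampled) inventory and each part is
    scored with fresh START padding — the trigram context resets at every
    morph boundary.  The score is the total log-probability over all
    symbols divided by the total symbol count.  With ``parse=False`` the
    form is scored whole, as a single morph.
    """
    form = tuple(form)
    if not form:
        raise ValueError("cannot score an empty form")
    if parse:
        if len(inv) == 0:
            raise ValueError("morph inventory sample is empty")
        parts = viterbi_segment(form, inv).parts
    else:
        parts = (form,)
    total_lp = 0.0
    total_n = 0
    for part in parts:
        s = morph_model.score(part, include_end=include_end)
        total_lp += s.value * s.n_symbols
        total_n += s.n_symbols
    return PhonotacticScore(total_lp / total_n, total_n)
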