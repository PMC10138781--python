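"""Stimulus pool construction: frequency bins, matched nonwords, sessions.

Words are binned by corpus frequency (low: < 10 per million; mid: 10–100;
high: > 100).  Each word is paired with the candidate nonword closest to
it in phonotactic score among candidates matched for orthographic length,
phonemic length, and accent-character positions.  Experimental sessions
hold 240 critical trials sampled with per-group quotas proportional to
group pool sizes (largest-remainder rounding), in random order, plus 6
attention-check trials distributed evenly throughout, targeting the
leftmost, middle, and rightmost response buttons twice each.

Post-hoc exclusions drop stimuli orthographically identical to English
words (borrowings survive via an allowlist) and whole pairs whose
phonotactic match degraded beyond tolerance when the scoring system
changed between stimulus selection and analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .phonology import OrthForm, PhonForm, RuleTable, ACCENT_CHARS, to_phonemes

BINS = ("low", "mid", "high")


def assign_frequency_bin(freq_per_million: float) -> str:
    """low: f < 10; mid: 10 ≤ f ≤ 100 (boundaries inclusive); high: f > 100."""
    if freq_per_million < 0:
        raise ValueError("frequency must be nonnegative")
    if freq_per_million < 10:
        return "low"
    if freq_per_million <= 100:
        return "mid"
    return "high"


def accent_positions(text: str) -> tuple[int, ...]:
    return tuple(i for i, ch in enumerate(text) if ch in ACCENT_CHARS)


@dataclass
class StimulusPair:
    pair_id: str
    word: OrthForm
    nonword: OrthForm
    word_phon: PhonForm
    nonword_phon: PhonForm
    freq_per_million: float
    bin: str = field(init=False)
    score_word: float = float("nan")
    score_nonword: float = float("nan")

    def __post_init__(self):
        self.bin = assign_frequency_bin(self.freq_per_million)
        if self.word.orth_length != self.nonword.orth_length:
            raise ValueError("pair members differ in orthographic length")
        if self.word_phon.phon_length != self.nonword_phon.phon_length:
            raise ValueError("pair members differ in phonemic length")
        if accent_positions(self.word.text) != accent_positions(self.nonword.text):
            raise ValueError("accent-character positions do not match")
        if not 5 <= self.word_phon.phon_length <= 8:
            raise ValueError("phoneme length must be 5–8")

    @property
    def phon_length(self) -> int:
        return self.word_phon.phon_length


class NoCandidateError(ValueError):
    pass


def select_matched_nonword(
    word: OrthForm,
    word_phon: PhonForm,
    word_score: float,
    candidates: Sequence[OrthForm],
    scorer: Callable[[PhonForm], float],
    rules: RuleTable,
    veto: Callable[[OrthForm], bool] | None = None,
) -> tuple[OrthForm, list[tuple[str, str]]]:
    """Best score-matched candidate nonword; (chosen, rejection log).

    Candidates failing the length/accent constraints or the veto predicate
    are filtered with a logged reason; among the rest the one minimizing
    |score(candidate) − score(word)| wins, ties broken lexicographically.
    """
    if not candidates:
        raise NoCandidateError("no candidates supplied")
    log: list[tuple[str, str]] = []
    eligible: list[tuple[float, str, OrthForm]] = []
    for cand in candidates:
        if cand.orth_length != word.orth_length:
            log.append((cand.text, "orthographic length mismatch"))
            continue
        if accent_positions(cand.text) != accent_positions(word.text):
            log.append((cand.text, "accent position mismatch"))
            continue
        try:
            phon = to_phonemes(cand, rules)
        except ValueError:
            log.append((cand.text, "unconvertible"))
            continue
        if phon.phon_length != word_phon.phon_length:
            log.append((cand.text, "phonemic length mismatch"))
            continue
        if veto is not None and veto(cand):
            log.append((cand.text, "vetoed"))
            continue
        eligible.append((abs(scorer(phon) - word_score), cand.text, cand))
    if not eligible:
        raise NoCandidateError("all candidates filtered or vetoed")
    eligible.sort(key=lambda t: (t[0], t[1]))
    return eligible[0][2], log


def generate_candidates(
    word: OrthForm,
    rules: RuleTable,
    rng: np.random.Generator,
    n: int = 10,
    n_swaps: int = 2,
    max_tries: int = 500,
) -> list[OrthForm]:
    """Stand-in candidate generator: constituent swaps within length class.

    Replaces consonants with consonants and unaccented vowels with vowels,
    keeping orthographic length and accent positions fixed, and keeping
    only results with the word's phonemic length.
    """
    vowels = "aeiou"
    consonants = "bdfglmnprst"
    word_phon = to_phonemes(word, rules)
    out: list[OrthForm] = []
    seen = {word.text}
    for _ in range(max_tries):
        if len(out) >= n:
            break
        chars = list(word.text)
        idx = [i for i, ch in enumerate(chars) if ch in vowels + consonants]
        if not idx:
            break
        for i in rng.choice(idx, size=min(n_swaps, len(idx)), replace=False):
            pool = vowels if chars[i] in vowels else consonants
            chars[i] = pool[rng.integers(len(pool))]
        text = "".join(chars)
        if text in seen:
            continue
        seen.add(text)
        try:
            cand = OrthForm(text)
            if to_phonemes(cand, rules).phon_length != word_phon.phon_length:
                continue
        except ValueError:
            continue
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# sessions

CHECK_TARGETS = ("leftmost", "middle", "rightmost")


@dataclass
class Session:
    participant: str
    seed: int
    trials: list[tuple[str, object]]  # ("stimulus", item) or ("check", target)

    @property
    def n_critical(self) -> int:
        return sum(1 for kind, _ in self.trials if kind == "stimulus")


def largest_remainder_quotas(sizes: Sequence[int], total: int) -> list[int]:
    """Integer quotas proportional to group sizes, summing exactly to total."""
    sizes = np.asarray(sizes, float)
    if sizes.sum() <= 0:
        raise ValueError("empty pool")
    exact = total * sizes / sizes.sum()
    base = np.floor(exact).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def sample_session(pool, mode: str, participant: str = "p0", n: int = 240,
                   seed: int = 0, n_checks: int = 6) -> Session:
    """Sample one experimental session from the stimulus pool.

    exp1: `pool` is a list of StimulusPair; n/2 pairs are drawn with
    quotas proportional to (length, bin) group sizes, and both members
    enter the trial list.  exp2: `pool` is a list of (item, length); n
    single nonwords are drawn with quotas proportional to length groups.
    Attention checks are inserted one per block, targeting each of
    leftmost/middle/rightmost twice, in random order.
    """
    rng = np.random.default_rng(seed)
    if mode == "exp1":
        if n % 2:
            raise ValueError("n must be even for paired sampling")
        groups: dict = {}
        for pair in pool:
            groups.setdefault((pair.phon_length, pair.bin), []).append(pair)
        keys = sorted(groups)
        quotas = largest_remainder_quotas([len(groups[k]) for k in keys], n // 2)
        for k, q in zip(keys, quotas):
            if q > len(groups[k]):
                raise ValueError(f"insufficient pool in group {k}")
        chosen_pairs = []
        for k, q in zip(keys, quotas):
            idx = rng.choice(len(groups[k]), size=q, replace=False)
            chosen_pairs.extend(groups[k][i] for i in idx)
        items = [m for p in chosen_pairs for m in (("word", p), ("nonword", p))]
    elif mode == "exp2":
        groups = {}
        for item, length in pool:
            groups.setdefault(length, []).append(item)
        keys = sorted(groups)
        quotas = largest_remainder_quotas([len(groups[k]) for k in keys], n)
        for k, q in zip(keys, quotas):
            if q > len(groups[k]):
                raise ValueError(f"insufficient pool in length group {k}")
        items = []
        for k, q in zip(keys, quotas):
            idx = rng.choice(len(groups[k]), size=q, replace=False)
            items.extend(groups[k][i] for i in idx)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    order = rng.permutation(len(items))
    trials: list[tuple[str, object]] = [("stimulus", items[i]) for i in order]
    targets = list(CHECK_TARGETS) * (n_checks // len(CHECK_TARGETS))
    targets = [targets[i] for i in rng.permutation(len(targets))]
    block = len(trials) // n_checks
    out: list[tuple[str, object]] = []
    for b in range(n_checks):
        seg = trials[b * block:(b + 1) * block if b < n_checks - 1 else len(trials)]
        pos = int(rng.integers(0, len(seg) + 1))
        out.extend(seg[:pos])
        out.append(("check", targets[b]))
        out.extend(seg[pos:])
    return Session(participant=participant, seed=seed, trials=out)


# ---------------------------------------------------------------------------
# post-hoc exclusions

def exclusion_filter(
    pairs: Iterable[StimulusPair],
    english_wordlist: Iterable[str],
    scores_old: dict[str, float],
    scores_new: dict[str, float],
    tol: float,
    allowlist: Iterable[str] = (),
) -> tuple[list[StimulusPair], list[dict]]:
    """Apply the post-hoc stimulus exclusions.

    A pair is dropped (with a per-item reason) when either member is
    orthographically identical to an English word not on the borrowing
    allowlist, or when the within-pair score difference was ≤ tol under
    the selection-time scoring system but > tol under the analysis-time
    system.  Returns (kept pairs, drop log).
    """
    english = set(english_wordlist) - set(allowlist)
    kept, dropped = [], []
    for pair in pairs:
        reasons = []
        for role, form in (("word", pair.word.text), ("nonword", pair.nonword.text)):
            if form in english:
                reasons.append({"pair_id": pair.pair_id, "stimulus": form,
                                "reason": "orthographically identical to English word"})
        d_old = abs(scores_old[pair.word.text] - scores_old[pair.nonword.text])
        d_new = abs(scores_new[pair.word.text] - scores_new[pair.nonword.text])
        if d_old <= tol < d_new:
            reasons.append({"pair_id": pair.pair_id, "stimulus": None,
                            "reason": "phonotactic match degraded between "
                                      "scoring systems"})
        if reasons:
            dropped.extend(reasons)
        else:
            kept.append(pair)
    return kept, dropped
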