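import numpy as np
import pytest

from protolex.phonology import OrthForm, to_phonemes
from protolex.stimuli import (NoCandidateError, StimulusPair,
                              assign_frequency_bin, exclusion_filter,
                              generate_candidates, largest_remainder_quotas,
                              sample_session, select_matched_nonword)


@pytest.mark.parametrize("freq,expected", [
    (5, "low"), (9.99, "low"), (10, "mid"), (55, "mid"), (100, "mid"),
    (100.01, "high"), (250, "high"), (0, "low"),
])
def test_frequency_bins(freq, expected):
    assert assign_frequency_bin(freq) == expected


def test_negative_frequency_rejected():
    with pytest.raises(ValueError):
        assign_frequency_bin(-1)


def _pair(word, nonword, freq=50.0, rules=None):
    return StimulusPair(
        pair_id="p0", word=OrthForm(word), nonword=OrthForm(nonword),
        word_phon=to_phonemes(word, rules), nonword_phon=to_phonemes(nonword, rules),
        freq_per_million=freq)


def test_pair_invariants(rules):
    p = _pair("manta", "lanta", rules=rules)
    assert p.bin == "mid" and p.phon_length == 5
    with pytest.raises(ValueError, match="orthographic length"):
        _pair("manta", "mantas", rules=rules)
    with pytest.raises(ValueError, match="accent"):
        _pair("mantá", "lanta", rules=rules)
    with pytest.raises(ValueError, match="5–8"):
        _pair("mano", "lano", rules=rules)


class _FlatScorer:
    """Deterministic toy scorer: score = fraction of 'a' symbols."""

    def __call__(self, phon):
        return -1.0 + 0.5 * sum(s == "a" for s in phon.phonemes) / phon.phon_length


def test_matched_nonword_is_brute_force_argmin(rules, rng):
    scorer = _FlatScorer()
    word = OrthForm("mantos")
    wphon = to_phonemes(word, rules)
    wscore = scorer(wphon)
    cands = [OrthForm(t) for t in
             ("lantos", "bantos", "mintas", "fontus", "dastos", "pastas",
              "montas", "tontos", "lestos", "nantas")]
    chosen, log = select_matched_nonword(word, wphon, wscore, cands,
                                         scorer, rules)
    diffs = sorted((abs(scorer(to_phonemes(c, rules)) - wscore), c.text)
                   for c in cands)
    assert chosen.text == diffs[0][1]
    assert log == []


def test_single_eligible_candidate_returned(rules):
    word = OrthForm("manta")
    wphon = to_phonemes(word, rules)
    chosen, _ = select_matched_nonword(word, wphon, -1.0,
                                       [OrthForm("lanta")], _FlatScorer(), rules)
    assert chosen.text == "lanta"


def test_all_candidates_wrong_length_error(rules):
    word = OrthForm("manta")
    wphon = to_phonemes(word, rules)
    with pytest.raises(NoCandidateError):
        select_matched_nonword(word, wphon, -1.0,
                               [OrthForm("mant"), OrthForm("mantas")],
                               _FlatScorer(), rules)


def test_veto_filters_with_reason(rules):
    word = OrthForm("manta")
    wphon = to_phonemes(word, rules)
    with pytest.raises(NoCandidateError):
        select_matched_nonword(word, wphon, -1.0, [OrthForm("lanta")],
                               _FlatScorer(), rules, veto=lambda c: True)


def test_candidate_generator_respects_constraints(rules, rng):
    word = OrthForm("mantós")
    wphon = to_phonemes(word, rules)
    for cand in generate_candidates(word, rules, rng, n=10):
        assert cand.orth_length == word.orth_length
        assert to_phonemes(cand, rules).phon_length == wphon.phon_length
        assert [i for i, c in enumerate(cand.text) if c == "ó"] == [4]


# ---------------------------------------------------------------------------
# quotas and sessions

def test_largest_remainder_exact_proportions():
    # a group holding 25% of the pool contributes exactly 30 of 120
    assert largest_remainder_quotas([25, 75], 120) == [30, 90]


def test_largest_remainder_properties(rng):
    for _ in range(200):
        sizes = rng.integers(1, 50, rng.integers(2, 8))
        total = int(rng.integers(1, 100))
        q = largest_remainder_quotas(sizes, total)
        assert sum(q) == total
        exact = total * sizes / sizes.sum()
        assert all(np.floor(e) <= qi <= np.ceil(e) for e, qi in zip(exact, q))


def _make_pool(rules, n_per_group=40):
    pool = []
    words = {5: ("manta", "lanta"), 6: ("mantas", "lantas"),
             7: ("mantras", "lantras")}
    rng = np.random.default_rng(0)
    i = 0
    for length, (w, nw) in words.items():
        for freq in (5.0, 50.0, 500.0):
            for _ in range(n_per_group):
                pool.append(StimulusPair(
                    pair_id=f"p{i}", word=OrthForm(w), nonword=OrthForm(nw),
                    word_phon=to_phonemes(w, rules),
                    nonword_phon=to_phonemes(nw, rules),
                    freq_per_million=freq))
                i += 1
    return pool


def test_session_structure_exp1(rules):
    pool = _make_pool(rules)
    s = sample_session(pool, "exp1", seed=4)
    assert s.n_critical == 240
    checks = [t for t in s.trials if t[0] == "check"]
    assert len(checks) == 6
    targets = sorted(t[1] for t in checks)
    assert targets == ["leftmost", "leftmost", "middle", "middle",
                       "rightmost", "rightmost"]
    assert len(s.trials) == 246
    # one check per sixth of the session
    positions = [i for i, t in enumerate(s.trials) if t[0] == "check"]
    for k, p in enumerate(positions):
        assert k * 41 <= p <= (k + 1) * 41


def test_session_quota_proportionality(rules):
    pool = _make_pool(rules)
    s = sample_session(pool, "exp1", seed=5)
    pairs = {t[1][1].pair_id for t in s.trials if t[0] == "stimulus"}
    assert len(pairs) == 120
    # 9 equal groups of 120 pairs → groups contribute 13 or 14 pairs
    from collections import Counter
    counts = Counter()
    for t in s.trials:
        if t[0] == "stimulus" and t[1][0] == "word":
            pair = t[1][1]
            counts[(pair.phon_length, pair.bin)] += 1
    assert all(13 <= c <= 14 for c in counts.values())


def test_session_deterministic(rules):
    pool = _make_pool(rules)
    a = sample_session(pool, "exp1", seed=11)
    b = sample_session(pool, "exp1", seed=11)
    ids_a = [t[1][1].pair_id if t[0] == "stimulus" else t[1] for t in a.trials]
    ids_b = [t[1][1].pair_id if t[0] == "stimulus" else t[1] for t in b.trials]
    assert ids_a == ids_b


def test_session_exp2_lengths_proportional():
    pool = [(f"s{i}", 5) for i in range(150)] + [(f"t{i}", 7) for i in range(450)]
    s = sample_session(pool, "exp2", seed=6)
    assert s.n_critical == 240
    lens = [5 if item.startswith("s") else 7
            for kind, item in s.trials if kind == "stimulus"]
    assert lens.count(5) == 60 and lens.count(7) == 180


def test_insufficient_pool_raises(rules):
    pool = _make_pool(rules, n_per_group=5)
    with pytest.raises(ValueError, match="insufficient"):
        sample_session(pool, "exp1", seed=0)


# ---------------------------------------------------------------------------
# exclusions

def test_exclusion_filter_toy_pool(rules):
    pairs = [StimulusPair(pair_id=f"p{i}", word=OrthForm(w), nonword=OrthForm(nw),
                          word_phon=to_phonemes(w, rules),
                          nonword_phon=to_phonemes(nw, rules),
                          freq_per_million=50.0)
             for i, (w, nw) in enumerate([("manta", "lanta"),
                                          ("hospital", "hospinal"),
                                          ("mantas", "lantas"),
                                          ("mantra", "lantra"),
                                          ("pastel", "bastel")])]
    scores_old = {f: -1.0 for p in pairs for f in (p.word.text, p.nonword.text)}
    scores_new = dict(scores_old)
    scores_new["lantra"] = -1.4  # match degrades beyond tol for pair p3
    kept, dropped = exclusion_filter(pairs, english_wordlist=["hospital"],
                                     scores_old=scores_old,
                                     scores_new=scores_new, tol=0.2)
    assert [p.pair_id for p in kept] == ["p0", "p2", "p4"]
    reasons = {d["pair_id"]: d["reason"] for d in dropped}
    assert "English" in reasons["p1"]
    assert "degraded" in reasons["p3"]


def test_exclusion_allowlist_keeps_borrowings(rules):
    pairs = [_pair("manta", "lanta", rules=rules)]
    scores = {"manta": -1.0, "lanta": -1.0}
    kept, dropped = exclusion_filter(pairs, ["manta"], scores, scores,
                                     tol=0.2, allowlist=["manta"])
    assert len(kept) == 1 and not dropped
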