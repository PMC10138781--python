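"""Self-consistency simulation studies.

Each study generates data from a known ground truth with the
synthetic-data generator, runs the corresponding inference machinery,
and reports whether the truth is recovered.  They double as the
package's validation suite and as worked examples of composing the
modules.

* `parameter_recovery_study` — simulate rating tables from a known
  cumulative-logit mixed model and check that `fit_clmm` recovers each
  generating coefficient within 2 standard errors.
* `word_size_recovery_study` — simulate ratings whose phonotactic
  predictor comes from a frequency-weighted sub-lexicon of known size,
  then run the word-based Monte Carlo over a size grid: the mean-AIC
  minimum should sit at the true size, and frequency-weighted sampling
  should explain ratings at least as well as unweighted sampling.
* `morph_parse_study` — on a concatenative lexicon, simulate ratings
  from parsed morph scoring and check that the parsed Monte Carlo mode
  yields lower mean AIC than the unparsed mode at matched sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .montecarlo import MCConfig, run_monte_carlo, sample_inventory, score_stimuli
from .morphology import learn_morph_inventory
from .ngram import WittenBellTrigram
from .ordinal import fit_clmm
from .phonology import OrthForm, load_rules, to_phonemes
from .stimuli import NoCandidateError, generate_candidates, select_matched_nonword
from .synth import (SynthConfig, generate_lexicon, generate_participants,
                    simulate_responses)


def _derive_seed(seed: int, tag: str) -> int:
    import hashlib
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def make_nonword_stimuli(lex: pd.DataFrame, n_stimuli: int, seed: int,
                         rules=None) -> pd.DataFrame:
    """Score-matched nonword stimuli built from lexicon words (phoneme
    length 5–8), with phon tuples and the accent covariate."""
    rules = rules or load_rules()
    phon = {f: to_phonemes(f, rules).phonemes for f in lex["form"]}
    model = WittenBellTrigram.train(list(phon.values()))
    rng = np.random.default_rng(seed)
    eligible = [f for f in lex["form"] if 5 <= len(phon[f]) <= 8]
    order = rng.permutation(len(eligible))
    rows = []
    for i in order:
        if len(rows) >= n_stimuli:
            break
        word = OrthForm(eligible[i])
        wphon = phon[word.text]
        cands = generate_candidates(word, rules, rng, n=10)
        try:
            nw, _ = select_matched_nonword(
                word, to_phonemes(word, rules),
                model.score_value(wphon), cands,
                lambda p: model.score_value(p.phonemes), rules)
        except NoCandidateError:
            continue
        nphon = to_phonemes(nw, rules).phonemes
        rows.append({"stimulus": f"nw{len(rows):04d}", "orth": nw.text,
                     "phon": nphon, "accent": float(nw.has_accent_char)})
    return pd.DataFrame(rows)


def parameter_recovery_study(seed: int = 0, replicates: int = 50,
                             n_participants: int = 40, n_items: int = 240,
                             betas: dict | None = None) -> pd.DataFrame:
    """Coverage of generating coefficients by ±2 SE across replicates.

    Items carry a continuous `score` and a binary `accent` covariate;
    ratings come from the generator's mixed cumulative-logit model.
    Returns one row per (replicate, coefficient) with estimate, SE, and
    whether |estimate − truth| ≤ 2 SE.
    """
    betas = dict(betas or {"score": 2.178, "accent": 0.884})
    cfg = SynthConfig(n_participants=n_participants, betas=betas)
    rows = []
    for rep in range(replicates):
        rng = np.random.default_rng(_derive_seed(seed, f"recovery{rep}"))
        stim = pd.DataFrame({
            "stimulus": [f"s{i}" for i in range(n_items)],
            "score": rng.uniform(-1.8, -0.7, n_items),
            "accent": (rng.random(n_items) < 0.3).astype(float),
        })
        parts = generate_participants(cfg, seed=_derive_seed(seed, f"parts{rep}"))
        resp = simulate_responses(stim, parts, cfg,
                                  seed=_derive_seed(seed, f"resp{rep}"))
        fit = fit_clmm(resp, "rating ~ score + accent"
                              " + (1|participant) + (1|stimulus)")
        for name, truth in betas.items():
            est = fit.coef[name]
            se = fit.se[name]
            rows.append({"replicate": rep, "coefficient": name,
                         "truth": truth, "estimate": est, "se": se,
                         "covered": bool(abs(est - truth) <= 2 * se)})
    return pd.DataFrame(rows)


def word_size_recovery_study(
    seed: int = 0,
    n_types: int = 10_000,
    true_size: int = 2_000,
    sizes: tuple[int, ...] = (500, 1000, 2000, 4000, 8000),
    replicates: int = 100,
    n_participants: int = 40,
    n_trials: int = 240,
    n_stimuli: int = 255,
    synth_overrides: dict | None = None,
) -> dict:
    """Word-based Monte Carlo against ratings from a known sub-lexicon.

    Ratings are generated from phonotactic scores under a single
    frequency-weighted sample of `true_size` words out of the `n_types`
    lexicon; the Monte Carlo then sweeps the size grid under both
    sampling schemes.

    The study lexicon is an order of magnitude smaller than a realistic
    frequency database, so its Zipf exponent and complexity bias are
    raised above the generator defaults to preserve the concentration of
    frequency mass relative to the sample sizes — without this, a
    frequency-weighted draw of the true size is far less determined at
    reduced scale than at full scale, and the size signal washes out.
    """
    overrides = {"zipf_exponent": 2.0, "freq_complexity_bias": 4.0,
                 **(synth_overrides or {})}
    scfg = SynthConfig(n_types=n_types, n_participants=n_participants,
                       true_size=true_size, **overrides)
    lex, _ = generate_lexicon(scfg, seed=_derive_seed(seed, "lexicon"))
    rules = load_rules()
    forms = [to_phonemes(f, rules).phonemes for f in lex["form"]]
    freqs = lex["freq_per_million"].to_numpy()

    rng = np.random.default_rng(_derive_seed(seed, "truth"))
    idx = sample_inventory(len(forms), true_size, scfg.true_scheme, rng,
                           freqs=freqs)
    alphabet = frozenset(s for f in forms for s in f)
    true_model = WittenBellTrigram.train([forms[i] for i in idx],
                                         alphabet=alphabet)
    stim = make_nonword_stimuli(lex, n_stimuli, _derive_seed(seed, "stimuli"),
                                rules=rules)
    stim["score"] = [true_model.score_value(p) for p in stim["phon"]]
    parts = generate_participants(scfg, seed=_derive_seed(seed, "parts"))
    resp = simulate_responses(stim, parts, scfg,
                              seed=_derive_seed(seed, "resp"),
                              n_trials=min(n_trials, len(stim)))

    out = {"true_size": true_size, "summaries": {}}
    for scheme in ("unweighted", "frequency"):
        cfg = MCConfig(unit="word", scheme=scheme, sizes=sizes,
                       replicates=replicates,
                       seed=_derive_seed(seed, f"mc_{scheme}"))
        res = run_monte_carlo(cfg, stim, resp, forms=forms, freqs=freqs)
        out["summaries"][scheme] = res.summary(seed=_derive_seed(seed, "boot"))
    fw = out["summaries"]["frequency"]
    out["best_size"] = int(fw.loc[fw["mean_aic"].idxmin(), "size"])
    return out


def morph_parse_study(
    seed: int = 0,
    n_types: int = 4_000,
    sizes: tuple[int, ...] = (150, 300, 600),
    replicates: int = 50,
    n_participants: int = 40,
    n_trials: int = 200,
    n_stimuli: int = 200,
    true_size: int = 500,
) -> dict:
    """Parsed vs unparsed morph scoring on a concatenative lexicon.

    The lexicon is suffix-heavy with substantial compounding, so morphs
    recur across words; ratings are generated from parsed scores under a
    frequency-weighted morph sample of `true_size`.
    """
    scfg = SynthConfig(n_types=n_types, n_stems=max(400, n_types // 8),
                       compounding_rate=0.3, p_suffix=0.6,
                       n_participants=n_participants)
    lex, _ = generate_lexicon(scfg, seed=_derive_seed(seed, "lexicon"))
    rules = load_rules()
    forms = [to_phonemes(f, rules).phonemes for f in lex["form"]]
    freqs = lex["freq_per_million"].to_numpy()
    inv = learn_morph_inventory(forms, seed=_derive_seed(seed, "mdl"))
    inv.attach_frequencies(dict(zip(forms, freqs)))

    morphs = sorted(inv.type_counts)
    weights = np.array([inv.token_freq.get(m, 0.0) for m in morphs])
    rng = np.random.default_rng(_derive_seed(seed, "truth"))
    k = min(true_size, len(morphs))
    idx = sample_inventory(len(morphs), k, "frequency", rng, freqs=weights)
    sampled = [morphs[i] for i in idx]
    alphabet = frozenset(s for f in forms for s in f)
    true_model = WittenBellTrigram.train(sampled, alphabet=alphabet)
    true_inv = inv.restrict(sampled)

    stim = make_nonword_stimuli(lex, n_stimuli, _derive_seed(seed, "stimuli"),
                                rules=rules)
    stim["score"] = score_stimuli(true_model, list(stim["phon"]),
                                  parse_mode="parsed", inventory=true_inv)
    parts = generate_participants(scfg, seed=_derive_seed(seed, "parts"))
    resp = simulate_responses(stim, parts, scfg,
                              seed=_derive_seed(seed, "resp"),
                              n_trials=min(n_trials, len(stim)))

    sizes = tuple(s for s in sizes if s <= len(morphs))
    out = {"n_morphs": len(morphs), "summaries": {}}
    for mode in ("parsed", "unparsed"):
        cfg = MCConfig(unit="morph", scheme="frequency", parse_mode=mode,
                       sizes=sizes, replicates=replicates,
                       seed=_derive_seed(seed, "mc_morph"))
        res = run_monte_carlo(cfg, stim, resp, morph_inventory=inv)
        out["summaries"][mode] = res.summary(seed=_derive_seed(seed, "boot"))
    return out
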