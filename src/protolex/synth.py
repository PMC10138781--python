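"""Synthetic data with the statistical structure the analyses assume.

The generator emulates, at reduced scale, the three data layers of an
ambient-language rating study:

* a Zipf-distributed lexicon of morphologically structured word types
  (stem + optional suffix, occasional stem-stem compounds) built from
  syllable templates over a restricted Spanish-like alphabet, with
  orthographic accents attached at a configurable rate (orthography
  only — the accent is a visual covariate, not a phoneme);
* participants whose questionnaire items (A–F, 5-point) arise from
  independent latent traits, yielding a wide spread of Spanish-value,
  nationalism, and exposure composites;
* 1–5 ratings drawn from a cumulative-logit model: latent
  η = x'β + u_participant + v_item (plus optional by-item slopes for
  attitude interactions), cut at fixed thresholds.

The grapheme inventory is restricted so that the shipped rewrite-rule
table maps each letter to exactly one phoneme with no digraphs; morph
boundaries in orthography then correspond one-to-one to boundaries in
phoneme space, which lets ground-truth segmentations be emitted
alongside the lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attitudes import add_composites

VOWELS = "aeiou"
ONSETS = "bdflmnpst"
CODAS = "ns"
ACCENT_MAP = {"a": "á", "e": "é", "i": "í", "o": "ó", "u": "ú"}

DEFAULT_SUFFIXES = ("o", "a", "os", "as", "e", "es", "an", "en",
                    "ado", "ando", "ino", "ita")


@dataclass
class SynthConfig:
    # lexicon
    n_types: int = 10_000
    n_stems: int = 4_000
    suffixes: tuple[str, ...] = DEFAULT_SUFFIXES
    p_suffix: float = 0.6
    compounding_rate: float = 0.02
    zipf_exponent: float = 1.0
    top_freq_per_million: float = 20_000.0  # rank-1 occurrence rate
    # high-frequency words tend to be bare stems; inflected and compound
    # forms sit lower in the rank order (strength in latent-noise units)
    freq_complexity_bias: float = 3.0
    accent_rate: float = 0.15
    corpus_size: float = 5e7
    syllable_weights: dict = field(default_factory=lambda: {
        "CV": 0.55, "CVC": 0.25, "V": 0.10, "VC": 0.10})
    # participants: items load on a per-construct latent trait
    n_participants: int = 40
    item_loading: float = 1.3
    item_noise_sd: float = 0.9
    # true generating rating model
    thresholds: tuple[float, ...] = (-4.6, -3.4, -2.0, -0.6)
    betas: dict = field(default_factory=lambda: {"score": 2.178,
                                                 "accent": 0.884})
    sigma_participant: float = 0.5
    sigma_item: float = 0.3
    item_slope_sd: dict = field(default_factory=dict)  # participant col -> sd
    # true proto-lexicon used to score stimuli before simulating ratings
    true_size: int = 2_000
    true_scheme: str = "frequency"

    def __post_init__(self):
        if self.zipf_exponent <= 0:
            raise ValueError("Zipf exponent must be positive")
        if not 0 <= self.compounding_rate <= 1 or not 0 <= self.p_suffix <= 1:
            raise ValueError("rates must be probabilities")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")


def _syllable(rng: np.random.Generator, weights: dict) -> str:
    tmpl = rng.choice(list(weights), p=np.array(list(weights.values()))
                      / sum(weights.values()))
    out = []
    for slot in tmpl:
        if slot == "C":
            out.append(ONSETS[rng.integers(len(ONSETS))])
        else:
            out.append(VOWELS[rng.integers(len(VOWELS))])
    return "".join(out)


def _stem(rng: np.random.Generator, weights: dict) -> str:
    n_syll = 2 + int(rng.random() < 0.35)
    return "".join(_syllable(rng, weights) for _ in range(n_syll))


def generate_lexicon(cfg: SynthConfig, seed: int = 0
                     ) -> tuple[pd.DataFrame, dict[str, tuple[str, ...]]]:
    """Generate a frequency lexicon and its ground-truth segmentations.

    Returns (lexicon DataFrame with form/freq_per_million/raw_count,
    mapping form → morph parts).  Deterministic given (cfg, seed).
    """
    rng = np.random.default_rng(seed)
    stems: list[str] = []
    seen = set()
    while len(stems) < cfg.n_stems:
        s = _stem(rng, cfg.syllable_weights)
        if s not in seen:
            seen.add(s)
            stems.append(s)
    words: list[str] = []
    truth: dict[str, tuple[str, ...]] = {}
    tries = 0
    while len(words) < cfg.n_types and tries < cfg.n_types * 60:
        tries += 1
        stem = stems[rng.integers(len(stems))]
        u = rng.random()
        if u < cfg.compounding_rate:
            other = stems[rng.integers(len(stems))]
            parts = (stem, other)
        elif u < cfg.compounding_rate + cfg.p_suffix:
            suf = cfg.suffixes[rng.integers(len(cfg.suffixes))]
            parts = (stem, suf)
        else:
            parts = (stem,)
        w = "".join(parts)
        if w in truth:
            continue
        if rng.random() < cfg.accent_rate:
            vow = [i for i, ch in enumerate(w) if ch in ACCENT_MAP]
            if vow:
                i = vow[rng.integers(len(vow))]
                lens = np.cumsum([len(p) for p in parts])
                w2 = w[:i] + ACCENT_MAP[w[i]] + w[i + 1:]
                parts = tuple(w2[(0 if j == 0 else lens[j - 1]):lens[j]]
                              for j in range(len(parts)))
                w = w2
        if w in truth:
            continue
        truth[w] = parts
        words.append(w)
    if len(words) < cfg.n_types:
        raise ValueError("unsatisfiable template constraints: "
                         "could not generate enough distinct types")
    complexity = np.array([len(truth[w]) - 1 + 0.5 * (len(truth[w]) > 1 and
                                                      truth[w][-1] not in cfg.suffixes)
                           for w in words], float)
    order = np.argsort(cfg.freq_complexity_bias * complexity
                       + rng.normal(size=len(words)), kind="stable")
    ranks = np.arange(1, len(words) + 1, dtype=float)
    fpm = cfg.top_freq_per_million * ranks ** (-cfg.zipf_exponent)
    lex = pd.DataFrame({
        "form": [words[i] for i in order],
        "freq_per_million": fpm,
        "raw_count": np.maximum(1, np.round(fpm * cfg.corpus_size / 1e6)).astype(int),
    })
    return lex, truth


def generate_participants(cfg: SynthConfig, seed: int = 0) -> pd.DataFrame:
    """Participant profiles with items A–F, state, and composite scores.

    Items within a construct load on a shared latent trait; traits are
    independent across constructs, so e.g. the polychoric correlation of
    items A and C is near zero at large n.  Centered composites
    (suffix ``_c``) are included for use in interaction terms.
    """
    if cfg.n_participants < 1:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(seed)
    n = cfg.n_participants
    latents = {"spanish_value": rng.normal(size=n),
               "nationalism": rng.normal(size=n),
               "exposure": rng.normal(size=n)}
    items = {}
    for (i1, i2), lat in zip((("A", "B"), ("C", "D"), ("E", "F")),
                             latents.values()):
        for item in (i1, i2):
            raw = (3.0 + cfg.item_loading * lat
                   + cfg.item_noise_sd * rng.normal(size=n))
            items[item] = np.clip(np.round(raw), 1, 5).astype(int)
    prof = pd.DataFrame({"participant": [f"p{i:03d}" for i in range(n)],
                         **items,
                         "state": rng.choice(["CA", "TX"], size=n)})
    prof = add_composites(prof)
    for construct in latents:
        prof[f"{construct}_c"] = prof[construct] - prof[construct].mean()
    return prof


def simulate_responses(stimuli: pd.DataFrame, participants: pd.DataFrame,
                       cfg: SynthConfig, seed: int = 0,
                       n_trials: int | None = None) -> pd.DataFrame:
    """Draw 1–5 ratings from the configured cumulative-logit model.

    `stimuli` must carry a ``stimulus`` id, a ``score`` column (the
    phonotactic score under the configured true proto-lexicon), and any
    further covariates named in ``cfg.betas``; interaction terms ``a:b``
    multiply the referenced columns of the merged trial table.
    """
    if "score" not in stimuli.columns or stimuli["score"].isna().any():
        raise ValueError("stimuli must be scored before simulating responses")
    rng = np.random.default_rng(seed)
    frames = []
    for _, p in participants.iterrows():
        if n_trials is None or n_trials >= len(stimuli):
            chosen = stimuli
        else:
            idx = rng.choice(len(stimuli), size=n_trials, replace=False)
            chosen = stimuli.iloc[idx]
        t = chosen.copy()
        for col in participants.columns:
            t[col] = p[col]
        t["trial_index"] = np.arange(len(t))
        frames.append(t)
    trials = pd.concat(frames, ignore_index=True)

    eta = np.zeros(len(trials))
    for term, beta in cfg.betas.items():
        x = np.ones(len(trials))
        for name in term.split(":"):
            x = x * trials[name].astype(float).to_numpy()
        eta += beta * x
    pid, pcode = np.unique(trials["participant"], return_inverse=True)
    sid, scode = np.unique(trials["stimulus"], return_inverse=True)
    u = rng.normal(0, cfg.sigma_participant, len(pid))
    v = rng.normal(0, cfg.sigma_item, len(sid))
    eta += u[pcode] + v[scode]
    for col, sd in cfg.item_slope_sd.items():
        w = rng.normal(0, sd, len(sid))
        eta += w[scode] * trials[col].astype(float).to_numpy()
    th = np.asarray(cfg.thresholds)
    cum = 1.0 / (1.0 + np.exp(-(th[None, :] - eta[:, None])))
    draws = rng.random(len(trials))
    trials["rating"] = 1 + (draws[:, None] > cum).sum(axis=1)
    return trials
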