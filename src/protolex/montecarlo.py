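"""Monte Carlo proto-lexicon inference.

The core question: how many word (or morph) forms, sampled how, generate
phonotactic scores that best explain participants' wellformedness
ratings?  For each candidate inventory size, R sub-inventories are drawn
— uniformly at random (unweighted scheme) or by successive draws
proportional to remaining items' frequencies (frequency-weighted scheme,
without replacement) — and each sample is used to train a fresh
Witten-Bell trigram model, rescore every stimulus, and refit the
fixed-effects cumulative-logit rating model with the new score
substituted.  The per-sample AICs are collated into means with 95%
bootstrap percentile intervals and compared against the full-inventory
baseline (lower AIC = better explanation of the ratings).

For morph-based proto-lexicons, stimuli are scored either *parsed*
(segmented against the sampled morphs, trigram context resetting at each
boundary) or *unparsed* (whole form as one morph).

A representative (population-level-averaged) scoring system — the
per-stimulus mean score across a size's samples — supports a single
mixed-effects fit per size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .morphology import MorphInventory, parsed_score
from .ngram import WittenBellTrigram
from .ordinal import ConvergenceError, bootstrap_ci, fit_clm

SCHEMES = ("unweighted", "frequency")


@dataclass(frozen=True)
class MCConfig:
    unit: str = "word"                    # "word" | "morph"
    scheme: str = "frequency"             # "unweighted" | "frequency"
    parse_mode: str | None = None         # morph unit: "parsed" | "unparsed"
    sizes: tuple[int, ...] = (500, 1000, 2000, 4000, 8000)
    replicates: int = 100
    seed: int = 0
    formula: str = "rating ~ score + accent"
    include_end: bool = False
    with_replacement: bool = False

    def __post_init__(self):
        if self.unit not in ("word", "morph"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.unit == "morph" and self.parse_mode not in ("parsed", "unparsed"):
            raise ValueError("morph unit requires parse_mode parsed|unparsed")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class MCResult:
    table: pd.DataFrame        # unit, scheme, parse_mode, size, replicate, aic, converged
    baseline_aic: float
    config: MCConfig

    def summary(self, B: int = 1000, seed: int = 0) -> pd.DataFrame:
        rows = []
        for size, grp in self.table.groupby("size"):
            ok = grp.loc[grp["converged"], "aic"]
            lo, hi = bootstrap_ci(ok.to_numpy(), B=B, seed=seed)
            rows.append({
                "unit": self.config.unit, "scheme": self.config.scheme,
                "parse_mode": self.config.parse_mode, "size": size,
                "mean_aic": ok.mean(), "ci_lo": lo, "ci_hi": hi,
                "n_replicates": len(grp), "n_failed": int((~grp["converged"]).sum()),
                "baseline_aic": self.baseline_aic,
                "delta_aic": ok.mean() - self.baseline_aic,
            })
        return pd.DataFrame(rows)


def sample_inventory(n_items: int, size: int, scheme: str,
                     rng: np.random.Generator,
                     freqs: Sequence[float] | None = None,
                     with_replacement: bool = False) -> np.ndarray:
    """Indices of a sampled sub-inventory.

    The frequency-weighted scheme draws successively in proportion to the
    remaining items' frequencies (exponential-key equivalent), without
    replacement unless requested.
    """
    if size < 1:
        raise ValueError("sample size must be ≥ 1")
    if size > n_items and not with_replacement:
        raise ValueError(f"sample size {size} exceeds inventory size {n_items}")
    if scheme == "unweighted":
        if with_replacement:
            return rng.integers(0, n_items, size)
        return rng.choice(n_items, size=size, replace=False)
    if scheme != "frequency":
        raise ValueError(f"unknown scheme {scheme!r}")
    w = np.asarray(freqs, float)
    if w is None or len(w) != n_items:
        raise ValueError("frequency scheme requires per-item frequencies")
    if np.any(w <= 0):
        raise ValueError("frequencies must be positive for weighted sampling")
    if with_replacement:
        return rng.choice(n_items, size=size, replace=True, p=w / w.sum())
    # successive weighted draws without replacement == smallest Exp(rate=w) keys
    keys = rng.exponential(size=n_items) / w
    return np.argpartition(keys, size - 1)[:size]


def score_stimuli(model: WittenBellTrigram, phon_forms: Sequence[tuple],
                  parse_mode: str | None = None,
                  inventory: MorphInventory | None = None,
                  include_end: bool = False) -> np.ndarray:
    if parse_mode == "parsed":
        return np.array([parsed_score(f, model, inventory,
                                      include_end=include_end).value
                         for f in phon_forms])
    # unparsed / word unit: the whole form is scored as a single unit
    return np.array([model.score_value(f, include_end=include_end)
                     for f in phon_forms])


def _aggregate_responses(stimuli: pd.DataFrame, responses: pd.DataFrame,
                         covariates: Sequence[str]) -> pd.DataFrame:
    missing = set(responses["stimulus"]) - set(stimuli["stimulus"])
    if missing:
        raise ValueError(f"responses reference unscored stimuli: "
                         f"{sorted(missing)[:5]} ...")
    agg = (responses.groupby(["stimulus", "rating"]).size()
           .rename("weight").reset_index())
    cols = ["stimulus"] + [c for c in covariates if c in stimuli.columns]
    return agg.merge(stimuli[cols], on="stimulus", how="left")


def run_monte_carlo(cfg: MCConfig, stimuli: pd.DataFrame,
                    responses: pd.DataFrame,
                    forms: Sequence[tuple] | None = None,
                    freqs: Sequence[float] | None = None,
                    morph_inventory: MorphInventory | None = None) -> MCResult:
    """Full Monte Carlo sweep for one (unit, scheme, parse_mode) config.

    `stimuli` needs columns stimulus/phon (symbol tuples) plus any fixed
    covariates in the formula; `responses` needs participant/stimulus/
    rating.  Word unit: `forms` (+`freqs`) is the training inventory.
    Morph unit: `morph_inventory` supplies morphs, usage counts and token
    frequencies.  Fully reproducible from (cfg.seed, cfg).
    """
    from .ordinal import parse_formula
    _, fixed_terms, _ = parse_formula(cfg.formula)
    covariates = sorted({f for t in fixed_terms for f in t.split(":")
                         if f != "score"})
    if cfg.unit == "morph":
        if morph_inventory is None:
            raise ValueError("morph unit requires a MorphInventory")
        items = sorted(morph_inventory.type_counts)
        weights = np.array([morph_inventory.token_freq.get(m, 0.0) for m in items])
    else:
        if forms is None:
            raise ValueError("word unit requires training forms")
        items = [tuple(f) for f in forms]
        weights = None if freqs is None else np.asarray(freqs, float)

    phon = [tuple(f) for f in stimuli["phon"]]
    alphabet = frozenset(s for f in items for s in f) | frozenset(
        s for f in phon for s in f)
    agg = _aggregate_responses(stimuli, responses, covariates)
    stim_order = stimuli["stimulus"].to_numpy()
    pos = {s: i for i, s in enumerate(stim_order)}
    agg_idx = agg["stimulus"].map(pos).to_numpy()

    def fit_aic(scores: np.ndarray) -> float:
        df = agg.copy()
        df["score"] = scores[agg_idx]
        fit = fit_clm(df, cfg.formula, weights="weight")
        return fit.aic

    def replicate_scores(idx: np.ndarray) -> np.ndarray:
        sampled = [items[i] for i in idx]
        model = WittenBellTrigram.train(sampled, alphabet=alphabet,
                                        unit=cfg.unit)
        inv = (morph_inventory.restrict(sampled)
               if cfg.unit == "morph" else None)
        return score_stimuli(model, phon, parse_mode=cfg.parse_mode,
                             inventory=inv, include_end=cfg.include_end)

    baseline_scores = replicate_scores(np.arange(len(items)))
    baseline_aic = fit_aic(baseline_scores)

    rows = []
    for si, size in enumerate(cfg.sizes):
        for rep in range(cfg.replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.seed, spawn_key=(si, rep)))
            idx = sample_inventory(len(items), size, cfg.scheme, rng,
                                   freqs=weights,
                                   with_replacement=cfg.with_replacement)
            try:
                aic = fit_aic(replicate_scores(idx))
                ok = True
            except (ConvergenceError, ValueError):
                aic, ok = float("nan"), False
            rows.append({"unit": cfg.unit, "scheme": cfg.scheme,
                         "parse_mode": cfg.parse_mode, "size": size,
                         "replicate": rep, "aic": aic, "converged": ok})
    return MCResult(pd.DataFrame(rows), baseline_aic, cfg)


def representative_scores(tables: Sequence[pd.Series]) -> pd.Series:
    """Per-stimulus arithmetic mean of sampled score tables."""
    if not tables:
        raise ValueError("need at least one score table")
    first = tables[0].sort_index()
    for t in tables[1:]:
        if set(t.index) != set(first.index):
            raise ValueError("score tables cover different stimulus sets")
    return pd.concat([t.sort_index() for t in tables], axis=1).mean(axis=1)
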