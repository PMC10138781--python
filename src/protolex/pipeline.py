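"""End-to-end orchestration: synth → score → fit → Monte Carlo → report.

A single TOML config drives the run.  Every output directory receives a
manifest (config hash, global seed, per-stage seeds, package version) so
that reruns with the same config are byte-reproducible.  The global seed
fans out to per-stage seeds by stable hashing, so stages can be rerun
independently without disturbing each other's streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attitudes import add_composites, polychoric_from_ratings
from .lexicon import read_lexicon, write_lexicon
from .montecarlo import (MCConfig, MCResult, representative_scores,
                         run_monte_carlo, sample_inventory)
from .morphology import learn_morph_inventory
from .ngram import WittenBellTrigram
from .ordinal import fit_clm, fit_clmm, marginal_contrast
from .phonology import load_rules, to_phonemes
from .stimuli import (NoCandidateError, assign_frequency_bin,
                      generate_candidates, select_matched_nonword)
from .synth import (SynthConfig, generate_lexicon, generate_participants,
                    simulate_responses)

log = logging.getLogger("protolex")


@dataclass
class RunConfig:
    output_dir: str = "protolex_run"
    seed: int = 0
    log_level: str = "INFO"
    lexicon: str | None = None
    stimuli: str | None = None
    responses: str | None = None
    questionnaire: str | None = None
    synth: dict = field(default_factory=dict)
    mc: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def write_manifest(outdir: Path, cfg: RunConfig, stages: dict) -> None:
    manifest = {"config_hash": cfg.hash(), "seed": cfg.seed,
                "version": __version__, "stage_seeds": stages}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _validate_responses(responses: pd.DataFrame) -> None:
    bad = responses.index[~responses["rating"].isin([1, 2, 3, 4, 5])]
    if len(bad):
        raise ValueError(f"invalid rating at row {bad[0]}: "
                         f"{responses.loc[bad[0], 'rating']!r}")


# ---------------------------------------------------------------------------
# synthetic bundle

def build_synthetic_bundle(cfg: RunConfig, n_words: int = 250,
                           n_trials: int = 240) -> dict[str, pd.DataFrame]:
    """Generate a full synthetic study: lexicon, matched stimulus pool,
    participants, and exp1/exp2 response tables."""
    scfg = SynthConfig(**cfg.synth)
    seed = cfg.seed
    rules = load_rules()
    lex, truth = generate_lexicon(scfg, seed=stage_seed(seed, "lexicon"))
    phon = {f: to_phonemes(f, rules).phonemes for f in lex["form"]}
    model = WittenBellTrigram.train(list(phon.values()))

    rng = np.random.default_rng(stage_seed(seed, "stimuli"))
    eligible = lex[[5 <= len(phon[f]) <= 8 for f in lex["form"]]]
    chosen = eligible.iloc[rng.choice(len(eligible), size=min(n_words, len(eligible)),
                                      replace=False)]
    rows = []
    pair_id = 0
    for _, rec in chosen.iterrows():
        word = rec["form"]
        from .phonology import OrthForm
        worth = OrthForm(word)
        wphon = to_phonemes(worth, rules)
        cands = generate_candidates(worth, rules, rng, n=10)
        try:
            nw, _ = select_matched_nonword(
                worth, wphon, model.score_value(wphon.phonemes), cands,
                lambda p: model.score_value(p.phonemes), rules)
        except NoCandidateError:
            continue
        b = assign_frequency_bin(rec["freq_per_million"])
        for role, orth in (("word", worth), ("nonword", OrthForm(nw.text))):
            p = to_phonemes(orth, rules)
            rows.append({"pair_id": f"pair{pair_id:04d}", "role": role,
                         "orth": orth.text, "phon": " ".join(p.phonemes),
                         "bin": b, "freq_per_million": rec["freq_per_million"],
                         "accent": float(orth.has_accent_char),
                         "wordhood": float(role == "word"),
                         "score": model.score_value(p.phonemes)})
        pair_id += 1
    pool = pd.DataFrame(rows)
    pool["stimulus"] = pool["pair_id"] + ":" + pool["role"]

    participants = generate_participants(scfg, seed=stage_seed(seed, "participants"))
    stim1 = pool.copy()
    stim1["phon"] = [tuple(p.split(" ")) for p in stim1["phon"]]
    resp1 = simulate_responses(stim1, participants, scfg,
                               seed=stage_seed(seed, "responses_exp1"),
                               n_trials=n_trials)
    nonwords = stim1[stim1["role"] == "nonword"].reset_index(drop=True)
    resp2 = simulate_responses(nonwords, participants, scfg,
                               seed=stage_seed(seed, "responses_exp2"),
                               n_trials=min(n_trials, len(nonwords)))
    keep = ["participant", "stimulus", "rating", "trial_index"]
    return {"lexicon": lex, "pool": pool, "participants": participants,
            "responses_exp1": resp1[keep], "responses_exp2": resp2[keep]}


def write_bundle(bundle: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_lexicon(bundle["lexicon"], outdir / "lexicon.tsv")
    bundle["pool"].to_csv(outdir / "stimuli.csv", index=False)
    bundle["participants"].to_csv(outdir / "questionnaire.csv", index=False)
    bundle["responses_exp1"].to_csv(outdir / "responses_exp1.csv", index=False)
    bundle["responses_exp2"].to_csv(outdir / "responses_exp2.csv", index=False)


def _load_inputs(cfg: RunConfig):
    if cfg.stimuli is None:
        bundle = build_synthetic_bundle(cfg)
    else:
        bundle = {
            "lexicon": read_lexicon(cfg.lexicon),
            "pool": pd.read_csv(cfg.stimuli),
            "participants": pd.read_csv(cfg.questionnaire),
            "responses_exp1": pd.read_csv(cfg.responses),
            "responses_exp2": pd.read_csv(str(cfg.responses).replace("exp1", "exp2")),
        }
    return bundle


# ---------------------------------------------------------------------------
# analyses

def run_experiment_analysis(cfg: RunConfig) -> dict:
    """Mixed-model analyses of the two rating experiments + attitudes."""
    logging.basicConfig(level=cfg.log_level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = _load_inputs(cfg)
    pool, participants = bundle["pool"], bundle["participants"]
    results = {}
    for exp, default_formula in (
        ("exp1", "rating ~ wordhood + bin + wordhood:bin + score + accent"
                 " + (1|participant) + (1|stimulus)"),
        ("exp2", "rating ~ score + accent + (1|participant) + (1|stimulus)"),
    ):
        resp = bundle[f"responses_{exp}"]
        _validate_responses(resp)
        data = resp.merge(pool, on="stimulus").merge(participants,
                                                     on="participant")
        data["bin"] = pd.Categorical(data["bin"],
                                     categories=["low", "mid", "high"])
        formula = cfg.models.get(exp, default_formula)
        log.info("fitting %s: %s", exp, formula)
        fit = fit_clmm(data, formula)
        fit.coef_table().to_csv(outdir / f"coefficients_{exp}.csv")
        fit.to_json(outdir / f"fit_{exp}.json")
        results[exp] = fit
        if exp == "exp1" and "wordhood:bin" in formula.replace(" ", ""):
            bin_cols = [c for c in fit.col_means
                        if c.startswith("bin[") and ":" not in c]
            reference = [b for b in ("low", "mid", "high")
                         if f"bin[{b}]" not in bin_cols]
            rows = []
            for b in reference + [c[4:-1] for c in bin_cols]:
                at = {c: float(c == f"bin[{b}]") for c in bin_cols}
                est, z, (lo, hi) = marginal_contrast(fit, "wordhood", at=at)
                rows.append({"bin": b, "estimate": est, "z": z,
                             "ci_lo": lo, "ci_hi": hi})
            pd.DataFrame(rows).to_csv(outdir / "contrasts_exp1.csv", index=False)
        # attitude-interaction model
        att_terms = ("spanish_value_c:score" if exp == "exp2"
                     else "spanish_value_c:wordhood + spanish_value_c:score")
        att_formula = cfg.models.get(
            f"{exp}_attitudes",
            formula.replace("~", "~ spanish_value_c + ", 1)
            .replace("+ (1|participant)", f"+ {att_terms} + (1|participant)", 1))
        afit = fit_clmm(data, att_formula)
        afit.coef_table().to_csv(outdir / f"coefficients_{exp}_attitudes.csv")
        results[f"{exp}_attitudes"] = afit
    # questionnaire structure
    rho = polychoric_from_ratings(participants["A"], participants["C"])
    (outdir / "polychoric.json").write_text(json.dumps(
        {"rho_A_C": rho.rho}, indent=2))
    write_manifest(outdir, cfg, {s: stage_seed(cfg.seed, s) for s in
                                 ("lexicon", "stimuli", "participants",
                                  "responses_exp1", "responses_exp2")})
    (outdir / "aic.json").write_text(json.dumps(
        {k: f.aic for k, f in results.items()}, indent=2))
    return results


def run_proto_lexicon_analysis(cfg: RunConfig) -> dict[str, MCResult]:
    """Word- and morph-based Monte Carlo sweeps with summary plots."""
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = _load_inputs(cfg)
    pool = bundle["pool"]
    rules = load_rules()
    stim = pool[pool["role"] == "nonword"].copy()
    if isinstance(stim["phon"].iloc[0], str):
        stim["phon"] = [tuple(p.split(" ")) for p in stim["phon"]]
    resp = bundle["responses_exp2"]
    _validate_responses(resp)
    lex = bundle["lexicon"]
    forms = [to_phonemes(f, rules).phonemes for f in lex["form"]]
    freqs = lex["freq_per_million"].to_numpy()

    mc_opts = dict(cfg.mc)
    word_sizes = tuple(mc_opts.get("word_sizes", (500, 1000, 2000, 4000, 8000)))
    morph_sizes = tuple(mc_opts.get("morph_sizes", (250, 500, 1000, 2000)))
    reps = int(mc_opts.get("replicates", 100))
    results: dict[str, MCResult] = {}
    tables = []
    for scheme in ("unweighted", "frequency"):
        c = MCConfig(unit="word", scheme=scheme, sizes=word_sizes,
                     replicates=reps, seed=stage_seed(cfg.seed, f"mc_word_{scheme}"))
        results[f"word_{scheme}"] = run_monte_carlo(
            c, stim, resp, forms=forms, freqs=freqs)
        tables.append(results[f"word_{scheme}"])
    inv = learn_morph_inventory(forms, seed=stage_seed(cfg.seed, "morphs"))
    inv.attach_frequencies(dict(zip(forms, freqs)))
    inv.to_tsv(outdir / "morph_inventory.tsv")
    for parse_mode in ("parsed", "unparsed"):
        for scheme in ("unweighted", "frequency"):
            sizes = tuple(s for s in morph_sizes if s <= len(inv))
            c = MCConfig(unit="morph", scheme=scheme, parse_mode=parse_mode,
                         sizes=sizes, replicates=reps,
                         seed=stage_seed(cfg.seed, f"mc_morph_{scheme}_{parse_mode}"))
            results[f"morph_{scheme}_{parse_mode}"] = run_monte_carlo(
                c, stim, resp, morph_inventory=inv)
            tables.append(results[f"morph_{scheme}_{parse_mode}"])
    long = pd.concat([r.table for r in tables], ignore_index=True)
    long.to_csv(outdir / "mc_replicates.csv", index=False)
    summary = pd.concat([r.summary(seed=stage_seed(cfg.seed, "bootstrap"))
                         for r in tables], ignore_index=True)
    summary.to_csv(outdir / "mc_summary.csv", index=False)
    plot_mc_panels(summary, outdir)
    write_manifest(outdir, cfg, {"mc": stage_seed(cfg.seed, "mc")})
    return results


def plot_mc_panels(summary: pd.DataFrame, outdir: Path) -> None:
    """AIC-vs-size panels in the style of the word/morph MC figures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    word = summary[summary["unit"] == "word"]
    if len(word):
        fig, ax = plt.subplots(figsize=(6, 4))
        for scheme, grp in word.groupby("scheme"):
            ax.errorbar(grp["size"], grp["mean_aic"],
                        yerr=[grp["mean_aic"] - grp["ci_lo"],
                              grp["ci_hi"] - grp["mean_aic"]],
                        marker="o", capsize=3, label=scheme)
        ax.axhline(word["baseline_aic"].iloc[0], ls="--", c="k",
                   label="full inventory")
        ax.set_xscale("log")
        ax.set_xlabel("vocabulary size")
        ax.set_ylabel("AIC")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "mc_words.png", dpi=150)
        plt.close(fig)
    morph = summary[summary["unit"] == "morph"]
    if len(morph):
        modes = sorted(morph["parse_mode"].dropna().unique())
        fig, axes = plt.subplots(1, len(modes), figsize=(6 * len(modes), 4),
                                 sharey=True, squeeze=False)
        for ax, mode in zip(axes[0], modes):
            sub = morph[morph["parse_mode"] == mode]
            for scheme, grp in sub.groupby("scheme"):
                ax.errorbar(grp["size"], grp["mean_aic"],
                            yerr=[grp["mean_aic"] - grp["ci_lo"],
                                  grp["ci_hi"] - grp["mean_aic"]],
                            marker="o", capsize=3, label=scheme)
            ax.axhline(sub["baseline_aic"].iloc[0], ls=":", c="k",
                       label="full morph inventory")
            ax.set_xscale("log")
            ax.set_title(mode)
            ax.set_xlabel("morph set size")
            ax.legend()
        axes[0][0].set_ylabel("AIC")
        fig.tight_layout()
        fig.savefig(outdir / "mc_morphs.png", dpi=150)
        plt.close(fig)
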