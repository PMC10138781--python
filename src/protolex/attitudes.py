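"""Questionnaire composites and polychoric correlation.

Attitude and exposure constructs are each measured by two 5-point items:
Spanish value (A, B), nationalism (C, D), and exposure (E, F).  A
composite is the sum of the two items when they share polarity (range
2–10) or their difference when opposed (range −4–4); which rule applies
per construct is configuration, not hard-coded, since item polarity
depends on the questionnaire wording.

Association between ordinal measures is summarized by the polychoric
correlation: the latent bivariate-normal correlation estimated from the
cross-table by the standard two-step method (margins fix the normal
thresholds, then ρ maximizes the cell likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

ITEMS = ("A", "B", "C", "D", "E", "F")
DEFAULT_POLARITY = {"spanish_value": "same", "nationalism": "same",
                    "exposure": "same"}
CONSTRUCT_ITEMS = {"spanish_value": ("A", "B"), "nationalism": ("C", "D"),
                   "exposure": ("E", "F")}


def composite_score(r1: int, r2: int, polarity: str = "same") -> int:
    """Combine two 5-point ratings: same polarity → r1 + r2; opposed → r1 − r2."""
    for r in (r1, r2):
        if not (isinstance(r, (int, np.integer)) and 1 <= r <= 5):
            raise ValueError(f"rating {r!r} outside 1..5")
    if polarity == "same":
        return int(r1 + r2)
    if polarity == "opposed":
        return int(r1 - r2)
    raise ValueError(f"unknown polarity {polarity!r}")


def add_composites(profiles: pd.DataFrame,
                   polarity: dict[str, str] | None = None) -> pd.DataFrame:
    """Append spanish_value, nationalism, and exposure columns."""
    polarity = {**DEFAULT_POLARITY, **(polarity or {})}
    out = profiles.copy()
    for construct, (i1, i2) in CONSTRUCT_ITEMS.items():
        out[construct] = [
            composite_score(int(a), int(b), polarity[construct])
            for a, b in zip(profiles[i1], profiles[i2])
        ]
    return out


@dataclass
class PolychoricResult:
    rho: float
    row_thresholds: np.ndarray
    col_thresholds: np.ndarray
    loglike: float


def _cell_logprobs(rho: float, rt: np.ndarray, ct: np.ndarray) -> np.ndarray:
    a = np.concatenate(([-8.0], rt, [8.0]))
    b = np.concatenate(([-8.0], ct, [8.0]))
    bvn = multivariate_normal(mean=[0.0, 0.0],
                              cov=[[1.0, rho], [rho, 1.0]])
    grid = np.array([(x, y) for x in a for y in b])
    C = bvn.cdf(grid).reshape(len(a), len(b))
    P = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
    return np.log(np.clip(P, 1e-300, None))


def polychoric_corr(table) -> PolychoricResult:
    """Two-step polychoric correlation from a K1×K2 contingency table."""
    tab = np.asarray(table, float)
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("table needs ≥ 2 occupied rows and columns")
    n = tab.sum()
    rt = norm.ppf(np.cumsum(tab.sum(axis=1))[:-1] / n)
    ct = norm.ppf(np.cumsum(tab.sum(axis=0))[:-1] / n)

    def negll(rho):
        return -float((tab * _cell_logprobs(rho, rt, ct)).sum())

    res = minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-6})
    return PolychoricResult(rho=float(res.x), row_thresholds=rt,
                            col_thresholds=ct, loglike=-float(res.fun))


def polychoric_from_ratings(x, y) -> PolychoricResult:
    """Polychoric correlation of two ordinal vectors."""
    tab = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
    return polychoric_corr(tab)


def response_percentages(counts) -> np.ndarray:
    """Percentages (0–100) of response counts, e.g. disagree/neutral/agree."""
    c = np.asarray(counts, float)
    if c.sum() <= 0 or np.any(c < 0):
        raise ValueError("counts must be nonnegative with positive total")
    return 100.0 * c / c.sum()
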