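"""Constant-stimuli psychometric analysis of the touch comparison task.

A standard monofilament force (1.4 g) is compared against six comparison
forces in a two-interval design; per comparison force x the fraction of
"stronger" reports is tabulated and a two-parameter cumulative logistic

    F(x) = 1 / (1 + exp(-(a + b·x)))

is fitted by (weakly ridge-penalized) maximum likelihood.  The point of
subjective equality is PSE = −a/b and the slope of the curve at the 50 %
point — the sensitivity index compared between groups — is b/4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit


@dataclass(frozen=True)
class ConstantStimuliDesign:
    """Trial plan: 6 comparison forces × 32 trials split over 4 blocks."""

    standard_g: float = 1.4
    comparisons_g: tuple = (0.4, 0.6, 1.0, 2.0, 4.0, 6.0)
    trials_per_comparison: int = 32
    blocks: int = 4

    def __post_init__(self) -> None:
        if self.standard_g in self.comparisons_g:
            raise ValueError("the standard force must not appear among the comparisons")
        if self.trials_per_comparison % self.blocks:
            raise ValueError("trials_per_comparison must divide evenly into blocks")

    @property
    def total_trials(self) -> int:
        return len(self.comparisons_g) * self.trials_per_comparison

    def trial_list(self, rng: np.random.Generator | None = None) -> pd.DataFrame:
        """Full trial table; order shuffled within block when an rng is given.

        ``order`` records which interval held the standard stimulus
        (counterbalanced stochastically when shuffled).
        """
        per_block = self.trials_per_comparison // self.blocks
        rows = []
        for block in range(self.blocks):
            forces = np.repeat(self.comparisons_g, per_block)
            if rng is not None:
                forces = rng.permutation(forces)
            for i, force in enumerate(forces):
                order = "standard_first"
                if rng is not None and rng.random() < 0.5:
                    order = "comparison_first"
                rows.append({"block": block, "trial_index": i,
                             "comparison_g": float(force), "order": order})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ResponseTable:
    """Counts of "stronger" responses per comparison force (ascending)."""

    table: pd.DataFrame  # columns: comparison_g, n_trials, n_stronger, fraction_stronger

    @property
    def forces(self) -> np.ndarray:
        return self.table["comparison_g"].to_numpy()

    @property
    def is_separable(self) -> bool:
        """True when every observed fraction is exactly 0 or 1 (the MLE of
        the scale parameter then diverges)."""
        f = self.table["fraction_stronger"].to_numpy()
        return bool(np.all((f == 0.0) | (f == 1.0)))


def tabulate(trials: pd.DataFrame,
             design: ConstantStimuliDesign | None = None) -> ResponseTable:
    """Aggregate per-trial stronger/weaker responses into a response table.

    ``trials`` needs columns ``comparison_g`` and ``response_stronger``
    (boolean / 0-1).  Forces not in the design are rejected, naming the
    offending trial.
    """
    if len(trials) == 0:
        raise ValueError("no trials to tabulate")
    design = design or ConstantStimuliDesign()
    known = np.asarray(design.comparisons_g)
    for idx, force in trials["comparison_g"].items():
        if not np.any(np.isclose(known, force)):
            raise ValueError(f"trial {idx}: force {force} g is not part of the design")
    grouped = trials.groupby("comparison_g")["response_stronger"].agg(["count", "sum"])
    grouped = grouped.sort_index().reset_index()
    grouped.columns = ["comparison_g", "n_trials", "n_stronger"]
    grouped["n_stronger"] = grouped["n_stronger"].astype(int)
    grouped["fraction_stronger"] = grouped["n_stronger"] / grouped["n_trials"]
    return ResponseTable(grouped)


@dataclass(frozen=True)
class PsychometricFit:
    """Two-parameter cumulative-logistic fit F(x) = expit(a + b·x)."""

    a: float
    b: float
    log_likelihood: float
    converged: bool
    guess_rate: float = 0.0
    lapse_rate: float = 0.0

    @property
    def pse(self) -> float:
        """Force at which the core logistic crosses 0.5 (grams)."""
        return -self.a / self.b

    def predict(self, x) -> np.ndarray:
        core = expit(self.a + self.b * np.asarray(x, dtype=float))
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * core


def fit_logistic(
    table: ResponseTable,
    guess_rate: float = 0.0,
    lapse_rate: float = 0.0,
    ridge: float = 1e-4,
) -> PsychometricFit:
    """Penalized maximum-likelihood fit of the two-parameter logistic.

    Maximizes the Bernoulli log-likelihood of the counts with a weak ridge
    penalty ``ridge·b²`` that stabilizes near-separable data (6 forces ×
    32 trials can separate).  ``guess_rate``/``lapse_rate`` are optional
    *fixed* asymptotes, not free parameters.  On fully separable data the
    fit is returned with ``converged = False`` and a warning.
    """
    df = table.table
    if len(df) < 2:
        raise ValueError("need responses at >= 2 distinct forces")
    x = df["comparison_g"].to_numpy(dtype=float)
    n = df["n_trials"].to_numpy(dtype=float)
    k = df["n_stronger"].to_numpy(dtype=float)

    def nll(params: np.ndarray) -> float:
        a, b = params
        core = expit(a + b * x)
        p = guess_rate + (1.0 - guess_rate - lapse_rate) * core
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        ll = np.sum(k * np.log(p) + (n - k) * np.log1p(-p))
        return -ll + ridge * b * b

    # moment-based start: regress empirical logits on force
    frac = np.clip((k + 0.5) / (n + 1.0), 1e-6, 1 - 1e-6)
    logits = np.log(frac / (1.0 - frac))
    b0 = max(np.polyfit(x, logits, 1)[0], 0.05)
    a0 = float(np.mean(logits) - b0 * np.mean(x))
    res = minimize(nll, x0=np.array([a0, b0]), method="L-BFGS-B",
                   bounds=[(None, None), (1e-9, None)])
    converged = bool(res.success)
    if table.is_separable:
        converged = False
        warnings.warn("response fractions are fully separable; the scale "
                      "parameter is only bounded by the ridge penalty",
                      RuntimeWarning, stacklevel=2)
    a, b = (float(v) for v in res.x)
    ll = -(float(nll(res.x)) - ridge * b * b)  # data log-likelihood, penalty removed
    return PsychometricFit(a=a, b=b, log_likelihood=ll, converged=converged,
                           guess_rate=guess_rate, lapse_rate=lapse_rate)


def slope_at_pse(fit: PsychometricFit) -> float:
    """Derivative of the fitted curve at the 50 % point of its core
    logistic: (1 − guess − lapse) · b / 4 (fraction per gram).

    Raises on a non-converged fit — a diverging scale makes the slope
    meaningless.
    """
    if not fit.converged:
        raise ValueError("slope_at_pse requires a converged fit")
    return (1.0 - fit.guess_rate - fit.lapse_rate) * fit.b / 4.0


def simulate_comparison_trials(
    p_stronger, design: ConstantStimuliDesign, rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate a full constant-stimuli session for one observer.

    ``p_stronger`` maps a comparison force (g) to the probability of a
    "stronger" report.
    """
    trials = design.trial_list(rng)
    probs = np.array([p_stronger(f) for f in trials["comparison_g"]])
    trials["response_stronger"] = rng.random(len(trials)) < probs
    return trials
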