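"""2AFC experiment engine, psychometric fitting and bootstrap CIs.

A run produces one :class:`TrialRecord` per trial; the proportion of "test
chosen" (or correct) responses as a function of the signed number offset W is
fitted with a two-parameter cumulative Gaussian by maximum likelihood:

    signed:    P(choose test | W) = Phi((W - mu) / sigma)
    unsigned:  P(correct | W)     = Phi(W / sigma)        (mu fixed at 0)

mu is the 50% point (PSE) and sigma the slope.  The just-noticeable
difference is the 84%-correct offset, i.e. one sigma, so the Weber fraction
in percent of the 64-dot standard is simply 100 * sigma.  Confidence
intervals are parametric bootstrap: 160 simulated re-runs of the exact
experimental procedure at the fitted parameters, refitted, central 95%.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import binomtest, norm

from .observers import EnergyObserver
from .stimuli import GenConfig, gen_trial_pair

SIGMA_FLOOR = 1e-3   # complete-separation guard, well below the 5% W grid
SIGMA_CEIL = 10.0


class FitError(RuntimeError):
    """Raised when a psychometric fit cannot be computed."""


@dataclass
class TrialRecord:
    """One 2AFC trial of a model observer."""

    index: int
    W_signed: float          # positive = test more numerous
    realized_test_n: int
    condition: str
    blur_std: float
    blur_test: float
    contrast_std: float
    contrast_test: float
    choice: str              # 'standard' | 'test'
    correct: bool
    energy_std: float | None = None
    energy_test: float | None = None
    s_hat_std: float | None = None
    s_hat_test: float | None = None


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian psychometric fit."""

    mu: float
    sigma: float
    loglik: float
    n_trials: int
    parameterization: str    # 'signed' | 'unsigned'
    converged: bool
    at_bound: bool = False

    def prob(self, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        if self.parameterization == "signed":
            return norm.cdf((w - self.mu) / self.sigma)
        return norm.cdf(np.abs(w) / self.sigma)


@dataclass
class BootstrapCI:
    """Central 95% parametric-bootstrap intervals (160 refits)."""

    mu: tuple[float, float]
    sigma: tuple[float, float]
    weber: tuple[float, float]
    n_boot: int = 160
    level: float = 0.95
    unreliable: bool = False


def _nll(w: np.ndarray, y: np.ndarray, mu: float, sigma: float, signed: bool) -> float:
    if signed:
        p = norm.cdf((w - mu) / sigma)
    else:
        p = norm.cdf(w / sigma)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_psychometric(w, y, mode: str = "signed") -> PsychometricFit:
    """ML Bernoulli fit of the cumulative-Gaussian psychometric function.

    ``w``: stimulus levels (signed W, or unsigned |W| for percent-correct
    mode); ``y``: binary responses (chose-test, or correct).  Five restarts
    around moment-based initial values; sigma constrained to
    [1e-3, 10] — a fit pinned at the lower bound indicates responses that
    are perfectly separated at the grid's resolution.
    """
    w = np.asarray(w, dtype=float)
    y = np.asarray(y, dtype=float)
    if w.shape != y.shape or w.ndim != 1:
        raise FitError("w and y must be 1D arrays of equal length")
    if len(w) < 4:
        raise FitError("need at least 4 trials")
    if mode not in ("signed", "unsigned"):
        raise FitError(f"unknown parameterization {mode!r}")
    levels = np.unique(w)
    if len(levels) < 2 or len(np.unique(y)) < 2:
        # complete one-sidedness: all the same response, or a single level
        if len(np.unique(y)) < 2:
            sigma = SIGMA_FLOOR if y.mean() in (0.0, 1.0) else SIGMA_CEIL
            return PsychometricFit(0.0, sigma, -_nll(w, y, 0.0, sigma, mode == "signed"),
                                   len(w), mode, converged=True, at_bound=True)
        raise FitError("need responses at >= 2 distinct stimulus levels")

    signed = mode == "signed"
    span = max(w.max() - w.min(), 0.05)
    if signed:
        inits = [(0.0, 0.3 * span), (0.0, 0.05), (float(np.median(w)), 0.15),
                 (0.1 * span, 0.5 * span), (-0.1 * span, 0.1 * span)]
        best = None
        for mu0, s0 in inits:
            res = minimize(
                lambda t: _nll(w, y, t[0], math.exp(t[1]), True),
                x0=np.array([mu0, math.log(max(s0, SIGMA_FLOOR))]),
                method="L-BFGS-B",
                bounds=[(-2.0, 2.0), (math.log(SIGMA_FLOOR), math.log(SIGMA_CEIL))])
            if best is None or res.fun < best.fun:
                best = res
        mu = float(best.x[0])
        sigma = float(math.exp(best.x[1]))
        ok = bool(best.success) or best.fun < _nll(w, y, 0.0, 0.3 * span, True)
        loglik = -float(best.fun)
    else:
        res = minimize_scalar(
            lambda ls: _nll(w, y, 0.0, math.exp(ls), False),
            bounds=(math.log(SIGMA_FLOOR), math.log(SIGMA_CEIL)), method="bounded")
        mu = 0.0
        sigma = float(math.exp(res.x))
        ok = bool(res.success)
        loglik = -float(res.fun)
    at_bound = sigma <= SIGMA_FLOOR * 1.01 or sigma >= SIGMA_CEIL * 0.99
    return PsychometricFit(mu, sigma, loglik, len(w), mode, ok, at_bound)


def fit_records(records: Sequence[TrialRecord], mode: str = "signed") -> PsychometricFit:
    """Fit a psychometric function to a list of trial records."""
    if mode == "signed":
        w = np.array([r.W_signed for r in records])
        y = np.array([1.0 if r.choice == "test" else 0.0 for r in records])
    else:
        w = np.array([abs(r.W_signed) for r in records])
        y = np.array([1.0 if r.correct else 0.0 for r in records])
    return fit_psychometric(w, y, mode)


def weber_from_fit(fit: PsychometricFit, n_standard: int = 64) -> float:
    """Weber fraction in percent: JND (= 64 * sigma dots, the 84% offset)
    times 100 / 64, i.e. simply 100 * sigma."""
    if not fit.converged:
        raise FitError("cannot derive a Weber fraction from an unconverged fit")
    return 100.0 * fit.sigma


def jnd_dots_from_fit(fit: PsychometricFit, n_standard: int = 64) -> float:
    """JND in dots at the 84% criterion: n_standard * sigma."""
    return n_standard * fit.sigma


# ---------------------------------------------------------------------------
# trial placement
# ---------------------------------------------------------------------------

def adaptive_place(records: Sequence[TrialRecord], grid: Sequence[float],
                   rng: np.random.Generator, burn_in: int = 10) -> float:
    """Adaptive W placement: uniform over the grid for the first ``burn_in``
    trials, then the signed grid value nearest mu_hat + sigma_hat or
    mu_hat - sigma_hat (alternating), from a refit on all trials so far.
    Falls back to uniform sampling when the interim fit is degenerate."""
    grid = np.asarray(grid, dtype=float)
    signed_grid = np.concatenate([-grid[::-1], grid])
    if len(records) < burn_in:
        return float(rng.choice(signed_grid))
    try:
        fit = fit_records(records, "signed")
    except FitError:
        return float(rng.choice(signed_grid))
    target = fit.mu + (fit.sigma if len(records) % 2 == 0 else -fit.sigma)
    return float(signed_grid[np.argmin(np.abs(signed_grid - target))])


def constant_place(grid: Sequence[float], rng: np.random.Generator,
                   test_always_more: bool) -> float:
    """Constant-stimulus placement: W uniform on the grid, with a random sign
    unless the design forces the test to be the more numerous stimulus."""
    w = float(rng.choice(np.asarray(grid, dtype=float)))
    if test_always_more or rng.random() < 0.5:
        return w
    # negative offsets: a test with 64(1 - W) = 0 dots is not a
    # discrimination trial, so W = 1 only ever appears with positive sign
    return -w if w < 0.999 else w


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------

def _one_trial(observer: EnergyObserver, config: GenConfig, w_signed: float,
               index: int, gen_rng: np.random.Generator,
               dec_rng: np.random.Generator,
               record_energies: bool) -> TrialRecord:
    sign = 1 if w_signed > 0 else -1
    pair = gen_trial_pair(config, abs(w_signed), sign, gen_rng)
    dec = observer.decide(pair, dec_rng)
    correct = (dec.choice == "test") == (sign > 0)
    rec = TrialRecord(index=index, W_signed=w_signed,
                      realized_test_n=pair.n_test, condition=pair.condition,
                      blur_std=pair.blur_std, blur_test=pair.blur_test,
                      contrast_std=pair.contrast_std,
                      contrast_test=pair.contrast_test,
                      choice=dec.choice, correct=correct)
    if record_energies:
        rec.energy_std = dec.E_std_used
        rec.energy_test = dec.E_test_used
        rec.s_hat_std = dec.s_hat_std
        rec.s_hat_test = dec.s_hat_test
    return rec


def run_2afc(observer: EnergyObserver, config: GenConfig, n_trials: int,
             rng: np.random.Generator, placement: str = "constant",
             record_energies: bool = False) -> list[TrialRecord]:
    """Run a seeded block of 2AFC trials with one observer.

    ``placement`` is ``'constant'`` (W uniform over the grid) or
    ``'adaptive'`` (burn-in then +/- sigma concentration).  The whole
    sequence — stimuli and decisions — is reproducible from ``rng``.
    """
    if placement not in ("constant", "adaptive"):
        raise ValueError(f"unknown placement {placement!r}")
    gen_rng, dec_rng, place_rng = (np.random.default_rng(s)
                                   for s in rng.spawn(3))
    records: list[TrialRecord] = []
    for i in range(n_trials):
        if placement == "constant":
            w_signed = constant_place(config.w_grid, place_rng, config.test_always_more)
        else:
            w_signed = adaptive_place(records, config.w_grid, place_rng)
            if config.test_always_more:
                w_signed = abs(w_signed)
        try:
            records.append(_one_trial(observer, config, w_signed, i,
                                      gen_rng, dec_rng, record_energies))
        except Exception as exc:
            raise RuntimeError(f"observer failed on trial {i}") from exc
    return records


def run_2afc_shared(observers: dict[str, EnergyObserver], config: GenConfig,
                    n_trials: int, rng: np.random.Generator,
                    record_energies: bool = False) -> dict[str, list[TrialRecord]]:
    """Run several observers on the *identical* stimulus sequence (the yoked
    design: the sequence is generated once and every observer judges the same
    trials).  Constant-stimulus placement only."""
    seeds = rng.spawn(2 + len(observers))
    gen_rng = np.random.default_rng(seeds[0])
    place_rng = np.random.default_rng(seeds[1])
    dec_rngs = {name: np.random.default_rng(s)
                for name, s in zip(observers, seeds[2:])}
    out: dict[str, list[TrialRecord]] = {name: [] for name in observers}
    for i in range(n_trials):
        w_signed = constant_place(config.w_grid, place_rng, config.test_always_more)
        sign = 1 if w_signed > 0 else -1
        pair = gen_trial_pair(config, abs(w_signed), sign, gen_rng)
        for name, obs in observers.items():
            dec = obs.decide(pair, dec_rngs[name])
            correct = (dec.choice == "test") == (sign > 0)
            rec = TrialRecord(index=i, W_signed=w_signed,
                              realized_test_n=pair.n_test,
                              condition=pair.condition,
                              blur_std=pair.blur_std, blur_test=pair.blur_test,
                              contrast_std=pair.contrast_std,
                              contrast_test=pair.contrast_test,
                              choice=dec.choice, correct=correct)
            if record_energies:
                rec.energy_std = dec.E_std_used
                rec.energy_test = dec.E_test_used
                rec.s_hat_std = dec.s_hat_std
                rec.s_hat_test = dec.s_hat_test
            out[name].append(rec)
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(fit: PsychometricFit, w, n_boot: int = 160,
                 rng: np.random.Generator | None = None,
                 level: float = 0.95) -> BootstrapCI:
    """Parametric bootstrap: simulate ``n_boot`` full response sets from the
    fitted model at the same W placements, refit each, and return the central
    ``level`` interval of mu, sigma and the Weber fraction."""
    if not fit.converged:
        raise FitError("bootstrap requires a converged fit")
    if rng is None:
        rng = np.random.default_rng()
    w = np.asarray(w, dtype=float)
    p = fit.prob(w)
    mus, sigmas = [], []
    failures = 0
    for _ in range(n_boot):
        y = (rng.random(len(w)) < p).astype(float)
        try:
            f = fit_psychometric(w if fit.parameterization == "signed" else np.abs(w),
                                 y, fit.parameterization)
        except FitError:
            failures += 1
            continue
        mus.append(f.mu)
        sigmas.append(f.sigma)
    if not sigmas:
        raise FitError("all bootstrap refits failed")
    q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
    mu_ci = tuple(np.percentile(mus, q))
    sg_ci = tuple(np.percentile(sigmas, q))
    weber_ci = (100 * sg_ci[0], 100 * sg_ci[1])
    return BootstrapCI(mu_ci, sg_ci, weber_ci, n_boot, level,
                       unreliable=failures > 0.1 * n_boot)


def binomial_point_cis(w, y, level: float = 0.95) -> pd.DataFrame:
    """Per-level binomial confidence intervals for plotting the psychometric
    data points: one row per distinct W with p_hat and the exact
    (Clopper-Pearson) interval."""
    w = np.asarray(w, dtype=float)
    y = np.asarray(y, dtype=float)
    rows = []
    for lvl in np.unique(w):
        sel = w == lvl
        n = int(sel.sum())
        k = int(y[sel].sum())
        ci = binomtest(k, n).proportion_ci(confidence_level=level)
        rows.append({"W": float(lvl), "n": n, "k": k, "p": k / n,
                     "lo": float(ci.low), "hi": float(ci.high)})
    return pd.DataFrame(rows)
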