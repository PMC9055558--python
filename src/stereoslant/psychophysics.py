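"""Trial simulation, psychometric fitting, and the internal-noise +
efficiency model.

Discrimination performance is summarized by a cumulative-Gaussian
psychometric function of the slant difference Δs between test and
reference:

    p("more slanted") = Φ((Δs − β) / (k·σ))

β is the bias (50% point) and σ the spread.  With the default link factor
k = 1, discriminability is d' = Δs/σ, and the threshold — defined as the
Δs at which d' = 1 — equals σ.

Model observers are additionally summarized by the first two moments of
their slant-difference estimates per condition: the mean Δs̄ at each test
level and the dispersion σ.  Two free parameters map model moments onto a
real observer's data: an efficiency scalar ε that scales down all d'
values, and an internal estimation noise σ₀ added in quadrature:

    d'(Δs) = ε·Δs̄ / sqrt(σ² + σ₀²)        threshold Δs_t = (1/ε)·sqrt(σ² + σ₀²)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm


@dataclass
class PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit."""

    beta: float  # bias: 50% point, degrees
    sigma: float  # spread, degrees
    log_likelihood: float
    k: float = 1.0  # link factor in Phi((x - beta)/(k sigma))
    ci: dict = field(default_factory=dict)  # percentile bootstrap CIs

    @property
    def threshold(self) -> float:
        """Δs at d' = 1 (equals the spread parameter)."""
        return self.sigma


@dataclass
class NoiseEfficiencyModel:
    """Efficiency scalar and internal estimation noise fitted to data."""

    epsilon: float
    sigma0: float
    conditions: pd.DataFrame  # per condition: sigma, predicted_threshold, ...
    log_likelihood: float | None = None
    rmse: float | None = None
    ci: dict = field(default_factory=dict)


def predicted_threshold(sigma, epsilon: float, sigma0: float):
    """Threshold of the two-parameter model: (1/ε)·sqrt(σ² + σ₀²)."""
    return np.sqrt(np.asarray(sigma) ** 2 + sigma0**2) / epsilon


# ---------------------------------------------------------------------------
# trial simulation


def simulate_condition(
    estimator: Callable[[float, int], float],
    reference_slant: float,
    test_slants: Sequence[float],
    n_trials: int,
    seed: int,
    noise_rms: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate binary discrimination trials of a model observer.

    ``estimator(test_slant, seed)`` returns one slant estimate for a fresh
    stimulus (new texture and noise every trial).  The response on each
    trial is 1 if the estimated test slant exceeds the known reference
    slant.  Returns ``(trials, stats)``: the trial table and per-level
    moments of the slant-difference estimates (Δs̄ and their SD).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    test_slants = list(test_slants)
    if not test_slants:
        raise ValueError("need at least one test slant")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(test_slants) * n_trials).reshape(
        len(test_slants), n_trials
    )
    rows = []
    for i, s_t in enumerate(test_slants):
        for j in range(n_trials):
            trial_seed = int(seeds[i, j] % (2**31))
            est = float(estimator(float(s_t), trial_seed))
            rows.append(
                {
                    "reference_slant": reference_slant,
                    "test_slant": s_t,
                    "delta": s_t - reference_slant,
                    "noise_rms": noise_rms,
                    "estimate": est,
                    "estimate_delta": est - reference_slant,
                    "response": int(est > reference_slant),
                    "seed": trial_seed,
                }
            )
    trials = pd.DataFrame(rows)
    stats = (
        trials.groupby("delta")["estimate_delta"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return trials, stats


# ---------------------------------------------------------------------------
# psychometric fitting


def _nll_psychometric(params, deltas, responses, k):
    beta, log_sigma = params
    sigma = np.exp(log_sigma)
    p = norm.cdf((deltas - beta) / (k * sigma))
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -np.sum(responses * np.log(p) + (1 - responses) * np.log(1 - p))


def fit_psychometric(
    trials: pd.DataFrame,
    k: float = 1.0,
    n_boot: int = 0,
    ci_level: float = 0.95,
    seed: int = 0,
) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit to binary trials.

    ``trials`` needs columns ``delta`` and ``response``.  Bootstrap CIs
    (optional) resample the number of positive responses at each level
    from a binomial with the observed rate, refitting each resample.
    """
    deltas = np.asarray(trials["delta"], dtype=float)
    responses = np.asarray(trials["response"], dtype=int)
    if len(np.unique(deltas)) < 2:
        raise ValueError("need at least two distinct test levels")
    if responses.min() == responses.max():
        raise ValueError("responses are all identical: fit not identifiable")

    def do_fit(d, r):
        # moment-based start: probit-linear approximation
        beta0 = float(np.interp(0.5, *_empirical_curve(d, r))) if len(d) else 0.0
        spread0 = max(np.ptp(d) / 4.0, 1e-3)
        res = optimize.minimize(
            _nll_psychometric,
            x0=[beta0, np.log(spread0)],
            args=(d, r, k),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
        )
        return res.x[0], float(np.exp(res.x[1])), -res.fun

    beta, sigma, ll = do_fit(deltas, responses)
    ci = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        levels, counts = np.unique(deltas, return_counts=True)
        rates = np.array(
            [responses[deltas == lv].mean() for lv in levels]
        )
        bs, bb = [], []
        for _ in range(n_boot):
            pos = rng.binomial(counts, rates)
            d_rep = np.repeat(levels, counts)
            r_rep = np.concatenate(
                [
                    np.r_[np.ones(p, dtype=int), np.zeros(c - p, dtype=int)]
                    for p, c in zip(pos, counts)
                ]
            )
            if r_rep.min() == r_rep.max():
                continue
            b, s, _ = do_fit(d_rep, r_rep)
            bb.append(b)
            bs.append(s)
        if bs:
            q = [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100]
            ci = {
                "threshold": tuple(np.percentile(bs, q)),
                "beta": tuple(np.percentile(bb, q)),
                "level": ci_level,
            }
    return PsychometricFit(beta=float(beta), sigma=float(sigma), log_likelihood=ll, k=k, ci=ci)


def _empirical_curve(deltas, responses):
    levels = np.unique(deltas)
    rates = np.array([responses[deltas == lv].mean() for lv in levels])
    order = np.argsort(rates)
    return rates[order], levels[order]


def threshold_from_estimates(
    deltas: Sequence[float],
    mean_estimates: Sequence[float],
    sd: float,
    epsilon: float = 1.0,
    sigma0: float = 0.0,
) -> float:
    """Threshold from the moments of a model's slant-difference estimates.

    Discriminability grows along the estimate-vs-level regression line:
    d'(Δs) = ε·b·Δs / sqrt(σ² + σ₀²) with slope b fitted by least squares
    (b = 1 for an unbiased observer).  The threshold (d' = 1) is
    sqrt(σ² + σ₀²) / (ε·b).
    """
    deltas = np.asarray(deltas, dtype=float)
    means = np.asarray(mean_estimates, dtype=float)
    if len(deltas) < 2:
        raise ValueError("need at least two levels to estimate the slope")
    slope = np.polyfit(deltas, means, 1)[0]
    if slope <= 0:
        raise ValueError("non-positive response slope: threshold undefined")
    return float(np.sqrt(sd**2 + sigma0**2) / (epsilon * slope))


def pooled_sd(trials: pd.DataFrame) -> float:
    """Dispersion of slant-difference estimates pooled across levels after
    removing each level's mean (bias-corrected)."""
    resid = trials.groupby("delta")["estimate_delta"].transform(
        lambda v: v - v.mean()
    )
    n_levels = trials["delta"].nunique()
    return float(np.sqrt(np.sum(resid**2) / max(len(resid) - n_levels, 1)))


# ---------------------------------------------------------------------------
# merging mirrored conditions and observer scaling


def merge_mirrored_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Merge conditions with mirrored reference slants (e.g. +50 and −50).

    Trials with a negative reference slant are reflected: the sign of the
    slant difference flips, and so does the response.  The merged table is
    keyed by the reference-slant magnitude.
    """
    refs = set(np.round(trials["reference_slant"], 9))
    for r in refs:
        if r != 0 and -r not in refs:
            raise ValueError(f"unmatched mirrored condition for reference {r}")
    out = trials.copy()
    neg = out["reference_slant"] < 0
    out.loc[neg, "delta"] = -out.loc[neg, "delta"]
    if "estimate_delta" in out:
        out.loc[neg, "estimate_delta"] = -out.loc[neg, "estimate_delta"]
    out.loc[neg, "response"] = 1 - out.loc[neg, "response"]
    out["reference_slant"] = out["reference_slant"].abs()
    return out


def scale_to_anchor(
    thresholds: pd.DataFrame,
    anchor: str,
    observer_col: str = "observer",
    value_col: str = "threshold",
) -> dict[str, float]:
    """Per-observer multiplicative factors aligning each observer's
    thresholds with an anchor observer's, in the least-squares sense.

    The factor c minimizes sum((c·t_obs − t_anchor)²) over the shared
    conditions; the same factor should be applied to biases.
    """
    cond_cols = [
        c for c in thresholds.columns if c not in (observer_col, value_col)
    ]
    wide = thresholds.pivot_table(
        index=cond_cols, columns=observer_col, values=value_col
    )
    if anchor not in wide:
        raise ValueError(f"anchor observer {anchor!r} not in table")
    factors = {}
    ta = wide[anchor].to_numpy()
    for obs in wide.columns:
        to = wide[obs].to_numpy()
        mask = np.isfinite(to) & np.isfinite(ta)
        if not mask.any():
            raise ValueError(f"no shared conditions between {obs!r} and anchor")
        factors[obs] = float(np.sum(to[mask] * ta[mask]) / np.sum(to[mask] ** 2))
    return factors


# ---------------------------------------------------------------------------
# internal noise + efficiency fitting


def _nll_noise_efficiency(params, table, k=1.0):
    log_eps, sigma0 = params
    eps = np.exp(log_eps)
    dprime = eps * table["model_mean"].to_numpy() / np.sqrt(
        table["model_sd"].to_numpy() ** 2 + sigma0**2
    )
    p = np.clip(norm.cdf(dprime / k), 1e-9, 1 - 1e-9)
    n_pos = table["n_pos"].to_numpy()
    n_tot = table["n"].to_numpy()
    return -np.sum(n_pos * np.log(p) + (n_tot - n_pos) * np.log(1 - p))


def fit_noise_efficiency(
    model_stats: pd.DataFrame,
    trials: pd.DataFrame,
    condition_cols: Sequence[str] = ("reference_slant", "noise_rms"),
    k: float = 1.0,
    n_boot: int = 0,
    seed: int = 0,
) -> NoiseEfficiencyModel:
    """Fit the efficiency scalar ε and internal noise σ₀ by maximizing the
    likelihood of binary trial data under the model observer's moments.

    ``model_stats`` must carry, per condition and test level (``delta``),
    the model's mean slant-difference estimate (``mean``) and the
    condition's estimate dispersion (``sd``).  ``trials`` carries binary
    responses at matching conditions and levels.  Predicted thresholds per
    condition follow the quadrature rule Δs_t = (1/ε)·sqrt(σ² + σ₀²).
    """
    condition_cols = list(condition_cols)
    key = condition_cols + ["delta"]
    agg = (
        trials.groupby(key)["response"].agg(n_pos="sum", n="count").reset_index()
    )
    stats = model_stats.rename(
        columns={"mean": "model_mean", "sd": "model_sd"}
    )
    table = agg.merge(stats[key + ["model_mean", "model_sd"]], on=key, how="left")
    if table["model_mean"].isna().any():
        missing = table[table["model_mean"].isna()][key]
        raise ValueError(f"model stats missing for conditions:\n{missing}")

    def do_fit(tbl):
        best = None
        for s0_init in (0.1, 1.0, 3.0):
            res = optimize.minimize(
                _nll_noise_efficiency,
                x0=[0.0, s0_init],
                args=(tbl, k),
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        eps = float(np.exp(best.x[0]))
        s0 = float(abs(best.x[1]))
        return eps, s0, -float(best.fun)

    eps, s0, ll = do_fit(table)
    if not np.isfinite(ll):
        raise ValueError("non-finite likelihood in noise/efficiency fit")

    cond = (
        stats.groupby(condition_cols)["model_sd"].first().reset_index()
        .rename(columns={"model_sd": "sigma"})
    )
    cond["predicted_threshold"] = predicted_threshold(cond["sigma"], eps, s0)

    ci = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        eb, sb = [], []
        for _ in range(n_boot):
            t = table.copy()
            t["n_pos"] = rng.binomial(t["n"], np.clip(t["n_pos"] / t["n"], 0, 1))
            try:
                e_i, s_i, _ = do_fit(t)
            except Exception:
                continue
            eb.append(e_i)
            sb.append(s_i)
        if eb:
            ci = {
                "epsilon": tuple(np.percentile(eb, [16, 84])),
                "sigma0": tuple(np.percentile(sb, [16, 84])),
                "level": 0.68,
            }
    return NoiseEfficiencyModel(
        epsilon=eps, sigma0=s0, conditions=cond, log_likelihood=ll, ci=ci
    )


def fit_rmse(model: NoiseEfficiencyModel, observed: pd.DataFrame,
             condition_cols: Sequence[str] = ("reference_slant", "noise_rms"),
             value_col: str = "threshold") -> float:
    """Root-mean-squared error between predicted and observed thresholds."""
    merged = model.conditions.merge(observed, on=list(condition_cols))
    err = merged["predicted_threshold"] - merged[value_col]
    rmse = float(np.sqrt(np.mean(err**2)))
    model.rmse = rmse
    return rmse


def efficiency_scalar(
    model_stats: pd.DataFrame,
    trials: pd.DataFrame,
    condition_cols: Sequence[str] = ("reference_slant", "noise_rms"),
    k: float = 1.0,
    n_boot: int = 0,
    seed: int = 0,
) -> NoiseEfficiencyModel:
    """Single-parameter (σ₀ = 0) efficiency fit to trial data.

    Used to align a model observer's thresholds with a participant's in a
    condition subset (e.g. the highest-noise condition of either task).
    """
    condition_cols = list(condition_cols)
    key = condition_cols + ["delta"]
    agg = trials.groupby(key)["response"].agg(n_pos="sum", n="count").reset_index()
    stats = model_stats.rename(columns={"mean": "model_mean", "sd": "model_sd"})
    table = agg.merge(stats[key + ["model_mean", "model_sd"]], on=key, how="left")
    if table["model_mean"].isna().any():
        raise ValueError("model stats missing for some conditions")

    def nll(log_eps, tbl):
        return _nll_noise_efficiency([log_eps[0], 0.0], tbl, k)

    def do_fit(tbl):
        res = optimize.minimize_scalar(
            lambda le: nll([le], tbl), bounds=(-8, 8), method="bounded",
            options={"xatol": 1e-9},
        )
        return float(np.exp(res.x)), -float(res.fun)

    eps, ll = do_fit(table)
    cond = (
        stats.groupby(condition_cols)["model_sd"].first().reset_index()
        .rename(columns={"model_sd": "sigma"})
    )
    cond["predicted_threshold"] = predicted_threshold(cond["sigma"], eps, 0.0)
    ci = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        eb = []
        for _ in range(n_boot):
            t = table.copy()
            t["n_pos"] = rng.binomial(t["n"], np.clip(t["n_pos"] / t["n"], 0, 1))
            try:
                e_i, _ = do_fit(t)
            except Exception:
                continue
            eb.append(e_i)
        if eb:
            ci = {"epsilon": tuple(np.percentile(eb, [16, 84])), "level": 0.68}
    return NoiseEfficiencyModel(
        epsilon=eps, sigma0=0.0, conditions=cond, log_likelihood=ll, ci=ci
    )
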