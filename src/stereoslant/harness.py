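"""End-to-end simulation experiments: slant grid, depth variant, cutoff
search, and patch-width sweeps.

Thresholds are computed by the moments route: per condition the observer's
slant-difference (or distance-difference) estimates are simulated at a few
test levels around the reference, and the threshold is the bias-corrected
estimate dispersion divided by the response slope (the Δs at d' = 1).  A
trial route (binary responses fitted with a cumulative Gaussian) is
available through :mod:`stereoslant.psychophysics` and agrees with the
moments route within Monte-Carlo error (asserted in the test suite).

Every condition cell derives its random stream from the experiment seed
and its position in the condition grid, so a rerun with the same
configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import PlaneParams, ViewingGeometry, Window
from .observers import (
    ObserverConfig,
    local_matching,
    pm_estimate,
    pool_distances,
    pool_slants,
    prepare_context,
)
from .prefilter import build_lowpass, cutoff_for_noise, FilterSpec
from .psychophysics import threshold_from_estimates
from .stimulus import make_stereo_stimulus, make_texture_spec

logger = logging.getLogger("stereoslant")

#: equivalent-disparity change per cm of distance change at 100 cm, arcsec
ARCSEC_PER_CM = 6.5 / 100.0**2 * (180.0 / np.pi) * 3600.0

#: the standard slant-task condition grid
STANDARD_REFERENCE_SLANTS = (0.0, 12.5, 25.0, 50.0)
STANDARD_NOISE_LEVELS = (0.05, 0.175, 0.34)


@dataclass
class ExperimentConfig:
    """Configuration of a simulation experiment.

    ``trials_per_level`` defaults to 50 estimate draws per psychometric
    level (reduced from the human experiment's 360 trials per condition);
    bootstrap confidence intervals are always reported so comparisons at
    reduced trial counts stay honest.
    """

    task: Literal["slant", "depth"] = "slant"
    observers: tuple[str, ...] = ("PM", "LPM", "LFM")
    reference_slants: tuple[float, ...] = STANDARD_REFERENCE_SLANTS
    noise_levels: tuple[float, ...] = STANDARD_NOISE_LEVELS
    trials_per_level: int = 50
    n_levels: int = 4
    n_pilot: int = 6
    n_boot: int = 200
    seed: int = 0
    patch_width: float = 0.5
    patch_stride: float | None = None
    depth_test_slant: float = 44.0
    vg: ViewingGeometry = field(default_factory=ViewingGeometry)
    distance_jitter: tuple[float, float] = (99.0, 101.0)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class ThresholdResult:
    """Simulated discrimination threshold for one condition cell."""

    observer: str
    threshold: float
    ci_low: float
    ci_high: float
    sd: float  # bias-corrected estimate dispersion
    slope: float  # d(mean estimate)/d(level)
    n_trials: int
    seed: int
    reference_slant: float | None = None
    noise_rms: float | None = None
    units: str = "deg"
    extras: dict = field(default_factory=dict)


def _seed_for(root_seed: int, *key) -> int:
    """Deterministic per-cell seed derived from the experiment seed and a
    structured key."""
    payload = json.dumps([root_seed, *key], default=str).encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# estimators


def _observer_cfg(observer: str, base: ObserverConfig | None, **over) -> ObserverConfig:
    cfg = base or ObserverConfig()
    return replace(cfg, kind=observer, **over)


def make_slant_estimator(
    observer: str,
    noise_rms: float,
    vg: ViewingGeometry,
    fs: FilterSpec,
    ocfg: ObserverConfig,
    distance_jitter: tuple[float, float] = (99.0, 101.0),
    window: Window | None = None,
) -> Callable[[float, int], dict]:
    """Build a closure that renders one fresh trial and runs the observer.

    Returns per trial a dict of slant cues: ``s`` for PM; ``s_z`` (from
    pooled distances) and, for LPM, ``s_s`` (from pooled slants).
    """

    def estimator(test_slant: float, seed: int) -> dict:
        ss = np.random.SeedSequence(seed)
        s_tex, s_jit, s_noise = (int(x % (2**31)) for x in ss.generate_state(3))
        spec = make_texture_spec(seed=s_tex)
        zeta = float(np.random.default_rng(s_jit).uniform(*distance_jitter))
        plane = PlaneParams(test_slant, 0.0, zeta)
        stim = make_stereo_stimulus(
            spec, plane, vg, noise_rms=noise_rms, seed=s_noise, window=window
        )
        if observer == "PM":
            est = pm_estimate(stim, ocfg, fs, vg)
            return {"s": est.slant}
        emap = local_matching(stim, ocfg, fs, vg)
        s_z, _zeta_z = pool_distances(emap, vg, eye=ocfg.direction.source)
        out = {"s_z": s_z}
        if observer == "LPM":
            out["s_s"] = pool_slants(emap)
        return out

    return estimator


def make_depth_estimator(
    observer: str,
    noise_rms: float,
    vg: ViewingGeometry,
    fs: FilterSpec,
    ocfg: ObserverConfig,
    test_slant: float = 44.0,
    window: Window | None = None,
) -> Callable[[float, int], dict]:
    """Estimator for the depth task: the test plane has a fixed known
    slant and its center distance is varied; the observer reports the
    estimated center distance (cm).

    PM searches distance only, with the slant clamped to the known test
    slant; LPM/LFM run their usual local searches, and the pooled
    intercept gives the distance at the window center.
    """
    depth_cfg = replace(
        ocfg,
        kind=observer,
        fixed_slant=test_slant if observer == "PM" else None,
        distance_bounds=(98.0, 102.0),
        local_distance_bounds=(95.0, 105.0),
        distance_step=0.002,
        coarse_distance_step=0.1,
    )

    def estimator(center_distance: float, seed: int) -> dict:
        ss = np.random.SeedSequence(seed)
        s_tex, s_noise = (int(x % (2**31)) for x in ss.generate_state(2))
        spec = make_texture_spec(seed=s_tex)
        plane = PlaneParams(test_slant, 0.0, center_distance)
        stim = make_stereo_stimulus(
            spec, plane, vg, noise_rms=noise_rms, seed=s_noise, window=window
        )
        if observer == "PM":
            est = pm_estimate(stim, depth_cfg, fs, vg)
            return {"s": est.intercept_distance}
        emap = local_matching(stim, depth_cfg, fs, vg)
        _s_z, zeta_z = pool_distances(emap, vg, eye=depth_cfg.direction.source)
        return {"s_z": zeta_z}

    return estimator


# ---------------------------------------------------------------------------
# condition simulation (moments route)


def _combine_cues(df: pd.DataFrame, observer: str) -> np.ndarray:
    """Per-trial slant estimate from the simulated cue columns.

    For LPM the two cues are combined with reliability weights calibrated
    from this condition's own simulations (reciprocal variance of the
    bias-corrected cue estimates across trials).
    """
    if observer == "PM":
        return df["s"].to_numpy()
    if observer == "LFM":
        return df["s_z"].to_numpy()
    resid_z = df.groupby("level")["s_z"].transform(lambda v: v - v.mean())
    resid_s = df.groupby("level")["s_s"].transform(lambda v: v - v.mean())
    n_lev = df["level"].nunique()
    var_z = float(np.sum(resid_z**2) / max(len(df) - n_lev, 1))
    var_s = float(np.sum(resid_s**2) / max(len(df) - n_lev, 1))
    r_z = 1.0 / max(var_z, 1e-12)
    r_s = 1.0 / max(var_s, 1e-12)
    return (
        r_z * df["s_z"].to_numpy() + r_s * df["s_s"].to_numpy()
    ) / (r_z + r_s)


def simulate_threshold(
    estimator: Callable[[float, int], dict],
    observer: str,
    reference: float,
    n_trials: int,
    seed: int,
    n_levels: int = 4,
    n_pilot: int = 6,
    n_boot: int = 200,
    level_floor: float = 1e-3,
    level_cap: float = 30.0,
    levels: Sequence[float] | None = None,
) -> ThresholdResult:
    """Simulate estimates around a reference level and extract the
    threshold (dispersion / slope) with a bootstrap CI.

    Test levels are placed at ±0.75 and ±1.5 pilot SDs around the
    reference (8-level grids use ±{0.5, 1, 1.5, 2}).  The pilot SD comes
    from a handful of trials at the reference level itself.
    """
    ss = np.random.SeedSequence(seed)
    pilot_seeds, trial_entropy = ss.spawn(2)
    if levels is None:
        pseeds = pilot_seeds.generate_state(n_pilot)
        pilot = []
        for j in range(n_pilot):
            cues = estimator(reference, int(pseeds[j] % (2**31)))
            pilot.append(next(iter(cues.values())))
        sd_pilot = float(np.std(pilot, ddof=1))
        sd_pilot = min(max(sd_pilot, level_floor), level_cap)
        if n_levels >= 8:
            offsets = np.array([-2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0])
        else:
            offsets = np.array([-1.5, -0.75, 0.75, 1.5])
        levels = reference + offsets * sd_pilot
    else:
        levels = np.asarray(list(levels), dtype=float)

    tseeds = trial_entropy.generate_state(len(levels) * n_trials).reshape(
        len(levels), n_trials
    )
    rows = []
    for i, lv in enumerate(levels):
        for j in range(n_trials):
            cues = estimator(float(lv), int(tseeds[i, j] % (2**31)))
            rows.append({"level": lv - reference, **cues})
    df = pd.DataFrame(rows)

    def threshold_of(frame: pd.DataFrame) -> tuple[float, float, float]:
        est = _combine_cues(frame, observer)
        tmp = frame.assign(_est=est)
        means = tmp.groupby("level")["_est"].mean()
        resid = tmp.groupby("level")["_est"].transform(lambda v: v - v.mean())
        sd = float(
            np.sqrt(np.sum(resid**2) / max(len(tmp) - means.size, 1))
        )
        slope = float(np.polyfit(means.index.to_numpy(), means.to_numpy() - reference, 1)[0])
        thr = threshold_from_estimates(
            means.index.to_numpy(), means.to_numpy() - reference, sd
        )
        return thr, sd, slope

    thr, sd, slope = threshold_of(df)
    rng = np.random.default_rng(ss.generate_state(1)[0])
    boots = []
    for _ in range(n_boot):
        parts = [
            g.sample(n=len(g), replace=True, random_state=rng.integers(2**31))
            for _, g in df.groupby("level")
        ]
        try:
            b, _, _ = threshold_of(pd.concat(parts, ignore_index=True))
            boots.append(b)
        except ValueError:
            continue
    if boots:
        lo, hi = (float(x) for x in np.percentile(boots, [2.5, 97.5]))
    else:
        lo = hi = float("nan")
    return ThresholdResult(
        observer=observer,
        threshold=thr,
        ci_low=lo,
        ci_high=hi,
        sd=sd,
        slope=slope,
        n_trials=len(df),
        seed=seed,
    )


def model_threshold(
    observer: str = "PM",
    reference_slant: float = 50.0,
    noise_rms: float = 0.34,
    cutoff: float | None = None,
    n_trials: int = 50,
    n_levels: int = 4,
    n_pilot: int = 6,
    n_boot: int = 200,
    seed: int = 0,
    vg: ViewingGeometry | None = None,
    observer_cfg: ObserverConfig | None = None,
    patch_width: float | None = None,
    distance_jitter: tuple[float, float] = (99.0, 101.0),
) -> ThresholdResult:
    """Simulated slant-discrimination threshold for one condition cell."""
    vg = vg or ViewingGeometry()
    cutoff = cutoff if cutoff is not None else cutoff_for_noise(noise_rms)
    fs = build_lowpass(cutoff, vg)
    over = {} if patch_width is None else {"patch_width": patch_width}
    ocfg = _observer_cfg(observer, observer_cfg, **over)
    estimator = make_slant_estimator(
        observer, noise_rms, vg, fs, ocfg, distance_jitter
    )
    res = simulate_threshold(
        estimator, observer, reference_slant, n_trials, seed,
        n_levels=n_levels, n_pilot=n_pilot, n_boot=n_boot,
    )
    res.reference_slant = reference_slant
    res.noise_rms = noise_rms
    res.extras["cutoff"] = cutoff
    if observer != "PM":
        res.extras["patch_width"] = ocfg.patch_width
    return res


def depth_threshold(
    observer: str = "PM",
    noise_rms: float = 0.34,
    test_slant: float = 44.0,
    cutoff: float | None = None,
    n_trials: int = 50,
    n_levels: int = 4,
    n_pilot: int = 6,
    n_boot: int = 200,
    seed: int = 0,
    vg: ViewingGeometry | None = None,
    observer_cfg: ObserverConfig | None = None,
    patch_width: float | None = None,
) -> ThresholdResult:
    """Simulated depth-discrimination threshold (arcsec of equivalent
    disparity at the window center; cm and mm in ``extras``)."""
    vg = vg or ViewingGeometry()
    cutoff = cutoff if cutoff is not None else cutoff_for_noise(noise_rms)
    fs = build_lowpass(cutoff, vg)
    over = {} if patch_width is None else {"patch_width": patch_width}
    ocfg = _observer_cfg(observer, observer_cfg, **over)
    estimator = make_depth_estimator(observer, noise_rms, vg, fs, ocfg, test_slant)
    res = simulate_threshold(
        estimator, "PM" if observer == "PM" else "LFM",  # cue key handling
        reference=100.0, n_trials=n_trials, seed=seed,
        n_levels=n_levels, n_pilot=n_pilot, n_boot=n_boot,
        level_floor=1e-4, level_cap=1.0,
    )
    thr_cm, lo_cm, hi_cm = res.threshold, res.ci_low, res.ci_high
    res.observer = observer
    res.noise_rms = noise_rms
    res.threshold = thr_cm * ARCSEC_PER_CM
    res.ci_low = lo_cm * ARCSEC_PER_CM
    res.ci_high = hi_cm * ARCSEC_PER_CM
    res.units = "arcsec"
    res.extras.update(
        {
            "threshold_cm": thr_cm,
            "threshold_mm": thr_cm * 10.0,
            "test_slant": test_slant,
            "cutoff": cutoff,
        }
    )
    if observer != "PM":
        res.extras["patch_width"] = ocfg.patch_width
    return res


# ---------------------------------------------------------------------------
# experiment drivers


def _result_row(res: ThresholdResult) -> dict:
    row = {
        "observer": res.observer,
        "reference_slant": res.reference_slant,
        "noise_rms": res.noise_rms,
        "threshold": res.threshold,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "sd": res.sd,
        "slope": res.slope,
        "units": res.units,
        "n_trials": res.n_trials,
        "seed": res.seed,
    }
    row.update(res.extras)
    return row


def run_slant_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Thresholds over the (observer x reference slant x noise) grid.

    Per-cell failures are logged and the cell marked missing; the run
    continues.  Writes ``slant_thresholds.csv`` plus a JSON provenance
    sidecar when ``out_dir`` is given.
    """
    rows = []
    for observer in cfg.observers:
        for ref in cfg.reference_slants:
            for noise in cfg.noise_levels:
                cell_seed = _seed_for(cfg.seed, "slant", observer, ref, noise)
                try:
                    res = model_threshold(
                        observer=observer,
                        reference_slant=ref,
                        noise_rms=noise,
                        n_trials=cfg.trials_per_level,
                        n_levels=cfg.n_levels,
                        n_pilot=cfg.n_pilot,
                        n_boot=cfg.n_boot,
                        seed=cell_seed,
                        vg=cfg.vg,
                        patch_width=cfg.patch_width if observer != "PM" else None,
                        distance_jitter=cfg.distance_jitter,
                    )
                    rows.append(_result_row(res))
                    logger.info(
                        "slant cell %s ref=%s noise=%s -> %.3f deg",
                        observer, ref, noise, res.threshold,
                    )
                except Exception:
                    logger.exception(
                        "slant cell failed: %s ref=%s noise=%s", observer, ref, noise
                    )
                    rows.append(
                        {
                            "observer": observer,
                            "reference_slant": ref,
                            "noise_rms": noise,
                            "threshold": np.nan,
                            "seed": cell_seed,
                        }
                    )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        _write_outputs(table, cfg, Path(out_dir), "slant_thresholds")
    return table


def run_depth_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Depth-discrimination thresholds (arcsec and mm) per observer and
    noise level at the fixed ±test-slant."""
    rows = []
    for observer in cfg.observers:
        for noise in cfg.noise_levels:
            cell_seed = _seed_for(cfg.seed, "depth", observer, noise)
            try:
                res = depth_threshold(
                    observer=observer,
                    noise_rms=noise,
                    test_slant=cfg.depth_test_slant,
                    n_trials=cfg.trials_per_level,
                    n_levels=cfg.n_levels,
                    n_pilot=cfg.n_pilot,
                    n_boot=cfg.n_boot,
                    seed=cell_seed,
                    vg=cfg.vg,
                    patch_width=cfg.patch_width if observer != "PM" else None,
                )
                rows.append(_result_row(res))
                logger.info(
                    "depth cell %s noise=%s -> %.2f arcsec",
                    observer, noise, res.threshold,
                )
            except Exception:
                logger.exception("depth cell failed: %s noise=%s", observer, noise)
                rows.append(
                    {
                        "observer": observer,
                        "noise_rms": noise,
                        "threshold": np.nan,
                        "seed": cell_seed,
                    }
                )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        _write_outputs(table, cfg, Path(out_dir), "depth_thresholds")
    return table


def sweep_patch_width(
    cfg: ExperimentConfig,
    widths: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
    observers: Sequence[str] = ("LPM", "LFM"),
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Threshold-vs-patch-width table for the local observers."""
    if len(widths) < 2:
        raise ValueError("need at least two patch widths")
    rows = []
    for observer in observers:
        for w in widths:
            for ref in cfg.reference_slants:
                for noise in cfg.noise_levels:
                    cell_seed = _seed_for(cfg.seed, "sweep", observer, w, ref, noise)
                    res = model_threshold(
                        observer=observer,
                        reference_slant=ref,
                        noise_rms=noise,
                        n_trials=cfg.trials_per_level,
                        n_levels=cfg.n_levels,
                        n_pilot=cfg.n_pilot,
                        n_boot=cfg.n_boot,
                        seed=cell_seed,
                        vg=cfg.vg,
                        patch_width=w,
                    )
                    row = _result_row(res)
                    row["patch_width"] = w
                    rows.append(row)
                    logger.info(
                        "sweep %s w=%.2f ref=%s noise=%s -> %.3f deg",
                        observer, w, ref, noise, res.threshold,
                    )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        _write_outputs(table, cfg, Path(out_dir), "patch_width_sweep")
    return table


def _write_outputs(
    table: pd.DataFrame, cfg: ExperimentConfig, out_dir: Path, stem: str
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / f"{stem}.csv", index=False)
    meta = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "rows": len(table),
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2, default=str))
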