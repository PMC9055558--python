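"""Low-pass prefiltering of the stereo pair.

Before matching, both eyes' images are passed through the same radially
symmetric low-pass filter.  The filter discards white-noise power at
spatial frequencies above the (slant-compressed) texture band, which is
the dominant way an observer can mitigate uncorrelated noise.  The gain
profile is 1 below the ramp, falls along a half-cosine ramp of fixed 1 cpd
span centered on the nominal cutoff, and is 0 above it.

The performance-optimal cutoff depends on the noise contrast: heavier
noise favors a lower cutoff (less noise passed) at the cost of some signal
at high image frequencies.  :func:`optimize_cutoff` reproduces that search
by simulating slant-discrimination thresholds of the planar-matching
observer per candidate cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import fft as sp_fft

from .geometry import ViewingGeometry
from .stimulus import StereoStimulus

#: optimal cutoffs (cpd) per noise RMS contrast, from the pilot search
DEFAULT_CUTOFFS = {0.05: 16.0, 0.175: 8.0, 0.34: 5.0}


def cutoff_for_noise(noise_rms: float) -> float:
    """Cutoff frequency used for a given noise contrast (nearest standard
    level)."""
    keys = np.array(sorted(DEFAULT_CUTOFFS))
    nearest = keys[np.argmin(np.abs(keys - noise_rms))]
    return DEFAULT_CUTOFFS[float(nearest)]


@dataclass(frozen=True)
class FilterSpec:
    """Radially symmetric low-pass filter specification.

    ``noise_sd_unit`` is the standard deviation of filtered unit-variance
    white pixel noise (Parseval: sqrt of the mean squared gain over the
    raster's frequency square); multiply by the stimulus noise RMS to get
    ``sigma_f``.
    """

    cutoff: float  # cpd
    ramp_span: float = 1.0  # cpd
    noise_sd_unit: float = 1.0

    def gain(self, f: np.ndarray) -> np.ndarray:
        """Frequency-domain gain at radial frequency ``f`` (cpd)."""
        f = np.asarray(f, dtype=float)
        lo = self.cutoff - self.ramp_span / 2.0
        hi = self.cutoff + self.ramp_span / 2.0
        g = np.where(
            f <= lo,
            1.0,
            np.where(
                f >= hi,
                0.0,
                0.5 * (1.0 + np.cos(np.pi * (f - lo) / self.ramp_span)),
            ),
        )
        return g


def build_lowpass(cutoff: float, vg: ViewingGeometry, ramp_span: float = 1.0,
                  _grid_n: int = 512) -> FilterSpec:
    """Construct the low-pass filter and its analytic filtered-noise SD.

    White pixel noise of unit variance spreads its power uniformly over the
    raster's frequency square, so the filtered variance is the mean squared
    gain over that square (evaluated on a fine FFT grid).
    """
    if not 0 < cutoff < vg.nyquist:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={vg.nyquist} cpd), got {cutoff}"
        )
    spec = FilterSpec(cutoff=cutoff, ramp_span=ramp_span)
    f1 = sp_fft.fftfreq(_grid_n, d=1.0 / vg.pixels_per_degree)
    fr = np.hypot(f1[:, None], f1[None, :])
    sd = float(np.sqrt(np.mean(spec.gain(fr) ** 2)))
    return FilterSpec(cutoff=cutoff, ramp_span=ramp_span, noise_sd_unit=sd)


def filter_image(
    img: np.ndarray,
    fs: FilterSpec,
    vg: ViewingGeometry,
    pad_deg: float = 2.0,
) -> np.ndarray:
    """Apply the filter in the frequency domain with zero padding.

    The padded window makes the implicit periodic boundary irrelevant: the
    spatial kernel's sidelobes decay well inside the default 2-degree pad
    (checked against direct spatial convolution in the test suite).
    """
    pad = int(round(pad_deg * vg.pixels_per_degree))
    ny, nx = img.shape
    sy = sp_fft.next_fast_len(ny + 2 * pad)
    sx = sp_fft.next_fast_len(nx + 2 * pad)
    fy = sp_fft.fftfreq(sy, d=1.0 / vg.pixels_per_degree)
    fx = sp_fft.rfftfreq(sx, d=1.0 / vg.pixels_per_degree)
    gain = fs.gain(np.hypot(fy[:, None], fx[None, :]))
    spec = sp_fft.rfft2(img, s=(sy, sx))
    out = sp_fft.irfft2(spec * gain, s=(sy, sx))
    return out[:ny, :nx]


def apply_prefilter(
    stim: StereoStimulus,
    fs: FilterSpec,
    vg: ViewingGeometry,
    pad_deg: float = 2.0,
):
    """Filter both eyes' images with the identical kernel.

    Returns ``(L_f, R_f, sigma_f)`` where ``sigma_f`` is the standard
    deviation of the filtered white-noise component.
    """
    L_f = filter_image(stim.left, fs, vg, pad_deg)
    R_f = filter_image(stim.right, fs, vg, pad_deg)
    sigma_f = stim.noise_rms_contrast * fs.noise_sd_unit
    return L_f, R_f, sigma_f


def optimize_cutoff(
    noise_rms: float,
    candidate_cutoffs: Sequence[float],
    sim_config: dict | None = None,
):
    """Search for the cutoff minimizing the planar-matching observer's
    simulated slant-discrimination threshold.

    ``sim_config`` keys (all optional): ``reference_slants`` (list of
    degrees, default [50.0]), ``n_trials`` (estimates per psychometric
    level), ``n_levels``, ``seed``, ``vg``.  Thresholds are averaged over
    the reference slants.  Returns ``(best_cutoff, table)`` where the table
    is a DataFrame with one row per candidate (cutoff, threshold, CI).
    """
    import pandas as pd

    from .harness import model_threshold  # local import: avoids cycle

    candidates = list(candidate_cutoffs)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate cutoffs")
    cfg = dict(sim_config or {})
    reference_slants = cfg.pop("reference_slants", [50.0])
    rows = []
    for cutoff in candidates:
        thr = []
        los, his = [], []
        for ref in reference_slants:
            res = model_threshold(
                observer="PM",
                reference_slant=ref,
                noise_rms=noise_rms,
                cutoff=cutoff,
                **cfg,
            )
            thr.append(res.threshold)
            los.append(res.ci_low)
            his.append(res.ci_high)
        rows.append(
            {
                "cutoff": cutoff,
                "threshold": float(np.mean(thr)),
                "ci_low": float(np.mean(los)),
                "ci_high": float(np.mean(his)),
            }
        )
    table = pd.DataFrame(rows)
    best = float(table.loc[table["threshold"].idxmin(), "cutoff"])
    return best, table
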