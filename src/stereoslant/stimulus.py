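"""Stereo stimulus synthesis: sum-of-sinewaves textures on 3D planes.

Textures are defined directly on the planar surface as a sum of sinewave
components with equal amplitudes and random phases/orientations.  Each
eye's image is rendered analytically: every raster pixel's ray is
intersected with the plane, the in-plane coordinates of the intersection
are computed, and the texture is evaluated there in closed form.  No
interpolation enters the rendering, so the left and right images are exact
perspective views of the same 3D texture.

Component frequencies are specified in cycles/degree as the texture would
appear frontoparallel at the standard 100 cm distance; one degree
corresponds to ``100 * tan(1 deg)`` cm on the surface.  Images are stored
as zero-mean contrast images (luminance offset and display gamma are
display-side concerns and never enter the models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Tuple

import numpy as np

from .geometry import DEG, PlaneParams, ViewingGeometry, Window, surface_point

#: cm subtended by one degree at the standard 100 cm distance
CM_PER_DEG = 100.0 * np.tan(DEG)

#: standard texture band and spacing
DEFAULT_F_MIN = 0.1
DEFAULT_F_MAX = 3.0
DEFAULT_F_STEP = 0.05
DEFAULT_TARGET_RMS = 0.147

#: right-eye analysis rectangle, degrees
DEFAULT_WINDOW = Window(center=(0.0, 0.0), width=2.23, height=2.12)


@dataclass(frozen=True)
class TextureSpec:
    """A sum-of-sinewaves surface texture.

    ``frequencies`` are in cycles/degree (frontoparallel at 100 cm),
    ``orientations`` and ``phases`` in radians, ``amplitudes`` in contrast
    units.  All components share one amplitude chosen so that the expected
    RMS contrast of the full planar texture equals ``target_rms_contrast``
    (for K equal-amplitude sinewaves the expected RMS is ``A*sqrt(K/2)``).
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    orientations: np.ndarray
    phases: np.ndarray
    target_rms_contrast: float
    seed: int | None = None

    @property
    def n_components(self) -> int:
        return len(self.frequencies)


def make_texture_spec(
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    step: float = DEFAULT_F_STEP,
    target_rms: float = DEFAULT_TARGET_RMS,
    seed: int | None = None,
    phase_range: float = 2.0 * np.pi,
) -> TextureSpec:
    """Draw a random texture on the closed arithmetic frequency grid.

    Orientations are i.i.d. uniform on ``[0, pi)`` (which covers all
    orientations of a sinewave) and phases on ``[0, phase_range)``.  The
    full phase circle is the default: restricting phases to a half circle
    would give every component a nonzero spatial mean, adding a coherent
    (seed-independent) pattern to every texture and inflating its contrast
    above nominal.  The common amplitude is set so the expected planar RMS
    contrast equals ``target_rms`` (``A = target_rms * sqrt(2/K)``).
    """
    if f_min <= 0 or step <= 0:
        raise ValueError("frequencies and step must be positive")
    if f_max < f_min:
        raise ValueError("f_max must be >= f_min")
    n = int(round((f_max - f_min) / step)) + 1
    freqs = f_min + step * np.arange(n)
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, phase_range, size=n)
    orientations = rng.uniform(0.0, np.pi, size=n)
    amp = target_rms * np.sqrt(2.0 / n)
    return TextureSpec(
        frequencies=freqs,
        amplitudes=np.full(n, amp),
        orientations=orientations,
        phases=phases,
        target_rms_contrast=target_rms,
        seed=seed,
    )


def texture_value(spec: TextureSpec, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Evaluate the texture at in-plane coordinates (u, v) in cm."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    f_cm = spec.frequencies / CM_PER_DEG  # cycles per surface cm
    cos_o = np.cos(spec.orientations)
    sin_o = np.sin(spec.orientations)
    out = np.zeros(np.broadcast(u, v).shape, dtype=float)
    # accumulate per component; K ~ 59 keeps memory flat
    for fk, ak, ck, sk, pk in zip(
        f_cm, spec.amplitudes, cos_o, sin_o, spec.phases
    ):
        out += ak * np.sin(2.0 * np.pi * fk * (u * ck + v * sk) + pk)
    return out


def plane_basis(plane: PlaneParams) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis and origin of the textured surface.

    The u-axis points along the surface depth gradient (projected tilt
    direction), the v-axis is perpendicular to it within the plane, and the
    origin is the intercept point on the cyclopean axis.
    """
    s = plane.slant * DEG
    tau = plane.tilt * DEG
    u_hat = np.array(
        [np.cos(s) * np.cos(tau), np.cos(s) * np.sin(tau), np.sin(s)]
    )
    v_hat = np.array([-np.sin(tau), np.cos(tau), 0.0])
    origin = np.array([0.0, 0.0, plane.intercept_distance])
    return u_hat, v_hat, origin


def render_plane_image(
    spec: TextureSpec,
    plane: PlaneParams,
    vg: ViewingGeometry,
    eye: str,
    window: Window | None = None,
) -> np.ndarray:
    """Render one eye's view of the textured plane over a raster window.

    Each pixel is the exact texture value at the back-projected surface
    point of that pixel's ray.
    """
    window = window or DEFAULT_WINDOW
    yg, xg = window.grid(vg)
    X, Y, Z, valid = surface_point(xg, yg, plane, vg, eye)
    if not np.all(valid):
        raise ValueError("degenerate geometry: some rays miss the plane")
    u_hat, v_hat, origin = plane_basis(plane)
    relX, relY, relZ = X - origin[0], Y - origin[1], Z - origin[2]
    u = relX * u_hat[0] + relY * u_hat[1] + relZ * u_hat[2]
    v = relX * v_hat[0] + relY * v_hat[1] + relZ * v_hat[2]
    return texture_value(spec, u, v)


@dataclass
class StereoStimulus:
    """A rendered stereo pair with its truth metadata.

    ``left = left_texture + left_noise`` and likewise for the right eye.
    Both eyes' images cover the analysis rectangle plus a rendered margin,
    mirroring the experiment where texture and noise extended beyond the
    analysis region: the margin gives the prefilter real content at the
    window border and gives left-image predictions support over the full
    prior range of planes.  ``window`` is the fixed right-eye analysis
    rectangle to which the model observers are restricted.
    """

    left: np.ndarray
    right: np.ndarray
    left_texture: np.ndarray
    right_texture: np.ndarray
    left_noise: np.ndarray
    right_noise: np.ndarray
    truth: PlaneParams
    noise_rms_contrast: float
    seed: int | None
    window: Window  # right-eye analysis rectangle
    left_window: Window
    right_window: Window

    def __post_init__(self) -> None:
        assert self.left.shape == self.left_texture.shape == self.left_noise.shape
        assert self.right.shape == self.right_texture.shape == self.right_noise.shape


def make_stereo_stimulus(
    spec: TextureSpec,
    plane: PlaneParams,
    vg: ViewingGeometry,
    noise_rms: float = 0.0,
    seed: int | None = None,
    window: Window | None = None,
    margin: Tuple[float, float] = (0.5, 0.25),
) -> StereoStimulus:
    """Render both eyes' test-region images and add independent white noise.

    ``noise_rms`` is the RMS contrast of the spatial Gaussian white noise
    added independently to the left and right images (standard levels: 0.05,
    0.175, 0.34).  Both renders are expanded by ``margin`` degrees per
    side beyond the analysis rectangle (cf. the experiment's noise window,
    which was larger than the test plane).
    """
    if noise_rms < 0:
        raise ValueError("noise_rms must be >= 0")
    window = window or DEFAULT_WINDOW
    left_window = window.expanded(*margin)
    right_window = window.expanded(*margin)
    right_t = render_plane_image(spec, plane, vg, "R", right_window)
    left_t = render_plane_image(spec, plane, vg, "L", left_window)
    rng = np.random.default_rng(seed)
    if noise_rms > 0:
        left_n = rng.normal(0.0, noise_rms, size=left_t.shape)
        right_n = rng.normal(0.0, noise_rms, size=right_t.shape)
    else:
        left_n = np.zeros_like(left_t)
        right_n = np.zeros_like(right_t)
    return StereoStimulus(
        left=left_t + left_n,
        right=right_t + right_n,
        left_texture=left_t,
        right_texture=right_t,
        left_noise=left_n,
        right_noise=right_n,
        truth=plane,
        noise_rms_contrast=noise_rms,
        seed=seed,
        window=window,
        left_window=left_window,
        right_window=right_window,
    )


def rms_contrast(img: np.ndarray) -> float:
    """RMS contrast of a contrast image, measured about the true (zero)
    mean luminance of the display.

    The sample mean over a small analysis window is itself texture content
    (low-frequency components barely complete a cycle across 2.23 degrees),
    so it is not subtracted: for a sum of K equal-amplitude sinewaves with
    uniform phases the expectation of this measure is exactly
    ``A * sqrt(K/2)`` regardless of window size.
    """
    return float(np.sqrt(np.mean(np.square(img))))


def save_stimulus(stim: StereoStimulus, stem: str | Path) -> None:
    """Save a stereo pair as float32 grayscale TIFFs plus a JSON sidecar."""
    import tifffile

    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".left.tif"), stim.left.astype(np.float32))
    tifffile.imwrite(stem.with_suffix(".right.tif"), stim.right.astype(np.float32))
    meta = {
        "truth": {
            "slant": stim.truth.slant,
            "tilt": stim.truth.tilt,
            "intercept_distance": stim.truth.intercept_distance,
        },
        "noise_rms_contrast": stim.noise_rms_contrast,
        "seed": stim.seed,
        "window": asdict(stim.window),
        "left_window": asdict(stim.left_window),
        "right_window": asdict(stim.right_window),
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_stimulus_pair(stem: str | Path):
    """Load a saved stereo pair; returns (left, right, metadata dict)."""
    import tifffile

    stem = Path(stem)
    left = tifffile.imread(stem.with_suffix(".left.tif")).astype(float)
    right = tifffile.imread(stem.with_suffix(".right.tif")).astype(float)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return left, right, meta
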