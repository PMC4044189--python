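"""Polar Glass-pattern stimulus synthesis.

A Glass pattern is a field of dot pairs (dipoles) placed uniformly at
random; *signal* dipoles are oriented according to a polar rule relative
to fixation (circular = tangential, starburst = radial) while *noise*
dipoles take independent random orientations.  The proportion of signal
dipoles is the pattern *coherence*.  Patterns are rendered as grayscale
rasters on a mean-luminance (0.5) background inside an annular aperture
with raised-cosine contrast ramps at its inner and outer edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import as_rng

FORMS = ("circular", "starburst", "random")


@dataclass(frozen=True)
class GlassPatternSpec:
    """Geometric description of one polar Glass pattern.

    Defaults are the experimental stimulus: 25 dots/deg^2 over a 14.4 deg
    square field, 0.14 deg dipole separation, Gaussian dots (sigma =
    0.025 deg), annulus 1.5-14.4 deg diameter with 0.75 deg raised-cosine
    edge ramps.
    """

    coherence: float = 1.0
    form: str = "circular"
    dot_density: float = 25.0          # dots / deg^2
    dipole_separation: float = 0.14    # deg between the two dots
    dot_sigma: float = 0.025           # deg, Gaussian dot profile
    field_side: float = 14.4           # deg, square placement field
    aperture_outer_diam: float = 14.4  # deg
    aperture_inner_diam: float = 1.5   # deg
    edge_ramp: float = 0.75            # deg
    pixels_per_degree: float = 40.0

    def __post_init__(self):
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError(f"coherence must be in [0, 1], got {self.coherence}")
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}, got {self.form!r}")
        if self.dot_density < 0:
            raise ValueError("dot_density must be non-negative")
        for name in ("dipole_separation", "dot_sigma", "field_side",
                     "aperture_outer_diam", "aperture_inner_diam",
                     "edge_ramp", "pixels_per_degree"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.aperture_inner_diam < self.aperture_outer_diam <= self.field_side:
            raise ValueError("require aperture_inner_diam < aperture_outer_diam "
                             "<= field_side")


@dataclass
class DipoleField:
    """Sampled dipole geometry for one pattern instantiation."""

    centers: np.ndarray       # (n, 2) deg relative to fixation
    orientations: np.ndarray  # (n,) radians in [0, pi)
    polarities: np.ndarray    # (n,) +1 (increment) or -1 (decrement)
    is_signal: np.ndarray     # (n,) bool

    def __post_init__(self):
        n = len(self.centers)
        if not (len(self.orientations) == len(self.polarities)
                == len(self.is_signal) == n):
            raise ValueError("all DipoleField arrays must have equal length")

    @property
    def n_dipoles(self) -> int:
        return len(self.centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_deg": self.centers[:, 0],
            "y_deg": self.centers[:, 1],
            "orientation_rad": self.orientations,
            "polarity": self.polarities,
            "is_signal": self.is_signal.astype(int),
        })

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class PatternImage:
    """Rendered raster: normalized luminance in [0, 1], background 0.5."""

    pixels: np.ndarray
    degrees_per_pixel: float

    def save_png(self, path) -> None:
        from PIL import Image

        arr = np.round(255.0 * self.pixels).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(Path(path))


def dipole_count(spec: GlassPatternSpec) -> int:
    """Number of dipoles for the spec's density and placement field.

    The dot total ``density * side^2`` is forced to the nearest even
    number (dots come in pairs), so the dipole count is
    ``round(density * side^2 / 2)``.
    """
    return int(np.rint(spec.dot_density * spec.field_side ** 2 / 2.0))


def signal_dipole_count(n_dipoles: int, coherence: float) -> int:
    """Dipoles designated as signal: round(coherence * n), half-to-even."""
    if n_dipoles < 0:
        raise ValueError("n_dipoles must be non-negative")
    if not 0.0 <= coherence <= 1.0:
        raise ValueError(f"coherence must be in [0, 1], got {coherence}")
    return int(np.rint(coherence * n_dipoles))


def polar_orientation(x: float, y: float, form: str) -> float:
    """Orientation (radians in [0, pi)) of a signal dipole at (x, y).

    starburst: radial (along the line through fixation);
    circular: tangential (radial + pi/2).
    """
    if form not in ("circular", "starburst"):
        raise ValueError(f"no polar orientation rule for form {form!r}")
    if x == 0 and y == 0:
        raise ValueError("orientation undefined at fixation (0, 0)")
    theta = math.atan2(y, x)
    if form == "circular":
        theta += math.pi / 2.0
    return theta % math.pi


def _polar_orientations(centers: np.ndarray, form: str) -> np.ndarray:
    theta = np.arctan2(centers[:, 1], centers[:, 0])
    if form == "circular":
        theta = theta + np.pi / 2.0
    return np.mod(theta, np.pi)


def sample_dipole_field(spec: GlassPatternSpec, rng) -> DipoleField:
    """Sample dipole centers, orientations and polarities for one pattern.

    Centers are uniform over the square placement field; exactly
    ``signal_dipole_count`` dipoles follow the polar orientation rule
    (for ``form='random'`` no dipole is flagged signal); the remainder
    get independent uniform orientations in [0, pi).  Polarity is +-1
    with probability 1/2 each.
    """
    rng = as_rng(rng)
    n = dipole_count(spec)
    half = spec.field_side / 2.0
    centers = rng.uniform(-half, half, size=(n, 2))

    orientations = rng.uniform(0.0, np.pi, size=n)
    is_signal = np.zeros(n, dtype=bool)
    if spec.form != "random":
        n_signal = signal_dipole_count(n, spec.coherence)
        idx = rng.permutation(n)[:n_signal]
        is_signal[idx] = True
        if n_signal:
            orientations[idx] = _polar_orientations(centers[idx], spec.form)
    polarities = rng.integers(0, 2, size=n) * 2 - 1
    return DipoleField(centers, orientations, polarities.astype(int), is_signal)


def aperture_envelope(r: np.ndarray, spec: GlassPatternSpec) -> np.ndarray:
    """Radial contrast envelope of the annular aperture.

    0 inside the raw inner radius, raised-cosine 0->1 over one ramp
    width, 1 in the plateau, raised-cosine 1->0 over the last ramp
    width before the outer radius, 0 beyond.
    """
    r0 = spec.aperture_inner_diam / 2.0
    r_out = spec.aperture_outer_diam / 2.0
    ramp = spec.edge_ramp
    env = np.zeros_like(r, dtype=float)
    rising = (r > r0) & (r < r0 + ramp)
    env[rising] = 0.5 * (1.0 - np.cos(np.pi * (r[rising] - r0) / ramp))
    env[(r >= r0 + ramp) & (r <= r_out - ramp)] = 1.0
    falling = (r > r_out - ramp) & (r < r_out)
    env[falling] = 0.5 * (1.0 - np.cos(np.pi * (r_out - r[falling]) / ramp))
    return env


def render_pattern(dipoles: DipoleField, spec: GlassPatternSpec) -> PatternImage:
    """Rasterize a dipole field to a normalized-luminance image.

    Each dipole contributes two Gaussian dots at +-separation/2 along its
    orientation, amplitude polarity * 0.5, summed additively onto the
    0.5 background; the deviation from 0.5 is scaled by the annular
    raised-cosine envelope and the result clipped to [0, 1].
    """
    ppd = spec.pixels_per_degree
    if spec.dot_sigma * ppd < 1.0:
        warnings.warn(
            f"dot sigma ({spec.dot_sigma} deg) spans less than one pixel at "
            f"{ppd} px/deg; dots will be undersampled", RuntimeWarning)
    n_px = int(round(spec.field_side * ppd))
    half = spec.field_side / 2.0
    # pixel-center coordinates, x increasing rightwards, y increasing upwards
    coords = (np.arange(n_px) + 0.5) / ppd - half
    dev = np.zeros((n_px, n_px))

    if dipoles.n_dipoles:
        offs = spec.dipole_separation / 2.0
        ux = np.cos(dipoles.orientations)
        uy = np.sin(dipoles.orientations)
        dots_x = np.concatenate([dipoles.centers[:, 0] + offs * ux,
                                 dipoles.centers[:, 0] - offs * ux])
        dots_y = np.concatenate([dipoles.centers[:, 1] + offs * uy,
                                 dipoles.centers[:, 1] - offs * uy])
        amps = 0.5 * np.concatenate([dipoles.polarities, dipoles.polarities])

        # accumulate each dot on a +-4 sigma patch
        sig = spec.dot_sigma
        patch = max(1, int(math.ceil(4.0 * sig * ppd)))
        for x, y, a in zip(dots_x, dots_y, amps):
            cx = (x + half) * ppd - 0.5
            cy = (y + half) * ppd - 0.5
            ix, iy = int(round(cx)), int(round(cy))
            x0, x1 = max(ix - patch, 0), min(ix + patch + 1, n_px)
            y0, y1 = max(iy - patch, 0), min(iy + patch + 1, n_px)
            if x0 >= x1 or y0 >= y1:
                continue
            gx = np.exp(-((coords[x0:x1] - x) ** 2) / (2.0 * sig ** 2))
            gy = np.exp(-((coords[y0:y1] - y) ** 2) / (2.0 * sig ** 2))
            # rows index y (top row = largest y when saved; array row 0 = lowest y)
            dev[y0:y1, x0:x1] += a * np.outer(gy, gx)

    xx, yy = np.meshgrid(coords, coords)
    r = np.hypot(xx, yy)
    env = aperture_envelope(r, spec)
    pixels = np.clip(0.5 + env * dev, 0.0, 1.0)
    return PatternImage(pixels=pixels, degrees_per_pixel=1.0 / ppd)
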