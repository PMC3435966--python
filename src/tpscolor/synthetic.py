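"""Synthetic chart scenes under parameterized camera/illuminant distortions.

Real calibration studies photograph physical charts with several cameras
under several light sources. This module replaces that acquisition with a
forward distortion model applied to known reference colors, so the whole
fit -> warp -> evaluate chain can be exercised end to end with ground
truth in hand.

The distortion chain is, in fixed order:

    gain -> mixing -> [exposure normalization] -> gamma -> noise -> quantization

* per-channel gains model white-balance / illuminant casts (tungsten
  raises R and lowers B, neon pushes green);
* a 3x3 mixing matrix near identity models sensor channel crosstalk
  (each camera gets its own matrix);
* per-channel gamma on the [0, 1] scale models the nonlinear tone
  response;
* optional additive Gaussian noise and 8-bit quantization model shot
  noise and storage;
* exposure normalization (on in the presets) rescales the linear stage
  so no color in the cube can saturate, the way an operator meters
  exposure off the chart's white patch.

The preset numeric values are fixture choices of this package meant to
be plausible in magnitude; they are not measurements of any real camera
or lamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .checkers import get_checker
from .errors import InvalidInputError
from .pipeline import CheckerLayout, PatchRegion, RGBImage
from .reference import ColorCheckerReference

CONDITION_LABELS = ("T", "wTNE", "NE", "S")
CAMERA_LABELS = ("A", "B")


@dataclass(frozen=True)
class DistortionSpec:
    """Parameterized camera/illuminant distortion of sRGB triplets."""

    channel_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mixing_matrix: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )
    gamma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.0
    quantize: bool = False
    seed: int = 0
    #: When set, the linear stage is rescaled so the whole [0, 255] cube
    #: stays in gamut -- emulating an operator metering exposure so the
    #: chart's white patch never saturates. Without it, strong casts clip
    #: bright colors, an information loss no calibration can undo.
    normalize_exposure: bool = False

    def __post_init__(self) -> None:
        gains = np.asarray(self.channel_gains, dtype=float)
        gam = np.asarray(self.gamma, dtype=float)
        mix = np.asarray(self.mixing_matrix, dtype=float)
        object.__setattr__(self, "mixing_matrix", mix)
        if gains.shape != (3,) or np.any(gains <= 0):
            raise InvalidInputError("channel_gains must be 3 positive reals")
        if gam.shape != (3,) or np.any(gam <= 0):
            raise InvalidInputError("gamma must be 3 positive reals")
        if mix.shape != (3, 3) or abs(np.linalg.det(mix)) < 1e-12:
            raise InvalidInputError("mixing_matrix must be a non-singular 3x3")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be nonnegative")

    @property
    def is_affine(self) -> bool:
        """True when the chain is linear (all gammas equal 1)."""
        return bool(np.all(np.asarray(self.gamma) == 1.0))


def distort(rgb: np.ndarray, spec: DistortionSpec,
            rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Apply the gain -> mix -> gamma -> noise -> quantize chain.

    ``rgb`` is a triplet or (N, 3) array on [0, 255]. Noise draws come
    from ``rng`` (or a generator seeded with ``spec.seed``), so repeated
    calls with the same seed are bit-identical.
    """
    c = np.asarray(rgb, dtype=float)
    single = c.ndim == 1
    c = np.atleast_2d(c)
    if c.shape[1] != 3:
        raise InvalidInputError(f"expected (N, 3) colors, got shape {c.shape}")
    gains = np.asarray(spec.channel_gains, dtype=float)
    lin = (c / 255.0) * gains
    lin = lin @ spec.mixing_matrix.T
    if spec.normalize_exposure:
        # Peak of each output channel over the unit cube (corner maximum
        # of a linear map); divide by the largest so nothing can clip.
        coeff = spec.mixing_matrix * gains
        peak = float(np.clip(coeff, 0.0, None).sum(axis=1).max())
        lin = lin / max(1.0, peak)
    lin = np.clip(lin, 0.0, None)  # negative crosstalk residue has no power
    out = 255.0 * np.power(lin, np.asarray(spec.gamma, dtype=float))
    out = np.clip(out, 0.0, 255.0)
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    if spec.quantize:
        out = np.floor(np.clip(out, 0.0, 255.0) + 0.5)
    return out[0] if single else out


@dataclass
class SyntheticScene:
    """A rendered chart image with its layout, truth and distortion."""

    image: RGBImage
    layout: CheckerLayout
    true_reference: ColorCheckerReference
    distortion: DistortionSpec
    distorted_patch_rgb: np.ndarray  # pre-noise, pre-quantization truth


def render_checker(
    reference: ColorCheckerReference,
    spec: DistortionSpec,
    patch_px: int = 16,
    grid: Optional[tuple[int, int]] = None,
) -> SyntheticScene:
    """Render a tiled chart image with every patch distorted by ``spec``.

    Patches are ``patch_px`` squares separated by 1-pixel neutral gutters;
    layout regions cover each full patch square. Noise (if any) is applied
    per pixel with the spec's seed, so identical specs render identical
    images.
    """
    if patch_px < 4:
        raise InvalidInputError("patch_px must be at least 4")
    n = len(reference.patches)
    if grid is None:
        cols = int(np.ceil(np.sqrt(n * 1.5)))
        rows = int(np.ceil(n / cols))
    else:
        rows, cols = grid
    if rows * cols < n:
        raise InvalidInputError(f"grid {rows}x{cols} too small for {n} patches")

    ref_rgb = reference.rgb_matrix()
    clean = distort(ref_rgb, replace(spec, noise_sd=0.0, quantize=False))

    step = patch_px + 1
    h, w = rows * step + 1, cols * step + 1
    img = np.full((h, w, 3), 128.0)  # neutral gutter
    regions = []
    rng = np.random.default_rng(spec.seed)
    for k, patch in enumerate(reference.patches):
        r, c = divmod(k, cols)
        y0, x0 = r * step + 1, c * step + 1
        tile = np.tile(clean[k], (patch_px, patch_px, 1))
        if spec.noise_sd > 0:
            tile = tile + rng.normal(0.0, spec.noise_sd, size=tile.shape)
        if spec.quantize:
            tile = np.floor(np.clip(tile, 0.0, 255.0) + 0.5)
        img[y0 : y0 + patch_px, x0 : x0 + patch_px] = np.clip(tile, 0.0, 255.0)
        regions.append(
            PatchRegion(patch.patch_id, x0, y0, x0 + patch_px, y0 + patch_px)
        )
    layout = CheckerLayout(checker=reference.name, regions=regions)
    return SyntheticScene(
        image=RGBImage(pixels=img),
        layout=layout,
        true_reference=reference,
        distortion=spec,
        distorted_patch_rgb=clean,
    )


# Two synthetic "cameras": identity-leaning crosstalk vs. a stronger one.
_CAMERA_MIX = {
    "A": np.array(
        [
            [0.96, 0.03, 0.01],
            [0.02, 0.95, 0.03],
            [0.01, 0.04, 0.95],
        ]
    ),
    "B": np.array(
        [
            [0.92, 0.06, 0.02],
            [0.04, 0.90, 0.06],
            [0.02, 0.07, 0.91],
        ]
    ),
}

# Per-camera tone response (gamma deviation from unity).
_CAMERA_GAMMA = {"A": 1.08, "B": 0.92}

# Illuminant casts: tungsten warm, mixed, neon greenish, sun near-neutral.
_CONDITION_GAINS = {
    "T": (1.25, 1.0, 0.75),
    "wTNE": (1.12, 1.04, 0.86),
    "NE": (0.95, 1.12, 0.92),
    "S": (1.02, 1.0, 0.98),
}


def preset_conditions(noise_sd: float = 0.0, quantize: bool = False,
                      seed: int = 0) -> dict[str, DistortionSpec]:
    """Named distortions for 4 light conditions x 2 cameras (8 scenarios).

    Keys are ``"<condition>/<camera>"`` (e.g. ``"T/A"``). Noise and
    quantization default off so the presets are exactly invertible test
    conditions; turn them on to emulate a real acquisition.
    """
    out = {}
    for cam in CAMERA_LABELS:
        for cond in CONDITION_LABELS:
            out[f"{cond}/{cam}"] = DistortionSpec(
                channel_gains=_CONDITION_GAINS[cond],
                mixing_matrix=_CAMERA_MIX[cam],
                gamma=(_CAMERA_GAMMA[cam],) * 3,
                noise_sd=noise_sd,
                quantize=quantize,
                seed=seed,
                normalize_exposure=True,
            )
    return out


def random_distortion(rng: np.random.Generator, noise_sd: float = 0.0,
                      quantize: bool = False) -> DistortionSpec:
    """Draw a random plausible nonlinear distortion (gain + mix + gamma).

    Gains in [0.75, 1.3], gammas in [0.85, 1.2], crosstalk off-diagonals
    up to ~0.06 with rows renormalized so a neutral stays near neutral.
    """
    gains = tuple(rng.uniform(0.75, 1.3, size=3))
    gamma = tuple(rng.uniform(0.85, 1.2, size=3))
    off = rng.uniform(0.0, 0.06, size=(3, 3))
    mix = off + np.eye(3)
    mix /= mix.sum(axis=1, keepdims=True)
    seed = int(rng.integers(0, 2**31 - 1))
    return DistortionSpec(
        channel_gains=gains,
        mixing_matrix=mix,
        gamma=gamma,
        noise_sd=noise_sd,
        quantize=quantize,
        seed=seed,
        normalize_exposure=True,
    )


def sample_holdout_colors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform holdout colors over [10, 245]^3, away from gamut edges."""
    return rng.uniform(10.0, 245.0, size=(n, 3))


def simulate_measurement(
    checker: str | ColorCheckerReference,
    spec: DistortionSpec,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Distorted patch colors for a chart without rendering pixels.

    Returns (measured, reference_rgb, ids); ``measured`` includes noise
    and quantization when the spec asks for them.
    """
    ref = get_checker(checker) if isinstance(checker, str) else checker
    ref_rgb = ref.rgb_matrix()
    measured = distort(ref_rgb, spec)
    return measured, ref_rgb, ref.patch_ids
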