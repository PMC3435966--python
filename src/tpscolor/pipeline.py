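"""End-to-end image calibration: measure chart patches, fit, warp pixels.

The workflow mirrors how a chart-in-scene photograph is calibrated:

1. declare where each patch sits in the image (:class:`CheckerLayout`),
2. average the pixels of each patch (:func:`measure_patches`),
3. fit a map from measured to reference colors -- the thin-plate-spline
   warp (:func:`fit_tps_calibration`) or the PLS regression baseline
   (:func:`fit_pls_calibration`),
4. push every pixel of the image through the map
   (:func:`apply_calibration` / :func:`apply_pls_calibration`).

Warped values are clipped to [0, 255] and rounded half-away-from-zero
only at 8-bit export; the in-memory result keeps unrounded reals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.preprocessing import PolynomialFeatures

from .errors import BoundsError, InvalidInputError, PairingError
from .reference import ColorCheckerReference
from .tps import ControlPointSet, TPSModel, fit, merge_duplicate_controls

logger = logging.getLogger(__name__)

DEFAULT_SAMPLING_MARGIN = 0.2


@dataclass
class RGBImage:
    """An H x W x 3 color image as reals on the [0, 255] scale (8-bit source)."""

    pixels: np.ndarray
    bit_depth: int = 8
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidInputError(f"expected (H, W, 3) pixels, got {px.shape}")
        if self.bit_depth != 8:
            raise InvalidInputError("only 8-bit images are supported")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def to_uint8(self) -> np.ndarray:
        """Clip to [0, 255] and round half-away-from-zero to integers."""
        clipped = np.clip(self.pixels, 0.0, 255.0)
        return np.floor(clipped + 0.5).astype(np.uint8)

    @classmethod
    def read(cls, path: str | Path) -> "RGBImage":
        arr = iio.imread(path)
        if arr.ndim == 2:
            arr = np.repeat(arr[:, :, None], 3, axis=2)
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.dtype != np.uint8:
            raise InvalidInputError(
                f"{path}: expected an 8-bit image, got dtype {arr.dtype}"
            )
        return cls(pixels=arr.astype(float), source_path=str(path))

    def write(self, path: str | Path) -> None:
        """Write as 8-bit PNG or TIFF, by extension."""
        iio.imwrite(path, self.to_uint8())


@dataclass(frozen=True)
class PatchRegion:
    """Half-open pixel rectangle [x0, x1) x [y0, y1), x right / y down."""

    patch_id: str
    x0: int
    y0: int
    x1: int
    y1: int


@dataclass
class CheckerLayout:
    """Declared patch positions within an image.

    ``sampling_margin`` shrinks each rectangle by that fraction per side
    before averaging, to keep patch borders and gutters out of the mean.
    """

    checker: str
    regions: list[PatchRegion]
    sampling_margin: float = DEFAULT_SAMPLING_MARGIN

    def __post_init__(self) -> None:
        if not 0 <= self.sampling_margin < 0.5:
            raise InvalidInputError("sampling_margin must be in [0, 0.5)")
        ids = [r.patch_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate patch ids in layout")

    def to_json(self) -> str:
        return json.dumps(
            {
                "checker": self.checker,
                "margin": self.sampling_margin,
                "regions": [
                    {"id": r.patch_id, "x0": r.x0, "y0": r.y0, "x1": r.x1, "y1": r.y1}
                    for r in self.regions
                ],
            },
            indent=2,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "CheckerLayout":
        d = json.loads(text)
        return cls(
            checker=d["checker"],
            regions=[
                PatchRegion(r["id"], r["x0"], r["y0"], r["x1"], r["y1"])
                for r in d["regions"]
            ],
            sampling_margin=float(d.get("margin", DEFAULT_SAMPLING_MARGIN)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CheckerLayout":
        return cls.from_json(Path(path).read_text())


@dataclass
class PatchMeasurement:
    patch_id: str
    mean_rgb: np.ndarray
    pixel_count: int


@dataclass
class PatchMeasurementSet:
    """Mean sRGB per chart patch, measured from one image."""

    measurements: list[PatchMeasurement]
    image_id: str = ""

    @property
    def patch_ids(self) -> list[str]:
        return [m.patch_id for m in self.measurements]

    def rgb_matrix(self) -> np.ndarray:
        return np.vstack([m.mean_rgb for m in self.measurements])


def _shrunk_bounds(r: PatchRegion, margin: float) -> tuple[int, int, int, int]:
    w, h = r.x1 - r.x0, r.y1 - r.y0
    dx, dy = int(np.floor(w * margin)), int(np.floor(h * margin))
    return r.x0 + dx, r.y0 + dy, r.x1 - dx, r.y1 - dy


def measure_patches(
    image: RGBImage, layout: CheckerLayout, statistic: str = "mean"
) -> PatchMeasurementSet:
    """Average each layout rectangle (after margin shrink) per channel.

    ``statistic`` is ``"mean"`` (default, matching how chart patches are
    summarized) or ``"median"`` for robustness against specks.
    """
    if statistic not in ("mean", "median"):
        raise InvalidInputError(f"unknown statistic {statistic!r}")
    h, w = image.shape
    out = []
    for r in layout.regions:
        x0, y0, x1, y1 = _shrunk_bounds(r, layout.sampling_margin)
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            raise BoundsError(
                f"patch {r.patch_id!r}: region [{x0},{x1})x[{y0},{y1}) outside "
                f"image of size {w}x{h}"
            )
        if x1 <= x0 or y1 <= y0:
            raise BoundsError(
                f"patch {r.patch_id!r}: region empty after margin shrink"
            )
        block = image.pixels[y0:y1, x0:x1]
        if statistic == "mean":
            rgb = block.reshape(-1, 3).mean(axis=0)
        else:
            rgb = np.median(block.reshape(-1, 3), axis=0)
        out.append(PatchMeasurement(r.patch_id, rgb, block.shape[0] * block.shape[1]))
    return PatchMeasurementSet(out, image_id=image.source_path or "")


def _paired_control_set(
    measured: PatchMeasurementSet, reference: ColorCheckerReference
) -> ControlPointSet:
    missing = [i for i in measured.patch_ids if i not in set(reference.patch_ids)]
    if missing:
        raise PairingError(
            f"measured patches not present in reference {reference.name!r}: {missing}"
        )
    P = measured.rgb_matrix()
    V = reference.rgb_matrix(measured.patch_ids)
    P, V, ids = merge_duplicate_controls(P, V, measured.patch_ids)
    return ControlPointSet(P, V, tuple(ids))


def fit_tps_calibration(
    measured: PatchMeasurementSet, reference: ColorCheckerReference
) -> TPSModel:
    """Fit the thin-plate-spline warp from measured to reference colors."""
    control = _paired_control_set(measured, reference)
    return fit(control, checker_name=reference.name)


def apply_calibration(image: RGBImage, model: TPSModel) -> RGBImage:
    """Warp every pixel of ``image`` through a fitted TPS model.

    Evaluation streams through fixed-size pixel blocks (see
    :mod:`tpscolor.tps`), so memory stays flat on large images and the
    result is bit-identical however the image would be tiled. The returned
    image holds unrounded reals; clipping and rounding happen at export.
    """
    h, w = image.shape
    flat = image.pixels.reshape(-1, 3)
    warped = model.warp(flat)
    return RGBImage(pixels=warped.reshape(h, w, 3), source_path=image.source_path)


# ---------------------------------------------------------------------------
# PLS baseline
# ---------------------------------------------------------------------------


@dataclass
class PLSCalibrator:
    """Polynomial-expanded partial-least-squares color calibration.

    Measured RGB triplets are expanded to polynomial features (degree 2
    with cross terms by default), centered, and regressed onto reference
    RGB with a PLS2 (NIPALS) fit. A latent-variable baseline of this kind
    is the standard chemometric comparator for chart calibration.
    """

    n_components: int = 6
    expansion_degree: int = 2
    _expander: PolynomialFeatures = field(default=None, repr=False)
    _pls: PLSRegression = field(default=None, repr=False)
    x_mean: np.ndarray = None
    y_mean: np.ndarray = None
    fitted: bool = False

    def fit(self, measured_rgb: np.ndarray, reference_rgb: np.ndarray) -> "PLSCalibrator":
        X = np.asarray(measured_rgb, dtype=float)
        Y = np.asarray(reference_rgb, dtype=float)
        if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
            raise InvalidInputError("measured and reference must be matching (N, 3)")
        self._expander = PolynomialFeatures(
            degree=self.expansion_degree, include_bias=False
        )
        Xe = self._expander.fit_transform(X)
        max_comp = min(Xe.shape[0] - 1, Xe.shape[1], np.linalg.matrix_rank(Xe - Xe.mean(axis=0)))
        n_comp = self.n_components
        if n_comp > max_comp:
            logger.warning(
                "reducing PLS components from %d to %d (rank-deficient predictors)",
                n_comp, max_comp,
            )
            n_comp = max_comp
        self.n_components = int(n_comp)
        self._pls = PLSRegression(
            n_components=self.n_components, scale=False,
            max_iter=2000, tol=1e-12,
        )
        self._pls.fit(Xe, Y)
        self.x_mean = X.mean(axis=0)
        self.y_mean = Y.mean(axis=0)
        self.fitted = True
        return self

    def predict(self, colors: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise InvalidInputError("PLS calibrator is not fitted")
        c = np.asarray(colors, dtype=float)
        single = c.ndim == 1
        c = np.atleast_2d(c)
        out = self._pls.predict(self._expander.transform(c))
        return out[0] if single else out


def fit_pls_calibration(
    measured: PatchMeasurementSet,
    reference: ColorCheckerReference,
    n_components: int = 6,
    expansion_degree: int = 2,
) -> PLSCalibrator:
    """Fit the PLS baseline mapping measured patch means to reference RGB."""
    control = _paired_control_set(measured, reference)
    if control.n < 2:
        raise InvalidInputError("PLS needs at least 2 distinct patches")
    cal = PLSCalibrator(n_components=n_components, expansion_degree=expansion_degree)
    return cal.fit(control.P, control.V)


def apply_pls_calibration(image: RGBImage, calibrator: PLSCalibrator) -> RGBImage:
    """Map every pixel through the fitted PLS regression (same contract as
    :func:`apply_calibration`: unrounded reals, clip/round at export)."""
    h, w = image.shape
    flat = image.pixels.reshape(-1, 3)
    out = calibrator.predict(flat)
    return RGBImage(pixels=out.reshape(h, w, 3), source_path=image.source_path)
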