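"""Reference sRGB coordinates for color-checker charts.

A chart's reference is either supplied directly as sRGB triplets or
derived from spectral reflectance measurements of each patch (the route
taken when only an integrating-sphere spectrocolorimeter reading of the
physical chart is available). All reference values are kept as reals on
the 8-bit [0, 255] scale, because every distance computed downstream is
expressed in those units.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cie
from .errors import FormatError, InvalidInputError

logger = logging.getLogger(__name__)

N_SPECTRAL_SAMPLES = cie.WAVELENGTHS_NM.size


@dataclass(frozen=True)
class SpectralReflectance:
    """A reflectance spectrum, nominally on the 400-700 nm / 10 nm grid.

    Off-grid spectra are accepted and resampled linearly by
    :func:`spectrum_to_srgb`; wavelengths must be strictly increasing and
    reflectances fractions in [0, 1].
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", r)
        if wl.size == 0 or r.size == 0:
            raise InvalidInputError("spectrum is empty")
        if wl.shape != r.shape:
            raise InvalidInputError("wavelength and reflectance lengths differ")
        if np.any(np.diff(wl) <= 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if np.any(r < 0) or np.any(r > 1):
            raise InvalidInputError("reflectance values must lie in [0, 1]")

    def on_default_grid(self) -> np.ndarray:
        """Reflectance resampled onto the 400-700/10 grid (linear interp)."""
        if (
            self.wavelengths_nm.size == N_SPECTRAL_SAMPLES
            and np.array_equal(self.wavelengths_nm, cie.WAVELENGTHS_NM)
        ):
            return self.reflectance
        logger.info(
            "resampling spectrum from %d samples (%g-%g nm) onto the "
            "400-700/10 nm grid",
            self.wavelengths_nm.size,
            self.wavelengths_nm[0],
            self.wavelengths_nm[-1],
        )
        return np.interp(cie.WAVELENGTHS_NM, self.wavelengths_nm, self.reflectance)


@dataclass(frozen=True)
class ReferencePatch:
    patch_id: str
    rgb_ref: np.ndarray  # 3-vector on [0, 255]
    spectrum: Optional[SpectralReflectance] = None


@dataclass
class ColorCheckerReference:
    """Named chart with a reference sRGB triplet per patch.

    Invariants: unique patch ids; at least 4 patches (the warp needs four
    non-coplanar control points); every component on [0, 255].
    """

    name: str
    patches: list[ReferencePatch] = field(default_factory=list)
    illuminant: str = "D50"
    observer: str = "CIE 1931 2deg"

    def __post_init__(self) -> None:
        ids = [p.patch_id for p in self.patches]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate patch ids: {dupes}")
        if len(self.patches) < 4:
            raise InvalidInputError(
                f"a chart needs at least 4 patches, got {len(self.patches)}"
            )
        for p in self.patches:
            rgb = np.asarray(p.rgb_ref, dtype=float)
            if rgb.shape != (3,) or np.any(rgb < 0) or np.any(rgb > 255):
                raise InvalidInputError(
                    f"patch {p.patch_id!r}: rgb_ref must be 3 values in [0, 255]"
                )

    @property
    def patch_ids(self) -> list[str]:
        return [p.patch_id for p in self.patches]

    def rgb_matrix(self, ids: Optional[Sequence[str]] = None) -> np.ndarray:
        """Reference colors as an (N, 3) array, optionally reordered by id."""
        lookup = {p.patch_id: np.asarray(p.rgb_ref, dtype=float) for p in self.patches}
        if ids is None:
            ids = self.patch_ids
        try:
            return np.vstack([lookup[i] for i in ids])
        except KeyError as e:
            raise InvalidInputError(f"unknown patch id {e.args[0]!r}") from None

    def subset(self, ids: Sequence[str], name: Optional[str] = None) -> "ColorCheckerReference":
        keep = set(ids)
        return ColorCheckerReference(
            name=name or f"{self.name}-subset",
            patches=[p for p in self.patches if p.patch_id in keep],
            illuminant=self.illuminant,
            observer=self.observer,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "illuminant": self.illuminant,
                "observer": self.observer,
                "patches": [
                    {"id": p.patch_id, "rgb_ref": [float(v) for v in p.rgb_ref]}
                    for p in self.patches
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ColorCheckerReference":
        d = json.loads(text)
        return cls(
            name=d["name"],
            patches=[
                ReferencePatch(p["id"], np.asarray(p["rgb_ref"], dtype=float))
                for p in d["patches"]
            ],
            illuminant=d.get("illuminant", "D50"),
            observer=d.get("observer", "CIE 1931 2deg"),
        )


def spectrum_to_srgb(
    spectrum: SpectralReflectance,
    illuminant: str = "D50",
    observer: str = "CIE 1931 2deg",
) -> np.ndarray:
    """Convert a measured reflectance spectrum to an sRGB triplet on [0, 255].

    The chain is reflectance -> XYZ (illuminant-weighted summation over the
    400-700/10 nm grid, perfect diffuser at Y = 100) -> Bradford adaptation
    to D65 when the measurement illuminant is D50 -> linear sRGB matrix ->
    companding -> x255, clipped to [0, 255].

    Parameters
    ----------
    spectrum
        Reflectance fractions; resampled linearly if not on the default grid.
    illuminant
        Measurement illuminant, ``"D50"`` or ``"D65"``.
    observer
        Only the CIE 1931 2 degree observer is supported.
    """
    if observer not in ("CIE 1931 2deg", "2deg", "CIE 1931 2°"):
        raise InvalidInputError(f"unsupported observer {observer!r}")
    r = spectrum.on_default_grid()
    xyz = cie.reflectance_to_xyz(r, illuminant)
    return cie.xyz_to_srgb255(xyz, source_illuminant=illuminant)


def load_reference(path: str | Path, name: Optional[str] = None,
                   illuminant: str = "D50") -> ColorCheckerReference:
    """Read a chart reference from CSV.

    Two layouts are accepted (detected from the header):

    * ``patch_id,R,G,B`` - direct sRGB triplets on [0, 255];
    * ``patch_id`` followed by 31 spectral columns (reflectance fractions
      at 400, 410, ..., 700 nm), converted via :func:`spectrum_to_srgb`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: could not parse CSV ({e})") from e
    if df.shape[1] == 4:
        return _load_rgb_rows(df, name or path.stem)
    if df.shape[1] == 1 + N_SPECTRAL_SAMPLES:
        return _load_spectral_rows(df, name or path.stem, illuminant)
    raise FormatError(
        f"{path}: expected 4 columns (patch_id,R,G,B) or "
        f"{1 + N_SPECTRAL_SAMPLES} columns (patch_id + 31 spectral), "
        f"got {df.shape[1]}"
    )


def _load_rgb_rows(df: pd.DataFrame, name: str) -> ColorCheckerReference:
    patches = []
    for idx, row in df.iterrows():
        pid = str(row.iloc[0])
        try:
            rgb = np.asarray(row.iloc[1:4], dtype=float)
        except (TypeError, ValueError):
            raise FormatError(f"row {idx} (patch {pid!r}): non-numeric RGB") from None
        if np.any(~np.isfinite(rgb)) or np.any(rgb < 0) or np.any(rgb > 255):
            raise FormatError(f"row {idx} (patch {pid!r}): RGB outside [0, 255]")
        patches.append(ReferencePatch(pid, rgb))
    _check_unique(df)
    return ColorCheckerReference(name=name, patches=patches)


def _load_spectral_rows(df: pd.DataFrame, name: str,
                        illuminant: str) -> ColorCheckerReference:
    patches = []
    for idx, row in df.iterrows():
        pid = str(row.iloc[0])
        try:
            refl = np.asarray(row.iloc[1:], dtype=float)
        except (TypeError, ValueError):
            raise FormatError(f"row {idx} (patch {pid!r}): non-numeric spectrum") from None
        try:
            spec = SpectralReflectance(cie.WAVELENGTHS_NM.astype(float), refl)
        except InvalidInputError as e:
            raise FormatError(f"row {idx} (patch {pid!r}): {e}") from None
        rgb = spectrum_to_srgb(spec, illuminant=illuminant)
        patches.append(ReferencePatch(pid, rgb, spectrum=spec))
    _check_unique(df)
    return ColorCheckerReference(name=name, patches=patches, illuminant=illuminant)


def _check_unique(df: pd.DataFrame) -> None:
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise FormatError(f"duplicate patch ids: {dupes}")


def write_reference(reference: ColorCheckerReference, path: str | Path) -> None:
    """Write a reference as a ``patch_id,R,G,B`` CSV (full float precision)."""
    df = pd.DataFrame(
        {
            "patch_id": reference.patch_ids,
            "R": [float(p.rgb_ref[0]) for p in reference.patches],
            "G": [float(p.rgb_ref[1]) for p in reference.patches],
            "B": [float(p.rgb_ref[2]) for p in reference.patches],
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")
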