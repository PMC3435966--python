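"""CIE colorimetry tables and the reflectance -> sRGB conversion chain.

The conversion pipeline is the standard one used when a chart is measured
with a spectrocolorimeter and the calibration then runs in sRGB:

    reflectance --(illuminant-weighted summation, CIE 1931 2 deg)--> XYZ
        --(Bradford adaptation to D65 when measured under D50)-->
        XYZ_D65 --(sRGB matrix)--> linear RGB --(companding)--> sRGB * 255

Tables are the CIE 1931 2 degree standard observer and the D50/D65
illuminant spectral power distributions on the 400-700 nm grid at 10 nm
steps (31 samples), which is the grid portable integrating-sphere
instruments report on.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

#: Default spectral grid: 400-700 nm inclusive, 10 nm step.
WAVELENGTHS_NM = np.arange(400, 701, 10)

# CIE 1931 2 degree standard observer color matching functions, 10 nm step.
CMF_XYZ = np.array(
    [
        # x_bar   y_bar   z_bar
        [0.0143, 0.0004, 0.0679],  # 400
        [0.0435, 0.0012, 0.2074],
        [0.1344, 0.0040, 0.6456],
        [0.2839, 0.0116, 1.3856],
        [0.3483, 0.0230, 1.7471],
        [0.3362, 0.0380, 1.7721],  # 450
        [0.2908, 0.0600, 1.6692],
        [0.1954, 0.0910, 1.2876],
        [0.0956, 0.1390, 0.8130],
        [0.0320, 0.2080, 0.4652],
        [0.0049, 0.3230, 0.2720],  # 500
        [0.0093, 0.5030, 0.1582],
        [0.0633, 0.7100, 0.0782],
        [0.1655, 0.8620, 0.0422],
        [0.2904, 0.9540, 0.0203],
        [0.4334, 0.9950, 0.0087],  # 550
        [0.5945, 0.9950, 0.0039],
        [0.7621, 0.9520, 0.0021],
        [0.9163, 0.8700, 0.0017],
        [1.0263, 0.7570, 0.0011],
        [1.0622, 0.6310, 0.0008],  # 600
        [1.0026, 0.5030, 0.0003],
        [0.8544, 0.3810, 0.0002],
        [0.6424, 0.2650, 0.0000],
        [0.4479, 0.1750, 0.0000],
        [0.2835, 0.1070, 0.0000],  # 650
        [0.1649, 0.0610, 0.0000],
        [0.0874, 0.0320, 0.0000],
        [0.0468, 0.0170, 0.0000],
        [0.0227, 0.0082, 0.0000],
        [0.0114, 0.0041, 0.0000],  # 700
    ]
)

# Relative spectral power distributions (100 at 560 nm), 10 nm step.
ILLUMINANT_SPD = {
    "D50": np.array(
        [
            49.31, 56.51, 60.03, 57.82, 74.82, 87.25, 90.61, 91.37,
            95.11, 91.96, 95.72, 96.61, 97.13, 102.10, 100.75, 102.32,
            100.00, 97.74, 98.92, 93.50, 97.69, 99.27, 99.04, 95.72,
            97.30, 98.86, 95.67, 98.19, 103.00, 99.13, 87.38,
        ]
    ),
    "D65": np.array(
        [
            82.75, 91.49, 93.43, 86.68, 104.86, 117.01, 117.81, 114.86,
            115.92, 108.81, 109.35, 107.80, 104.79, 107.69, 104.41, 104.05,
            100.00, 96.33, 95.79, 88.69, 90.01, 89.60, 87.70, 83.29,
            83.70, 80.03, 80.21, 82.28, 78.28, 69.72, 71.61,
        ]
    ),
}

# Nominal D65 white point (Y = 100): the white sRGB is defined against.
WHITE_D65 = np.array([95.047, 100.0, 108.883])

# Bradford chromatic adaptation matrix (XYZ -> sharpened cone responses).
BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)

# IEC 61966-2-1 XYZ(D65) -> linear sRGB matrix (XYZ scaled so Y_white = 1).
XYZ_TO_LINEAR_SRGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


def illuminant_white_xyz(illuminant: str) -> np.ndarray:
    """XYZ of the perfect diffuser under ``illuminant``, normalized Y=100.

    Computed from the shipped SPD/CMF tables so a flat unit spectrum maps
    exactly onto this white.
    """
    spd = _get_spd(illuminant)
    k = 100.0 / float(spd @ CMF_XYZ[:, 1])
    return k * (spd[:, None] * CMF_XYZ).sum(axis=0)


def _get_spd(illuminant: str) -> np.ndarray:
    try:
        return ILLUMINANT_SPD[illuminant.upper()]
    except KeyError:
        raise InvalidInputError(
            f"unsupported illuminant {illuminant!r}; choose from "
            f"{sorted(ILLUMINANT_SPD)}"
        ) from None


def reflectance_to_xyz(reflectance: np.ndarray, illuminant: str = "D50") -> np.ndarray:
    """Integrate a reflectance spectrum on the default grid into CIE XYZ.

    Uses discrete illuminant-weighted summation with the normalization
    constant k = 100 / sum(S * y_bar), so the perfect diffuser has Y = 100.
    """
    r = np.asarray(reflectance, dtype=float)
    if r.shape != WAVELENGTHS_NM.shape:
        raise InvalidInputError(
            f"expected {WAVELENGTHS_NM.size} reflectance samples on the "
            f"400-700/10 nm grid, got {r.size}"
        )
    if r.size == 0 or np.any(r < 0) or np.any(r > 1):
        raise InvalidInputError("reflectance values must lie in [0, 1]")
    spd = _get_spd(illuminant)
    k = 100.0 / float(spd @ CMF_XYZ[:, 1])
    return k * ((spd * r)[:, None] * CMF_XYZ).sum(axis=0)


def bradford_adapt(xyz: np.ndarray, white_src: np.ndarray,
                   white_dst: np.ndarray = WHITE_D65) -> np.ndarray:
    """Chromatically adapt XYZ from one white point to another (Bradford)."""
    lms_src = BRADFORD @ np.asarray(white_src, dtype=float)
    lms_dst = BRADFORD @ np.asarray(white_dst, dtype=float)
    scale = np.diag(lms_dst / lms_src)
    m = np.linalg.solve(BRADFORD, scale @ BRADFORD)
    return m @ np.asarray(xyz, dtype=float)


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """Apply the sRGB transfer curve to linear values in [0, 1]."""
    linear = np.asarray(linear, dtype=float)
    out = np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(np.clip(linear, 0.0, None), 1.0 / 2.4) - 0.055,
    )
    return out


def xyz_to_srgb255(xyz: np.ndarray, source_illuminant: str = "D50") -> np.ndarray:
    """XYZ (Y_white = 100) measured under ``source_illuminant`` -> sRGB [0,255].

    Adapts to the nominal D65 white with Bradford before the sRGB matrix;
    out-of-gamut results are clipped.
    """
    white_src = illuminant_white_xyz(source_illuminant)
    adapted = bradford_adapt(np.asarray(xyz, dtype=float), white_src)
    linear = XYZ_TO_LINEAR_SRGB @ (adapted / 100.0)
    return np.clip(255.0 * srgb_encode(linear), 0.0, 255.0)
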