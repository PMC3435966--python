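"""Built-in chart references for the three chart sizes used in practice.

The 24-patch chart carries the widely published nominal sRGB values of
the classic 24-patch ColorChecker. The 7- and 140-patch charts are
synthetic stand-ins with the same structure as their physical
counterparts (a small primaries-plus-neutrals chart, and a dense chart
sampling the whole cube): their numeric values are fixture choices of
this package, not manufacturer data, and any real chart should be
measured and loaded via :func:`tpscolor.reference.load_reference`.
"""

from __future__ import annotations

import numpy as np

from .reference import ColorCheckerReference, ReferencePatch

# Nominal sRGB coordinates of the classic 24-patch chart.
_CLASSIC_24 = [
    ("dark_skin", (115, 82, 68)),
    ("light_skin", (194, 150, 130)),
    ("blue_sky", (98, 122, 157)),
    ("foliage", (87, 108, 67)),
    ("blue_flower", (133, 128, 177)),
    ("bluish_green", (103, 189, 170)),
    ("orange", (214, 126, 44)),
    ("purplish_blue", (80, 91, 166)),
    ("moderate_red", (193, 90, 99)),
    ("purple", (94, 60, 108)),
    ("yellow_green", (157, 188, 64)),
    ("orange_yellow", (224, 163, 46)),
    ("blue", (56, 61, 150)),
    ("green", (70, 148, 73)),
    ("red", (175, 54, 60)),
    ("yellow", (231, 199, 31)),
    ("magenta", (187, 86, 149)),
    ("cyan", (8, 133, 161)),
    ("white", (243, 243, 242)),
    ("neutral_8", (200, 200, 200)),
    ("neutral_65", (160, 160, 160)),
    ("neutral_5", (122, 122, 121)),
    ("neutral_35", (85, 85, 85)),
    ("black", (52, 52, 52)),
]

# Synthetic 7-patch chart: primaries, yellow, black, white, mid grey.
_SMALL_7 = [
    ("blue", (35, 60, 150)),
    ("green", (60, 150, 70)),
    ("red", (180, 50, 55)),
    ("yellow", (230, 200, 40)),
    ("black", (40, 40, 40)),
    ("grey", (128, 128, 128)),
    ("white", (245, 245, 245)),
]


def checker_24() -> ColorCheckerReference:
    """Classic 24-patch chart with its nominal sRGB reference values."""
    return ColorCheckerReference(
        name="checker24",
        patches=[
            ReferencePatch(pid, np.asarray(rgb, dtype=float))
            for pid, rgb in _CLASSIC_24
        ],
    )


def checker_7() -> ColorCheckerReference:
    """Small 7-patch chart (synthetic nominal values)."""
    return ColorCheckerReference(
        name="checker7",
        patches=[
            ReferencePatch(pid, np.asarray(rgb, dtype=float))
            for pid, rgb in _SMALL_7
        ],
    )


def checker_140() -> ColorCheckerReference:
    """Dense 140-patch chart (synthetic) sampling the whole sRGB cube.

    125 patches on a 5x5x5 lattice over [13, 242] plus 10 skin tones and
    5 extra neutrals, mirroring how dense physical charts add memory
    colors and a grey ramp to a cube sampling.
    """
    levels = np.linspace(13.0, 242.0, 5)
    patches = []
    k = 0
    for r in levels:
        for g in levels:
            for b in levels:
                patches.append(
                    ReferencePatch(f"cube_{k:03d}", np.array([r, g, b]))
                )
                k += 1
    skin = [
        (244, 220, 195), (230, 195, 170), (215, 170, 145), (198, 145, 120),
        (180, 125, 100), (160, 105, 82), (140, 88, 66), (118, 70, 52),
        (96, 56, 42), (75, 44, 34),
    ]
    for i, rgb in enumerate(skin):
        patches.append(ReferencePatch(f"skin_{i}", np.asarray(rgb, dtype=float)))
    for i, v in enumerate(np.linspace(26.0, 230.0, 5)):
        patches.append(ReferencePatch(f"grey_{i}", np.array([v, v, v])))
    return ColorCheckerReference(name="checker140", patches=patches)


BUILTIN_CHECKERS = {
    "7": checker_7,
    "24": checker_24,
    "140": checker_140,
}


def get_checker(name: str) -> ColorCheckerReference:
    """Look up a built-in chart by patch count ("7", "24", "140")."""
    key = str(name)
    if key not in BUILTIN_CHECKERS:
        raise KeyError(
            f"unknown built-in chart {name!r}; choose from {sorted(BUILTIN_CHECKERS)}"
        )
    return BUILTIN_CHECKERS[key]()
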