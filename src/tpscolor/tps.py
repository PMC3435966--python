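"""3D thin-plate-spline warping of the RGB color cube.

The calibration treats colors as points in a 3D space (R, G, B on the
8-bit scale) and finds the unique thin-plate-spline interpolant carrying
each measured control color P_i onto its reference color V_i. The map
decomposes into an affine part A (linear distortion: exposure, white
balance, channel crosstalk) plus a weighted sum of radial kernels W
(non-linear distortion: gamma, sensor response), obtained in closed form
from one dense linear solve:

    L [W; A] = [V; 0],   L = [[K, P_hom], [P_hom^T, 0_4x4]]

with K_ij = U(||P_i - P_j||), K_ii = 0, P_hom = [1 | P], and the radial
kernel

    U(r) = 2 r^2 log(r + eps),   eps = 1e-20

where the distance is Euclidean in RGB. The tiny eps regularizes log(0)
so that U(0) = 0 without branching. The four zero rows appended to the
right-hand side encode the side conditions P_hom^T W = 0, which make the
non-affine part orthogonal to the affine one; the bending energy of the
fitted map is zero exactly when V is an affine image of P, in which case
W vanishes.

This kernel is the 2D biharmonic form applied verbatim to 3D distances
(not the |r| kernel that minimizes 3D bending energy); the warp is still
an exact interpolant, which is the property the calibration relies on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .errors import InvalidInputError, SingularSystemError

logger = logging.getLogger(__name__)

#: Kernel regularizer, kept exactly as the closed form prescribes.
KERNEL_EPSILON = 1e-20

#: Condition-number ceiling above which a fit is refused. On the 0-255
#: scale kernel entries reach ~1e6, so cond(L) of a healthy system sits
#: around 1e13-1e14; genuinely near-duplicate control colors push it past
#: 1e16 and destroy the interpolation property.
MAX_CONDITION = 1e16

#: Pixels per internal evaluation block. Evaluation always streams through
#: blocks of this size, so results are bit-identical no matter how a caller
#: tiles a large image.
EVAL_BLOCK = 4096


def kernel_u(r, epsilon: float = KERNEL_EPSILON):
    """Radial basis kernel U(r) = 2 r^2 log(r + epsilon), natural log.

    Accepts scalars or arrays of nonnegative distances; U(0) = 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidInputError("kernel distances must be nonnegative")
    out = 2.0 * r * r * np.log(r + epsilon)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ControlPointSet:
    """Row-aligned measured (P) and reference (V) control colors.

    P and V are (N, 3) arrays on the [0, 255] scale; ``ids`` names each
    row. N must be at least 4 and the rows of P pairwise distinct --
    duplicate measured colors (possible after 8-bit quantization) should
    be merged upstream via :func:`merge_duplicate_controls`.
    """

    P: np.ndarray
    V: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        V = np.asarray(self.V, dtype=float)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if P.ndim != 2 or P.shape[1] != 3 or V.shape != P.shape:
            raise InvalidInputError("P and V must be matching (N, 3) arrays")
        if len(self.ids) != P.shape[0]:
            raise InvalidInputError("ids must match the number of control rows")
        if P.shape[0] < 4:
            raise InvalidInputError(
                f"TPS-3D needs at least 4 control points, got {P.shape[0]}"
            )

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def homogeneous(self) -> np.ndarray:
        """P with a leading column of ones: (N, 4)."""
        return np.hstack([np.ones((self.n, 1)), self.P])


def merge_duplicate_controls(
    P: np.ndarray, V: np.ndarray, ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Merge rows of P that are exactly equal, averaging their V targets.

    Returns deduplicated (P, V, ids); merged rows get a combined id. The
    kernel matrix is singular when two control points coincide, so this is
    the least-committal repair.
    """
    P = np.asarray(P, dtype=float)
    V = np.asarray(V, dtype=float)
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(P):
        groups.setdefault(tuple(row), []).append(i)
    if len(groups) == len(ids):
        return P, V, list(ids)
    new_p, new_v, new_ids = [], [], []
    for key, members in groups.items():
        new_p.append(P[members[0]])
        new_v.append(V[members].mean(axis=0))
        merged = "+".join(ids[m] for m in members)
        new_ids.append(merged)
        if len(members) > 1:
            logger.warning(
                "control colors of patches %s coincide after quantization; "
                "merged with averaged reference",
                [ids[m] for m in members],
            )
    return np.vstack(new_p), np.vstack(new_v), new_ids


def assemble_system(control: ControlPointSet) -> tuple[np.ndarray, np.ndarray]:
    """Build the (N+4)x(N+4) system matrix L and (N+4)x3 right-hand side.

    L = [[K, P_hom], [P_hom^T, 0]] with K_ij = U(||P_i - P_j||) and a zero
    diagonal; rhs = [V; 0_4x3].
    """
    dists = cdist(control.P, control.P)
    dup = np.argwhere((dists == 0) & ~np.eye(control.n, dtype=bool))
    if dup.size:
        i, j = dup[0]
        raise SingularSystemError(
            f"control points {control.ids[i]!r} and {control.ids[j]!r} have "
            "identical measured colors; merge them before fitting"
        )
    K = kernel_u(dists)
    np.fill_diagonal(K, 0.0)
    ph = control.homogeneous()
    n = control.n
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K
    L[:n, n:] = ph
    L[n:, :n] = ph.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = control.V
    return L, rhs


@dataclass
class TPSModel:
    """A fitted thin-plate-spline color calibration.

    ``W`` is the (N, 3) non-linear weight matrix, ``A`` the (4, 3) affine
    coefficient matrix (first row the translation); ``warp`` evaluates the
    interpolant at arbitrary colors. ``condition`` records cond(L) from
    the fit for diagnostics.
    """

    control: ControlPointSet
    W: np.ndarray
    A: np.ndarray
    kernel_epsilon: float = KERNEL_EPSILON
    condition: float = float("nan")
    checker_name: Optional[str] = None
    _lines: dict = field(default_factory=dict, repr=False)

    def warp(self, colors: np.ndarray) -> np.ndarray:
        """Evaluate the warp at an (M, 3) array (or single triplet) of colors.

        Output is the affine part plus the kernel-weighted sum; it is NOT
        clipped to [0, 255] -- gamut handling is the pipeline's job.
        """
        c = np.asarray(colors, dtype=float)
        single = c.ndim == 1
        c = np.atleast_2d(c)
        if c.shape[1] != 3:
            raise InvalidInputError(f"expected (M, 3) colors, got {c.shape}")
        out = np.empty_like(c)
        # Fixed-size blocks keep evaluation bit-identical across any tiling.
        for start in range(0, c.shape[0], EVAL_BLOCK):
            block = c[start : start + EVAL_BLOCK]
            kb = kernel_u(cdist(block, self.control.P), self.kernel_epsilon)
            hom = np.hstack([np.ones((block.shape[0], 1)), block])
            out[start : start + EVAL_BLOCK] = kb @ self.W + hom @ self.A
        return out[0] if single else out

    def residual(self) -> float:
        """Max per-channel interpolation error at the control points."""
        return float(np.abs(self.warp(self.control.P) - self.control.V).max())

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "tpscolor-model-v1",
                "method": "tps3d",
                "checker": self.checker_name,
                "kernel_epsilon": self.kernel_epsilon,
                "condition": self.condition,
                "ids": list(self.control.ids),
                "P": self.control.P.tolist(),
                "V": self.control.V.tolist(),
                "W": self.W.tolist(),
                "A": self.A.tolist(),
            },
            indent=2,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "TPSModel":
        d = json.loads(text)
        if d.get("schema") != "tpscolor-model-v1":
            raise InvalidInputError("unrecognized model schema")
        control = ControlPointSet(
            np.asarray(d["P"], dtype=float),
            np.asarray(d["V"], dtype=float),
            tuple(d["ids"]),
        )
        return cls(
            control=control,
            W=np.asarray(d["W"], dtype=float),
            A=np.asarray(d["A"], dtype=float),
            kernel_epsilon=float(d.get("kernel_epsilon", KERNEL_EPSILON)),
            condition=float(d.get("condition", float("nan"))),
            checker_name=d.get("checker"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TPSModel":
        return cls.from_json(Path(path).read_text())


def fit(control: ControlPointSet, checker_name: Optional[str] = None) -> TPSModel:
    """Solve the interpolation system and return a fitted :class:`TPSModel`.

    The solve is a dense LU factorization; no smoothing term is added, so
    the result interpolates exactly: warp(P_i) = V_i to solver precision.
    Raises :class:`SingularSystemError` when cond(L) exceeds
    ``MAX_CONDITION``, which in practice means two control patches
    measured nearly identical colors.
    """
    L, rhs = assemble_system(control)
    condition = float(np.linalg.cond(L))
    if not np.isfinite(condition) or condition > MAX_CONDITION:
        raise SingularSystemError(
            f"interpolation system is ill-conditioned (cond={condition:.3g}); "
            "review control points for near-duplicate measured colors"
        )
    coeffs = scipy.linalg.solve(L, rhs)
    n = control.n
    model = TPSModel(
        control=control,
        W=coeffs[:n],
        A=coeffs[n:],
        condition=condition,
        checker_name=checker_name,
    )
    logger.debug(
        "TPS fit: N=%d, cond(L)=%.3g, control residual=%.3g",
        n, condition, model.residual(),
    )
    return model
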