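"""Quantitative evaluation of a color calibration.

All errors are Euclidean distances in sRGB on the 8-bit scale (dRGB),
bounded by the cube diagonal 255*sqrt(3) ~ 441.67:

* within-distance -- mean dRGB to reference over the N patches used to
  fit the calibration (how well the fit reproduces its own controls);
* holdout distance -- mean dRGB to reference over the M patches NOT used
  to fit (generalization of the warp to unseen colors);
* inter-distance -- for each holdout patch, the mean pairwise dRGB of its
  calibrated color across acquisition conditions, averaged over patches
  (how consistent the same physical color looks after calibration under
  different illuminants);
* nearest-control association -- Spearman rank correlation between a
  holdout patch's distance to its nearest calibrated control color and
  its residual error, testing whether errors grow away from the control
  cloud (the signature of an interpolation-based method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .pipeline import PatchMeasurementSet

MAX_DELTA = 255.0 * math.sqrt(3.0)


def delta_rgb(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two sRGB triplets on [0, 255]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise InvalidInputError("delta_rgb expects two RGB triplets")
    for v in (a, b):
        if np.any(v < 0) or np.any(v > 255):
            raise InvalidInputError("RGB components must lie in [0, 255]")
    return float(np.linalg.norm(a - b))


def delta_rgb_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise dRGB between two (N, 3) arrays (no range check; vector path)."""
    return np.linalg.norm(np.asarray(a, float) - np.asarray(b, float), axis=1)


@dataclass
class PatchEvaluation:
    patch_id: str
    delta_rgb: float
    used_in_fit: bool
    min_dist_to_control: Optional[float] = None


@dataclass
class CalibrationEvaluation:
    """Per-patch errors plus the summary distances of one calibrated image."""

    per_patch: list[PatchEvaluation]
    within_distance: Optional[float]
    distance_from_reference: Optional[float]
    inter_distance: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-patch table (one row per patch) for downstream stats."""
        return pd.DataFrame(
            {
                "patch_id": [p.patch_id for p in self.per_patch],
                "delta_rgb": [p.delta_rgb for p in self.per_patch],
                "used_in_fit": [p.used_in_fit for p in self.per_patch],
                "min_dist_to_control": [
                    p.min_dist_to_control for p in self.per_patch
                ],
            }
        )

    def summary(self) -> dict:
        return {
            "within_distance": self.within_distance,
            "distance_from_reference": self.distance_from_reference,
            "inter_distance": self.inter_distance,
            "n_patches": len(self.per_patch),
        }


def within_distance(deltas: Mapping[str, float], fit_ids: Iterable[str]) -> float:
    """Mean dRGB over the patches used for the calibration."""
    fit_ids = set(fit_ids)
    if not fit_ids:
        raise InvalidInputError("fit_ids must be non-empty")
    missing = fit_ids - set(deltas)
    if missing:
        raise InvalidInputError(f"fit ids without deltas: {sorted(missing)}")
    vals = [deltas[i] for i in sorted(fit_ids)]
    return float(np.mean(vals))


def holdout_distance(deltas: Mapping[str, float], fit_ids: Iterable[str]) -> float:
    """Mean dRGB over the patches NOT used for the calibration."""
    fit_ids = set(fit_ids)
    rest = [v for k, v in deltas.items() if k not in fit_ids]
    if not rest:
        raise InvalidInputError("no holdout patches: every patch was used to fit")
    return float(np.mean(rest))


def inter_distance(
    condition_measurements: Mapping[str, PatchMeasurementSet],
    fit_ids: Iterable[str],
) -> float:
    """Cross-condition consistency of calibrated holdout patches.

    For each patch absent from ``fit_ids`` and present in every condition,
    average the pairwise dRGB of its calibrated mean color over all
    unordered condition pairs; return the mean over those M patches.
    """
    labels = sorted(condition_measurements)
    if len(labels) < 2:
        raise InvalidInputError("inter-distance needs at least 2 conditions")
    fit_ids = set(fit_ids)
    per_cond = {
        lab: {m.patch_id: np.asarray(m.mean_rgb, float)
              for m in condition_measurements[lab].measurements}
        for lab in labels
    }
    shared = set.intersection(*(set(d) for d in per_cond.values())) - fit_ids
    if not shared:
        raise InvalidInputError("no shared holdout patches across conditions")
    patch_means = []
    for pid in sorted(shared):
        pair_d = [
            float(np.linalg.norm(per_cond[a][pid] - per_cond[b][pid]))
            for a, b in combinations(labels, 2)
        ]
        patch_means.append(np.mean(pair_d))
    return float(np.mean(patch_means))


def nearest_control_association(
    evaluation: CalibrationEvaluation, exact_threshold: int = 10
) -> tuple[float, int, float]:
    """Spearman correlation between nearest-control distance and error.

    Runs over holdout patches only; requires at least 5 of them with a
    ``min_dist_to_control``. Ties get average ranks. The p-value uses the
    large-sample t approximation t = rho*sqrt((n-2)/(1-rho^2)); for
    n <= ``exact_threshold`` an exact permutation p-value is computed
    instead. Returns (rho, n, p).
    """
    pairs = [
        (p.min_dist_to_control, p.delta_rgb)
        for p in evaluation.per_patch
        if not p.used_in_fit and p.min_dist_to_control is not None
    ]
    n = len(pairs)
    if n < 5:
        raise InvalidInputError(
            f"association test needs >= 5 holdout patches, got {n}"
        )
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError(
            "Spearman correlation undefined: zero variance in ranks"
        )
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_threshold:
        p = _exact_permutation_p(rx, ry, rho)
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, n, p


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (tiny n only)."""
    count = 0
    total = 0
    for perm in permutations(range(len(ry))):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def evaluate_measurements(
    calibrated: PatchMeasurementSet,
    reference_rgb: Mapping[str, np.ndarray],
    fit_ids: Iterable[str],
) -> CalibrationEvaluation:
    """Build a full evaluation from calibrated patch means and references.

    ``min_dist_to_control`` is the smallest dRGB from a holdout patch's
    calibrated color to any calibrated control patch color.
    """
    fit_ids = set(fit_ids)
    colors = {m.patch_id: np.asarray(m.mean_rgb, float) for m in calibrated.measurements}
    control_colors = np.array(
        [colors[i] for i in sorted(fit_ids & set(colors))], dtype=float
    )
    per_patch = []
    deltas = {}
    for m in calibrated.measurements:
        pid = m.patch_id
        if pid not in reference_rgb:
            raise InvalidInputError(f"no reference color for patch {pid!r}")
        d = float(np.linalg.norm(colors[pid] - np.asarray(reference_rgb[pid], float)))
        deltas[pid] = d
        used = pid in fit_ids
        min_dist = None
        if not used and control_colors.size:
            min_dist = float(
                np.linalg.norm(control_colors - colors[pid], axis=1).min()
            )
        per_patch.append(PatchEvaluation(pid, d, used, min_dist))
    present_fit = fit_ids & set(deltas)
    within = within_distance(deltas, present_fit) if present_fit else None
    holdout = (
        holdout_distance(deltas, fit_ids)
        if set(deltas) - fit_ids
        else None
    )
    return CalibrationEvaluation(
        per_patch=per_patch,
        within_distance=within,
        distance_from_reference=holdout,
    )
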