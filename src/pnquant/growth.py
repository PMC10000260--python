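"""Exponential pronucleus growth model f(t) = beta1 * beta2**t.

The pronucleus area grows multiplicatively: fitting is done by ordinary
least squares on the log scale, ln(area) = ln(beta1) + t * ln(beta2),
which is closed-form and needs no initialisation.  beta1 is the
fictitious PN area at the time of ICSI (t = 0, um^2) and beta2 the hourly
growth factor (cohort statistics: mean 1.04, SD 0.017, range 1.01-1.11).
R^2 is reported on the original area scale against the back-transformed
predictions, where observed values range 98-99.99% on well-behaved
trajectories.

Four fitting-window variants address detector error structure: *original*
(all frames), *adjusted* (first and last three frames dropped — those
carry most recognition error and the highest leverage), *h12* and *h14*
(only frames from 12 h / 14 h post-insemination onward, where overcalls
have died out).  beta1 always refers to the t = 0 intercept regardless of
the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .track import Trajectory

__all__ = [
    "VARIANTS",
    "GrowthFit",
    "fit_exponential",
    "coefficient_variants",
    "fit_quality_report",
    "compare_model_families",
    "fits_to_frame",
]

VARIANTS = ("original", "adjusted", "h12", "h14")

MIN_POINTS = 4  # 2 parameters + 2 residual degrees of freedom


@dataclass
class GrowthFit:
    embryo_id: str
    sex: str
    variant: str
    beta1: float
    beta2: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.beta1 <= 0:
            raise ValueError(f"beta1 must be > 0, got {self.beta1}")
        if self.n_points < MIN_POINTS:
            raise ValueError(f"n_points must be >= {MIN_POINTS}")
        if self.r2 > 1 + 1e-12:
            raise ValueError(f"r2 must be <= 1, got {self.r2}")

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.beta1 * self.beta2 ** np.asarray(t, dtype=float)


def _r2_original_scale(areas: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((areas - predicted) ** 2))
    ss_tot = float(np.sum((areas - areas.mean()) ** 2))
    if ss_tot == 0:
        # degenerate constant series: perfect if residuals vanish
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_exponential(traj: Trajectory, variant: str = "original") -> GrowthFit:
    """Closed-form log-scale least-squares fit of beta1 * beta2**t.

    Raises ``ValueError`` for fewer than 4 points or non-positive areas
    (non-positive areas cannot enter a log-scale fit).
    """
    t = traj.times_h
    a = traj.areas_um2
    if len(t) < MIN_POINTS:
        raise ValueError(
            f"need at least {MIN_POINTS} points to fit, got {len(t)}"
        )
    if np.any(a <= 0):
        raise ValueError("trajectory contains non-positive areas")
    slope, intercept = np.polyfit(t, np.log(a), 1)
    beta1 = float(np.exp(intercept))
    beta2 = float(np.exp(slope))
    r2 = _r2_original_scale(a, beta1 * beta2**t)
    return GrowthFit(traj.embryo_id, traj.sex, variant, beta1, beta2, min(r2, 1.0), len(t))


def _subset(traj: Trajectory, variant: str) -> Trajectory | None:
    if variant == "original":
        pts = traj.points
    elif variant == "adjusted":
        pts = traj.points[3:-3]
    elif variant == "h12":
        pts = [(t, a) for t, a in traj.points if t >= 12.0]
    elif variant == "h14":
        pts = [(t, a) for t, a in traj.points if t >= 14.0]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if len(pts) < MIN_POINTS:
        return None
    return Trajectory(traj.embryo_id, traj.sex, list(pts))


def coefficient_variants(
    traj: Trajectory, variants: Sequence[str] = VARIANTS
) -> dict[str, GrowthFit | None]:
    """Fit each requested windowing variant independently.

    A variant whose window keeps fewer than 4 points maps to ``None``
    (unavailable) rather than raising.
    """
    out: dict[str, GrowthFit | None] = {}
    for variant in variants:
        sub = _subset(traj, variant)
        out[variant] = None if sub is None else fit_exponential(sub, variant)
    return out


def fit_quality_report(fits: Iterable[GrowthFit]) -> pd.DataFrame:
    """Cohort summary of beta2 and R^2, one row per (sex, variant).

    Columns: n, beta2_mean, beta2_sd, beta2_min, beta2_max, r2_min, r2_max.
    SD is 0 for a single fit.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to summarise")
    df = fits_to_frame(fits)
    rows = []
    for (sex, variant), grp in df.groupby(["sex", "variant"], sort=True):
        rows.append(
            {
                "sex": sex,
                "variant": variant,
                "n": len(grp),
                "beta2_mean": grp["beta2"].mean(),
                "beta2_sd": grp["beta2"].std(ddof=1) if len(grp) > 1 else 0.0,
                "beta2_min": grp["beta2"].min(),
                "beta2_max": grp["beta2"].max(),
                "r2_min": grp["r2"].min(),
                "r2_max": grp["r2"].max(),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rejected model families (comparison utility only)


def _fit_r2(t: np.ndarray, a: np.ndarray, design: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, a, rcond=None)
    return _r2_original_scale(a, design @ coef)


def compare_model_families(traj: Trajectory) -> dict[str, float]:
    """Original-scale R^2 of alternative model families on one trajectory.

    Fits linear, logarithmic, cosine and quadratic models alongside the
    exponential model.  On real PN growth only the exponential family
    tracks the data (R^2 >= 0.98); the alternatives stay below 0.90.
    Provided for model-choice audits, not a production path.
    """
    t = traj.times_h
    a = traj.areas_um2
    ones = np.ones_like(t)
    out = {
        "exponential": fit_exponential(traj).r2,
        "linear": _fit_r2(t, a, np.column_stack([ones, t])),
        "logarithmic": _fit_r2(t, a, np.column_stack([ones, np.log(t)])),
        "cosine": _fit_r2(t, a, np.column_stack([ones, np.cos(t)])),
        "quadratic": _fit_r2(t, a, np.column_stack([ones, t, t**2])),
    }
    return out


def fits_to_frame(fits: Iterable[GrowthFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "embryo_id": f.embryo_id,
                "sex": f.sex,
                "variant": f.variant,
                "beta1": f.beta1,
                "beta2": f.beta2,
                "r2": f.r2,
                "n_points": f.n_points,
            }
            for f in fits
        ]
    )
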