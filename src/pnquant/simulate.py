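"""Seeded synthetic-zygote simulator.

Generates every input the measurement pipeline consumes — pronucleus
area trajectories, per-frame detection/annotation tables, optional
rendered z-stacks, and patient cohorts with rank-dependent PGT outcome
strings — together with the ground truth, so every pipeline stage can be
benchmarked end to end.

The generator emulates the acquisition and biology it stands in for:

* two pronuclei inside a 250 um well imaged at 0.3275 um/pixel every
  10-15 min;
* exponential area growth ``area(t) = beta1 * beta2**t`` with per-PN
  ``beta2`` drawn from a truncated normal, mean 1.04, SD 0.017, bounds
  [1.01, 1.11], and multiplicative lognormal measurement noise on areas;
* the male PN appearing earlier (6.5-8 h post-ICSI; the female follows
  0.5-1.5 h later, occasionally much later) and being larger early;
* detector error modes: spurious extra detections on early-stage frames
  (vacuole overcalls, concentrated before 12 h), overlap-merged misses in
  mid/late frames, and per-frame female/male label flips;
* chromosomal-outcome labels whose probability of being in the
  "chromosome-normal" group rises with the within-patient beta1 z-score
  through a logistic model, with non-normal embryos assigned a category
  and a synthesised karyotype string from the report grammar.

Everything is deterministic under ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .detect import PIXEL_SCALE_UM, PNDetection, area_to_microns
from .karyotype import ChromError, serialize_errors
from .track import Trajectory

__all__ = [
    "SimConfig",
    "EmbryoSim",
    "simulate_trajectories",
    "simulate_detections",
    "simulate_outcomes",
    "simulate_patient_beta1s",
    "recognition_tables",
    "detections_from_frame",
    "render_zstack",
    "simulate_cohort",
]


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator (units in names)."""

    # cohort
    n_patients: int = 155
    embryos_per_patient: tuple[int, int] = (2, 8)  # uniform inclusive
    # growth coefficients (um^2 at t=0; hourly factor)
    beta1_mean_um2: float = 250.0
    beta1_between_patient_sd: float = 80.0
    beta1_within_patient_sd: float = 30.0
    beta1_floor_um2: float = 60.0
    male_beta1_factor: float = 1.15
    beta2_mean: float = 1.04
    beta2_sd: float = 0.017
    beta2_bounds: tuple[float, float] = (1.01, 1.11)
    # areas: multiplicative lognormal measurement noise
    noise_sigma: float = 0.02
    # acquisition
    frame_interval_min: float = 15.0
    monitor_start_h: float = 5.0
    scale_um_per_px: float = PIXEL_SCALE_UM
    # PN appearance / fade windows (hours post-ICSI)
    male_appear_h: tuple[float, float] = (6.5, 8.0)
    female_delay_h: tuple[float, float] = (0.5, 1.5)
    female_long_delay_h: tuple[float, float] = (1.5, 6.0)
    female_long_delay_prob: float = 0.08
    fade_h: tuple[float, float] = (20.0, 23.0)
    # detector error model
    early_overcall_rate: float = 0.25  # per pre-2PN frame
    vacuole_rate: float = 0.0  # spurious 3rd PN on a true-2PN frame
    overlap_miss_rate: float = 0.02  # merge both PNs from 14 h onward
    swap_rate: float = 0.0  # provisional-label flip per 2PN frame
    # outcome model: P(normal group) = logistic(alpha + gamma * z)
    outcome_alpha: float = 0.06
    outcome_gamma: float = 0.23
    mosaic_share_of_normal_group: float = 0.25
    abnormal_category_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "sole_aneuploidy": 0.45,
            "sole_del_dup": 0.20,
            "aneuploidy_with_errors": 0.15,
            "euploidy_with_errors": 0.10,
            "complex": 0.10,
        }
    )
    # rendering
    render_size_px: int = 256
    render_scale_um_per_px: float = 1.0
    render_n_planes: int = 11
    render_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.beta2_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        lo, hi = self.beta2_bounds
        if lo >= hi:
            raise ValueError("beta2 truncation bounds must be ordered")
        for r in (0.0 + self.early_overcall_rate, self.vacuole_rate,
                  self.overlap_miss_rate, self.swap_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if max(self.male_appear_h) + max(self.female_delay_h) >= min(self.fade_h):
            raise ValueError("PNs would fade before appearing")

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval_min / 60.0


@dataclass
class EmbryoSim:
    """One simulated embryo with its ground truth."""

    patient_id: str
    embryo_id: str
    beta1_female: float
    beta2_female: float
    beta1_male: float
    beta2_male: float
    t_male_appear_h: float
    t_female_appear_h: float
    t_fade_h: float
    axis_deg: float
    female: Trajectory | None = None
    male: Trajectory | None = None


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               bounds: tuple[float, float], size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _frame_grid(config: SimConfig, t_end: float) -> np.ndarray:
    dt = config.frame_interval_h
    n = int(math.floor((t_end - config.monitor_start_h) / dt)) + 1
    return config.monitor_start_h + dt * np.arange(n)


def simulate_trajectories(
    config: SimConfig | None = None, seed: int | np.random.Generator = 0
) -> list[EmbryoSim]:
    """Draw a patient cohort of embryos with noisy PN area trajectories.

    Trajectory points run on the frame grid from female-PN appearance
    (both PNs present) to fade; ``area(t) = beta1 * beta2**t *
    exp(noise)``.  With ``noise_sigma = 0`` the points are exactly
    exponential.  Deterministic under a fixed seed.
    """
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    embryos: list[EmbryoSim] = []
    for p in range(config.n_patients):
        patient_id = f"P{p:04d}"
        patient_beta1 = rng.normal(config.beta1_mean_um2, config.beta1_between_patient_sd)
        n_emb = int(rng.integers(config.embryos_per_patient[0],
                                 config.embryos_per_patient[1] + 1))
        for e in range(n_emb):
            b1f = max(
                config.beta1_floor_um2,
                patient_beta1 + rng.normal(0.0, config.beta1_within_patient_sd),
            )
            b1m = b1f * config.male_beta1_factor * math.exp(rng.normal(0.0, 0.03))
            # growth factors of the two PNs are strongly correlated within
            # an embryo (they share the zygote), so draw the male's as a
            # small perturbation of the female's
            b2f = float(_truncnorm(rng, config.beta2_mean, config.beta2_sd,
                                   config.beta2_bounds, 1)[0])
            b2m = float(np.clip(b2f + rng.normal(0.0, 0.004), *config.beta2_bounds))
            t_male = rng.uniform(*config.male_appear_h)
            if rng.uniform() < config.female_long_delay_prob:
                delay = rng.uniform(*config.female_long_delay_h)
            else:
                delay = rng.uniform(*config.female_delay_h)
            t_female = t_male + delay
            t_fade = rng.uniform(*config.fade_h)
            emb = EmbryoSim(
                patient_id=patient_id,
                embryo_id=f"{patient_id}-E{e:02d}",
                beta1_female=float(b1f),
                beta2_female=float(b2f),
                beta1_male=float(b1m),
                beta2_male=float(b2m),
                t_male_appear_h=float(t_male),
                t_female_appear_h=float(t_female),
                t_fade_h=float(t_fade),
                axis_deg=float(rng.uniform(0.0, 360.0)),
            )
            grid = _frame_grid(config, t_fade)
            both = grid[grid >= t_female]
            pts_f, pts_m = [], []
            for t in both:
                nf = rng.normal(0.0, config.noise_sigma) if config.noise_sigma else 0.0
                nm = rng.normal(0.0, config.noise_sigma) if config.noise_sigma else 0.0
                pts_f.append((float(t), emb.beta1_female * emb.beta2_female**t * math.exp(nf)))
                pts_m.append((float(t), emb.beta1_male * emb.beta2_male**t * math.exp(nm)))
            if len(pts_f) >= 4:
                emb.female = Trajectory(emb.embryo_id, "female", pts_f)
                emb.male = Trajectory(emb.embryo_id, "male", pts_m)
            embryos.append(emb)
    return embryos


# ---------------------------------------------------------------------------
# Detection tables

# PN centre paths: both PNs migrate from the periphery toward the zygote
# centre along parallel lines separated by a fixed perpendicular offset,
# so the female->male vector keeps a stable direction (what the cosine
# rule protects).
_START_RADIUS_UM = 75.0
_END_RADIUS_UM = 0.0
_HALF_SEPARATION_UM = 18.0


def _pn_positions_um(emb: EmbryoSim, t: float) -> tuple[np.ndarray, np.ndarray]:
    """(female, male) centre offsets from the zygote centre, in um."""
    phi = math.radians(emb.axis_deg)
    u = np.array([math.cos(phi), math.sin(phi)])
    perp = np.array([-math.sin(phi), math.cos(phi)])
    span = max(emb.t_fade_h - emb.t_male_appear_h, 1e-6)
    frac = min(max((t - emb.t_male_appear_h) / span, 0.0), 1.0)
    radial = (_START_RADIUS_UM + (_END_RADIUS_UM - _START_RADIUS_UM) * frac) * u
    return radial + _HALF_SEPARATION_UM * perp, radial - _HALF_SEPARATION_UM * perp


def _embryo_center_px(config: SimConfig) -> np.ndarray:
    return np.array([640.0, 512.0]) if config.scale_um_per_px < 0.5 else np.array([128.0, 128.0])


def simulate_detections(
    embryos: Sequence[EmbryoSim],
    config: SimConfig | None = None,
    seed: int | np.random.Generator = 0,
    swap_frames: Mapping[str, set[int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[int]]]:
    """Convert true PN states to detection and annotation tables.

    Returns ``(detections, annotations, injected_swaps)``.  Detections
    carry ``embryo_id, frame_index, time_h, x_px, y_px, area_px, sex``
    (``sex`` is the provisional per-frame label; spurious detections are
    unassigned).  Annotations carry the true ``pn_count`` per frame.
    Error injection follows the config rates; ``swap_frames`` pins the
    injected label flips per embryo instead of drawing them at
    ``swap_rate``.
    """
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center = _embryo_center_px(config)
    scale = config.scale_um_per_px
    det_rows, ann_rows = [], []
    injected: dict[str, list[int]] = {}
    for emb in embryos:
        if emb.female is None:
            continue
        grid = _frame_grid(config, emb.t_fade_h)
        area_f = dict(emb.female.points)
        area_m = dict(emb.male.points)
        wanted = swap_frames.get(emb.embryo_id, set()) if swap_frames else None
        swaps: list[int] = []
        first_2pn = True
        for fi, t in enumerate(grid):
            pos_f, pos_m = _pn_positions_um(emb, t)
            true_count = int(t >= emb.t_male_appear_h) + int(t >= emb.t_female_appear_h)
            ann_rows.append(
                {"embryo_id": emb.embryo_id, "frame_index": fi, "time_h": t,
                 "pn_count": int(true_count)}
            )

            def _row(pos_um, area_um2, sex):
                xy = center + pos_um / scale
                return {
                    "embryo_id": emb.embryo_id, "frame_index": fi, "time_h": t,
                    "x_px": float(xy[0]), "y_px": float(xy[1]),
                    "area_px": area_um2 / scale**2, "sex": sex,
                }

            if true_count == 2:
                sex_f, sex_m = "female", "male"
                do_swap = (
                    fi in wanted
                    if wanted is not None
                    else (not first_2pn and rng.uniform() < config.swap_rate)
                )
                if do_swap and not first_2pn:
                    sex_f, sex_m = sex_m, sex_f
                    swaps.append(fi)
                first_2pn = False
                merged = t >= 14.0 and rng.uniform() < config.overlap_miss_rate
                if merged:
                    mid = (pos_f + pos_m) / 2.0
                    det_rows.append(_row(mid, area_f[t] + area_m[t], "unassigned"))
                else:
                    det_rows.append(_row(pos_f, area_f[t], sex_f))
                    det_rows.append(_row(pos_m, area_m[t], sex_m))
                    if rng.uniform() < config.vacuole_rate:
                        off = rng.uniform(-40, 40, size=2)
                        det_rows.append(_row(off, rng.uniform(60, 150), "unassigned"))
            else:
                # early-stage vacuole overcalls bring the frame to 2 calls;
                # the upstream labeller still tags its two calls, so these
                # frames look like (wrong) 2PN frames downstream
                overcalled = rng.uniform() < config.early_overcall_rate
                labels = ["female", "male"] if rng.uniform() < 0.5 else ["male", "female"]
                if t >= emb.t_male_appear_h:
                    amale = emb.beta1_male * emb.beta2_male**t
                    det_rows.append(
                        _row(pos_m, amale, labels.pop() if overcalled else "unassigned")
                    )
                    n_extra = 1 if overcalled else 0
                else:
                    n_extra = 2 if overcalled else 0
                for _ in range(n_extra):
                    off = rng.uniform(-50, 50, size=2)
                    det_rows.append(_row(off, rng.uniform(60, 200), labels.pop()))
        injected[emb.embryo_id] = swaps
    detections = pd.DataFrame(det_rows)
    annotations = pd.DataFrame(ann_rows)
    return detections, annotations, injected


def recognition_tables(
    detections: pd.DataFrame, annotations: pd.DataFrame
) -> tuple[dict, dict, dict]:
    """Build ``(auto_counts, annotated_counts, frame_times)`` mappings for
    :func:`pnquant.detect.evaluate_recognition`, keyed by
    ``(embryo_id, frame_index)`` over every annotated frame (frames with
    no detection rows count as zero calls)."""
    ann_map = {
        (r.embryo_id, r.frame_index): int(r.pn_count)
        for r in annotations.itertuples(index=False)
    }
    times = {
        (r.embryo_id, r.frame_index): float(r.time_h)
        for r in annotations.itertuples(index=False)
    }
    auto_map = dict.fromkeys(ann_map, 0)
    if len(detections):
        counts = detections.groupby(["embryo_id", "frame_index"]).size()
        for key, n in counts.items():
            auto_map[key] = int(n)
    return auto_map, ann_map, times


def detections_from_frame(
    df: pd.DataFrame, scale_um_per_px: float | None = None
) -> list[PNDetection]:
    """Materialise :class:`PNDetection` objects from a detection table."""
    out = []
    for row in df.itertuples(index=False):
        area_px = float(row.area_px)
        scale = scale_um_per_px if scale_um_per_px is not None else PIXEL_SCALE_UM
        out.append(
            PNDetection(
                embryo_id=str(row.embryo_id),
                frame_index=int(row.frame_index),
                time_h=float(row.time_h),
                center_px=(float(row.x_px), float(row.y_px)),
                area_px=area_px,
                area_um2=area_to_microns(area_px, scale),
                sex=getattr(row, "sex", "unassigned"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# PGT outcomes


def _random_band(rng: np.random.Generator, arm: str) -> str:
    a = int(rng.integers(11, 25))
    b = int(rng.integers(25, 37))
    return f"{arm}{a / 10:.1f}{arm}{b / 10:.1f}"


def _random_errors(rng: np.random.Generator, category: str) -> list[ChromError]:
    chroms = [str(c) for c in rng.choice(np.arange(1, 23), size=4, replace=False)]
    arm = "p" if rng.uniform() < 0.5 else "q"

    def whole(i, kind=None):
        kind = kind or ("gain" if rng.uniform() < 0.5 else "loss")
        return ChromError(chroms[i], kind)

    def seg(i, mosaic=False):
        kind = "dup" if rng.uniform() < 0.5 else "del"
        pct = float(rng.integers(20, 81)) if mosaic else None
        return ChromError(
            chroms[i], kind, segment=_random_band(rng, arm),
            size_mb=float(np.round(rng.uniform(1.5, 90.0), 1)),
            mosaic=mosaic, mosaic_pct=pct,
        )

    def whole_mosaic(i):
        return ChromError(chroms[i], "gain" if rng.uniform() < 0.5 else "loss",
                          mosaic_pct=float(rng.integers(20, 81)))

    if category == "chromosome_normal":
        return []
    if category == "sole_mosaic":
        return [whole_mosaic(0)] if rng.uniform() < 0.5 else [seg(0, mosaic=True)]
    if category == "sole_aneuploidy":
        return [whole(i) for i in range(int(rng.integers(1, 3)))]
    if category == "sole_del_dup":
        return [seg(i) for i in range(int(rng.integers(1, 3)))]
    if category == "euploidy_with_errors":
        other = whole_mosaic(1) if rng.uniform() < 0.5 else seg(1, mosaic=True)
        return [seg(0), other]
    if category == "aneuploidy_with_errors":
        other = seg(1) if rng.uniform() < 0.5 else whole_mosaic(1)
        return [whole(0), other]
    if category == "complex":
        mos = whole_mosaic(2) if rng.uniform() < 0.5 else seg(2, mosaic=True)
        return [whole(0), seg(1), mos]
    raise ValueError(f"unknown category {category!r}")


def simulate_outcomes(
    cohort: pd.DataFrame,
    config: SimConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Attach PGT outcome labels to a beta1 cohort.

    ``cohort`` needs ``patient_id, embryo_id, beta1``.  The probability
    of landing in the chromosome-normal group follows
    ``logistic(alpha + gamma * z)`` with ``z`` the within-patient beta1
    z-score (z = 0 for single-embryo patients).  Adds columns
    ``normal_group, category, pgt_string``.
    """
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = cohort.copy().sort_values(["patient_id", "embryo_id"]).reset_index(drop=True)
    zs = np.zeros(len(out))
    for _, idx in out.groupby("patient_id").groups.items():
        b = out.loc[idx, "beta1"].to_numpy(dtype=float)
        sd = b.std(ddof=0)
        zs[np.asarray(idx)] = (b - b.mean()) / sd if sd > 0 else 0.0
    logit = config.outcome_alpha + config.outcome_gamma * zs
    p_normal = 1.0 / (1.0 + np.exp(-logit))
    normal = rng.uniform(size=len(out)) < p_normal
    cats, strings = [], []
    ab_cats = list(config.abnormal_category_probs)
    ab_p = np.array([config.abnormal_category_probs[c] for c in ab_cats], dtype=float)
    ab_p /= ab_p.sum()
    for ok in normal:
        if ok:
            cat = (
                "sole_mosaic"
                if rng.uniform() < config.mosaic_share_of_normal_group
                else "chromosome_normal"
            )
        else:
            cat = str(rng.choice(ab_cats, p=ab_p))
        cats.append(cat)
        errors = _random_errors(rng, cat)
        strings.append(serialize_errors(errors) if errors else "46 XN")
    out["z_beta1"] = zs
    out["normal_group"] = normal
    out["category"] = cats
    out["pgt_string"] = strings
    return out


def simulate_patient_beta1s(
    config: SimConfig | None = None, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Cohort of true beta1 values only (no frames) — fast path for
    outcome-model studies."""
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        mu = rng.normal(config.beta1_mean_um2, config.beta1_between_patient_sd)
        n = int(rng.integers(config.embryos_per_patient[0],
                             config.embryos_per_patient[1] + 1))
        for e in range(n):
            b1 = max(config.beta1_floor_um2,
                     mu + rng.normal(0.0, config.beta1_within_patient_sd))
            rows.append({"patient_id": pid, "embryo_id": f"{pid}-E{e:02d}", "beta1": b1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rendering


def render_zstack(
    emb: EmbryoSim,
    time_h: float,
    config: SimConfig | None = None,
    seed: int | np.random.Generator = 0,
    sharp_plane: int | None = None,
) -> list[np.ndarray]:
    """Render one time point as a z-stack of plane images.

    Draws the zygote disk and the two PN disks (areas taken from the
    true growth model at ``time_h``) at ``render_scale_um_per_px``, then
    applies a per-plane Gaussian blur growing with the distance from the
    sharp plane, plus sensor noise.  Returns ``render_n_planes`` images.
    """
    from scipy.ndimage import gaussian_filter

    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.render_size_px
    scale = config.render_scale_um_per_px
    if sharp_plane is None:
        sharp_plane = config.render_n_planes // 2
    if not 0 <= sharp_plane < config.render_n_planes:
        raise ValueError("sharp_plane out of range")

    yy, xx = np.mgrid[0:n, 0:n]
    center = np.array([n / 2.0, n / 2.0])
    zygote_r_px = 110.0 / scale  # zygote radius ~110 um
    img = np.full((n, n), 0.05)
    # oblique-contrast imagery shows the membrane as an edge, not a filled
    # body: draw a thin bright ring (its low circularity lets the
    # area/circularity filters reject it downstream)
    rr2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    ring = (rr2 <= zygote_r_px**2) & (rr2 >= (zygote_r_px - 3.0) ** 2)
    img[ring] = 0.35

    pos_f, pos_m = _pn_positions_um(emb, time_h)
    for pos, b1, b2 in (
        (pos_f, emb.beta1_female, emb.beta2_female),
        (pos_m, emb.beta1_male, emb.beta2_male),
    ):
        area_um2 = b1 * b2**time_h
        r_um = math.sqrt(area_um2 / math.pi)
        if r_um >= 110.0:
            raise ValueError(f"PN radius {r_um:.1f} um exceeds the zygote radius")
        c = center + pos / scale
        r_px = r_um / scale
        img[(xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= r_px**2] = 0.75

    planes = []
    for k in range(config.render_n_planes):
        sigma = 0.6 + 1.6 * abs(k - sharp_plane)
        plane = gaussian_filter(img, sigma=sigma)
        if config.render_noise_sd:
            plane = plane + rng.normal(0.0, config.render_noise_sd, size=img.shape)
        planes.append(plane)
    return planes


def simulate_cohort(
    config: SimConfig | None = None, seed: int = 0
) -> dict[str, object]:
    """One-call cohort simulation: trajectories, tables, outcomes, truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    embryos = simulate_trajectories(config, rng)
    detections, annotations, swaps = simulate_detections(embryos, config, rng)
    cohort = pd.DataFrame(
        [
            {"patient_id": e.patient_id, "embryo_id": e.embryo_id,
             "beta1": e.beta1_female}
            for e in embryos
            if e.female is not None
        ]
    )
    outcomes = simulate_outcomes(cohort, config, rng)
    return {
        "config": config,
        "embryos": embryos,
        "detections": detections,
        "annotations": annotations,
        "injected_swaps": swaps,
        "outcomes": outcomes,
    }
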