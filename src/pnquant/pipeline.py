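"""End-to-end orchestration: inputs -> growth fits -> outcome statistics.

``run_quantify`` chains the measurement stages in acquisition order
(focal selection when starting from images, detection, abandonment
filtering, sexing, cosine-stability enforcement, trajectory building,
variant fitting) and ``run_stats`` runs the statistical battery on the
fitted coefficients joined with PGT outcomes.  Every run writes a
manifest carrying the configuration hash and seed so reruns are
reproducible; CSV outputs are byte-stable for a fixed config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import detect as _detect
from . import focal as _focal
from .detect import DetectorParams, PNDetection, evaluate_recognition
from .growth import coefficient_variants, fit_quality_report, fits_to_frame
from .karyotype import annotate_pgt_table
from .ranking import (
    cochran_heterogeneity,
    odds_ratio_woolf,
    pearson_chi_square,
    rank_rate_table,
    rank_within_patient,
    spearman_rank_corr,
    top_vs_last_table,
)
from .simulate import SimConfig, detections_from_frame, simulate_cohort
from .track import IndistinguishablePNError, track_embryo, track_to_frame

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_quantify", "run_stats"]

VALID_MODES = ("images", "detections", "simulate")


class StageError(RuntimeError):
    """A pipeline stage failed for a specific embryo."""

    def __init__(self, embryo_id: str, stage: str, message: str):
        self.embryo_id = embryo_id
        self.stage = stage
        super().__init__(f"[{stage}] embryo {embryo_id}: {message}")


@dataclass
class RunConfig:
    mode: str = "simulate"
    input_path: str | None = None  # manifest CSV (images) or detection CSV
    scale_um_per_px: float | None = _detect.PIXEL_SCALE_UM
    variants: Sequence[str] = ("original", "adjusted", "h12", "h14")
    pool_after: int = 8
    detector: DetectorParams = field(default_factory=DetectorParams)
    sim: SimConfig = field(default_factory=SimConfig)
    min_retained_frames: int = 4
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}")
        if self.pool_after < 1:
            raise ValueError("pool_after must be >= 1")
        if self.mode == "images" and self.scale_um_per_px is None:
            raise ValueError("image mode requires scale_um_per_px")

    def config_hash(self) -> str:
        payload = _as_jsonable(self)
        payload.pop("output_dir", None)  # where results land is not an analysis parameter
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def _detections_from_images(config: RunConfig) -> list[PNDetection]:
    stacks = _focal.load_stack_manifest(config.input_path)
    detections: list[PNDetection] = []
    frame_counters: dict[str, int] = {}
    for stack in stacks:
        _, image = _focal.select_clearest_plane(stack)
        fi = frame_counters.setdefault(stack.embryo_id, 0)
        frame_counters[stack.embryo_id] = fi + 1
        detections.extend(
            _detect.detect_pronuclei(
                image,
                config.detector,
                embryo_id=stack.embryo_id,
                frame_index=fi,
                time_h=stack.time_h,
                scale_um_per_px=config.scale_um_per_px,
            )
        )
    return detections


def _appearance_times(
    embryo_dets: Sequence[PNDetection],
) -> tuple[float, float] | None:
    """Derive (identity0, identity1) first-seen times from pre-2PN frames.

    Frames holding a single detection before the first two-detection
    frame mark the earlier (male) pronucleus; identity is resolved by
    which PN of the first 2PN frame sits nearer the last single
    detection.  Returns None when no single-PN prologue exists.
    """
    by_frame: dict[int, list[PNDetection]] = {}
    for d in embryo_dets:
        by_frame.setdefault(d.frame_index, []).append(d)
    singles, first_pair = [], None
    for fi in sorted(by_frame):
        dets = by_frame[fi]
        if len(dets) == 2 and first_pair is None:
            first_pair = dets
            break
        if len(dets) == 1:
            singles.append(dets[0])
    if not singles or first_pair is None:
        return None
    last_single = np.asarray(singles[-1].center_px)
    pair_sorted = sorted(first_pair, key=lambda d: d.center_px)
    d0 = np.linalg.norm(np.asarray(pair_sorted[0].center_px) - last_single)
    d1 = np.linalg.norm(np.asarray(pair_sorted[1].center_px) - last_single)
    t_early = singles[0].time_h
    t_late = pair_sorted[0].time_h
    return (t_early, t_late) if d0 <= d1 else (t_late, t_early)


def run_quantify(config: RunConfig) -> dict[str, object]:
    """Run the measurement chain; returns fits, tracks and logs.

    Output keys: ``fits`` (DataFrame), ``tracks`` (DataFrame),
    ``discards`` (DataFrame), ``excluded`` (list of (embryo_id, stage,
    reason)), ``manifest`` (dict) and, in simulate mode, ``sim``
    (the full simulated cohort dict).
    """
    rng_seed = config.seed
    sim_bundle = None
    if config.mode == "simulate":
        sim_bundle = simulate_cohort(config.sim, seed=rng_seed)
        detections = detections_from_frame(
            sim_bundle["detections"], config.sim.scale_um_per_px
        )
    elif config.mode == "detections":
        detections = _detect.load_detection_table(
            config.input_path, config.scale_um_per_px or _detect.PIXEL_SCALE_UM
        )
    else:
        detections = _detections_from_images(config)

    by_embryo: dict[str, list[PNDetection]] = {}
    for d in detections:
        by_embryo.setdefault(d.embryo_id, []).append(d)

    fits, tracks, discards, excluded = [], [], [], []
    for eid in sorted(by_embryo):
        dets = by_embryo[eid]
        try:
            track, female, male = track_embryo(
                dets,
                _appearance_times(dets),
                min_retained_frames=config.min_retained_frames,
            )
        except IndistinguishablePNError as err:
            excluded.append((eid, "sexing", str(err)))
            log.info("excluding embryo %s at sexing: %s", eid, err)
            continue
        except ValueError as err:
            excluded.append((eid, "tracking", str(err)))
            log.info("excluding embryo %s at tracking: %s", eid, err)
            continue
        tracks.append(track_to_frame(track))
        discards.extend(
            {"embryo_id": eid, "frame_index": fi, "reason": reason}
            for fi, reason in track.discarded_frames
        )
        for traj in (female, male):
            for variant, fit in coefficient_variants(traj, config.variants).items():
                if fit is not None:
                    fits.append(fit)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "n_embryos_in": len(by_embryo),
        "n_embryos_excluded": len(excluded),
    }
    out = {
        "fits": fits_to_frame(fits),
        "fit_objects": fits,
        "tracks": pd.concat(tracks, ignore_index=True) if tracks else pd.DataFrame(),
        "discards": pd.DataFrame(discards, columns=["embryo_id", "frame_index", "reason"]),
        "excluded": excluded,
        "manifest": manifest,
    }
    if sim_bundle is not None:
        out["sim"] = sim_bundle
    if config.output_dir:
        _write_quantify(out, Path(config.output_dir))
    return out


def _write_quantify(out: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    out["fits"].to_csv(outdir / "fits.csv", index=False)
    out["tracks"].to_csv(outdir / "tracks.csv", index=False)
    out["discards"].to_csv(outdir / "discard_log.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(out["manifest"], indent=2))


def run_stats(
    fits: pd.DataFrame,
    outcomes: pd.DataFrame,
    *,
    variants: Sequence[str] = ("original", "adjusted", "h12", "h14"),
    sex: str = "female",
    pool_after: int = 8,
    outcome_col: str = "normal_group",
    output_dir: str | Path | None = None,
) -> dict[str, object]:
    """Statistical battery on fitted coefficients joined with outcomes.

    ``fits`` is the quantify output table; ``outcomes`` needs
    ``patient_id, embryo_id`` and an outcome column (``normal_group`` by
    default; PGT tables with a ``pgt_string`` column are classified
    first).  Produces, per variant: the within-patient ranking, the rank
    rate table, top-1 and top-2 vs last odds ratios, a Pearson chi-square
    on the rank x outcome table, and embryo-level Spearman correlation;
    plus a patient-level Cochran heterogeneity test of beta1.
    """
    if "pgt_string" in outcomes.columns and outcome_col not in outcomes.columns:
        outcomes = annotate_pgt_table(outcomes)
    have = set(outcomes["embryo_id"])
    report: dict[str, object] = {"variants": {}}
    for variant in variants:
        sub = fits[(fits["variant"] == variant) & (fits["sex"] == sex)]
        if sub.empty:
            continue
        orphans = sorted(set(sub["embryo_id"]) - have)
        if orphans:
            raise ValueError(f"embryo ids without outcomes: {orphans[:10]}")
        cols = ["embryo_id"] + (
            ["patient_id"] if "patient_id" not in sub.columns else []
        )
        merged = sub.merge(outcomes[list(dict.fromkeys(cols + [outcome_col]))],
                           on="embryo_id", how="inner")
        ranked = rank_within_patient(merged, pool_after=pool_after)
        ranked = ranked.rename(columns={outcome_col: "outcome"})
        n_patients = ranked["patient_id"].nunique()
        entry: dict[str, object] = {
            "ranked": ranked,
            "rate_table": rank_rate_table(ranked),
            "n_patients": n_patients,
        }
        for k in (1, 2):
            a, b, c, d = top_vs_last_table(ranked, top=k)
            if n_patients < 2 or min(a + b, c + d) == 0:
                # a single patient (or an empty arm) cannot support a
                # between-stratum odds ratio
                entry[f"or_top{k}_vs_last{k}"] = None
            else:
                entry[f"or_top{k}_vs_last{k}"] = odds_ratio_woolf(a, b, c, d)
                entry[f"table_top{k}"] = (a, b, c, d)
        # rank x outcome chi-square over pooled labels
        tab = (
            ranked.assign(pos=ranked["outcome"].astype(bool))
            .groupby("pooled_rank_label")["pos"]
            .agg(["sum", "count"])
        )
        rx2 = np.column_stack([tab["sum"], tab["count"] - tab["sum"]])
        rx2 = rx2[rx2.sum(axis=1) > 0]
        entry["chi_square"] = (
            pearson_chi_square(rx2)
            if len(rx2) > 1 and (rx2.sum(axis=0) > 0).all()
            else None
        )
        entry["spearman"] = spearman_rank_corr(
            ranked["rank"], ranked["outcome"].astype(float)
        )
        report["variants"][variant] = entry

    # patient-level heterogeneity of beta1 (original variant by default)
    base = fits[(fits["variant"] == variants[0]) & (fits["sex"] == sex)]
    if "patient_id" not in base.columns:
        base = base.merge(
            outcomes[["embryo_id", "patient_id"]].drop_duplicates(),
            on="embryo_id",
            how="inner",
        )
    groups = [
        (float(g["beta1"].mean()), float(g["beta1"].std(ddof=1)), len(g))
        for _, g in base.groupby("patient_id")
        if len(g) >= 2 and g["beta1"].std(ddof=1) > 0
    ]
    report["heterogeneity"] = (
        cochran_heterogeneity(groups) if len(groups) >= 2 else None
    )
    if output_dir:
        _write_stats(report, Path(output_dir))
    return report


def _jsonable_stats(report: dict) -> dict:
    out: dict[str, object] = {"variants": {}}
    for variant, entry in report["variants"].items():
        e: dict[str, object] = {"n_patients": entry["n_patients"]}
        for k in (1, 2):
            orr = entry.get(f"or_top{k}_vs_last{k}")
            if orr is not None:
                e[f"or_top{k}_vs_last{k}"] = {
                    "or": orr.estimate, "ci_low": orr.ci_low,
                    "ci_high": orr.ci_high, "p": orr.p_value,
                }
        if entry.get("chi_square") is not None:
            cs = entry["chi_square"]
            e["chi_square"] = {"chi2": cs.estimate, "df": cs.df, "p": cs.p_value}
        sp = entry["spearman"]
        e["spearman"] = {"rho": sp.estimate, "p": sp.p_value}
        out["variants"][variant] = e
    het = report.get("heterogeneity")
    if het is not None:
        out["heterogeneity"] = {"Q": het.Q, "df": het.df, "I2_pct": het.I2_pct}
    return out


def _write_stats(report: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for variant, entry in report["variants"].items():
        entry["rate_table"].to_csv(outdir / f"rate_table_{variant}.csv", index=False)
        entry["ranked"].to_csv(outdir / f"ranked_{variant}.csv", index=False)
    (outdir / "stats_summary.json").write_text(
        json.dumps(_jsonable_stats(report), indent=2, default=float)
    )
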