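"""Within-patient ranking of growth coefficients and outcome statistics.

The absolute pronucleus growth intercept beta1 is strongly heterogeneous
between patients (no usable normal range exists), so all outcome
comparisons are made on *within-patient ranks*: each patient's embryos
are ordered by beta1, largest first, and rank strata are compared across
patients.  The statistical battery on top of the ranks:

* rank-stratified rate tables ("102/155 (65.81)" style cells),
* Woolf (log) odds ratios with normal-approximation confidence
  intervals for top-vs-last rank comparisons,
* Pearson chi-square on rank x outcome contingency tables,
* Spearman rank correlation, and
* Cochran Q / I^2 fixed-effect heterogeneity across patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RankedEmbryo",
    "ContingencyResult",
    "HeterogeneityResult",
    "rank_within_patient",
    "rank_rate_table",
    "odds_ratio_woolf",
    "pearson_chi_square",
    "spearman_rank_corr",
    "cochran_heterogeneity",
    "top_vs_last_table",
]

#: z quantile of the two-sided 95% normal interval.
Z_95 = 1.95996


@dataclass
class RankedEmbryo:
    patient_id: str
    embryo_id: str
    beta1: float
    rank: int
    pooled_rank_label: str
    outcome: object = None


@dataclass
class ContingencyResult:
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    df: int | None = None
    p_value: float = float("nan")
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.ci_low is not None and not (
            self.ci_low <= self.estimate <= self.ci_high
        ):
            raise ValueError("CI must contain the point estimate")


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    I2_pct: float
    flagged_groups: list[str] | None = None


def rank_within_patient(
    embryos: pd.DataFrame, *, pool_after: int = 10
) -> pd.DataFrame:
    """Rank embryos within each patient by descending beta1.

    ``embryos`` needs columns ``patient_id, embryo_id, beta1``.  Rank 1 is
    the largest beta1 in the patient; ties break by ascending embryo_id so
    reruns are deterministic.  Ranks above ``pool_after`` share the pooled
    label ``">K"`` (the published tables pool after rank 10 for
    blastocyst-formation analysis and after rank 8 for PGT analysis).
    """
    required = {"patient_id", "embryo_id", "beta1"}
    if missing := required - set(embryos.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    b = embryos["beta1"]
    if not np.all(np.isfinite(b)) or np.any(b <= 0):
        raise ValueError("beta1 values must be finite and positive")
    dup = embryos.duplicated(subset=["patient_id", "embryo_id"])
    if dup.any():
        raise ValueError(
            f"duplicate embryo ids within patient: "
            f"{embryos.loc[dup, 'embryo_id'].tolist()}"
        )
    out = embryos.copy()
    out = out.sort_values(
        ["patient_id", "beta1", "embryo_id"], ascending=[True, False, True]
    )
    out["rank"] = out.groupby("patient_id").cumcount() + 1
    out["pooled_rank_label"] = [
        str(r) if r <= pool_after else f">{pool_after}" for r in out["rank"]
    ]
    return out.reset_index(drop=True)


def _label_order(labels: Iterable[str]) -> list[str]:
    plain = sorted({l for l in labels if not l.startswith(">")}, key=int)
    pooled = sorted({l for l in labels if l.startswith(">")}, key=lambda s: int(s[1:]))
    return plain + pooled


def rank_rate_table(ranked: pd.DataFrame, outcome_col: str = "outcome") -> pd.DataFrame:
    """Per-rank outcome counts and rates.

    One row per pooled rank label, with ``positive``, ``total``,
    ``rate_pct`` (2-dp) and a formatted ``cell`` like ``"102/155
    (65.81)"``.  Empty strata are simply absent.
    """
    if outcome_col not in ranked.columns:
        raise ValueError(f"missing outcome column {outcome_col!r}")
    if ranked[outcome_col].isna().any():
        raise ValueError("every embryo needs an outcome")
    rows = []
    for label in _label_order(ranked["pooled_rank_label"]):
        grp = ranked[ranked["pooled_rank_label"] == label]
        pos = int(grp[outcome_col].astype(bool).sum())
        tot = len(grp)
        pct = round(100.0 * pos / tot, 2)
        rows.append(
            {
                "rank": label,
                "positive": pos,
                "total": tot,
                "rate_pct": pct,
                "cell": f"{pos}/{tot} ({pct:g})",
            }
        )
    return pd.DataFrame(rows)


def odds_ratio_woolf(
    a: int, b: int, c: int, d: int, *, haldane_if_zero: bool = True
) -> ContingencyResult:
    """Woolf odds ratio with 95% log-normal CI for a 2x2 table.

    Cells: ``a`` exposed-positive, ``b`` exposed-negative, ``c``
    unexposed-positive, ``d`` unexposed-negative; OR = ad/bc, 95% CI =
    exp(ln OR +/- 1.95996 * sqrt(1/a + 1/b + 1/c + 1/d)), two-sided p from
    the normal approximation of ln OR.  A zero cell triggers the Haldane
    +0.5 correction on all cells (flagged via ``corrected``) unless
    disabled, in which case it raises.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative")
    corrected = False
    if any(x == 0 for x in cells):
        if not haldane_if_zero:
            raise ValueError(f"zero cell in {cells} and correction disabled")
        cells = [x + 0.5 for x in cells]
        corrected = True
    a_, b_, c_, d_ = cells
    orr = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    log_or = math.log(orr)
    lo = math.exp(log_or - Z_95 * se)
    hi = math.exp(log_or + Z_95 * se)
    z = log_or / se
    p = 2.0 * sps.norm.sf(abs(z))
    return ContingencyResult(
        estimate=orr, ci_low=lo, ci_high=hi, p_value=float(p), corrected=corrected
    )


def pearson_chi_square(table: np.ndarray | pd.DataFrame) -> ContingencyResult:
    """Pearson chi-square on an R x 2 contingency table (no continuity
    correction); df = R - 1, p from the chi-square upper tail."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError(f"expected an Rx2 table, got shape {t.shape}")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal total in contingency table")
    chi2, p, df, expected = sps.chi2_contingency(t, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected cell count <= 0")
    return ContingencyResult(estimate=float(chi2), df=int(df), p_value=float(p))


def spearman_rank_corr(x: Sequence[float], y: Sequence[float]) -> ContingencyResult:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p).

    A constant input vector leaves the correlation undefined; the result
    then carries ``estimate = nan`` and ``p_value = nan`` rather than
    raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ContingencyResult(estimate=float("nan"), p_value=float("nan"))
    rho, p = sps.spearmanr(x, y)
    return ContingencyResult(estimate=float(rho), p_value=float(p))


def cochran_heterogeneity(
    groups: Sequence[tuple[float, float, int]] | pd.DataFrame,
    group_ids: Sequence[str] | None = None,
) -> HeterogeneityResult:
    """Fixed-effect Cochran Q and I^2 over per-group summaries.

    ``groups`` holds ``(mean, sd, n)`` per group (or a DataFrame with
    ``mean, sd, n`` columns); each group is weighted by the inverse of its
    squared standard error, ``w = n / sd^2``.  ``Q = sum w_i (m_i -
    m_pooled)^2``, ``df = k - 1`` and ``I^2 = max(0, (Q - df) / Q) * 100``.
    Zero-variance groups get their weight capped at the largest finite
    weight and are flagged.
    """
    if isinstance(groups, pd.DataFrame):
        ids = list(groups.index.astype(str))
        groups = list(zip(groups["mean"], groups["sd"], groups["n"]))
    else:
        ids = list(group_ids) if group_ids is not None else [str(i) for i in range(len(groups))]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(n < 2 for _, _, n in groups):
        raise ValueError("each group needs n >= 2")
    means = np.array([m for m, _, _ in groups], dtype=float)
    ses2 = np.array([sd**2 / n for _, sd, n in groups], dtype=float)
    flagged = [ids[i] for i in np.flatnonzero(ses2 == 0)]
    with np.errstate(divide="ignore"):
        w = 1.0 / ses2
    if flagged:
        finite = w[np.isfinite(w)]
        if finite.size == 0:
            raise ValueError("all groups have zero variance")
        w[~np.isfinite(w)] = finite.max()
    pooled = float(np.sum(w * means) / np.sum(w))
    Q = float(np.sum(w * (means - pooled) ** 2))
    df = len(groups) - 1
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return HeterogeneityResult(Q=Q, df=df, I2_pct=I2, flagged_groups=flagged or None)


def top_vs_last_table(
    ranked: pd.DataFrame, *, top: int = 1, outcome_col: str = "outcome"
) -> tuple[int, int, int, int]:
    """Build the 2x2 table comparing the top-k vs last-k ranked embryos.

    For each patient the ``top`` highest-beta1 embryos form the exposed
    group and the ``top`` lowest-beta1 embryos the unexposed group
    (patients with fewer than ``2 * top`` embryos are skipped to keep the
    groups disjoint).  Returns ``(a, b, c, d)`` suitable for
    :func:`odds_ratio_woolf`.
    """
    a = b = c = d = 0
    for _, grp in ranked.groupby("patient_id"):
        if len(grp) < 2 * top:
            continue
        srt = grp.sort_values("rank")
        head = srt.head(top)
        tail = srt.tail(top)
        a += int(head[outcome_col].astype(bool).sum())
        b += top - int(head[outcome_col].astype(bool).sum())
        c += int(tail[outcome_col].astype(bool).sum())
        d += top - int(tail[outcome_col].astype(bool).sum())
    return a, b, c, d
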