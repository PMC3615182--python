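"""Longitudinal statistics: annual rates of change, scan comparisons,
FDR screening, and polynomial aging trajectories with AIC selection.

The unit of observation is the age group (overlapping boxcar windows), so the
per-group values entering the paired t-test and the trajectory regressions
are statistically dependent; they are treated as observations all the same,
and the dependence is documented in the run metadata rather than corrected.

Trajectory models of an annual rate of change against mean baseline age:

* Model I    ARC = mean + a1*Age + e                (linear)
* Model II   ARC = mean + a1*Age + a2*Age^2 + e     (quadratic)
* Model III  ARC = mean + a1*Age + a2*Age^2 + a3*Age^3 + e  (cubic)

Each is an OLS fit; the overall F statistic tests the model against the
intercept-only model.  The best model minimizes AIC = n*ln(RSS/n) + 2k with
k coefficients including the intercept (RSS floored at 1e-12 so exact fits
stay finite).  When the quadratic model is selected, the trajectory's peak
age is the vertex ``-a1 / (2*a2)`` regardless of curvature sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .grouping import correct_rgmv
from .metrics import DEFAULT_COST_GRID, summary_metric_from_correlation
from .network import correlation_matrix

logger = logging.getLogger(__name__)

RSS_FLOOR = 1e-12
MODEL_DEGREES = {"I": 1, "II": 2, "III": 3}


def annual_rate_of_change(x1, x2, age1, age2):
    """``(x2 - x1) / (age2 - age1)``: change per year between the two scans."""
    x1, x2 = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    age1, age2 = np.asarray(age1, dtype=float), np.asarray(age2, dtype=float)
    if not (age2 > age1).all():
        raise ValueError("age2 must exceed age1 for every observation")
    out = (x2 - x1) / (age2 - age1)
    return float(out) if out.ndim == 0 else out


def paired_t(xs, ys) -> tuple[float, float]:
    """Paired t on ``ys - xs`` (scan2 minus scan1), two-tailed, df = n - 1.

    Positive t means the second scan is larger.  All-zero differences return
    (0, 1) by convention (logged).
    """
    xs, ys = np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 3:
        raise ValueError("paired_t needs two equal-length vectors of length >= 3")
    diffs = ys - xs
    if np.all(diffs == 0):
        logger.info("paired_t: all differences zero; returning t=0, p=1")
        return 0.0, 1.0
    res = sps.ttest_rel(ys, xs)
    return float(res.statistic), float(res.pvalue)


def fdr_correct(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def peak_age(a1: float, a2: float) -> float:
    """Vertex ``-a1/(2*a2)`` of a quadratic trajectory (either curvature sign)."""
    if a2 == 0:
        raise ValueError("a2 = 0: quadratic vertex undefined")
    return -a1 / (2.0 * a2)


@dataclass
class ModelFit:
    name: str
    coef: np.ndarray  # intercept first, then ascending powers of age
    rss: float
    fvalue: float
    pvalue: float
    aic: float


@dataclass
class TrajectoryFit:
    metric: str
    models: dict[str, ModelFit]
    selected_model: str
    peak_age: float | None = None

    @property
    def selected(self) -> ModelFit:
        return self.models[self.selected_model]


def fit_trajectory(arc, age1, metric: str = "") -> TrajectoryFit:
    """Fit Models I-III of an annual rate of change on baseline age, pick by AIC."""
    y = np.asarray(arc, dtype=float)
    age = np.asarray(age1, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError(f"need >= 5 observations to fit up to a cubic, got {n}")
    tss = float(((y - y.mean()) ** 2).sum())
    models: dict[str, ModelFit] = {}
    for name, deg in MODEL_DEGREES.items():
        X = np.vander(age, deg + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        df_num, df_den = deg, n - deg - 1
        if rss <= RSS_FLOOR or tss <= RSS_FLOOR:
            fval, pval = float("inf"), 0.0
        else:
            fval = ((tss - rss) / df_num) / (rss / df_den)
            pval = float(sps.f.sf(fval, df_num, df_den))
        aic = n * np.log(max(rss, RSS_FLOOR) / n) + 2 * (deg + 1)
        models[name] = ModelFit(
            name=name, coef=beta, rss=rss, fvalue=float(fval), pvalue=pval, aic=float(aic)
        )
    selected = min(models, key=lambda m: models[m].aic)
    peak = None
    if selected == "II" and models["II"].coef[2] != 0:
        peak = peak_age(models["II"].coef[1], models["II"].coef[2])
    return TrajectoryFit(metric=metric, models=models, selected_model=selected, peak_age=peak)


# ---------------------------------------------------------------------------
# permutation inference on group scan pairs


@dataclass
class GroupScans:
    """Raw per-subject data of one age group at both scans (aligned rows)."""

    vol1: np.ndarray  # subjects x regions, baseline
    vol2: np.ndarray
    tgv1: np.ndarray
    tgv2: np.ndarray
    age1: np.ndarray
    age2: np.ndarray
    sex: np.ndarray  # {F: 0, M: 1}

    @classmethod
    def from_arrays(cls, arrays: dict[str, dict[str, np.ndarray]]) -> "GroupScans":
        b, f = arrays["baseline"], arrays["followup"]
        return cls(
            vol1=b["volumes"], vol2=f["volumes"], tgv1=b["total_gmv"], tgv2=f["total_gmv"],
            age1=b["age"], age2=f["age"], sex=b["sex"],
        )


def _scan_summary(vol, tgv, age, sex, metric, cost_grid) -> float:
    resid = correct_rgmv(vol, tgv, age, sex)
    r = correlation_matrix(resid)
    return summary_metric_from_correlation(r, metric, cost_grid)


@dataclass
class PermutationResult:
    delta_obs: float  # follow-up minus baseline summary metric
    p: float
    n_perm: int
    n_failed: int = 0


def permutation_test_scans(
    group: GroupScans,
    metric: str = "GE",
    cost_grid: np.ndarray = DEFAULT_COST_GRID,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> PermutationResult:
    """Two-tailed scan-label permutation test for one group's summary metric.

    The observed statistic is summary(follow-up) - summary(baseline).  Each
    permutation independently swaps every subject's baseline/follow-up rows
    (volumes and covariates) with probability 1/2 and re-runs residualization,
    correlation, thresholding and the summary metric; this respects the
    paired design.  ``p = (1 + #{|d*| >= |d_obs|}) / (1 + n_perm)``, with
    failed permutations excluded from the denominator (logged).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    s1 = _scan_summary(group.vol1, group.tgv1, group.age1, group.sex, metric, cost_grid)
    s2 = _scan_summary(group.vol2, group.tgv2, group.age2, group.sex, metric, cost_grid)
    delta_obs = s2 - s1
    n = group.vol1.shape[0]
    count = 0
    failed = 0
    for _ in range(n_perm):
        swap = rng.random(n) < 0.5
        v1 = np.where(swap[:, None], group.vol2, group.vol1)
        v2 = np.where(swap[:, None], group.vol1, group.vol2)
        t1 = np.where(swap, group.tgv2, group.tgv1)
        t2 = np.where(swap, group.tgv1, group.tgv2)
        a1 = np.where(swap, group.age2, group.age1)
        a2 = np.where(swap, group.age1, group.age2)
        try:
            d = (
                _scan_summary(v2, t2, a2, group.sex, metric, cost_grid)
                - _scan_summary(v1, t1, a1, group.sex, metric, cost_grid)
            )
        except ValueError:
            failed += 1
            logger.warning("permutation failed and was excluded", exc_info=True)
            continue
        if abs(d) >= abs(delta_obs) - 1e-15:
            count += 1
    effective = n_perm - failed
    p = (1 + count) / (1 + effective) if effective > 0 else 1.0
    return PermutationResult(delta_obs=float(delta_obs), p=float(p), n_perm=n_perm,
                             n_failed=failed)


# ---------------------------------------------------------------------------
# regional screen


SHAPE_NEGATIVE_LINEAR = "negative-linear"
SHAPE_POSITIVE_QUADRATIC = "positive-quadratic"
SHAPE_OTHER = "other"


def _shape_label(fit: TrajectoryFit, alpha: float) -> str:
    sel = fit.selected
    if fit.selected_model == "I" and sel.coef[1] < 0 and sel.pvalue < alpha:
        return SHAPE_NEGATIVE_LINEAR
    if fit.selected_model == "II" and sel.coef[2] < 0 and sel.pvalue < alpha:
        # inverted-U: the vertex is a maximum of ARC over the age range
        return SHAPE_POSITIVE_QUADRATIC
    return SHAPE_OTHER


@dataclass
class RegionalScreen:
    table: pd.DataFrame  # region, t, p, significant, shape, selected_model, ...
    fits: dict[str, TrajectoryFit] = field(default_factory=dict)


def regional_screen(
    ns1: np.ndarray,
    ns2: np.ndarray,
    age1: np.ndarray,
    age2: np.ndarray,
    labels: list[str],
    q: float = 0.05,
    alpha: float = 0.05,
) -> RegionalScreen:
    """Screen regions for longitudinal node-strength change and fit trajectories.

    ``ns1``/``ns2`` are groups x regions summary node strengths at baseline
    and follow-up; ``age1``/``age2`` the per-group mean ages.  Per region: a
    paired t-test over groups, then BH-FDR at level ``q``; surviving regions
    get an AIC-selected trajectory fit of ARC_NS on baseline age and a shape
    label (negative-linear / positive-quadratic / other).
    """
    ns1, ns2 = np.asarray(ns1, dtype=float), np.asarray(ns2, dtype=float)
    if ns1.shape != ns2.shape or ns1.shape[1] != len(labels):
        raise ValueError("ns1/ns2 must be aligned groups x regions tables")
    tstats, pvals = zip(*(paired_t(ns1[:, j], ns2[:, j]) for j in range(len(labels))))
    flags = fdr_correct(np.asarray(pvals), q=q)
    arc = annual_rate_of_change(ns1, ns2, age1[:, None], age2[:, None])
    fits: dict[str, TrajectoryFit] = {}
    rows = []
    for j, label in enumerate(labels):
        row = {
            "region": label,
            "t": tstats[j],
            "p": pvals[j],
            "significant_fdr": bool(flags[j]),
            "shape": "",
            "selected_model": "",
            "model_F": np.nan,
            "model_p": np.nan,
            "peak_age": np.nan,
        }
        if flags[j]:
            fit = fit_trajectory(arc[:, j], age1, metric=f"ARC_NS[{label}]")
            fits[label] = fit
            row.update(
                shape=_shape_label(fit, alpha),
                selected_model=fit.selected_model,
                model_F=fit.selected.fvalue,
                model_p=fit.selected.pvalue,
                peak_age=fit.peak_age if fit.peak_age is not None else np.nan,
            )
        rows.append(row)
    return RegionalScreen(table=pd.DataFrame(rows), fits=fits)
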