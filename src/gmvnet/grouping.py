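"""Sliding-boxcar age grouping and per-group confound residualization.

Subjects are sorted by baseline age and grouped by an overlapping fixed-width
window (e.g. 380 subjects, window 100, step 10 -> 29 groups: 1-100, 11-110,
..., 281-380).  Follow-up groups reuse the baseline membership.  Within each
group and scan, every regional volume is residualized by ordinary least
squares against total gray matter volume, age, sex and the age-by-sex
interaction; the residuals (cRGMV) feed the correlation networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import cohort_region_columns

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("intercept", "total_gmv", "age", "sex", "age_sex")


def boxcar_groups(n_subjects: int, window: int, step: int = 10) -> list[range]:
    """0-based index windows over age-sorted subjects.

    Group ``k`` (1-based) covers indices ``[step*(k-1), step*(k-1)+window)``;
    groups are emitted while the window fits entirely, i.e.
    ``floor((n_subjects - window)/step) + 1`` of them.
    """
    if window < 1:
        raise ValueError(f"window must be positive, got {window}")
    if step < 1:
        raise ValueError(f"step must be positive, got {step}")
    if window > n_subjects:
        raise ValueError(f"window ({window}) exceeds n_subjects ({n_subjects})")
    n_groups = (n_subjects - window) // step + 1
    return [range(k * step, k * step + window) for k in range(n_groups)]


@dataclass
class AgeGroup:
    """One boxcar window: ordered member ids and mean ages at both scans."""

    index: int  # 1-based
    member_ids: list[str]
    mean_age_baseline: float
    mean_age_followup: float

    def __post_init__(self):
        if not self.mean_age_followup > self.mean_age_baseline:
            raise ValueError(
                f"group {self.index}: mean follow-up age must exceed baseline "
                f"({self.mean_age_followup} <= {self.mean_age_baseline})"
            )


def make_age_groups(cohort: pd.DataFrame, window: int = 100, step: int = 10) -> list[AgeGroup]:
    """Boxcar groups over baseline-age-sorted subjects (age ties by subject_id)."""
    base = cohort[cohort["scan"] == "baseline"].sort_values(
        ["age", "subject_id"], kind="mergesort"
    )
    follow_age = (
        cohort[cohort["scan"] == "followup"].set_index("subject_id")["age"]
    )
    groups = []
    for k, window_idx in enumerate(boxcar_groups(len(base), window, step), start=1):
        members = base["subject_id"].iloc[list(window_idx)].tolist()
        groups.append(
            AgeGroup(
                index=k,
                member_ids=members,
                mean_age_baseline=float(base["age"].iloc[list(window_idx)].mean()),
                mean_age_followup=float(follow_age.loc[members].mean()),
            )
        )
    return groups


def correct_rgmv(
    volumes: np.ndarray,
    total_gmv: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> np.ndarray:
    """Residualize regional volumes against [1, total_gmv, age, sex, age*sex].

    ``sex`` is coded {F: 0, M: 1}.  A rank-deficient design (e.g. a single-sex
    group) drops the collinear columns with a logged warning.  Returns the
    residual matrix (same shape as ``volumes``); residuals are orthogonal to
    every retained design column and have zero column means.
    """
    V = np.asarray(volumes, dtype=float)
    n = V.shape[0]
    if n < 6:
        raise ValueError(f"need at least 6 subjects for the 5-column design, got {n}")
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    X = np.column_stack(
        [np.ones(n), np.asarray(total_gmv, dtype=float), age, sex, age * sex]
    )
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    if len(keep) < X.shape[1]:
        dropped = [DESIGN_COLUMNS[j] for j in range(X.shape[1]) if j not in keep]
        logger.warning("rank-deficient confound design; dropped columns: %s", dropped)
    Xk = X[:, keep]
    beta, *_ = np.linalg.lstsq(Xk, V, rcond=None)
    return V - Xk @ beta


def group_scan_arrays(cohort: pd.DataFrame, group: AgeGroup) -> dict[str, dict[str, np.ndarray]]:
    """Per-scan raw arrays for one group, rows ordered as ``group.member_ids``."""
    region_cols = cohort_region_columns(cohort)
    out: dict[str, dict[str, np.ndarray]] = {}
    for scan in ("baseline", "followup"):
        sub = (
            cohort[cohort["scan"] == scan]
            .set_index("subject_id")
            .loc[group.member_ids]
        )
        out[scan] = {
            "volumes": sub[region_cols].to_numpy(dtype=float),
            "total_gmv": sub["total_gmv"].to_numpy(dtype=float),
            "age": sub["age"].to_numpy(dtype=float),
            "sex": (sub["sex"] == "M").to_numpy(dtype=float),
        }
    return out


def corrected_group(cohort: pd.DataFrame, group: AgeGroup) -> dict[str, np.ndarray]:
    """cRGMV matrices (subjects x regions) for both scans of one group."""
    arrays = group_scan_arrays(cohort, group)
    return {
        scan: correct_rgmv(d["volumes"], d["total_gmv"], d["age"], d["sex"])
        for scan, d in arrays.items()
    }


def write_groups_manifest(groups: list[AgeGroup], path, step: int = 10) -> None:
    """TSV manifest: index range, mean ages and member ids per group."""
    rows = []
    for g in groups:
        first = (g.index - 1) * step + 1
        rows.append(
            {
                "group_index": g.index,
                "first_index": first,
                "last_index": first + len(g.member_ids) - 1,
                "mean_age_baseline": g.mean_age_baseline,
                "mean_age_followup": g.mean_age_followup,
                "member_subject_ids": ";".join(g.member_ids),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
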