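"""Synthetic two-timepoint cohorts of regional gray matter volumes.

The original cohort (380 community-dwelling adults scanned twice ~7.4 years
apart) is not publicly deposited, so every downstream stage is exercised on
synthetic cohorts with known ground truth.  A cohort is a long-format table:
two rows per subject (baseline and follow-up scan), with demographics, total
gray matter volume and 90 regional volumes.

Generative model (per subject, volumes in cm^3):

* baseline age ~ truncated Normal(mean, sd) within ``age_range``
  (reject-and-resample), follow-up age = baseline + Normal interval;
* each region's structural component is a unit-variance latent
  ``a*F_block + b*H_pair + c*eps`` where ``F`` is a shared per-block factor,
  ``H`` a shared factor per homotopic (left/right) pair and ``eps`` region
  noise, with ``a = sqrt(r_block)``, ``a^2 + b^2 = homotopic_r``; this gives
  closed-form control of the inter-region correlations the pipeline must
  recover;
* additive confounds: a global size factor (reflected in total gray matter
  volume), age, sex, and age-by-sex terms;
* longitudinal change between scans through two channels: a per-region
  volume drift ``(lin*(age-c) + quad*(age-c)^2) * interval`` and, optionally,
  a per-region modulation of the shared-factor loadings at follow-up
  (``strength_trajectory``), which plants signed, age-dependent changes in a
  region's covariance with the rest of the network (and hence in its node
  strength);
* independent per-scan measurement noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import homotopic_pairs, lobe_blocks, region_labels

logger = logging.getLogger(__name__)

META_COLUMNS = ["subject_id", "sex", "scan", "age", "total_gmv"]
SCANS = ("baseline", "followup")

#: baseline-cohort statistics of the study this generator emulates
STUDY_N_SUBJECTS = 380
STUDY_AGE_RANGE = (21.0, 80.0)
STUDY_AGE_MEAN_SD = (51.1, 11.7)
STUDY_INTERVAL_MEAN_SD = (7.41, 0.54)
STUDY_FRACTION_MALE = 157 / 380


def default_block_structure(n_regions: int = 90) -> list[tuple[list[int], float]]:
    """Within-lobe covariance blocks (r = 0.3); single block for toy parcellations."""
    if n_regions == 90:
        return [(idx, 0.3) for idx in lobe_blocks(90).values()]
    return [(list(range(n_regions)), 0.3)]


@dataclass
class CohortSpec:
    """Ground-truth parameters of a synthetic cohort.

    ``confound_betas`` maps ``total_volume`` (loading of a shared N(0,1) size
    factor), ``age``, ``sex`` and ``age_sex`` to per-region coefficients
    (scalar or length-``n_regions``); age enters centered at
    ``trajectory_center`` years.  ``trajectory_coeffs`` is an
    ``(n_regions, 2)`` array of (linear, quadratic) annual volume-change
    coefficients in the centered baseline age; ``strength_trajectory`` is an
    ``(n_regions, 3)`` array of (d0, d1, d2) annual loading-modulation
    coefficients.  Both default to zero (no true longitudinal change).
    """

    n_subjects: int = STUDY_N_SUBJECTS
    n_regions: int = 90
    age_range: tuple[float, float] = STUDY_AGE_RANGE
    age_mean_sd: tuple[float, float] = STUDY_AGE_MEAN_SD
    interval_mean_sd: tuple[float, float] = STUDY_INTERVAL_MEAN_SD
    sex_fraction_male: float = STUDY_FRACTION_MALE
    block_structure: list[tuple[list[int], float]] | None = None
    homotopic_r: float = 0.65
    confound_betas: dict = field(
        default_factory=lambda: {
            "total_volume": 0.5,
            "age": -0.015,
            "sex": 0.3,
            "age_sex": -0.004,
        }
    )
    trajectory_coeffs: np.ndarray | None = None
    strength_trajectory: np.ndarray | None = None
    trajectory_center: float = 50.0
    region_mean: float = 10.0
    latent_sd: float = 1.0
    noise_sd: float = 0.25
    seed: int = 0

    def resolved_blocks(self) -> list[tuple[list[int], float]]:
        if self.block_structure is None:
            return default_block_structure(self.n_regions)
        return [(list(idx), float(r)) for idx, r in self.block_structure]

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        if self.n_regions % 2 != 0 or self.n_regions < 2:
            raise ValueError(
                f"n_regions must be even and >= 2 (paired hemispheres), got {self.n_regions}"
            )
        lo, hi = self.age_range
        if not (0 <= lo < hi <= 120):
            raise ValueError(f"age_range must be within [0, 120] and increasing, got {self.age_range}")
        if self.age_mean_sd[1] <= 0:
            raise ValueError("age_mean_sd: SD must be positive")
        if self.interval_mean_sd[0] <= 0 or self.interval_mean_sd[1] <= 0:
            raise ValueError("interval_mean_sd: mean and SD must be positive")
        if not 0 <= self.sex_fraction_male <= 1:
            raise ValueError(f"sex_fraction_male must be in [0, 1], got {self.sex_fraction_male}")
        if not 0 <= self.homotopic_r <= 1:
            raise ValueError(f"homotopic_r must be in [0, 1], got {self.homotopic_r}")
        for idx, r in self.resolved_blocks():
            if not 0 <= r <= 1:
                raise ValueError(f"block_structure: correlation {r} outside [0, 1]")
            if r > self.homotopic_r:
                raise ValueError(
                    "block_structure: within-block correlation must not exceed homotopic_r "
                    f"({r} > {self.homotopic_r})"
                )
            if any(not 0 <= j < self.n_regions for j in idx):
                raise ValueError("block_structure: region index out of range")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.latent_sd <= 0:
            raise ValueError(f"latent_sd must be positive, got {self.latent_sd}")
        for name, arr, width in (
            ("trajectory_coeffs", self.trajectory_coeffs, 2),
            ("strength_trajectory", self.strength_trajectory, 3),
        ):
            if arr is not None and np.asarray(arr).shape != (self.n_regions, width):
                raise ValueError(f"{name} must have shape ({self.n_regions}, {width})")


def _per_region(value, n_regions: int) -> np.ndarray:
    return np.broadcast_to(np.asarray(value, dtype=float), (n_regions,)).copy()


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Reject-and-resample truncated normal (honors mean/SD and hard range)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        good = draw[(draw >= lo) & (draw <= hi)]
        take = min(good.size, size - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a two-scan cohort table; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, R = spec.n_subjects, spec.n_regions
    labels = region_labels(R)
    pairs = homotopic_pairs(R)
    blocks = spec.resolved_blocks()

    age1 = _truncated_normal(
        rng, spec.age_mean_sd[0], spec.age_mean_sd[1], *spec.age_range, size=n
    )
    interval = rng.normal(*spec.interval_mean_sd, size=n)
    while (interval <= 0).any():  # pathological only for extreme specs
        bad = interval <= 0
        interval[bad] = rng.normal(*spec.interval_mean_sd, size=int(bad.sum()))
    age2 = age1 + interval
    sex = (rng.random(n) < spec.sex_fraction_male).astype(float)  # M=1, F=0

    # factor loadings: a^2 = block r, a^2 + b^2 = homotopic r, a^2+b^2+c^2 = 1
    a = np.zeros(R)
    block_of = np.full(R, -1)
    for bi, (idx, r) in enumerate(blocks):
        a[idx] = np.sqrt(r)
        block_of[idx] = bi
    b2 = spec.homotopic_r - a**2
    b = np.sqrt(np.clip(b2, 0.0, None))
    c = np.sqrt(np.clip(1.0 - a**2 - b**2, 0.0, None))
    pair_of = np.empty(R, dtype=int)
    for p, (l, r_) in enumerate(pairs):
        pair_of[l] = pair_of[r_] = p

    F = rng.standard_normal((n, len(blocks))) if blocks else np.zeros((n, 1))
    H = rng.standard_normal((n, len(pairs)))
    eps = rng.standard_normal((n, R))
    size_factor = rng.standard_normal(n)

    Fr = F[:, np.clip(block_of, 0, None)] * (block_of >= 0)
    shared = a * Fr + b * H[:, pair_of]
    latent1 = shared + c * eps

    x1 = age1 - spec.trajectory_center
    x2 = age2 - spec.trajectory_center

    # follow-up loading modulation (connectivity trajectory)
    if spec.strength_trajectory is not None:
        d = np.asarray(spec.strength_trajectory, dtype=float)
        g = (d[:, 0] + np.outer(x1, d[:, 1]) + np.outer(x1**2, d[:, 2])) * interval[:, None]
        m = np.clip(1.0 + g, 0.05, None)
    else:
        m = np.ones((n, R))
    z = np.sqrt(m**2 * (a**2 + b**2) + c**2)
    latent2 = (m * shared + c * eps) / z

    betas = spec.confound_betas
    bt = _per_region(betas.get("total_volume", 0.0), R)
    ba = _per_region(betas.get("age", 0.0), R)
    bs = _per_region(betas.get("sex", 0.0), R)
    bas = _per_region(betas.get("age_sex", 0.0), R)

    def confounds(x):
        return (
            np.outer(size_factor, bt)
            + np.outer(x, ba)
            + np.outer(sex, bs)
            + np.outer(x * sex, bas)
        )

    if spec.trajectory_coeffs is not None:
        tc = np.asarray(spec.trajectory_coeffs, dtype=float)
        drift = (np.outer(x1, tc[:, 0]) + np.outer(x1**2, tc[:, 1])) * interval[:, None]
    else:
        drift = 0.0

    vol1 = (
        spec.region_mean
        + spec.latent_sd * latent1
        + confounds(x1)
        + rng.normal(0.0, spec.noise_sd, (n, R))
    )
    vol2 = (
        spec.region_mean
        + spec.latent_sd * latent2
        + confounds(x2)
        + drift
        + rng.normal(0.0, spec.noise_sd, (n, R))
    )
    for name, v in (("baseline", vol1), ("followup", vol2)):
        if (v <= 0).any():
            logger.warning(
                "%d non-positive %s volumes clipped to 1e-3; consider a larger region_mean",
                int((v <= 0).sum()), name,
            )
            np.clip(v, 1e-3, None, out=v)

    width = len(str(n))
    ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    rows = []
    for scan, vol, age in (("baseline", vol1, age1), ("followup", vol2, age2)):
        df = pd.DataFrame(vol, columns=labels)
        df.insert(0, "total_gmv", vol.sum(axis=1))
        df.insert(0, "age", age)
        df.insert(0, "scan", scan)
        df.insert(0, "sex", np.where(sex > 0.5, "M", "F"))
        df.insert(0, "subject_id", ids)
        rows.append(df)
    table = (
        pd.concat(rows)
        .sort_values(["subject_id", "scan"], kind="mergesort")
        .reset_index(drop=True)
    )
    return table


def study_spec(**overrides) -> CohortSpec:
    """A :class:`CohortSpec` at the emulated study's stated cohort statistics."""
    return CohortSpec(**overrides)


def cohort_region_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort CSV (header row, UTF-8, '.' decimal)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path, n_regions: int | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises ``ValueError`` on malformed input.

    Error messages name the offending column or cite the 1-based data row.
    """
    table = pd.read_csv(path, encoding="utf-8")
    if n_regions is None:
        n_regions = len([c for c in table.columns if c not in META_COLUMNS])
        if n_regions % 2 != 0 or n_regions == 0:
            n_regions = 90
    expected = META_COLUMNS + region_labels(n_regions)
    for col in expected:
        if col not in table.columns:
            raise ValueError(f"cohort file {path}: missing column {col!r}")
    table = table[expected]
    vols = table[region_labels(n_regions)].to_numpy()
    bad = np.where(~(vols > 0) | ~np.isfinite(vols))
    if bad[0].size:
        row = int(bad[0][0])
        raise ValueError(
            f"cohort file {path}: non-positive volume in data row {row + 1} "
            f"(column {region_labels(n_regions)[int(bad[1][0])]!r})"
        )
    counts = table.groupby("subject_id")["scan"].agg(list)
    for sid, scans in counts.items():
        if sorted(scans) != ["baseline", "followup"]:
            raise ValueError(
                f"cohort file {path}: subject {sid} must have exactly one baseline "
                f"and one followup row, got {scans}"
            )
    piv = table.pivot(index="subject_id", columns="scan", values="age")
    if not (piv["followup"] > piv["baseline"]).all():
        sid = piv.index[~(piv["followup"] > piv["baseline"])][0]
        raise ValueError(f"cohort file {path}: follow-up age not greater than baseline for {sid}")
    return table
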