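"""End-to-end orchestration: simulate/load -> group -> correct -> correlate ->
threshold -> metrics -> nulls -> longitudinal statistics.

A run is driven by a :class:`RunConfig` (YAML-serializable flat key-value
config).  The global seed fans out deterministically to per-stage child
seeds, so stages rerun in isolation reproduce the full run's results, and a
rerun with the same config and seed is bit-identical for every output table.

Defaults follow the emulated study's settings (window 100, step 10, costs
0.11..0.25 step 0.01, 1000 nulls, 1000 permutations, FDR q = 0.05); at those
settings the null-model and permutation stages are compute-intensive, so
both have switches and counts in the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, cohort_region_columns, generate_cohort, read_cohort, write_cohort
from .grouping import AgeGroup, corrected_group, group_scan_arrays, make_age_groups, write_groups_manifest
from .metrics import profile_from_correlation
from .network import correlation_matrix, edge_table, n_edges_at_cost, threshold_by_cost
from .nulls import null_ensemble, small_world_assessment
from .stats import (
    GroupScans,
    annual_rate_of_change,
    fit_trajectory,
    paired_t,
    permutation_test_scans,
    regional_screen,
)

logger = logging.getLogger(__name__)

ASSUMPTIONS = [
    "residualization is per scan, with scan-specific total gray matter volume and age",
    "edge count at cost t is round(t*N(N-1)/2); |r| ties broken by (i, j) order",
    "AIC = n*ln(RSS/n) + 2k, no small-sample correction",
    "permutation scheme: within-subject scan-label swapping (paired design)",
    "overlapping boxcar groups are treated as observations in t-tests and regressions; "
    "their dependence is documented, not corrected",
]


@dataclass
class RunConfig:
    """Flat run configuration; ``cohort`` holds CohortSpec overrides."""

    input_path: str | None = None
    cohort: dict = field(default_factory=dict)
    window: int = 100
    step: int = 10
    cost_min: float = 0.11
    cost_max: float = 0.25
    cost_step: float = 0.01
    n_null: int = 1000
    n_perm: int = 1000
    fdr_q: float = 0.05
    seed: int = 0
    outdir: str = "gmvnet_results"
    run_nulls: bool = True
    run_permutation: bool = True

    def __post_init__(self):
        for name in ("window", "step", "n_null", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 < self.fdr_q < 1:
            raise ValueError(f"fdr_q must be in (0, 1), got {self.fdr_q}")
        if not 0 < self.cost_min <= self.cost_max < 1 or self.cost_step <= 0:
            raise ValueError("cost grid must satisfy 0 < cost_min <= cost_max < 1, cost_step > 0")

    @property
    def cost_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.cost_min, self.cost_max + self.cost_step / 2, self.cost_step), 10
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


class PipelineRun:
    """Lazy, stage-cached pipeline over one cohort."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.seeds = dict(
            zip(["cohort", "nulls", "permutation"], _child_seeds(config.seed, 3))
        )
        self._cohort: pd.DataFrame | None = None
        self._groups: list[AgeGroup] | None = None
        self._profiles: dict | None = None

    # -- stages -------------------------------------------------------------

    @property
    def cohort(self) -> pd.DataFrame:
        if self._cohort is None:
            cfg = self.config
            if cfg.input_path:
                self._cohort = read_cohort(cfg.input_path)
            else:
                spec = CohortSpec(**{"seed": self.seeds["cohort"], **cfg.cohort})
                self._cohort = generate_cohort(spec)
        return self._cohort

    @property
    def labels(self) -> list[str]:
        return cohort_region_columns(self.cohort)

    @property
    def groups(self) -> list[AgeGroup]:
        if self._groups is None:
            self._groups = make_age_groups(self.cohort, self.config.window, self.config.step)
        return self._groups

    def corrected(self, group: AgeGroup) -> dict[str, np.ndarray]:
        return corrected_group(self.cohort, group)

    @property
    def profiles(self) -> dict[tuple[int, str], "object"]:
        """(group_index, scan) -> MetricProfile over the cost grid."""
        if self._profiles is None:
            grid = self.config.cost_grid
            self._profiles = {}
            for g in self.groups:
                resid = self.corrected(g)
                for scan, mat in resid.items():
                    r = correlation_matrix(mat, labels=self.labels)
                    self._profiles[(g.index, scan)] = profile_from_correlation(
                        r, grid, labels=self.labels, group_index=g.index, scan=scan
                    )
        return self._profiles

    # -- writers ------------------------------------------------------------

    def write_cohort(self) -> Path:
        path = self.outdir / "cohort.csv"
        self.outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(self.cohort, path)
        return path

    def write_groups(self) -> Path:
        path = self.outdir / "groups.tsv"
        self.outdir.mkdir(parents=True, exist_ok=True)
        write_groups_manifest(self.groups, path, step=self.config.step)
        return path

    def write_networks(self) -> Path:
        """Edge lists at the maximal grid cost, annotated with each edge's
        smallest grid cost (thresholds are nested)."""
        edges_dir = self.outdir / "edges"
        edges_dir.mkdir(parents=True, exist_ok=True)
        grid = self.config.cost_grid
        n = len(self.labels)
        for g in self.groups:
            resid = self.corrected(g)
            for scan, mat in resid.items():
                r = correlation_matrix(mat, labels=self.labels)
                net = threshold_by_cost(r, float(grid[-1]), labels=self.labels)
                iu, ju = np.nonzero(np.triu(net.adjacency, k=1))
                w = net.adjacency[iu, ju]
                rank = (-w).argsort(kind="stable").argsort()  # 0 = strongest kept edge
                ks = np.array([n_edges_at_cost(n, t) for t in grid])
                min_cost = grid[np.searchsorted(ks, rank + 1)]
                df = edge_table(net, min_costs=min_cost)
                df.to_csv(edges_dir / f"group{g.index:02d}_{scan}.tsv", sep="\t", index=False)
        return edges_dir

    def write_metrics(self) -> Path:
        path = self.outdir / "metrics.tsv"
        self.outdir.mkdir(parents=True, exist_ok=True)
        frames = [p.to_frame() for p in self.profiles.values()]
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
        return path

    def write_nulls(self) -> Path:
        """Small-world assessment per group/scan at each grid cost."""
        path = self.outdir / "nulls.tsv"
        self.outdir.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        rng = np.random.default_rng(self.seeds["nulls"])
        rows = []
        for g in self.groups:
            resid = self.corrected(g)
            for scan, mat in resid.items():
                r = correlation_matrix(mat, labels=self.labels)
                for t in cfg.cost_grid:
                    net = threshold_by_cost(r, float(t), labels=self.labels)
                    ens = null_ensemble(
                        net, n_null=cfg.n_null, rng=rng,
                        source_id=f"group{g.index}_{scan}_t{t}",
                    )
                    sw = small_world_assessment(net, ens)
                    rows.append(
                        {
                            "source_id": ens.source_id,
                            "n_null": ens.n_null,
                            "GE_real": sw.ge_ratio * ens.ge_mean,
                            "GE_null_mean": ens.ge_mean,
                            "GE_null_sd": ens.ge_sd,
                            "LE_real": sw.le_ratio * ens.le_mean,
                            "LE_null_mean": ens.le_mean,
                            "LE_null_sd": ens.le_sd,
                            "GE_ratio": sw.ge_ratio,
                            "LE_ratio": sw.le_ratio,
                            "small_world": sw.is_small_world,
                        }
                    )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    def write_stats(self) -> list[Path]:
        cfg = self.config
        self.outdir.mkdir(parents=True, exist_ok=True)
        prof = self.profiles
        groups = self.groups
        age1 = np.array([g.mean_age_baseline for g in groups])
        age2 = np.array([g.mean_age_followup for g in groups])
        ge1 = np.array([prof[(g.index, "baseline")].summary_ge for g in groups])
        ge2 = np.array([prof[(g.index, "followup")].summary_ge for g in groups])
        le1 = np.array([prof[(g.index, "baseline")].summary_le for g in groups])
        le2 = np.array([prof[(g.index, "followup")].summary_le for g in groups])

        arc = pd.DataFrame(
            {
                "group_index": [g.index for g in groups],
                "Age_1": age1,
                "Age_2": age2,
                "ARC_GE": annual_rate_of_change(ge1, ge2, age1, age2),
                "ARC_LE": annual_rate_of_change(le1, le2, age1, age2),
            }
        )
        if cfg.run_permutation:
            rng = np.random.default_rng(self.seeds["permutation"])
            for metric, col in (("GE", "perm_p_GE"), ("LE", "perm_p_LE")):
                ps = []
                for g in groups:
                    gs = GroupScans.from_arrays(group_scan_arrays(self.cohort, g))
                    res = permutation_test_scans(
                        gs, metric=metric, cost_grid=cfg.cost_grid,
                        n_perm=cfg.n_perm, rng=rng,
                    )
                    ps.append(res.p)
                arc[col] = ps
        arc_path = self.outdir / "global_arc.tsv"
        arc.to_csv(arc_path, sep="\t", index=False)

        # paired t across groups + trajectory fits for the global metrics
        fit_rows = []
        test_rows = []
        for name, v1, v2 in (("GE", ge1, ge2), ("LE", le1, le2)):
            tval, pval = paired_t(v1, v2)
            test_rows.append({"metric": name, "paired_t": tval, "p": pval})
            fit = fit_trajectory(
                annual_rate_of_change(v1, v2, age1, age2), age1, metric=f"ARC_{name}"
            )
            for mf in fit.models.values():
                fit_rows.append(
                    {
                        "metric": f"ARC_{name}",
                        "model": mf.name,
                        "coefficients": ";".join(f"{c:.10g}" for c in mf.coef),
                        "F": mf.fvalue,
                        "p": mf.pvalue,
                        "AIC": mf.aic,
                        "selected": mf.name == fit.selected_model,
                        "peak_age": fit.peak_age
                        if (mf.name == "II" and fit.peak_age is not None)
                        else np.nan,
                    }
                )
        tests_path = self.outdir / "global_tests.tsv"
        pd.DataFrame(test_rows).to_csv(tests_path, sep="\t", index=False)

        ns1 = np.vstack([prof[(g.index, "baseline")].summary_ns for g in groups])
        ns2 = np.vstack([prof[(g.index, "followup")].summary_ns for g in groups])
        screen = regional_screen(ns1, ns2, age1, age2, self.labels, q=cfg.fdr_q)
        screen_path = self.outdir / "regional_screen.tsv"
        screen.table.to_csv(screen_path, sep="\t", index=False)
        for label, fit in screen.fits.items():
            for mf in fit.models.values():
                fit_rows.append(
                    {
                        "metric": f"ARC_NS[{label}]",
                        "model": mf.name,
                        "coefficients": ";".join(f"{c:.10g}" for c in mf.coef),
                        "F": mf.fvalue,
                        "p": mf.pvalue,
                        "AIC": mf.aic,
                        "selected": mf.name == fit.selected_model,
                        "peak_age": fit.peak_age
                        if (mf.name == "II" and fit.peak_age is not None)
                        else np.nan,
                    }
                )
        fits_path = self.outdir / "trajectory_fits.tsv"
        pd.DataFrame(fit_rows).to_csv(fits_path, sep="\t", index=False)
        return [arc_path, tests_path, fits_path, screen_path]

    def write_metadata(self) -> Path:
        path = self.outdir / "run_metadata.json"
        self.outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "gmvnet_version": __version__,
            "config": asdict(self.config),
            "stage_seeds": self.seeds,
            "n_groups": len(self.groups),
            "cost_grid": [float(t) for t in self.config.cost_grid],
            "assumptions": ASSUMPTIONS,
        }
        path.write_text(json.dumps(meta, indent=2), encoding="utf-8")
        return path


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run every stage and write the results bundle; returns output paths."""
    run = PipelineRun(config)
    _ = run.groups  # validate window/step against the cohort before any output
    logger.info("pipeline: %d subjects, %d groups", len(run.cohort) // 2, len(run.groups))
    outputs: dict[str, object] = {}
    if not config.input_path:
        outputs["cohort"] = run.write_cohort()
    outputs["groups"] = run.write_groups()
    outputs["edges"] = run.write_networks()
    outputs["metrics"] = run.write_metrics()
    if config.run_nulls:
        outputs["nulls"] = run.write_nulls()
    outputs["stats"] = run.write_stats()
    outputs["metadata"] = run.write_metadata()
    return outputs
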