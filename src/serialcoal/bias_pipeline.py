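"""Scenario grid: heterochronous vs isochronous sampling across demographies.

Drives the simulation study behind the heterochronous-sampling bias result:
for each (sampling scheme, Ne, growth rate) cell, many independent replicate
chains of genealogy → mutations → summary statistics → D/Fs → significance
are run, and replicate-level values are aggregated into a table of means,
empirical 95% intervals, and the percentage of replicates called
significantly negative/positive per tail.

Seed hierarchy: a master seed spawns one seed per scenario (by grid index),
each scenario seed spawns one seed per replicate (by replicate counter) via
``numpy.random.SeedSequence(entropy, spawn_key)``, so any single replicate
can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .neutrality import (
    NeutralityResult,
    fu_fs,
    null_distribution,
    significance,
    summarize_alignment,
    tajima_d,
)
from .sim_core import (
    Demography,
    MutationModel,
    SampleSchedule,
    simulate_alignment,
)

__all__ = ["Scenario", "ScenarioResult", "GridSpec", "run_scenario", "run_grid",
           "export_boxplot_data"]

HET = "HET"
IS = "IS"

REPLICATE_COLUMNS = [
    "replicate", "S", "pi", "k", "D", "Fs",
    "p_neg_D", "p_pos_D", "p_neg_Fs", "p_pos_Fs",
    "sig_neg_D", "sig_pos_D", "sig_neg_Fs", "sig_pos_Fs",
]


@dataclass(frozen=True)
class Scenario:
    """One grid cell: sampling scheme × demography × mutation model."""

    scheme: str
    demography: Demography
    schedule: SampleSchedule
    model: MutationModel = MutationModel()
    n_reps: int = 1000
    null_reps: int = 1000
    alpha_d: float = 0.05
    alpha_fs: float = 0.05
    seed: int = 0
    null_seed: int | None = None  # defaults to `seed`; run_grid shares one

    def __post_init__(self) -> None:
        if self.scheme not in (HET, IS):
            raise ValueError(f"scheme must be {HET!r} or {IS!r}")
        if self.scheme == IS and not self.schedule.is_isochronous:
            raise ValueError("IS scenarios need an isochronous schedule")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class ScenarioResult:
    """Replicate table plus the Table-style summaries for one scenario."""

    scenario: Scenario
    replicates: pd.DataFrame

    def _col(self, statistic: str) -> pd.Series:
        if statistic not in ("D", "Fs"):
            raise ValueError("statistic must be 'D' or 'Fs'")
        return self.replicates[statistic]

    def mean(self, statistic: str) -> float:
        return float(self._col(statistic).mean())

    def ci95(self, statistic: str) -> tuple[float, float]:
        v = self._col(statistic).to_numpy()
        return float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975))

    def pct_sig_neg(self, statistic: str) -> float:
        self._col(statistic)
        return 100.0 * float(self.replicates[f"sig_neg_{statistic}"].mean())

    def pct_sig_pos(self, statistic: str) -> float:
        self._col(statistic)
        return 100.0 * float(self.replicates[f"sig_pos_{statistic}"].mean())

    def summary_rows(self) -> pd.DataFrame:
        sc = self.scenario
        rows = []
        for stat in ("D", "Fs"):
            lo, hi = self.ci95(stat)
            rows.append({
                "scheme": sc.scheme, "Ne": sc.demography.N0, "g": sc.demography.g,
                "statistic": stat, "mean": self.mean(stat),
                "ci_low": lo, "ci_high": hi,
                "pct_sig_neg": self.pct_sig_neg(stat),
                "pct_sig_pos": self.pct_sig_pos(stat),
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GridSpec:
    """The full simulation grid (defaults mirror the 3 × 3 × 2 study design)."""

    Ne_values: tuple[float, ...] = (500.0, 2000.0, 10000.0)
    g_values: tuple[float, ...] = (0.0, 0.001, 0.01)
    schemes: tuple[str, ...] = (HET, IS)
    het_ages_bp: tuple[float, ...] | None = None  # None -> default fixture
    n_tips: int = 37
    generation_time: float = 7.0
    model: MutationModel = MutationModel()
    n_reps: int = 1000
    null_reps: int = 1000
    alpha_d: float = 0.05
    alpha_fs: float = 0.05
    master_seed: int = 0


def _child_seed(entropy: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from (entropy, counter key)."""
    ss = np.random.SeedSequence(entropy=int(entropy), spawn_key=tuple(key))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def run_replicate(scenario: Scenario, rep_index: int) -> dict:
    """One independent chain; reproducible in isolation from the scenario seed."""
    sim_seed = np.random.SeedSequence(entropy=int(scenario.seed), spawn_key=(rep_index,))
    aln = simulate_alignment(scenario.schedule, scenario.demography, scenario.model, sim_seed)
    summ = summarize_alignment(aln)
    d, d_def = tajima_d(summ)
    fs, fs_def = fu_fs(summ)
    res = NeutralityResult(D=d, Fs=fs, d_defined=d_def, fs_defined=fs_def)
    if summ.S > 0:
        nseed = scenario.null_seed if scenario.null_seed is not None else scenario.seed
        null = null_distribution(summ.n, summ.S, scenario.null_reps, nseed)
        res = significance(res, null, scenario.alpha_d, scenario.alpha_fs)
    return {
        "replicate": rep_index, "S": summ.S, "pi": summ.pi, "k": summ.k,
        "D": res.D, "Fs": res.Fs,
        "p_neg_D": res.p_neg_D, "p_pos_D": res.p_pos_D,
        "p_neg_Fs": res.p_neg_Fs, "p_pos_Fs": res.p_pos_Fs,
        "sig_neg_D": res.sig_neg_D, "sig_pos_D": res.sig_pos_D,
        "sig_neg_Fs": res.sig_neg_Fs, "sig_pos_Fs": res.sig_pos_Fs,
    }


def run_scenario(scenario: Scenario) -> ScenarioResult:
    """Run all replicates of one scenario and aggregate."""
    rows = [run_replicate(scenario, r) for r in range(scenario.n_reps)]
    df = pd.DataFrame(rows, columns=REPLICATE_COLUMNS)
    return ScenarioResult(scenario=scenario, replicates=df)


def scenarios_from_spec(spec: GridSpec) -> list[Scenario]:
    """Expand a grid spec into scenarios with derived per-scenario seeds."""
    ages = spec.het_ages_bp
    if ages is None:
        from .sim_core import default_het_ages

        ages = tuple(default_het_ages())
    if len(ages) != spec.n_tips:
        raise ValueError("het age fixture length must equal n_tips")
    het_sched = SampleSchedule(ages, spec.generation_time)
    iso_sched = SampleSchedule.isochronous(spec.n_tips, spec.generation_time)
    out = []
    idx = 0
    for scheme in spec.schemes:
        for ne in spec.Ne_values:
            for g in spec.g_values:
                out.append(Scenario(
                    scheme=scheme,
                    demography=Demography(N0=ne, g=g),
                    schedule=het_sched if scheme == HET else iso_sched,
                    model=spec.model,
                    n_reps=spec.n_reps,
                    null_reps=spec.null_reps,
                    alpha_d=spec.alpha_d,
                    alpha_fs=spec.alpha_fs,
                    seed=_child_seed(spec.master_seed, idx),
                    null_seed=int(spec.master_seed),
                ))
                idx += 1
    return out


def run_grid(spec: GridSpec, progress: bool = False):
    """Run the whole grid; returns (summary table, {key: ScenarioResult}).

    The summary table has one row per (scheme, Ne, g, statistic) in the
    layout of the published simulation table; nulls are memoized by (n, S)
    across scenarios so each distinct conditioning is simulated once.
    """
    results: dict[tuple, ScenarioResult] = {}
    tables = []
    for sc in scenarios_from_spec(spec):
        if progress:
            print(f"running {sc.scheme} Ne={sc.demography.N0:g} g={sc.demography.g:g} "
                  f"({sc.n_reps} reps)", flush=True)
        res = run_scenario(sc)
        results[(sc.scheme, sc.demography.N0, sc.demography.g)] = res
        tables.append(res.summary_rows())
    if not tables:
        summary = pd.DataFrame(
            columns=["scheme", "Ne", "g", "statistic", "mean", "ci_low", "ci_high",
                     "pct_sig_neg", "pct_sig_pos"])
    else:
        summary = pd.concat(tables, ignore_index=True)
    return summary, results


def export_boxplot_data(results: dict, statistic: str) -> pd.DataFrame:
    """Long-format per-replicate values for the constant-size (g = 0) cells.

    One row per replicate labeled by (scheme, Ne), with per-group median,
    quartiles, and 1.5-IQR whiskers attached — ready for box plotting.
    """
    if statistic not in ("D", "Fs"):
        raise ValueError("statistic must be 'D' or 'Fs'")
    frames = []
    for (scheme, ne, g), res in sorted(results.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        if g != 0:
            continue
        vals = res.replicates[statistic].to_numpy()
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_w = vals[vals >= q1 - 1.5 * iqr].min()
        hi_w = vals[vals <= q3 + 1.5 * iqr].max()
        frames.append(pd.DataFrame({
            "scheme": scheme, "Ne": ne, "replicate": res.replicates["replicate"],
            "value": vals, "median": med, "q1": q1, "q3": q3,
            "whisker_low": lo_w, "whisker_high": hi_w,
        }))
    if not frames:
        return pd.DataFrame(columns=["scheme", "Ne", "replicate", "value", "median",
                                     "q1", "q3", "whisker_low", "whisker_high"])
    return pd.concat(frames, ignore_index=True)
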