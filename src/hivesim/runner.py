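"""Scenario configuration, replicate execution and summary tables.

A scenario pairs a genetic parameter setup (direct/maternal variances,
their correlation, residual variance) with a selection strategy (mass or
within-maternal-line), a polyandry level nD, a number of 23-year
replicates and a master seed.  The runner executes replicates with
deterministically derived seeds, aggregates per-year statistics across
replicates (within-replicate means/variances first, then cross-replicate
means and standard deviations), standardizes performance by the analytic
initial phenotypic standard deviation and breeding values by their
initial genetic standard deviations, and writes CSV/JSON outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expectations import phenotypic_variance
from .genetics import GeneticSetup
from .scheme import YEARLY_FIELDS, ReplicateFailure, SchemeConfig, run_replicate

__all__ = [
    "SETUPS",
    "ScenarioSpec",
    "ScenarioResult",
    "preset",
    "paper_scenarios",
    "load_scenario",
    "run_scenario",
    "run_scenarios",
    "standardize",
    "final_table",
    "inbreeding_slope",
    "replicate_inbreeding_slopes",
    "write_outputs",
]

#: The four canonical genetic parameter setups (residual variance 30).
SETUPS: dict[int, GeneticSetup] = {
    1: GeneticSetup(var_dir=10, var_mat=10, corr_dir_mat=0.0, var_residual=30),
    2: GeneticSetup(var_dir=20, var_mat=10, corr_dir_mat=0.0, var_residual=30),
    3: GeneticSetup(var_dir=10, var_mat=10, corr_dir_mat=-0.5, var_residual=30),
    4: GeneticSetup(var_dir=20, var_mat=10, corr_dir_mat=-0.5, var_residual=30),
}

_STRATEGY_CODE = {"M": "mass", "L": "within_line"}


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully specified simulation scenario."""

    name: str
    setup: GeneticSetup
    strategy: str  # "mass" | "within_line" | "random"
    n_drones: int
    n_replicates: int = 160
    years: int = 23
    seed: int = 0
    scheme_overrides: Mapping[str, object] = field(default_factory=dict)

    def scheme_config(self) -> SchemeConfig:
        return SchemeConfig(
            n_drones_per_queen=self.n_drones,
            selection_strategy=self.strategy,
            total_years=self.years,
            **dict(self.scheme_overrides),
        )


def preset(name: str, n_replicates: int = 160, seed: int = 0) -> ScenarioSpec:
    """Named scenario like ``setup1-M-nD1`` or ``setup3-L-nD8``."""
    try:
        setup_part, strat_part, nd_part = name.split("-")
        setup_id = int(setup_part.removeprefix("setup"))
        strategy = _STRATEGY_CODE[strat_part]
        n_drones = int(nd_part.removeprefix("nD"))
        setup = SETUPS[setup_id]
    except (ValueError, KeyError) as exc:
        raise ValueError(f"unknown preset: {name!r}") from exc
    return ScenarioSpec(
        name=name, setup=setup, strategy=strategy, n_drones=n_drones,
        n_replicates=n_replicates, seed=seed,
    )


def paper_scenarios(n_replicates: int = 160, seed: int = 0) -> list[ScenarioSpec]:
    """The 18 studied scenarios: 4 setups x {M, L} x {1, 8} drones, plus
    setup 1 x {M, L} x 16 drones."""
    names = [
        f"setup{s}-{m}-nD{nd}" for s in (1, 2, 3, 4) for m in ("M", "L") for nd in (1, 8)
    ] + [f"setup1-{m}-nD16" for m in ("M", "L")]
    return [preset(n, n_replicates=n_replicates, seed=seed) for n in names]


def load_scenario(path: str | Path) -> ScenarioSpec:
    """Read a flat YAML/JSON scenario file.

    Recognized keys: ``name``, ``setup`` (an id 1-4 or a mapping with
    var_dir/var_mat/corr_dir_mat/var_residual), ``strategy`` (M/L or the
    long names), ``n_drones``, ``n_replicates``, ``years``, ``seed`` and
    any field of the breeding-scheme configuration.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    setup_val = raw.pop("setup", 1)
    if isinstance(setup_val, Mapping):
        setup = GeneticSetup(**setup_val)
    else:
        setup = SETUPS[int(setup_val)]
    strategy = raw.pop("strategy", "within_line")
    strategy = _STRATEGY_CODE.get(strategy, strategy)
    known = dict(
        name=raw.pop("name", Path(path).stem),
        setup=setup,
        strategy=strategy,
        n_drones=int(raw.pop("n_drones", 8)),
        n_replicates=int(raw.pop("n_replicates", 160)),
        years=int(raw.pop("years", 23)),
        seed=int(raw.pop("seed", 0)),
    )
    scheme_fields = set(SchemeConfig.__dataclass_fields__)
    overrides = {k: raw.pop(k) for k in list(raw) if k in scheme_fields}
    if raw:
        raise ValueError(f"unknown scenario keys: {sorted(raw)}")
    return ScenarioSpec(scheme_overrides=overrides, **known)


@dataclass
class ScenarioResult:
    """Per-replicate yearly series for one scenario."""

    spec: ScenarioSpec
    #: field -> array of shape (n_completed_replicates, years)
    per_replicate: dict[str, np.ndarray]
    n_failed: int = 0

    @property
    def years(self) -> np.ndarray:
        return np.arange(1, self.spec.years + 1)

    def summary(self) -> pd.DataFrame:
        """Cross-replicate mean and SD of every yearly statistic."""
        data: dict[str, np.ndarray] = {"year": self.years.astype(float)}
        for k in YEARLY_FIELDS:
            arr = self.per_replicate[k]
            data[f"{k}_mean"] = arr.mean(axis=0)
            data[f"{k}_sd"] = arr.std(axis=0, ddof=1)
        return pd.DataFrame(data)


def run_scenario(
    spec: ScenarioSpec,
    max_failure_rate: float = 0.05,
    progress: bool = False,
) -> ScenarioResult:
    """Run all replicates of a scenario with derived per-replicate seeds."""
    config = spec.scheme_config()
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    rows: list[dict[str, np.ndarray]] = []
    n_failed = 0
    max_failures = int(np.floor(max_failure_rate * spec.n_replicates))
    for i, child in enumerate(children):
        try:
            rows.append(run_replicate(spec.setup, config, np.random.default_rng(child)))
        except ReplicateFailure as exc:
            n_failed += 1
            warnings.warn(f"{spec.name}: replicate {i} failed: {exc}")
            if n_failed > max_failures:
                raise ReplicateFailure(
                    f"{spec.name}: {n_failed} of {i + 1} replicates failed"
                ) from exc
        if progress and (i + 1) % 10 == 0:
            print(f"{spec.name}: {i + 1}/{spec.n_replicates} replicates", flush=True)
    per_rep = {k: np.stack([r[k] for r in rows]) for k in YEARLY_FIELDS}
    return ScenarioResult(spec=spec, per_replicate=per_rep, n_failed=n_failed)


def run_scenarios(
    specs: Iterable[ScenarioSpec], progress: bool = False
) -> dict[str, ScenarioResult]:
    """Run several scenarios; deterministic given each spec's seed."""
    return {spec.name: run_scenario(spec, progress=progress) for spec in specs}


def standardize(summary: pd.DataFrame, setup: GeneticSetup, n_drones: int) -> pd.DataFrame:
    """Express performance in units of the initial phenotypic SD and
    breeding values in units of their initial genetic SDs."""
    if setup.var_dir <= 0 or setup.var_mat <= 0:
        raise ValueError("standardization requires positive genetic variances")
    sd_p = np.sqrt(phenotypic_variance(setup, n_drones))
    out = summary.copy()
    for col in ("mean_P_mean", "mean_P_sd"):
        out[col.replace("mean_P", "std_P")] = summary[col] / sd_p
    for eff, var in (("dir", setup.var_dir), ("mat", setup.var_mat)):
        for stat in ("mean", "sd"):
            col = f"mean_bv_{eff}_{stat}"
            out[f"std_bv_{eff}_{stat}"] = summary[col] / np.sqrt(var)
    return out


def final_table(result: ScenarioResult) -> pd.DataFrame:
    """One-row summary of the final state, in the layout of the study
    tables: final F (%), standardized final performance and breeding
    values, final variances and direct-maternal correlation, each with
    its cross-replicate sampling SD in a ``*_sd`` column."""
    spec = result.spec
    sd_p = np.sqrt(phenotypic_variance(spec.setup, spec.n_drones))
    last = -1
    cols: dict[str, float] = {}

    def put(name: str, series: np.ndarray, scale: float = 1.0) -> None:
        cols[name] = float(series.mean() * scale)
        cols[f"{name}_sd"] = float(series.std(ddof=1) * scale)

    rep = result.per_replicate
    put("F_pct", rep["mean_F"][:, last], 100.0)
    put("P_std", rep["mean_P"][:, last], 1.0 / sd_p)
    put("BV_dir_std", rep["mean_bv_dir"][:, last], 1.0 / np.sqrt(spec.setup.var_dir))
    put("BV_mat_std", rep["mean_bv_mat"][:, last], 1.0 / np.sqrt(spec.setup.var_mat))
    put("V_P", rep["var_P"][:, last])
    put("V_BV_dir", rep["var_bv_dir"][:, last])
    put("V_BV_mat", rep["var_bv_mat"][:, last])
    put("r_dir_mat", rep["corr_dir_mat"][:, last])
    return pd.DataFrame([{"scenario": spec.name, **cols}])


def inbreeding_slope(
    mean_f_percent: np.ndarray,
    years: np.ndarray,
    from_year: int = 7,
    to_year: int = 23,
) -> float:
    """Least-squares slope (% per year) of mean inbreeding over a window."""
    years = np.asarray(years)
    mask = (years >= from_year) & (years <= to_year)
    if mask.sum() < 2:
        raise ValueError("slope window must contain at least two years")
    return float(np.polyfit(years[mask], np.asarray(mean_f_percent)[mask], 1)[0])


def replicate_inbreeding_slopes(
    result: ScenarioResult, from_year: int = 7, to_year: int = 23
) -> np.ndarray:
    """Per-replicate inbreeding slopes (% per year), for standard errors."""
    years = result.years
    return np.array(
        [
            inbreeding_slope(100.0 * row, years, from_year, to_year)
            for row in result.per_replicate["mean_F"]
        ]
    )


def write_outputs(results: Mapping[str, ScenarioResult], path: str | Path) -> list[Path]:
    """Write per-scenario trajectory and final-state CSVs plus a JSON manifest."""
    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict[str, object] = {"package": "hivesim", "version": __version__, "scenarios": {}}
    for name, result in results.items():
        spec = result.spec
        traj = standardize(result.summary(), spec.setup, spec.n_drones)
        traj_path = out_dir / f"{name}_trajectory.csv"
        traj.to_csv(traj_path, index=False)
        final_path = out_dir / f"{name}_final.csv"
        final_table(result).to_csv(final_path, index=False)
        written += [traj_path, final_path]
        manifest["scenarios"][name] = {  # type: ignore[index]
            "setup": asdict(spec.setup),
            "strategy": spec.strategy,
            "n_drones": spec.n_drones,
            "n_replicates": spec.n_replicates,
            "years": spec.years,
            "seed": spec.seed,
            "n_failed_replicates": result.n_failed,
            "files": [traj_path.name, final_path.name],
        }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written.append(manifest_path)
    return written
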