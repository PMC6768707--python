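"""Replicated simulation study of the venue-based scale-up estimator.

Four stress tests probe the estimator the way a field study would be
stressed:

* **Test A** — key population size varies (with the frame size fixed).
* **Test B** — the number of key members sampled varies.
* **Test C** — the shapes of the attendance-rate (inclusion-probability)
  distributions vary, crossing four families for key members with the same
  four for non-key members.
* **Test D** — false-positive reporting of ties increases.

Each scenario *cell* replicates the whole pipeline — generate a population,
dress it with attendance rates, apply reporting error, draw venue samples,
estimate — over ``n_networks`` populations × ``n_samples_per_network``
samples, and is summarised by relative bias and relative standard error:

    relative bias (%) = 100 · (mean estimate − N_K) / N_K
    relative SE  (%)  = 100 · SD(estimates) / N_K

Desk-scale defaults run 20 networks × 100 samples per cell; a full-scale
run (100 × 1,000) is a configuration change, not a code change.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InestimableVisibilityError
from .population import (
    ATTENDANCE_SCENARIOS,
    ReportingModel,
    apply_reporting_error,
    assign_attendance,
    generate_population,
)
from .sampling import draw_sample
from .estimators import vb_gnsum

TEST_IDS = ("A", "B", "C", "D")

# Default grid axes. The population/sample sizes are documented stand-ins:
# frame of 20,000 venue attenders, key populations of 500/1,000/5,000, key
# samples of 25/50/100 (anchored to "about 25 or so" being workable), 400
# non-key respondents, and false-positive rates from none to half.
_NKEY_AXIS = (500, 1000, 5000)
_SKEY_AXIS = (25, 50, 100)
_FPR_AXIS = (0.0, 0.05, 0.10, 0.25, 0.50)
_MID_NKEY = 1000
_MID_SKEY = 50


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid.

    ``se_over`` selects how the relative standard error pools replicates:
    ``"all"`` takes the SD over every estimate in the cell (default);
    ``"network_means"`` takes the SD of the per-network mean estimates.
    """

    n_frame: int = 20_000
    n_key: int = 1000
    n_key_sampled: int = 50
    n_nonkey_sampled: int = 400
    mean_degree_to_key: float = 3.0
    degree_dispersion: float = 1.0
    scenario_key: str = "S1"
    scenario_nonkey: str = "S1"
    false_positive_rate: float = 0.0
    false_negative_rate: float = 0.0
    misattribution_pool: float = 6.0
    n_networks: int = 20
    n_samples_per_network: int = 100
    seed: int = 0
    se_over: str = "all"

    def __post_init__(self):
        if not (0 < self.n_key < self.n_frame):
            raise ConfigurationError("need 0 < n_key < n_frame")
        if self.n_key_sampled > self.n_key:
            raise ConfigurationError("n_key_sampled cannot exceed n_key")
        if self.n_nonkey_sampled > self.n_frame - self.n_key:
            raise ConfigurationError("n_nonkey_sampled cannot exceed the non-key stratum")
        if min(self.n_key_sampled, self.n_nonkey_sampled, self.n_networks,
               self.n_samples_per_network) < 1:
            raise ConfigurationError("counts must be positive")
        for s in (self.scenario_key, self.scenario_nonkey):
            if s not in ATTENDANCE_SCENARIOS:
                raise ConfigurationError(f"unknown attendance scenario {s!r}")
        if self.se_over not in ("all", "network_means"):
            raise ConfigurationError("se_over must be 'all' or 'network_means'")
        # Rate ranges are validated by ReportingModel.
        ReportingModel(self.false_positive_rate, self.false_negative_rate,
                       self.misattribution_pool)


@dataclass(frozen=True)
class CellSummary:
    """Bias/variability summary of one scenario cell."""

    config: ScenarioConfig
    mean_estimate: float
    relative_bias_pct: float
    relative_se_pct: float
    n_failed: int
    n_estimates: int
    estimates: np.ndarray | None = field(default=None, compare=False, repr=False)

    def to_dict(self) -> dict:
        d = asdict(self.config)
        d.update(
            mean_estimate=self.mean_estimate,
            relative_bias_pct=self.relative_bias_pct,
            relative_se_pct=self.relative_se_pct,
            n_failed=self.n_failed,
            n_estimates=self.n_estimates,
        )
        return d


def run_cell(config: ScenarioConfig, *, keep_estimates: bool = False) -> CellSummary:
    """Run one scenario cell end to end.

    Fully reproducible from ``config`` (including its seed): every stream —
    network generation, attendance assignment, reporting error, and each
    sample draw — is split deterministically from ``config.seed``.
    Replicates whose key respondents all report zero in-ties are recorded
    as failed, not raised.
    """
    root = np.random.SeedSequence(config.seed)
    model = ReportingModel(
        config.false_positive_rate, config.false_negative_rate, config.misattribution_pool
    )
    needs_error = config.false_positive_rate > 0 or config.false_negative_rate > 0
    n_fk = config.n_frame - config.n_key  # true N_{F∖K}, known in simulation

    estimates: list[float] = []
    per_network_means: list[float] = []
    n_failed = 0
    for net_ss in root.spawn(config.n_networks):
        gen_ss, att_ss, err_ss, samp_ss = net_ss.spawn(4)
        pop = generate_population(
            config.n_frame, config.n_key, config.mean_degree_to_key,
            config.degree_dispersion, seed=gen_ss,
        )
        pop = assign_attendance(
            pop, scenario_nonkey=config.scenario_nonkey,
            scenario_key=config.scenario_key, seed=att_ss,
        )
        if needs_error:
            pop = apply_reporting_error(pop, model, seed=err_ss)
        net_estimates = []
        for s_ss in samp_ss.spawn(config.n_samples_per_network):
            sample = draw_sample(
                pop, config.n_key_sampled, config.n_nonkey_sampled, seed=s_ss
            )
            try:
                net_estimates.append(vb_gnsum(sample, n_fk).n_hat)
            except InestimableVisibilityError:
                n_failed += 1
        estimates.extend(net_estimates)
        if net_estimates:
            per_network_means.append(float(np.mean(net_estimates)))

    est = np.asarray(estimates)
    if est.size == 0:
        return CellSummary(config, float("nan"), float("nan"), float("nan"),
                           n_failed, 0, est if keep_estimates else None)
    pool = est if config.se_over == "all" else np.asarray(per_network_means)
    sd = float(np.std(pool, ddof=1)) if pool.size > 1 else 0.0
    mean = float(est.mean())
    return CellSummary(
        config=config,
        mean_estimate=mean,
        relative_bias_pct=100.0 * (mean - config.n_key) / config.n_key,
        relative_se_pct=100.0 * sd / config.n_key,
        n_failed=n_failed,
        n_estimates=int(est.size),
        estimates=est if keep_estimates else None,
    )


def default_grid(test_id: str) -> list[dict]:
    """The default cell grid (list of config overrides) for one test.

    Tests A and B share one 3×3 grid crossing key population size with key
    sample size — the two axes are two readings of the same table. Test C
    crosses the four attendance families for each stratum at the mid-grid
    population and sample size. Test D crosses population size with
    false-positive rate.
    """
    if test_id in ("A", "B"):
        return [
            {"n_key": nk, "n_key_sampled": sk}
            for nk in _NKEY_AXIS for sk in _SKEY_AXIS
        ]
    if test_id == "C":
        return [
            {"n_key": _MID_NKEY, "n_key_sampled": _MID_SKEY,
             "scenario_nonkey": sv, "scenario_key": sk}
            for sv in ATTENDANCE_SCENARIOS for sk in ATTENDANCE_SCENARIOS
        ]
    if test_id == "D":
        return [
            {"n_key": nk, "n_key_sampled": _MID_SKEY, "false_positive_rate": f}
            for nk in _NKEY_AXIS for f in _FPR_AXIS
        ]
    raise ConfigurationError(f"unknown test id {test_id!r}; expected one of {TEST_IDS}")


def run_test(
    test_id: str,
    out_dir: str | Path | None = None,
    *,
    base: ScenarioConfig | None = None,
    grid: Sequence[dict] | None = None,
    n_networks: int | None = None,
    n_samples_per_network: int | None = None,
    seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Run all cells of one test and return (and optionally write) a tidy table.

    Each cell's seed is derived deterministically from ``seed`` and the cell
    index, so any row of the output can be regenerated in isolation by
    rebuilding its :class:`ScenarioConfig`. When ``out_dir`` is given, the
    table is written to ``test_<id>.csv`` alongside a provenance record.
    """
    base = base if base is not None else ScenarioConfig()
    cells = list(grid) if grid is not None else default_grid(test_id)
    overrides = {}
    if n_networks is not None:
        overrides["n_networks"] = n_networks
    if n_samples_per_network is not None:
        overrides["n_samples_per_network"] = n_samples_per_network

    cell_seeds = [
        int(ss.generate_state(1)[0] & 0x7FFFFFFF)
        for ss in np.random.SeedSequence(seed).spawn(len(cells))
    ]
    iterator = enumerate(cells)
    if progress:
        from tqdm import tqdm  # optional nicety, CLI only

        iterator = enumerate(tqdm(cells, desc=f"Test {test_id}"))

    rows = []
    for i, cell in iterator:
        config = replace(base, **cell, **overrides, seed=cell_seeds[i])
        rows.append(run_cell(config).to_dict())
    df = pd.DataFrame(rows)
    df.insert(0, "test", test_id)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / f"test_{test_id}.csv", index=False)
        _write_provenance(out_dir / f"test_{test_id}.provenance.json",
                          test_id, base, seed, overrides, len(cells))
    return df


def _write_provenance(path: Path, test_id: str, base: ScenarioConfig,
                      seed: int, overrides: dict, n_cells: int) -> None:
    import json

    from . import __version__

    record = {
        "package": "vbgnsum",
        "version": __version__,
        "test": test_id,
        "seed": seed,
        "n_cells": n_cells,
        "base_config": asdict(base),
        "overrides": overrides,
    }
    path.write_text(json.dumps(record, indent=2) + "\n", encoding="utf-8")
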