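"""Monte Carlo robustness analysis of the multistep estimates.

Measured concentrations carry replicate-to-replicate noise.  To quantify how
that noise propagates into the 23 parameter estimates, each measured point
is redrawn from a Gaussian with its reported mean and standard deviation
(truncated at zero — concentrations cannot be negative), the full multistep
estimation is repeated on every perturbed table, replicates with outlying
total objectives are excluded by a quartile fence, and per-parameter means
and standard deviations (expressed as percent of the mean) are reported.

Quartiles follow the exclusive-median rule: the median splits the ordered
objective values into two halves (the median itself belongs to neither),
and the lower/upper quartile is the median of the corresponding half.  A
replicate is retained when its objective lies inside the closed interval
[q_low - 1.5 IQR, q_up + 1.5 IQR].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import MeasurementTable
from .estimation import DEFAULT_GLU0, EstimationResult, multistep_estimate
from .model import PARAM_NAMES, ExperimentDesign
from .pso import SwarmConfig

logger = logging.getLogger(__name__)


def perturb_table(table: MeasurementTable, rng: np.random.Generator) -> MeasurementTable:
    """Redraw every mean from N(mean, sd^2), truncated at zero.

    Standard deviations are copied unchanged; points with sd = 0 (e.g.
    fully depleted substrates) stay exactly at their mean.
    """
    noisy = rng.normal(table.mean, table.sd)
    noisy = np.where(table.sd > 0, np.maximum(noisy, 0.0), table.mean)
    return MeasurementTable(
        times=table.times.copy(),
        variables=table.variables,
        mean=noisy,
        sd=table.sd.copy(),
    )


def quartile_filter(objectives: np.ndarray) -> np.ndarray:
    """Boolean mask of replicates inside the quartile fence.

    Quartiles are medians of the exclusive halves of the ordered data; the
    fence is [q_low - 1.5 IQR, q_up + 1.5 IQR], closed at both ends.
    """
    vals = np.asarray(objectives, dtype=float)
    if vals.size < 4:
        raise ValueError(f"need at least 4 objective values, got {vals.size}")
    srt = np.sort(vals)
    n = srt.size
    half = n // 2
    lower = srt[:half]
    upper = srt[half + 1:] if n % 2 else srt[half:]
    q_low = float(np.median(lower))
    q_up = float(np.median(upper))
    iqr = q_up - q_low
    lo, hi = q_low - 1.5 * iqr, q_up + 1.5 * iqr
    return (vals >= lo) & (vals <= hi)


@dataclass(frozen=True)
class MonteCarloSummary:
    """Per-parameter variability over the retained replicates."""

    n_requested: int
    n_retained: int
    n_failed: int
    param_names: tuple[str, ...]
    mean: np.ndarray         # per parameter, natural units
    sd_percent: np.ndarray   # 100 * sd / mean, per parameter
    objectives: np.ndarray   # per completed replicate, total objective
    retained: np.ndarray     # boolean mask over completed replicates
    estimates: np.ndarray    # completed replicates x 23

    def sd_percent_of(self, name: str) -> float:
        return float(self.sd_percent[self.param_names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.param_names, "mean": self.mean,
             "sd_percent": self.sd_percent}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_monte_carlo(
    table: MeasurementTable,
    n_reps: int,
    cfg: SwarmConfig,
    design: ExperimentDesign | None = None,
    seed: int = 0,
    *,
    glu0: float = DEFAULT_GLU0,
    pso_seed: int | None = None,
) -> MonteCarloSummary:
    """Perturb -> interpolate -> estimate, ``n_reps`` times, then summarize.

    Replicate i perturbs the table with a generator seeded from
    ``seed + i``; the PSO seed (``pso_seed``, default ``seed``) is shared
    across replicates so that only the data vary between replicates.
    Failed replicates are dropped with a warning.
    """
    if n_reps < 4:
        raise ValueError("need at least 4 replicates for the quartile fence")
    design = design or ExperimentDesign()
    if pso_seed is None:
        pso_seed = seed

    estimates: list[np.ndarray] = []
    objectives: list[float] = []
    n_failed = 0
    for i in range(n_reps):
        rng = np.random.default_rng(seed + i)
        noisy = perturb_table(table, rng)
        try:
            res: EstimationResult = multistep_estimate(
                noisy, cfg, design, seed=pso_seed, glu0=glu0
            )
        except Exception as exc:  # noqa: BLE001 - a failed replicate is dropped
            logger.warning("replicate %d failed: %s", i, exc)
            n_failed += 1
            continue
        estimates.append(res.param_vector())
        objectives.append(res.total_objective)

    if len(objectives) < 4:
        raise RuntimeError(
            f"only {len(objectives)} replicates completed; cannot summarize"
        )
    est = np.array(estimates)
    obj = np.array(objectives)
    retained = quartile_filter(obj)
    kept = est[retained]
    mean = kept.mean(axis=0)
    sd = kept.std(axis=0, ddof=1) if kept.shape[0] > 1 else np.zeros(est.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        sd_percent = np.where(mean != 0, 100.0 * sd / np.abs(mean), 0.0)
    return MonteCarloSummary(
        n_requested=n_reps,
        n_retained=int(retained.sum()),
        n_failed=n_failed,
        param_names=PARAM_NAMES,
        mean=mean,
        sd_percent=sd_percent,
        objectives=obj,
        retained=retained,
        estimates=est,
    )
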