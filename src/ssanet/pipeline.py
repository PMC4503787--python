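"""Generate -> simulate -> analyze sweeps over clustering parameters.

One sweep point = one network realization + one LIF simulation +
spectral screening + SSA metrics, all deterministically derived from a
master seed: per-stage seeds (topology, initial conditions, shuffles)
are expanded with ``numpy.random.SeedSequence`` spawn keys so any
stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ssanet.lif import LIFParams, simulate
from ssanet.metrics import (pca_firing_patterns, principal_angle,
                            spike_rate_variability,
                            temporal_rate_variability)
from ssanet.spectral import spectral_summary
from ssanet.topology import NetworkSpec, make_network

log = logging.getLogger("ssanet")

__all__ = ["SweepConfig", "run_point", "run_sweep", "stage_seed"]

_STAGES = {"topology": 0, "init": 1, "shuffle": 2}


def stage_seed(master_seed: int, stage: str, point: int = 0,
               replicate: int = 0) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(_STAGES[stage], point, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SweepConfig:
    template: NetworkSpec
    sweep_field: str
    sweep_values: tuple
    seeds: tuple = (0, 1, 2)
    duration: float = 10.0
    dt: float = 0.1
    window_ms: float = 100.0
    pca_bin_ms: float = 250.0
    n_shuffles: int = 10
    compute_angle: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if len(self.sweep_values) == 0:
            raise ValueError("sweep needs at least one value")
        if len(self.seeds) == 0:
            raise ValueError("sweep needs at least one seed")
        if not hasattr(self.template, self.sweep_field):
            raise ValueError(f"unknown sweep field {self.sweep_field!r}")


def run_point(spec: NetworkSpec, master_seed: int, duration: float = 10.0,
              dt: float = 0.1, window_ms: float = 100.0,
              pca_bin_ms: float = 250.0, n_shuffles: int = 10,
              compute_angle: bool = True, point: int = 0) -> dict:
    """Evaluate one (spec, seed) point; returns a flat result row."""
    t0 = time.perf_counter()
    spec = spec.replace(seed=stage_seed(master_seed, "topology", point))
    W, part = make_network(spec)
    params = LIFParams(duration=duration, dt=dt,
                       seed=stage_seed(master_seed, "init", point))
    raster = simulate(W, params)

    m = part.n_groups - 1 if part.n_groups > 1 else None
    summ = spectral_summary(W, partition=part, m=m,
                            compute_basis=compute_angle)
    row = {
        "seed": master_seed,
        "rate_hz": raster.rate(),
        "gap": summ.gap,
        "lambda_max": summ.lambda_max,
        "wta": summ.wta_flag,
        "m": summ.m,
    }
    if part.n_groups >= 2:
        sh_seed = stage_seed(master_seed, "shuffle", point)
        sv = spike_rate_variability(raster, part, window_ms,
                                    n_shuffles, sh_seed)
        tv = temporal_rate_variability(raster, part, window_ms,
                                       n_shuffles, sh_seed)
        row.update(S_hat=sv.S_hat, S=sv.S, S_hat_T=tv.S_hat_T, S_T=tv.S_T)
        if compute_angle and summ.dominant_basis is not None:
            n_pc = summ.dominant_basis.shape[1]
            P = pca_firing_patterns(raster, pca_bin_ms, n_pc)
            align = principal_angle(P, summ.dominant_basis)
            row.update(theta_deg=align.theta_deg, cos_theta=align.cos_theta)
    row["runtime_s"] = time.perf_counter() - t0
    return row


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run all (value, seed) points; returns the long-format table.

    Points that fail are recorded with an ``error`` column and the
    sweep continues.  If ``config.out_dir`` is set, writes
    ``results.csv``, ``summary.csv`` and the config JSON there.
    """
    rows = []
    for pi, value in enumerate(config.sweep_values):
        spec = config.template.replace(**{config.sweep_field: value})
        for seed in config.seeds:
            try:
                row = run_point(
                    spec, master_seed=seed, duration=config.duration,
                    dt=config.dt, window_ms=config.window_ms,
                    pca_bin_ms=config.pca_bin_ms,
                    n_shuffles=config.n_shuffles,
                    compute_angle=config.compute_angle, point=pi)
                row["error"] = ""
            except Exception as exc:  # noqa: BLE001 - record and continue
                log.warning("point %s=%s seed=%s failed: %s",
                            config.sweep_field, value, seed, exc)
                row = {"seed": seed, "error": str(exc)}
            row[config.sweep_field] = value
            rows.append(row)
            log.info("point %s=%s seed=%s done (%.1fs)", config.sweep_field,
                     value, seed, row.get("runtime_s", float("nan")))
    table = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False)
        summary = sweep_summary(table, config.sweep_field)
        summary.to_csv(out / "summary.csv", index=False)
        cfg = dataclasses.asdict(config)
        cfg["template"] = dataclasses.asdict(config.template)
        (out / "config.json").write_text(json.dumps(cfg, default=str,
                                                    indent=2))
    return table


def sweep_summary(table: pd.DataFrame, sweep_field: str) -> pd.DataFrame:
    """Per-value mean and standard deviation of the numeric columns."""
    ok = table[table.get("error", "") == ""] if "error" in table else table
    num = ok.select_dtypes("number").columns.difference([sweep_field, "seed"])
    g = ok.groupby(sweep_field)[list(num)]
    summary = g.agg(["mean", "std"])
    summary.columns = ["_".join(c) for c in summary.columns]
    return summary.reset_index()
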