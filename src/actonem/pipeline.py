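"""Sweep orchestration: micro-simulations to hydrodynamic prediction tables.

Runs the in-silico parameter sweeps end to end — [ATP] x valency grids,
crosslink-elasticity (kappa) sweeps, and passive-crosslinker (cp) sweeps —
producing tidy long-format tables from which every downstream curve and
surface can be regenerated without recomputation.

A sweep first builds *micro-curves* (pair strain rate ``eps`` and
crosslinking probability ``Pcl`` on the [ATP] grid, one stochastic
realization per seed), then applies the deterministic scaling layer for
every (kappa, cp) combination. Because the scaling step is pure, cp and
kappa variations reuse the identical micro-curves bit-for-bit.

Determinism: identical config (including seeds) gives bit-identical result
tables. Every output file carries a run manifest (config hash, seeds,
package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .motors import ClusterParams, DEFAULT_STEP_LENGTH, RateConstants, DEFAULT_RATES, simulate_two_filaments
from .scaling import MicroCurve, ScalingParams, locate_peak, predict_curves

__all__ = [
    "SweepConfig",
    "SweepResult",
    "default_atp_grid",
    "build_micro_curves",
    "run_atp_valency_sweep",
    "run_crosslinker_sweep",
    "write_sweep_result",
]


def default_atp_grid(n: int = 16) -> np.ndarray:
    """16 log-spaced [ATP] points on [1, 1000] µM, covering the experimental
    range."""
    return np.logspace(0.0, 3.0, n)


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of one sweep (flat, YAML-serializable).

    ``kappa_over_k0`` values parameterize the elastic constant as
    ``K = K0 (1 + ratio * (cm Pcl + cp))``; ``cp_values`` are passive
    crosslinker concentrations applied on top of fixed micro-curves.
    """

    atp_grid: tuple[float, ...] = tuple(default_atp_grid())
    valencies: tuple[int, ...] = (3, 4, 8)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    kappa_over_k0: tuple[float, ...] = (10.0,)
    cp_values: tuple[float, ...] = (0.0,)
    K0: float = 0.001
    beta: float = 0.1
    eta: float = 1.0
    cm: float = 1.0
    total_time: float = 1000.0
    step_length: float = DEFAULT_STEP_LENGTH
    rates: tuple[float, float, float] = (
        DEFAULT_RATES.k12,
        DEFAULT_RATES.k23,
        DEFAULT_RATES.k31_per_atp,
    )

    def __post_init__(self) -> None:
        if not self.atp_grid or not self.valencies or not self.seeds:
            raise ValueError("atp_grid, valencies and seeds must be nonempty")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("atp_grid", "valencies", "seeds", "kappa_over_k0", "cp_values", "rates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))
        return path

    def manifest(self) -> dict:
        blob = json.dumps(_plain(asdict(self)), sort_keys=True)
        return {
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seeds": list(self.seeds),
            "package_version": __version__,
        }

    def scaling_params(self, kappa_ratio: float, cp: float) -> ScalingParams:
        return ScalingParams(
            K0=self.K0,
            kappa=kappa_ratio * self.K0,
            cm=self.cm,
            cp=cp,
            beta=self.beta,
            eta=self.eta,
        )

    def cluster_params(self, valency: int, atp: float) -> ClusterParams:
        k12, k23, k31 = self.rates
        return ClusterParams(
            valency=valency,
            step_length=self.step_length,
            atp=atp,
            rates=RateConstants(k12=k12, k23=k23, k31_per_atp=k31),
        )


def _plain(obj):
    """Recursively convert tuples/numpy scalars to YAML/JSON-plain types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class SweepResult:
    """Tidy table keyed by (atp, valency, cp, kappa_over_k0, seed) plus a
    peaks table keyed by (valency, cp, kappa_over_k0)."""

    table: pd.DataFrame
    peaks: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def build_micro_curves(
    config: SweepConfig, valency: int
) -> tuple[MicroCurve, pd.DataFrame]:
    """Pair micro-curves for one valency: per-seed rows + seed-mean curve.

    Each (atp, seed) cell is one two-filament simulation of
    ``config.total_time`` seconds; the returned :class:`MicroCurve` holds
    the across-seed means, the DataFrame every realization.
    """
    rows = []
    for atp in config.atp_grid:
        params = config.cluster_params(valency, atp)
        for seed in config.seeds:
            s = simulate_two_filaments(params, total_time=config.total_time, seed=seed)
            rows.append(
                {
                    "atp": atp,
                    "valency": valency,
                    "seed": seed,
                    "epsilon": s.strain_rate,
                    "p_crosslink": s.p_crosslink,
                }
            )
    df = pd.DataFrame(rows)
    mean = df.groupby("atp", sort=True)[["epsilon", "p_crosslink"]].mean()
    curve = MicroCurve(
        atp_grid=mean.index.to_numpy(),
        epsilon=mean["epsilon"].to_numpy(),
        p_crosslink=mean["p_crosslink"].to_numpy(),
    )
    return curve, df


def _apply_scaling(
    micro_df: pd.DataFrame,
    curve: MicroCurve,
    config: SweepConfig,
    valency: int,
    kappa_ratio: float,
    cp: float,
) -> tuple[pd.DataFrame, dict]:
    """Scale one micro-curve set: per-seed rows plus the seed-mean peak."""
    sp = config.scaling_params(kappa_ratio, cp)
    out = []
    for seed, grp in micro_df.groupby("seed"):
        grp = grp.sort_values("atp")
        mc = MicroCurve(
            atp_grid=grp["atp"].to_numpy(),
            epsilon=grp["epsilon"].to_numpy(),
            p_crosslink=grp["p_crosslink"].to_numpy(),
        )
        pred = predict_curves(mc, sp)
        out.append(
            pd.DataFrame(
                {
                    "atp": mc.atp_grid,
                    "valency": valency,
                    "cp": cp,
                    "kappa_over_k0": kappa_ratio,
                    "seed": seed,
                    "epsilon": mc.epsilon,
                    "p_crosslink": mc.p_crosslink,
                    "activity": pred.activity,
                    "elasticity": pred.elasticity,
                    "speed": pred.speed,
                    "length": pred.length,
                    "speed_norm": pred.speed_norm,
                    "length_norm": pred.length_norm,
                }
            )
        )
    pred_mean = predict_curves(curve, sp)
    peak = locate_peak(pred_mean)
    peak_row = {
        "valency": valency,
        "cp": cp,
        "kappa_over_k0": kappa_ratio,
        "atp_peak": peak.atp_peak,
        "alpha_peak": peak.alpha_peak,
        "eq_residual": peak.eq_residual,
        "interior": peak.interior,
    }
    return pd.concat(out, ignore_index=True), peak_row


def run_atp_valency_sweep(config: SweepConfig) -> SweepResult:
    """[ATP] x valency sweep with the configured kappa ratios (cp = 0).

    Micro-curves are simulated once per valency, then scaled for each
    kappa; peaks are located on the seed-averaged prediction curves.
    """
    tables, peaks = [], []
    for valency in config.valencies:
        curve, df = build_micro_curves(config, valency)
        for kr in config.kappa_over_k0:
            t, p = _apply_scaling(df, curve, config, valency, kr, cp=0.0)
            tables.append(t)
            peaks.append(p)
    return SweepResult(
        table=pd.concat(tables, ignore_index=True),
        peaks=pd.DataFrame(peaks),
        manifest=config.manifest(),
    )


def run_crosslinker_sweep(config: SweepConfig, valency: int = 3) -> SweepResult:
    """Passive-crosslinker sweep at fixed micro-curves (trimers by default,
    the valency with the lowest baseline crosslinking).

    The cp grid is applied to one set of micro-curves, so ``epsilon`` and
    ``p_crosslink`` are bit-identical across cp values.
    """
    curve, df = build_micro_curves(config, valency)
    tables, peaks = [], []
    for kr in config.kappa_over_k0:
        for cp in config.cp_values:
            t, p = _apply_scaling(df, curve, config, valency, kr, cp)
            tables.append(t)
            peaks.append(p)
    return SweepResult(
        table=pd.concat(tables, ignore_index=True),
        peaks=pd.DataFrame(peaks),
        manifest=config.manifest(),
    )


def write_sweep_result(result: SweepResult, outdir: str | Path, stem: str = "sweep") -> dict[str, Path]:
    """Write ``<stem>.csv``, ``<stem>_peaks.csv`` and ``<stem>_manifest.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": outdir / f"{stem}.csv",
        "peaks": outdir / f"{stem}_peaks.csv",
        "manifest": outdir / f"{stem}_manifest.json",
    }
    result.table.to_csv(paths["table"], index=False)
    result.peaks.to_csv(paths["peaks"], index=False)
    paths["manifest"].write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    return paths
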