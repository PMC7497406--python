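"""Release-assay driver: daily supernatant exchange over a gel-loaded well.

Reproduces the bench protocol in silico: the gel is premixed with growth
factor, protein-free media sits on top, and at each exchange time the whole
supernatant is collected (its protein mass logged as that interval's release)
and replaced with fresh protein-free media.  Results are reported as
percentages of the initial load: retained in the gel, currently in the media,
and cumulatively removed — the three always close to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solver import (
    SolverConfig,
    WellGeometry,
    advance,
    build_grid,
    initial_state,
    layer_masses,
)
from .transport import TransportParams

__all__ = [
    "ExchangeProtocol",
    "ReleaseCurve",
    "ElisaSeries",
    "run_release_experiment",
    "retention_at",
    "apply_degradation_correction",
]

HOUR_S = 3600.0


@dataclass(frozen=True)
class ExchangeProtocol:
    """Media replacement schedule: full-volume exchanges at fixed times."""

    horizon_s: float = 72 * HOUR_S
    exchange_times_s: tuple[float, ...] = (24 * HOUR_S, 48 * HOUR_S, 72 * HOUR_S)

    def __post_init__(self) -> None:
        if self.horizon_s <= 0:
            raise ValueError("horizon_s must be > 0")
        times = np.asarray(self.exchange_times_s, dtype=float)
        if times.size and (np.any(np.diff(times) <= 0) or times[0] <= 0):
            raise ValueError("exchange times must be strictly increasing and > 0")
        if times.size and times[-1] > self.horizon_s:
            raise ValueError("exchange times must not exceed the horizon")

    def to_dict(self) -> dict:
        return {
            "horizon_s": self.horizon_s,
            "exchange_times_s": list(self.exchange_times_s),
        }


@dataclass
class ReleaseCurve:
    """Time course of the release experiment, as % of the initial load."""

    times_s: np.ndarray
    retained_percent: np.ndarray
    media_percent: np.ndarray
    cumulative_released_percent: np.ndarray
    interval_end_times_s: np.ndarray
    interval_released_ng: np.ndarray
    initial_mass_ng: float

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view (time_h, quantity, value)."""
        t_h = self.times_s / HOUR_S
        frames = []
        for name, vals in (
            ("retained_percent", self.retained_percent),
            ("media_percent", self.media_percent),
            ("cumulative_released_percent", self.cumulative_released_percent),
        ):
            frames.append(
                pd.DataFrame({"time_h": t_h, "quantity": name, "value": vals})
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ElisaSeries:
    """Per-interval supernatant protein masses, one column per replicate well."""

    interval_end_times_s: np.ndarray
    masses_ng: np.ndarray  # shape (n_intervals, n_replicates)
    correction_factor: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.interval_end_times_s = np.asarray(self.interval_end_times_s, float)
        self.masses_ng = np.atleast_2d(np.asarray(self.masses_ng, float))
        if np.any(np.diff(self.interval_end_times_s) <= 0):
            raise ValueError("interval end times must be strictly increasing")
        if self.masses_ng.shape[0] != self.interval_end_times_s.size:
            raise ValueError("masses_ng rows must match the number of intervals")
        if np.any(self.masses_ng < 0):
            raise ValueError("masses must be >= 0")

    @property
    def n_replicates(self) -> int:
        return self.masses_ng.shape[1]

    def replicate_mean(self) -> np.ndarray:
        return self.masses_ng.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.interval_end_times_s):
            for r in range(self.n_replicates):
                rows.append(
                    {
                        "time_h": t / HOUR_S,
                        "quantity": "interval_released_ng",
                        "value": self.masses_ng[i, r],
                        "replicate": r + 1,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ElisaSeries":
        df = pd.read_csv(path)
        required = {"time_h", "value", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"ELISA CSV missing columns: {sorted(missing)}")
        wide = df.pivot_table(
            index="time_h", columns="replicate", values="value"
        ).sort_index()
        return cls(
            interval_end_times_s=wide.index.to_numpy() * HOUR_S,
            masses_ng=wide.to_numpy(),
        )


def run_release_experiment(
    params: TransportParams,
    geometry: WellGeometry,
    protocol: ExchangeProtocol,
    config: SolverConfig | None = None,
    output_dt_s: float | None = 900.0,
) -> ReleaseCurve:
    """Simulate the full exchange protocol and return the release curve.

    The initial condition is a uniform total concentration in the gel and zero
    in the media.  At each exchange time the media-layer mass is logged as that
    interval's released mass and the media concentration reset to zero.  Curve
    samples are taken every ``output_dt_s`` seconds (pass ``None`` to sample
    only at exchange times and the horizon, which is faster for fitting).
    """
    config = config or SolverConfig()
    grid = build_grid(params, geometry, config)
    state = initial_state(params, grid)
    m0 = sum(layer_masses(state, grid))
    if m0 <= 0:
        raise ValueError("initial protein load must be positive")

    exchange_times = list(protocol.exchange_times_s)
    if output_dt_s is not None:
        samples = np.arange(0.0, protocol.horizon_s + output_dt_s / 2, output_dt_s)
        event_times = np.unique(
            np.concatenate([samples, exchange_times, [protocol.horizon_s]])
        )
    else:
        event_times = np.unique(np.asarray(exchange_times + [protocol.horizon_s]))
        event_times = np.concatenate([[0.0], event_times])
    event_times = event_times[event_times <= protocol.horizon_s + 1e-9]
    if event_times[0] != 0.0:
        event_times = np.concatenate([[0.0], event_times])

    times, ret, med, cum = [], [], [], []
    interval_masses = []
    removed_ng = 0.0

    def record(t: float) -> None:
        gel, media = layer_masses(state, grid)
        times.append(t)
        ret.append(100.0 * gel / m0)
        med.append(100.0 * media / m0)
        cum.append(100.0 * removed_ng / m0)

    record(0.0)
    exchange_set = {round(float(t), 9) for t in exchange_times}
    for t_prev, t_next in zip(event_times[:-1], event_times[1:]):
        state = advance(state, grid, config, float(t_next - t_prev))
        if round(float(t_next), 9) in exchange_set:
            _, media_mass = layer_masses(state, grid)
            interval_masses.append(media_mass)
            removed_ng += media_mass
            state.concentration_ng_m3 = np.where(
                grid.is_gel, state.concentration_ng_m3, 0.0
            )
        record(float(t_next))

    return ReleaseCurve(
        times_s=np.asarray(times),
        retained_percent=np.asarray(ret),
        media_percent=np.asarray(med),
        cumulative_released_percent=np.asarray(cum),
        interval_end_times_s=np.asarray(exchange_times, float),
        interval_released_ng=np.asarray(interval_masses),
        initial_mass_ng=m0,
    )


def retention_at(curve: ReleaseCurve, t_s: float) -> float:
    """Gel-retained percentage at time ``t_s``, linearly interpolated."""
    if t_s < curve.times_s[0] - 1e-9 or t_s > curve.times_s[-1] + 1e-9:
        raise ValueError(
            f"time {t_s} s outside curve range "
            f"[{curve.times_s[0]}, {curve.times_s[-1]}] s"
        )
    return float(np.interp(t_s, curve.times_s, curve.retained_percent))


def apply_degradation_correction(series: ElisaSeries, factor: float) -> ElisaSeries:
    """Scale every interval measurement by a protein-degradation factor.

    The factor compensates for growth factor degraded in the supernatant
    before quantification; provenance is recorded in the series metadata.
    """
    if factor <= 0:
        raise ValueError(f"correction factor must be > 0, got {factor}")
    meta = dict(series.metadata)
    meta["degradation_correction_factor"] = factor * series.correction_factor
    return ElisaSeries(
        interval_end_times_s=series.interval_end_times_s.copy(),
        masses_ng=series.masses_ng * factor,
        correction_factor=series.correction_factor * factor,
        metadata=meta,
    )
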