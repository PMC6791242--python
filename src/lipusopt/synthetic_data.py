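"""Synthetic viability surfaces and simulated factorial experiments.

The generator draws per-condition replicate measurements from a smooth
unimodal "true" surface — a Gaussian bump over the stimulation box —
plus i.i.d. Gaussian replicate noise, then control-normalizes exactly as
a real CCK-8 experiment would (every value divided by the simulated
control group's mean, control mean = 100% by construction).

Defaults emulate the published factorial design: 4 voltages x 4
frequencies x 3 durations over [5, 8] V x [0.6, 1.2] MHz x [3, 9] min,
n = 20 replicates per cell, a planted peak of 120% near (6.5 V,
0.95 MHz, 7.5 min) with widths (1.1 V, 0.18 MHz, 3.0 min) back-solved
from the published ridge decay, and replicate noise SD of 8 percentage
points (printed cell SDs span roughly 3-20 points). It is purely
statistical: no acoustic physics, no noise heteroscedasticity unless a
per-cell SD mapping is supplied, and no replicate correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataset import (
    CONTROL,
    GroupSummary,
    ReplicateRecord,
    ResponseGrid,
    StimulationCondition,
    aggregate_replicates,
)

__all__ = ["SurfaceSpec", "true_surface", "simulate_grid", "DEFAULT_LEVELS"]

#: The published factorial design levels: voltages (V), frequencies (MHz),
#: durations (min).
DEFAULT_LEVELS = ((5.0, 6.0, 7.0, 8.0), (0.6, 0.8, 1.0, 1.2), (3.0, 6.0, 9.0))


@dataclass(frozen=True)
class SurfaceSpec:
    """A unimodal Gaussian-bump viability surface with a known optimum.

    ``peak`` is the planted optimum (V, MHz, min) inside ``box``;
    ``peak_viability`` and ``baseline`` are in percent of control;
    ``widths`` are the bump's per-dimension Gaussian sigmas in the
    dimension's own units; ``noise_sd`` is the replicate noise SD in
    percentage points (a mapping condition -> SD makes it per-cell).
    """

    peak: tuple[float, float, float] = (6.5, 0.95, 7.5)
    peak_viability: float = 120.0
    baseline: float = 100.0
    widths: tuple[float, float, float] = (1.1, 0.18, 3.0)
    noise_sd: float | Mapping[StimulationCondition, float] = 8.0
    box: tuple[tuple[float, float], ...] = ((5.0, 8.0), (0.6, 1.2), (3.0, 9.0))
    rng_seed: object = None

    def __post_init__(self) -> None:
        for x, (lo, hi), name in zip(self.peak, self.box, "Vft"):
            if not lo <= x <= hi:
                raise ValueError(f"peak {name}-coordinate {x} outside box [{lo}, {hi}]")
        if self.peak_viability <= self.baseline:
            raise ValueError("peak_viability must exceed baseline")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be > 0")
        if not isinstance(self.noise_sd, Mapping) and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def cell_noise_sd(self, condition: StimulationCondition) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd[condition])
        return float(self.noise_sd)


def true_surface(spec: SurfaceSpec, condition: StimulationCondition | Sequence[float]) -> float:
    """Noise-free viability (%) at a condition:
    ``baseline + (peak - baseline) * exp(-sum_d ((x_d - x*_d)/sigma_d)^2 / 2)``."""
    x = condition.as_array() if isinstance(condition, StimulationCondition) else np.asarray(
        condition, dtype=float)
    for xd, (lo, hi) in zip(x, spec.box):
        if not lo <= xd <= hi:
            raise ValueError(f"condition {x} outside box {spec.box}")
    z = (x - np.asarray(spec.peak)) / np.asarray(spec.widths)
    return float(spec.baseline + (spec.peak_viability - spec.baseline) * np.exp(-0.5 * z @ z))


def simulate_grid(
    spec: SurfaceSpec,
    levels: tuple[Sequence[float], Sequence[float], Sequence[float]] = DEFAULT_LEVELS,
    n_replicates: int = 20,
    rng_seed: object = None,
) -> tuple[ResponseGrid, list[ReplicateRecord]]:
    """Simulate the full factorial experiment and return the aggregated
    grid plus the raw (control-normalized) replicates.

    Per treated cell, ``n_replicates`` draws of true surface + N(0,
    noise_sd); the control cell draws around the baseline. Everything is
    then scaled by the control group's raw mean so the control mean is
    exactly 100, mirroring real CCK-8 normalization. With ``noise_sd=0``
    every cell mean equals the true surface exactly.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    voltages, frequencies, durations = levels
    rng = np.random.default_rng(rng_seed if rng_seed is not None else spec.rng_seed)

    conditions = [
        StimulationCondition(v, f, d)
        for v in voltages for f in frequencies for d in durations
    ]
    for c in conditions:
        true_surface(spec, c)  # raises if any level is outside the box

    control_sd = spec.cell_noise_sd(CONTROL) if isinstance(spec.noise_sd, Mapping) else float(
        spec.noise_sd)
    raw = {
        CONTROL: spec.baseline + control_sd * rng.standard_normal(n_replicates)
    }
    for c in conditions:
        raw[c] = true_surface(spec, c) + spec.cell_noise_sd(c) * rng.standard_normal(n_replicates)

    scale = 100.0 / float(np.mean(raw[CONTROL]))
    records: list[ReplicateRecord] = []
    summaries: list[GroupSummary] = []
    for cond, vals in raw.items():
        scaled = vals * scale
        records.extend(ReplicateRecord(cond, float(v)) for v in scaled)
        if cond == CONTROL:
            sd = float(np.std(scaled, ddof=1)) if n_replicates > 1 else 0.0
            control_summary = GroupSummary(CONTROL, 100.0, sd, n_replicates)
        else:
            summaries.append(aggregate_replicates(
                [ReplicateRecord(cond, float(v)) for v in scaled])[0])
    return ResponseGrid(summaries, control=control_summary), records
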