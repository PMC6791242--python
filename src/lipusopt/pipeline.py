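"""End-to-end GA-BPNN analysis.

Stage 1 (:func:`fit_surrogate`) trains the GA-initialized network on the
48 grid-cell means (condition -> mean viability); stage 2
(:func:`optimize_inputs`) runs a second GA over the continuous
stimulation box, maximizing the surrogate's predicted viability, to
locate a condition that may fall between the tested grid levels.
:func:`run_full_analysis` orchestrates both plus the group-statistics
tables and produces a reproducible JSON/CSV report bundle.

The two GA stages draw from independent random streams spawned from one
master seed, so either stage can be re-run in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bpnn, ga, stats
from .dataset import GroupSummary, ResponseGrid, StimulationCondition
from .model import GABPNNRegressor

__all__ = [
    "SurrogateModel",
    "OptimizationResult",
    "AnalysisConfig",
    "AnalysisReport",
    "fit_surrogate",
    "optimize_inputs",
    "run_full_analysis",
]


@dataclass
class SurrogateModel:
    """A fitted viability surrogate plus the provenance of its training grid.

    ``model`` is any object with a sklearn-style ``predict``; the fitted
    :class:`~lipusopt.model.GABPNNRegressor` in normal use. ``box`` is
    the (3, 2) bounding box of the training levels; predictions are
    defined on all of it.
    """

    model: object
    box: np.ndarray
    levels: tuple[tuple[float, ...], ...]
    n_cells: int
    grid_conditions: np.ndarray  # (n_cells, 3), used to seed the input search

    def predict(self, conditions) -> np.ndarray:
        """Predicted viability (%) for an (n, 3) array or a sequence of
        :class:`StimulationCondition`."""
        arr = np.asarray(
            [c.as_array() if isinstance(c, StimulationCondition) else c for c in conditions],
            dtype=float,
        )
        return self.model.predict(arr)

    def to_json(self) -> str:
        if not isinstance(self.model, GABPNNRegressor):
            raise TypeError("only GABPNNRegressor-backed surrogates serialize")
        m = self.model
        doc = {
            "network": json.loads(m.network_.to_json()),
            "hidden_activation": m.hidden_activation,
            "scaler_x": {"mins": m.scaler_x_.mins.tolist(), "maxs": m.scaler_x_.maxs.tolist()},
            "scaler_y": {"mins": m.scaler_y_.mins.tolist(), "maxs": m.scaler_y_.maxs.tolist()},
            "box": self.box.tolist(),
            "levels": [list(l) for l in self.levels],
            "n_cells": self.n_cells,
            "grid_conditions": self.grid_conditions.tolist(),
            "final_mse": m.final_mse_,
            "ga_mse": m.ga_mse_,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SurrogateModel":
        doc = json.loads(text)
        m = GABPNNRegressor(hidden_activation=doc["hidden_activation"])
        m.network_ = bpnn.NetworkParameters.from_json(json.dumps(doc["network"]))
        m.scaler_x_ = bpnn.Scaler(np.array(doc["scaler_x"]["mins"]),
                                  np.array(doc["scaler_x"]["maxs"]))
        m.scaler_y_ = bpnn.Scaler(np.array(doc["scaler_y"]["mins"]),
                                  np.array(doc["scaler_y"]["maxs"]))
        m.n_features_in_ = m.network_.topology.n_input
        m.final_mse_ = doc["final_mse"]
        m.ga_mse_ = doc["ga_mse"]
        m.training_trace_ = None
        m.ga_trace_ = None
        return cls(
            model=m,
            box=np.asarray(doc["box"], dtype=float),
            levels=tuple(tuple(l) for l in doc["levels"]),
            n_cells=doc["n_cells"],
            grid_conditions=np.asarray(doc["grid_conditions"], dtype=float),
        )


@dataclass
class OptimizationResult:
    """The located optimum, its predicted viability, and how the GA got there."""

    optimum: StimulationCondition
    predicted_viability: float
    ga_trace: ga.ConvergenceTrace
    bounds: np.ndarray


@dataclass
class AnalysisConfig:
    """Everything :func:`run_full_analysis` needs; one master seed drives
    every random stream. Network and GA defaults are the study's."""

    seed: int = 0
    include_control: bool = False
    n_hidden: int = 8
    learning_rate: float = 0.1
    max_epochs: int = 1000
    error_goal: float = 1e-4
    ga_population: int = 50
    ga_generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elitism: int = 1
    weight_bound: float = 5.0
    bounds: list | None = None  # [[Vlo,Vhi],[flo,fhi],[tlo,thi]]; default = grid box
    control_n: int | None = None
    comparison_method: str = "pooled"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        return d


def fit_surrogate(
    grid: ResponseGrid,
    bpnn_cfg: bpnn.TrainingConfig | None = None,
    ga_cfg: ga.GAConfig | None = None,
    include_control: bool = False,
    n_hidden: int = 8,
    weight_bound: float = 5.0,
    seed=None,
) -> SurrogateModel:
    """Fit the GA-initialized network surrogate to a response grid.

    Training pairs are one per grid cell (condition -> mean viability).
    ``bpnn_cfg``/``ga_cfg`` override the back-propagation and
    weight-search settings; ``seed`` (or ``bpnn_cfg.rng_seed``) is the
    master seed. ``include_control`` adds the 0 MHz control row to the
    training set.
    """
    if len(grid) + (1 if include_control and grid.control else 0) < 2:
        raise ValueError("grid must contain at least 2 conditions")
    bpnn_cfg = bpnn_cfg or bpnn.TrainingConfig()
    X, y = grid.training_arrays(include_control=include_control)
    reg = GABPNNRegressor(
        n_hidden=n_hidden,
        learning_rate=bpnn_cfg.learning_rate,
        max_epochs=bpnn_cfg.max_epochs,
        error_goal=bpnn_cfg.error_goal,
        hidden_activation=bpnn_cfg.hidden_activation,
        ga_population=ga_cfg.population_size if ga_cfg else 50,
        ga_generations=ga_cfg.n_iterations if ga_cfg else 100,
        crossover_prob=ga_cfg.crossover_prob if ga_cfg else 0.8,
        mutation_prob=ga_cfg.mutation_prob if ga_cfg else 0.1,
        elitism=ga_cfg.elitism_count if ga_cfg else 1,
        weight_bound=weight_bound,
        random_state=seed if seed is not None else bpnn_cfg.rng_seed,
    )
    reg.fit(X, y)
    return SurrogateModel(
        model=reg,
        box=np.column_stack([X.min(axis=0), X.max(axis=0)]),
        levels=grid.levels,
        n_cells=len(X),
        grid_conditions=X,
    )


def optimize_inputs(
    model: SurrogateModel,
    bounds=None,
    ga_cfg: ga.GAConfig | None = None,
    allow_extrapolation: bool = False,
    seed=None,
) -> OptimizationResult:
    """GA-maximize the surrogate's predicted viability over a box.

    ``bounds`` defaults to the surrogate's training box and, unless
    ``allow_extrapolation`` is set, must lie inside it (the network is
    an interpolator, not an extrapolator). The GA's initial population is
    seeded with the in-bounds training-grid conditions, so with elitism
    the located optimum can never be worse than the best grid vertex as
    judged by the surrogate itself.
    """
    bounds = np.asarray(bounds, dtype=float) if bounds is not None else model.box.copy()
    if bounds.shape != model.box.shape:
        raise ValueError(f"bounds must have shape {model.box.shape}")
    if not allow_extrapolation and (
        np.any(bounds[:, 0] < model.box[:, 0]) or np.any(bounds[:, 1] > model.box[:, 1])
    ):
        raise ValueError(
            "search bounds extend outside the surrogate's training box "
            f"{model.box.tolist()}; pass allow_extrapolation=True to override"
        )

    if isinstance(model.model, GABPNNRegressor):
        reg = model.model
        scaler = reg.scaler_x_

        def fitness(genes: np.ndarray) -> float:
            return float(reg._predict_scaled_input(scaler.apply(genes)[None, :])[0])
    else:
        def fitness(genes: np.ndarray) -> float:
            return float(model.predict([genes])[0])

    if ga_cfg is None:
        ga_cfg = ga.GAConfig(bounds=bounds, rng_seed=seed)
    else:
        ga_cfg = ga.GAConfig(
            bounds=bounds,
            population_size=ga_cfg.population_size,
            n_iterations=ga_cfg.n_iterations,
            mutation_prob=ga_cfg.mutation_prob,
            crossover_prob=ga_cfg.crossover_prob,
            mutation_sigma_frac=ga_cfg.mutation_sigma_frac,
            elitism_count=ga_cfg.elitism_count,
            rng_seed=seed if seed is not None else ga_cfg.rng_seed,
        )
    in_bounds = model.grid_conditions[
        np.all(
            (model.grid_conditions >= bounds[:, 0]) & (model.grid_conditions <= bounds[:, 1]),
            axis=1,
        )
    ]
    best, trace = ga.evolve(fitness, ga_cfg, initial_genes=in_bounds if len(in_bounds) else None)
    optimum = StimulationCondition(*best.genes)
    return OptimizationResult(optimum, best.fitness, trace, bounds)


@dataclass
class AnalysisReport:
    """Bundle of everything the analysis produces."""

    config: AnalysisConfig
    surrogate: SurrogateModel
    optimization: OptimizationResult
    stats_table: pd.DataFrame
    improvement: stats.ImprovementSummary

    def to_json(self) -> str:
        """Deterministic JSON serialization: same config and seed give a
        byte-identical document."""
        opt = self.optimization
        doc = {
            "config": self.config.to_dict(),
            "surrogate": {
                "n_cells": self.surrogate.n_cells,
                "levels": [list(l) for l in self.surrogate.levels],
                "final_mse": self.surrogate.model.final_mse_,
                "ga_mse": self.surrogate.model.ga_mse_,
                "backprop_epochs": self.surrogate.model.training_trace_.epochs_run,
                "stop_reason": self.surrogate.model.training_trace_.stop_reason,
            },
            "optimum": {
                "voltage_v": opt.optimum.voltage,
                "frequency_mhz": opt.optimum.frequency,
                "duration_min": opt.optimum.duration,
                "predicted_viability_pct": opt.predicted_viability,
                "bounds": opt.bounds.tolist(),
            },
            "grid_best": {
                "voltage_v": self.improvement.best_condition.voltage,
                "frequency_mhz": self.improvement.best_condition.frequency,
                "duration_min": self.improvement.best_condition.duration,
                "mean_pct": self.improvement.best_mean,
                "improvement_over_control_pct_points": self.improvement.improvement_over_control,
            },
            "stats": self.stats_table.to_dict(orient="records"),
        }
        return json.dumps(doc, sort_keys=True, indent=2)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        self.stats_table.to_csv(outdir / "stats.csv", index=False)
        self.optimization.ga_trace.to_csv(outdir / "input_search_trace.csv")
        if self.surrogate.model.ga_trace_ is not None:
            self.surrogate.model.ga_trace_.to_dataframe()[
                ["generation", "best_fitness"]
            ].to_csv(outdir / "weight_search_trace.csv", index=False)
        (outdir / "model.json").write_text(self.surrogate.to_json())


def run_full_analysis(grid: ResponseGrid, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Surrogate fit + input optimization + group statistics, reproducible
    from ``config.seed``."""
    config = config or AnalysisConfig()
    ss = np.random.SeedSequence(config.seed)
    ss_fit, ss_opt = ss.spawn(2)
    surrogate = fit_surrogate(
        grid,
        bpnn_cfg=bpnn.TrainingConfig(
            learning_rate=config.learning_rate,
            max_epochs=config.max_epochs,
            error_goal=config.error_goal,
        ),
        ga_cfg=ga.GAConfig(
            bounds=[[0, 1]],  # placeholder; fit_surrogate derives real bounds
            population_size=config.ga_population,
            n_iterations=config.ga_generations,
            mutation_prob=config.mutation_prob,
            crossover_prob=config.crossover_prob,
            elitism_count=config.elitism,
        ),
        include_control=config.include_control,
        n_hidden=config.n_hidden,
        weight_bound=config.weight_bound,
        seed=ss_fit,
    )
    result = optimize_inputs(surrogate, bounds=config.bounds, seed=ss_opt)
    table = stats.comparison_table(grid, method=config.comparison_method,
                                   control_n=config.control_n)
    cond, best_mean = stats.grid_argmax(grid)
    optimized = GroupSummary(result.optimum, result.predicted_viability, 0.0, 1)
    improvement = stats.improvement_summary(grid, optimized)
    return AnalysisReport(config, surrogate, result, table, improvement)
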