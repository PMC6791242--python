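"""scikit-learn style regressor wrapping the GA-initialized network.

`GABPNNRegressor` fits a one-hidden-layer network to (condition ->
viability) pairs in two stages: a real-coded GA first searches the
flattened weight/threshold vector (fitness = negative training MSE in
scaled space), then plain back-propagation fine-tunes the best GA
candidate. Inputs and the target are min-max scaled to [0, 1] from the
training data before fitting; predictions are inverse-scaled. Setting
``ga_generations=0`` ablates the GA stage and trains from a seeded
uniform [-1, 1] initialization.

The estimator composes with sklearn tooling (`clone`, pipelines,
`cross_val_score`).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import bpnn, ga

__all__ = ["GABPNNRegressor"]


class GABPNNRegressor(RegressorMixin, BaseEstimator):
    """GA-initialized back-propagation network regressor.

    Parameters
    ----------
    n_hidden : hidden-layer size (default 8, the study's value).
    learning_rate, max_epochs, error_goal : back-propagation settings
        (study values 0.1, 1000, 1e-4; the error goal applies to the MSE
        on [0, 1]-scaled targets).
    hidden_activation : "sigmoid" (default) or "identity".
    ga_population, ga_generations, crossover_prob, mutation_prob,
    elitism : weight-search GA settings (study values 50, 100, 0.8, 0.1).
        ``ga_generations=0`` skips the GA stage.
    weight_bound : GA search box for every weight/threshold gene, in
        scaled space (genes live in [-weight_bound, weight_bound]).
    random_state : int, SeedSequence or Generator; drives both stages
        through independent spawned streams.

    Attributes
    ----------
    network_ : fitted :class:`~lipusopt.bpnn.NetworkParameters`.
    scaler_x_, scaler_y_ : the fitted min-max scalers.
    training_trace_ : back-propagation :class:`~lipusopt.bpnn.TrainingTrace`.
    ga_trace_ : GA :class:`~lipusopt.ga.ConvergenceTrace` (None if ablated).
    ga_mse_, final_mse_ : scaled training MSE after the GA stage and
        after back-propagation.
    """

    def __init__(
        self,
        n_hidden: int = 8,
        learning_rate: float = 0.1,
        max_epochs: int = 1000,
        error_goal: float = 1e-4,
        hidden_activation: str = "sigmoid",
        ga_population: int = 50,
        ga_generations: int = 100,
        crossover_prob: float = 0.8,
        mutation_prob: float = 0.1,
        elitism: int = 1,
        weight_bound: float = 5.0,
        random_state=None,
    ):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.error_goal = error_goal
        self.hidden_activation = hidden_activation
        self.ga_population = ga_population
        self.ga_generations = ga_generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.elitism = elitism
        self.weight_bound = weight_bound
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _seed_sequence(self) -> np.random.SeedSequence:
        rs = self.random_state
        if isinstance(rs, np.random.SeedSequence):
            return rs
        if isinstance(rs, np.random.Generator):
            # derive a child sequence so the caller's generator is untouched
            return np.random.SeedSequence(int(rs.integers(0, 2**31)))
        return np.random.SeedSequence(rs)

    def _scaled_training_set(self, X, y):
        Xs = self.scaler_x_.apply(X)
        ys = self.scaler_y_.apply(y.reshape(-1, 1))
        return Xs, ys

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if len(np.unique(X, axis=0)) < 2:
            raise ValueError("need at least 2 distinct input conditions to fit")
        self.n_features_in_ = X.shape[1]

        x_bounds = np.column_stack([X.min(axis=0), X.max(axis=0)])
        if np.all(x_bounds[:, 0] >= x_bounds[:, 1]):
            raise ValueError("degenerate training grid: a single level in every dimension")
        self.scaler_x_ = bpnn.fit_scaler(x_bounds, allow_degenerate=True)
        ylo, yhi = float(y.min()), float(y.max())
        if yhi <= ylo:
            # constant target: widen so scaling is defined; net learns the constant
            ylo, yhi = ylo - 0.5, yhi + 0.5
        self.scaler_y_ = bpnn.fit_scaler([[ylo, yhi]])

        topology = bpnn.NetworkTopology(self.n_features_in_, self.n_hidden, 1)
        Xs, ys = self._scaled_training_set(X, y)
        ss_ga, ss_bp = self._seed_sequence().spawn(2)

        def neg_mse(genes: np.ndarray) -> float:
            params = bpnn.NetworkParameters.from_vector(topology, genes)
            _, O = bpnn.forward(params, Xs, self.hidden_activation)
            return -float(np.mean(0.5 * np.sum((ys - O) ** 2, axis=1)))

        if self.ga_generations > 0:
            cfg = ga.GAConfig(
                bounds=np.tile([-self.weight_bound, self.weight_bound], (topology.n_params, 1)),
                population_size=self.ga_population,
                n_iterations=self.ga_generations,
                mutation_prob=self.mutation_prob,
                crossover_prob=self.crossover_prob,
                elitism_count=self.elitism,
                rng_seed=ss_ga,
            )
            best, self.ga_trace_ = ga.evolve(neg_mse, cfg)
            params0 = bpnn.NetworkParameters.from_vector(topology, best.genes)
            self.ga_mse_ = -best.fitness
        else:
            params0 = bpnn.NetworkParameters.random(topology, np.random.default_rng(ss_bp))
            self.ga_trace_ = None
            self.ga_mse_ = -neg_mse(params0.to_vector())

        train_cfg = bpnn.TrainingConfig(
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            error_goal=self.error_goal,
            hidden_activation=self.hidden_activation,
        )
        self.network_, self.training_trace_ = bpnn.train(params0, Xs, ys, train_cfg)
        self.final_mse_ = -neg_mse(self.network_.to_vector())
        return self

    def _predict_scaled_input(self, Xs: np.ndarray) -> np.ndarray:
        """Fast path used by the input-search GA: scaled X -> viability %."""
        _, O = bpnn.forward(self.network_, Xs, self.hidden_activation)
        return self.scaler_y_.invert(O).ravel()

    def predict(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return self._predict_scaled_input(self.scaler_x_.apply(X))

    @property
    def training_box_(self) -> np.ndarray:
        """The (n_features, 2) bounding box of the training inputs."""
        check_is_fitted(self, "scaler_x_")
        return np.column_stack([self.scaler_x_.mins, self.scaler_x_.maxs])
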