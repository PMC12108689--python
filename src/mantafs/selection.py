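"""Scikit-learn estimator front end for the swarm feature selectors.

Both selectors follow the ``SelectorMixin`` contract: ``fit(X, y)`` runs the
wrapper search, ``get_support()`` exposes the selected mask, and
``transform`` reduces a matrix to the selected columns, so they compose with
sklearn pipelines and model selection.

Example
-------
>>> from mantafs import MantaRayBPSOSelector, SyntheticSpec, synthesize_dataset
>>> ds = synthesize_dataset(SyntheticSpec(seed=0))
>>> sel = MantaRayBPSOSelector(n_iterations=30, random_state=0).fit(ds.X, ds.y)
>>> sel.transform(ds.X).shape[1] == sel.n_selected_
True
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.multiclass import check_classification_targets
from sklearn.utils.validation import check_is_fitted, validate_data

from .core import RunResult, SwarmConfig, run_bpso_baseline, run_bpso_mrfl
from .fitness import MaskEvaluator

__all__ = ["MantaRayBPSOSelector", "BinaryPSOSelector"]


class _BaseSwarmSelector(SelectorMixin, BaseEstimator):
    """Shared fit machinery for the swarm-based wrapper selectors.

    The fitness of a candidate subset is ``omega * E + (1 - omega) * d/D``
    where ``E`` is the KNN error on an internal stratified holdout that is
    frozen once per fit.

    Fitted attributes
    -----------------
    support_ : bool array of shape (n_features_in_,)
        Mask of the selected features.
    n_selected_ : int
        Number of selected features.
    best_fitness_, best_error_ : float
        Objective value and internal-holdout KNN error of the winning subset.
    fitness_trace_ : ndarray
        Global-best fitness after initialization and after each iteration
        (non-increasing).
    n_evaluations_ : int
        Total objective calls spent by the search.
    """

    def __init__(
        self,
        n_particles: int = 20,
        n_iterations: int = 100,
        omega: float = 0.99,
        n_neighbors: int = 5,
        test_fraction: float = 0.2,
        scale: bool = True,
        w_max: float = 0.9,
        w_min: float = 0.4,
        v_clamp: float = 6.0,
        memoize: bool = False,
        random_state: int | None = None,
    ) -> None:
        self.n_particles = n_particles
        self.n_iterations = n_iterations
        self.omega = omega
        self.n_neighbors = n_neighbors
        self.test_fraction = test_fraction
        self.scale = scale
        self.w_max = w_max
        self.w_min = w_min
        self.v_clamp = v_clamp
        self.memoize = memoize
        self.random_state = random_state

    def _swarm_config(self) -> SwarmConfig:
        return SwarmConfig(
            n_particles=self.n_particles,
            n_iterations=self.n_iterations,
            w_max=self.w_max,
            w_min=self.w_min,
            v_clamp=self.v_clamp,
        )

    def _run(self, objective, D, config, rng) -> RunResult:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y):
        """Run the wrapper search on ``(X, y)`` and store the best subset."""
        X, y = validate_data(self, X, y)
        check_classification_targets(y)
        classes, y_enc = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        self.classes_ = classes

        rng = np.random.default_rng(self.random_state)
        evaluator = MaskEvaluator(
            X, y_enc,
            omega=self.omega,
            k=self.n_neighbors,
            test_fraction=self.test_fraction,
            scale=self.scale,
            memoize=self.memoize,
            rng=rng,
        )
        result = self._run(evaluator, X.shape[1], self._swarm_config(), rng)

        self.support_ = result.best_mask.astype(bool)
        self.n_selected_ = result.subset_size
        self.best_fitness_ = float(result.best_fitness)
        self.best_error_ = float(result.best_error)
        self.fitness_trace_ = result.fitness_trace
        self.n_evaluations_ = result.evaluations_used
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class MantaRayBPSOSelector(_BaseSwarmSelector):
    """Wrapper feature selection by binary PSO with manta-ray foraging learning.

    The search alternates three learning strategies borrowed from manta-ray
    foraging: chain learning (each particle follows the personal best of the
    particle ahead of it and the global best), cyclone learning (the social
    reference is either the global best or, with probability shrinking as
    ``t/T`` grows, a fresh random position — an exploration-to-exploitation
    schedule), and a somersault resampling that pivots every particle around
    the global best.  Positions are binarized through a V-shaped (tanh)
    transfer function that flips bits with probability ``tanh(|v|)``.

    See :class:`_BaseSwarmSelector` for parameters and fitted attributes.
    """

    def _run(self, objective, D, config, rng) -> RunResult:
        return run_bpso_mrfl(objective, D, config, rng)


class BinaryPSOSelector(_BaseSwarmSelector):
    """Classic global-best binary PSO baseline.

    Constant learning factors ``c1 = c2 = 2``, linearly decreasing inertia,
    and either the S-shaped (sigmoid sets the bit) or V-shaped (tanh flips
    the bit) transfer function.

    Parameters
    ----------
    transfer : {"s", "v"}
        Which transfer function binarizes the velocities.
    """

    def __init__(
        self,
        transfer: str = "s",
        n_particles: int = 20,
        n_iterations: int = 100,
        omega: float = 0.99,
        n_neighbors: int = 5,
        test_fraction: float = 0.2,
        scale: bool = True,
        w_max: float = 0.9,
        w_min: float = 0.4,
        v_clamp: float = 6.0,
        memoize: bool = False,
        random_state: int | None = None,
    ) -> None:
        super().__init__(
            n_particles=n_particles,
            n_iterations=n_iterations,
            omega=omega,
            n_neighbors=n_neighbors,
            test_fraction=test_fraction,
            scale=scale,
            w_max=w_max,
            w_min=w_min,
            v_clamp=v_clamp,
            memoize=memoize,
            random_state=random_state,
        )
        self.transfer = transfer

    def _run(self, objective, D, config, rng) -> RunResult:
        return run_bpso_baseline(objective, D, config, rng, transfer=self.transfer)
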