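"""scikit-learn estimator facade over the genetic-algorithm fit.

`DispersalSpeedGA` treats the dispersal model as a regressor: X holds site
coordinates (km, raster CRS), y the observed median calibrated ages (cal BP).
``fit`` runs the genetic algorithm to calibrate per-terrain-class friction
costs; ``predict`` returns simulated arrival dates at new coordinates.  The
class composes with sklearn tooling (clone, get_params/set_params,
cross-validation on held-out sites).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .ga import GAConfig, run_ga
from .model import SimulationConfig
from .raster import COST_FLOOR, ClassRaster, accumulate_cost, sample_surface


class DispersalSpeedGA(BaseEstimator, RegressorMixin):
    """Estimate terrain-class-dependent front speeds from dated sites.

    Parameters
    ----------
    raster : ClassRaster
        Terrain-class raster defining the friction-surface topology.
    origin_cell : (row, col)
        Cell the dispersal starts from.
    t0 : float
        Start date at the origin, cal BP.
    v0 : float
        Base front speed in km/yr (cost 1 ⇒ v0; cost c ⇒ v0/c).
    pop_size, n_parents, n_elite, p_mutation, n_generations,
    init_mu, init_sigma, clamp_floor
        Genetic-algorithm hyperparameters; defaults are the published
        settings (500 / 250 / 50 / 0.2 / 20, init N(1,1)).
    random_state : int or None
        Seed for the GA's random generator.

    Attributes
    ----------
    costs_ : ndarray of shape (K,)
        Best per-class friction costs found.
    speeds_ : ndarray of shape (K,)
        Corresponding local speeds v0 / costs_, km/yr.
    rmse_ : float
        RMSE (years) of the best individual.
    trace_ : GATrace
        Per-generation best/mean RMSE and best cost vectors.
    n_evaluations_ : int
        Number of fitness evaluations performed.
    """

    def __init__(
        self,
        raster: ClassRaster = None,
        origin_cell: tuple[int, int] = (0, 0),
        t0: float = 10000.0,
        v0: float = 1.0,
        pop_size: int = 500,
        n_parents: int = 250,
        n_elite: int = 50,
        p_mutation: float = 0.2,
        n_generations: int = 20,
        init_mu: float = 1.0,
        init_sigma: float = 1.0,
        clamp_floor: float = COST_FLOOR,
        random_state: int | None = None,
    ):
        self.raster = raster
        self.origin_cell = origin_cell
        self.t0 = t0
        self.v0 = v0
        self.pop_size = pop_size
        self.n_parents = n_parents
        self.n_elite = n_elite
        self.p_mutation = p_mutation
        self.n_generations = n_generations
        self.init_mu = init_mu
        self.init_sigma = init_sigma
        self.clamp_floor = clamp_floor
        self.random_state = random_state

    def _sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            origin_cell=tuple(self.origin_cell), t0=self.t0, v0=self.v0
        )

    def _ga_config(self) -> GAConfig:
        return GAConfig(
            pop_size=self.pop_size,
            n_parents=self.n_parents,
            n_elite=self.n_elite,
            p_mutation=self.p_mutation,
            n_generations=self.n_generations,
            init_mu=self.init_mu,
            init_sigma=self.init_sigma,
            clamp_floor=self.clamp_floor,
            rng_seed=self.random_state,
        )

    def fit(self, X, y):
        """Calibrate friction costs against observed arrival dates.

        X : array-like (n_sites, 2) of site x, y in km (raster CRS);
        y : array-like (n_sites,) of observed median cal BP.
        """
        if self.raster is None:
            raise ValueError("raster must be set before fitting")
        X, y = check_X_y(X, y, ensure_min_features=2)
        if X.shape[1] != 2:
            raise ValueError("X must have exactly two columns (x_km, y_km)")
        sites = pd.DataFrame({"x": X[:, 0], "y": X[:, 1], "observed_cal_bp": y})
        result = run_ga(self._ga_config(), self.raster, sites, self._sim_config())
        self.costs_ = result.best_costs
        self.speeds_ = result.speeds
        self.rmse_ = result.best_rmse
        self.trace_ = result.trace
        self.n_evaluations_ = result.n_evaluations
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        """Simulated arrival date (cal BP) at each coordinate pair.

        Sites outside the extent or unreachable get NaN.
        """
        check_is_fitted(self, "costs_")
        X = check_array(X)
        surface = accumulate_cost(self.raster, self.costs_, tuple(self.origin_cell))
        sampled = sample_surface(
            surface, pd.DataFrame({"x": X[:, 0], "y": X[:, 1]})
        )
        return self.t0 - sampled["D_km"].to_numpy() / self.v0
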