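"""Model/Results objects: the user-facing fitting surface.

Mirrors the conventions of statistical modelling packages: a model object
is built from data (`from_dataframe`/`from_csv` constructors available),
``fit()`` returns a results object carrying estimates, OFV and
empirical-Bayes diagnostics with a ``summary()`` table, and simulation /
VPC / likelihood-ratio utilities hang off the results.

>>> model = OralPaclitaxelPKModel(dataset, config)
>>> res = model.fit()
>>> print(res.summary())
>>> pd_res = TSP1TurnoverModel(dataset, res).fit()
"""

from __future__ import annotations

import pandas as pd

from . import estimate as est
from .params import ModelConfig, default_config
from .simulate import prediction_corrected_vpc, simulate_typical
from .trial import StudyDataset, read_dataset

__all__ = ["OralPaclitaxelPKModel", "TSP1TurnoverModel", "PopPKResults"]


class PopPKResults:
    """Results wrapper adding simulation and diagnostics to a fit."""

    def __init__(self, result: est.EstimationResult, model):
        self._result = result
        self.model = model

    # estimation payload -------------------------------------------------
    @property
    def params(self) -> dict:
        """Fixed-effect estimates (natural scale)."""
        return dict(self._result.theta)

    @property
    def omega(self) -> dict:
        return dict(self._result.omega)

    @property
    def sigma(self) -> dict:
        return dict(self._result.sigma)

    @property
    def ofv(self) -> float:
        """-2 log (approximate) marginal likelihood at the optimum."""
        return self._result.ofv

    @property
    def etas(self) -> pd.DataFrame:
        """Empirical-Bayes random-effect modes per subject."""
        return self._result.etas

    @property
    def shrinkage(self) -> dict:
        return dict(self._result.shrinkage)

    @property
    def converged(self) -> bool:
        return self._result.success

    @property
    def config(self) -> ModelConfig:
        """The configuration with estimates substituted in."""
        return self._result.config

    def summary(self) -> str:
        return self._result.summary()

    # diagnostics / downstream -------------------------------------------
    def lrt(self, reduced: "PopPKResults", df: int = 1) -> est.LRTResult:
        """Likelihood-ratio test against a nested reduced fit."""
        return est.lrt_compare(self.ofv, reduced.ofv, df)

    def simulate(self, regimen, grid, include_tsp1: bool = False):
        """Typical-value simulation at the fitted parameters."""
        return simulate_typical(regimen, self.config, grid,
                                include_tsp1=include_tsp1)

    def vpc(self, n_sim: int = 1000, bins: int = 8, rng_seed=None,
            **kwargs) -> pd.DataFrame:
        """Prediction-corrected VPC of the fit against its own dataset."""
        return prediction_corrected_vpc(
            self.model.dataset, self.config, n_sim=n_sim, bins=bins,
            rng_seed=rng_seed, **kwargs)

    def __repr__(self):
        state = "converged" if self.converged else "NOT converged"
        return (f"<PopPKResults {self._result.model} fit, "
                f"OFV={self.ofv:.2f}, {state}>")


class OralPaclitaxelPKModel:
    """Population PK model of oral paclitaxel boosted with ritonavir.

    Parameters
    ----------
    dataset
        Study records (doses + paclitaxel observations).
    config
        Initial values and fixed parameters; defaults to the packaged
        configuration.  Parameters not listed in ``estimate*`` stay fixed.
    estimate, estimate_omega, estimate_sigma
        Names of the free fixed effects, random-effect SDs and residual
        SDs.
    """

    def __init__(self, dataset: StudyDataset, config: ModelConfig = None,
                 estimate=("clint0", "vc", "rf_capsule"),
                 estimate_omega=(), estimate_sigma=(),
                 options: est.EstimationOptions | None = None):
        self.dataset = dataset
        self.config = config or default_config()
        self.problem = est.EstimationProblem(
            dataset=dataset, config=self.config,
            estimate=tuple(estimate),
            estimate_omega=tuple(estimate_omega),
            estimate_sigma=tuple(estimate_sigma),
            model="pk",
            options=options or est.EstimationOptions())

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, **kwargs
                       ) -> "OralPaclitaxelPKModel":
        return cls(StudyDataset(records), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "OralPaclitaxelPKModel":
        return cls(read_dataset(path), **kwargs)

    def loglike_components(self):
        """Per-subject Laplace OFV contributions at the initial values."""
        subjects = est.prepare_subjects(self.dataset, self.config)
        omega = est._initial_omega(self.config)
        spec = self.config.random_effects
        return [est._subject_ofv(s, self.config, omega, spec.sigma_pk,
                                 spec.sigma_pd, self.problem.options,
                                 False)[0] for s in subjects]

    def fit(self) -> PopPKResults:
        return PopPKResults(est.fit_population(self.problem), self)


class TSP1TurnoverModel:
    """Sequential TSP-1 turnover PD model on top of a fitted PK model.

    Population PK parameters are frozen at the PK results; individual PK
    random effects are re-estimated jointly with the PD parameters from
    the combined paclitaxel + TSP-1 records (the population-PK-parameters
    sequential approach).
    """

    def __init__(self, dataset: StudyDataset, pk_results: PopPKResults
                 | est.EstimationResult,
                 estimate=("ec50", "ebase"), estimate_omega=("ebase",),
                 estimate_sigma=("pd",),
                 options: est.EstimationOptions | None = None):
        self.dataset = dataset
        self.pk_result = (pk_results._result
                          if isinstance(pk_results, PopPKResults)
                          else pk_results)
        self.estimate = tuple(estimate)
        self.estimate_omega = tuple(estimate_omega)
        self.estimate_sigma = tuple(estimate_sigma)
        self.options = options or est.EstimationOptions()

    def fit(self) -> PopPKResults:
        res = est.fit_pd_sequential(
            self.pk_result, self.dataset, estimate=self.estimate,
            estimate_omega=self.estimate_omega,
            estimate_sigma=self.estimate_sigma, options=self.options)
        return PopPKResults(res, self)
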