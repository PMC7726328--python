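"""Model / Results front-end tying the toolkit together.

:class:`CircuitModel` bundles a circuit description with measurement data
and a parameter search space; ``fit()`` runs the Pareto-ensemble search
and returns :class:`EnsembleFitResults`, which carries the ensemble,
per-parameter summaries with spread, and hooks for simulation and Morris
sensitivity screening over the fitted ranges.

Typical use::

    spec, truth = builtin_circuit("C1")
    data = generate_measurements(spec, truth, seed=1)
    model = CircuitModel(spec, data, transform_from_reference(truth))
    res = model.fit(seed=1)
    print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circuits import CircuitSpec, ParameterSet, builtin_circuit, validate_circuit
from .estimation import (Ensemble, FitOptions, MeasurementSet, ParameterTransform,
                         PenaltySpec, fit_ensemble, transform_from_reference)
from .sensitivity import (MorrisResult, auc_performance, morris_screen,
                          ranges_from_ensemble)
from .simulation import Trajectory, simulate

__all__ = ["CircuitModel", "EnsembleFitResults"]


class CircuitModel:
    """A cell-free TX/TL circuit together with data and a search space.

    Parameters
    ----------
    spec : CircuitSpec
        Circuit structure with characteristic constants.
    measurements : MeasurementSet, optional
        Observed (or synthetic) time courses; required for ``fit``.
    transform : ParameterTransform, optional
        Free-parameter layout with bounds. If omitted and ``start_params``
        is given, a tenfold bracket around it is used.
    start_params : ParameterSet, optional
        Reference parameterization, e.g. the built-in table means.
    penalty : PenaltySpec, optional
        Overshoot penalty appended as an extra objective.
    """

    def __init__(self, spec: CircuitSpec, measurements: MeasurementSet | None = None,
                 transform: ParameterTransform | None = None,
                 start_params: ParameterSet | None = None,
                 penalty: PenaltySpec | None = None):
        diags = validate_circuit(spec)
        if diags:
            raise ValueError("invalid circuit spec:\n  " + "\n  ".join(diags))
        if transform is None and start_params is not None:
            transform = transform_from_reference(start_params)
        self.spec = spec
        self.measurements = measurements
        self.transform = transform
        self.start_params = start_params
        self.penalty = penalty

    @classmethod
    def from_builtin(cls, name: str, measurements: MeasurementSet | None = None,
                     penalty: PenaltySpec | None = None) -> "CircuitModel":
        """Model for a built-in circuit with its mean estimates as start."""
        spec, params = builtin_circuit(name)
        return cls(spec, measurements=measurements, start_params=params,
                   penalty=penalty)

    def simulate(self, params: ParameterSet | None = None, **kwargs) -> Trajectory:
        """Simulate with the given (or the start) parameters."""
        return simulate(self.spec, params or self.start_params, **kwargs)

    def fit(self, seed: int = 0, options: FitOptions | None = None,
            **option_kwargs) -> "EnsembleFitResults":
        """Run the Pareto-ensemble annealing search; reproducible by seed."""
        if self.measurements is None:
            raise ValueError("CircuitModel has no measurements to fit")
        if self.transform is None:
            raise ValueError("CircuitModel has no parameter transform; supply "
                             "one or start_params to derive it from")
        if options is None:
            options = FitOptions(**option_kwargs)
        elif option_kwargs:
            raise TypeError("pass either an options object or keyword options")
        ensemble = fit_ensemble(self.spec, self.transform, self.measurements,
                                options=options, seed=seed, penalty=self.penalty)
        return EnsembleFitResults(self, ensemble)


class EnsembleFitResults:
    """Fit output: the rank-filtered ensemble plus convenience accessors."""

    def __init__(self, model: CircuitModel, ensemble: Ensemble):
        self.model = model
        self.ensemble = ensemble

    @property
    def params(self) -> ParameterSet:
        """Parameter set with the lowest total error in the ensemble."""
        return self.ensemble.best().params

    @property
    def objectives(self) -> np.ndarray:
        return self.ensemble.best().objectives

    def params_table(self) -> pd.DataFrame:
        """Per-parameter ensemble statistics (mean, sd, min, max, best)."""
        mat = self.ensemble.parameter_matrix()
        best = self.params.values
        return pd.DataFrame({
            "mean": mat.mean(), "sd": mat.std(ddof=0),
            "min": mat.min(), "max": mat.max(),
            "best": pd.Series(best),
        })

    def simulate(self, params: ParameterSet | None = None, **kwargs) -> Trajectory:
        return simulate(self.model.spec, params or self.params, **kwargs)

    def sensitivity(self, samples_per_parameter: int = 10_000,
                    top_k: int = 1_000, seed: int | None = None,
                    t_end: float = 16.0) -> MorrisResult:
        """Morris screen over the ensemble's parameter ranges."""
        ranges = ranges_from_ensemble(self.ensemble)
        performance = auc_performance(self.model.spec, t_end=t_end)
        return morris_screen(performance, ranges,
                             samples_per_parameter=samples_per_parameter,
                             top_k=top_k, seed=seed)

    def summary(self) -> str:
        """Human-readable fit report."""
        prov = self.ensemble.provenance
        lines = [
            "Pareto-ensemble fit results",
            "=" * 60,
            f"circuit:            {prov.get('circuit')}",
            f"ensemble size:      {len(self.ensemble)}",
            f"objectives:         {prov.get('objectives')}",
            f"best total error:   {self.ensemble.best().total_error:.6g}",
            f"seed:               {prov.get('seed')}",
            f"failed simulations: {prov.get('failures')}",
            "-" * 60,
            self.params_table().to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
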