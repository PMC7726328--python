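"""Synthetic measurement generation from known ground-truth parameters.

Emulates the statistical structure of cell-free time-course data: a
handful of sample times over a 0-16 h reaction, at least three biological
replicates per point, and error bars that grow with the signal. Noise is
multiplicative Gaussian (sd = CV x true value, truncated at zero), and the
reported uncertainty is the 95% confidence half-width of the replicate
mean using the t-distribution appropriate for small replicate counts.

These generators let the estimation and sensitivity machinery be exercised
against a known truth without any laboratory data.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .circuits import CircuitSpec, ParameterSet
from .estimation import MeasurementSeries, MeasurementSet
from .simulation import simulate

__all__ = ["generate_measurements", "DEFAULT_SAMPLE_TIMES"]

#: Sampling schedule spanning the reaction window (h): dense early, where
#: mRNA equilibrates, sparser late where protein saturates.
DEFAULT_SAMPLE_TIMES = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0)


def generate_measurements(spec: CircuitSpec, truth: ParameterSet,
                          sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES,
                          noise_cv: float = 0.1, replicates: int = 3,
                          species_subset: Sequence[str] | None = None,
                          seed: int | None = None) -> MeasurementSet:
    """Simulate ``spec`` under ``truth`` and sample noisy replicate means.

    ``species_subset`` defaults to every gene's mRNA and protein (the
    species a fluorescence/qPCR experiment would observe). With
    ``noise_cv = 0`` the means equal the model outputs exactly and all
    confidence intervals are zero. Reproducible for a fixed seed.
    """
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0 (got {noise_cv})")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1 (got {replicates})")
    times = np.asarray(sorted(sample_times), dtype=float)
    if times.size == 0 or times[0] < 0:
        raise ValueError("sample_times must be non-negative and non-empty")

    observable = spec.mrna_species() + [g.name for g in spec.genes]
    if species_subset is None:
        species_subset = observable
    else:
        unknown = set(species_subset) - set(spec.species_names())
        if unknown:
            raise KeyError(f"species not in the model: {sorted(unknown)}")

    t_end = max(float(times[-1]), 1.0)
    traj = simulate(spec, truth, t_end=t_end)
    rng = np.random.default_rng(seed)
    # 95% two-sided t multiplier for the CI of the mean of `replicates` draws
    tcrit = (stats.t.ppf(0.975, replicates - 1) if replicates > 1 else 0.0)

    series = []
    for sp in species_subset:
        true_vals = traj.at(sp, times)
        if noise_cv == 0.0:
            means, ci = true_vals.copy(), np.zeros_like(true_vals)
        else:
            draws = true_vals[None, :] * (
                1.0 + noise_cv * rng.standard_normal((replicates, times.size)))
            draws = np.maximum(draws, 0.0)
            means = draws.mean(axis=0)
            if replicates > 1:
                sem = draws.std(axis=0, ddof=1) / np.sqrt(replicates)
                ci = tcrit * sem
            else:
                ci = np.zeros_like(means)
        series.append(MeasurementSeries(species=sp, times=times, means=means,
                                        ci95=ci, n_replicates=replicates))
    return MeasurementSet(series)
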