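"""Morris elementary-effects screening over ensemble-derived ranges.

The screen perturbs one parameter at a time: each parameter's range (taken
from the min/max across a fitted ensemble) is subdivided into a grid of
levels; for every sample a random base point is drawn on the grid, the
target parameter is moved to a different level, and the change in the
performance function — the area under the curve of each model species —
per unit parameter change is recorded as an elementary effect. For each
parameter the effects with the largest parameter steps (the best global
secants) are retained, and their mean and variance summarize direct
influence and nonlinearity/interaction respectively.

Elementary effects are raw secant slopes (output change per unit parameter
change), so on a linear performance function the mean effect equals the
coefficient exactly. For cross-parameter comparison and binning, effects
are additionally scaled by each parameter's range width (``scaled_means``),
making them the output change across a full range traversal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .circuits import CircuitSpec
from .estimation import Ensemble
from .simulation import SimulationError, area_under_curve, simulate

__all__ = ["MorrisResult", "ranges_from_ensemble", "morris_screen",
           "bin_sensitivities", "auc_performance"]

DEFAULT_SAMPLES = 10_000
DEFAULT_TOP_K = 1_000


@dataclass
class MorrisResult:
    """Elementary-effect statistics: parameters x outputs matrices."""

    parameters: list[str]
    outputs: list[str]
    means: np.ndarray  # raw mean elementary effect, per unit parameter
    variances: np.ndarray
    scaled_means: np.ndarray  # mean effect x range width
    ranges: dict[str, tuple[float, float]]
    samples_per_parameter: int
    evaluations: int  # perturbed-point model evaluations
    base_evaluations: int
    failures: int = 0

    def __post_init__(self):
        shape = (len(self.parameters), len(self.outputs))
        for name in ("means", "variances", "scaled_means"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            setattr(self, name, arr)
        if np.any(self.variances < -1e-30):
            raise ValueError("variances must be non-negative")

    def to_frame(self, which: str = "means") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, which), index=self.parameters,
                            columns=self.outputs)

    def to_csv(self, prefix) -> None:
        for which in ("means", "variances", "scaled_means"):
            self.to_frame(which).to_csv(f"{prefix}_{which}.csv")


def ranges_from_ensemble(ensemble: Ensemble) -> dict[str, tuple[float, float]]:
    """Per-parameter (min, max) across ensemble members.

    Degenerate ranges (a parameter constant across the ensemble) are
    widened by ±1% with a warning so the screen can still perturb them.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    df = ensemble.parameter_matrix()
    ranges: dict[str, tuple[float, float]] = {}
    for name in df.columns:
        lo, hi = float(df[name].min()), float(df[name].max())
        if lo == hi:
            pad = 0.01 * abs(lo) if lo != 0 else 0.01
            warnings.warn(f"parameter '{name}' is constant across the ensemble; "
                          f"widening its range by ±1%", RuntimeWarning)
            lo, hi = lo - pad, hi + pad
        ranges[name] = (lo, hi)
    return ranges


def auc_performance(spec: CircuitSpec, t_end: float = 16.0,
                    output_step: float = 0.01,
                    species: Sequence[str] | None = None) -> Callable:
    """Performance function mapping a named parameter dict to per-species AUC.

    Species default to every mRNA and protein state of the circuit.
    Integration failures propagate as :class:`SimulationError` and are
    counted (and the sample dropped) by :func:`morris_screen`.
    """
    from .circuits import ParameterSet

    targets = list(species) if species is not None else (
        spec.mrna_species() + spec.protein_species())

    def performance(values: Mapping[str, float]) -> dict[str, float]:
        traj = simulate(spec, ParameterSet(dict(values), spec.name),
                        t_end=t_end, output_grid=output_step)
        return {s: area_under_curve(traj, s) for s in targets}

    return performance


def morris_screen(performance: Callable[[Mapping[str, float]], Mapping[str, float]],
                  ranges: Mapping[str, tuple[float, float]],
                  samples_per_parameter: int = DEFAULT_SAMPLES,
                  top_k: int = DEFAULT_TOP_K,
                  seed: int | None = None) -> MorrisResult:
    """One-at-a-time elementary-effects screen.

    ``performance`` maps a complete parameter dict to a mapping of output
    name -> scalar. Each parameter contributes exactly
    ``samples_per_parameter`` perturbed-point evaluations (plus the same
    number of base-point evaluations, reported separately), and its top
    ``top_k`` effects by parameter-step size enter the mean/variance.
    Reproducible for a fixed seed.
    """
    names = list(ranges)
    lo = np.array([ranges[n][0] for n in names], dtype=float)
    hi = np.array([ranges[n][1] for n in names], dtype=float)
    if not np.all(np.isfinite(lo) & np.isfinite(hi)) or np.any(lo >= hi):
        raise ValueError("ranges must be finite with min < max")
    if samples_per_parameter < 1:
        raise ValueError("samples_per_parameter must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(names)
    levels = samples_per_parameter  # grid subdivisions of each range
    grid = [np.linspace(lo[i], hi[i], max(levels, 2)) for i in range(n)]

    outputs: list[str] | None = None
    effects: list[list[np.ndarray]] = [[] for _ in range(n)]
    steps: list[list[float]] = [[] for _ in range(n)]
    evaluations = base_evaluations = failures = 0

    def call(point: np.ndarray) -> np.ndarray | None:
        nonlocal outputs, failures
        try:
            res = performance(dict(zip(names, point)))
        except SimulationError:
            failures += 1
            return None
        if outputs is None:
            outputs = list(res)
        return np.array([res[k] for k in outputs], dtype=float)

    for i in range(n):
        base_idx = rng.integers(0, max(levels, 2), size=(samples_per_parameter, n))
        # perturbed level differs from the base level in coordinate i
        offsets = rng.integers(1, max(levels, 2), size=samples_per_parameter)
        pert_idx = (base_idx[:, i] + offsets) % max(levels, 2)
        for s in range(samples_per_parameter):
            base = np.array([grid[j][base_idx[s, j]] for j in range(n)])
            f_base = call(base)
            base_evaluations += 1
            point = base.copy()
            point[i] = grid[i][pert_idx[s]]
            f_pert = call(point)
            evaluations += 1
            if f_base is None or f_pert is None:
                continue
            delta = point[i] - base[i]
            effects[i].append((f_pert - f_base) / delta)
            steps[i].append(abs(delta))

    if outputs is None:
        raise SimulationError("every Morris sample failed to evaluate")

    means = np.zeros((n, len(outputs)))
    variances = np.zeros((n, len(outputs)))
    for i in range(n):
        if not effects[i]:
            continue
        ee = np.vstack(effects[i])
        order = np.argsort(np.asarray(steps[i]))[::-1][:top_k]
        kept = ee[order]
        means[i] = kept.mean(axis=0)
        variances[i] = kept.var(axis=0)
    scaled = means * (hi - lo)[:, None]

    return MorrisResult(parameters=names, outputs=outputs, means=means,
                        variances=variances, scaled_means=scaled,
                        ranges={k: tuple(v) for k, v in ranges.items()},
                        samples_per_parameter=samples_per_parameter,
                        evaluations=evaluations,
                        base_evaluations=base_evaluations, failures=failures)


def bin_sensitivities(result: MorrisResult, n_bins: int = 4) -> pd.DataFrame:
    """Categorical influence matrix from none (0) to high (n_bins - 1).

    Scaled mean effects are normalized per output to [0, 1] by their
    maximum magnitude, then equal-width binned; bin 0 is reserved for
    exactly-zero effects, so the matrix is invariant to rescaling any
    output by a positive constant.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mag = np.abs(result.scaled_means)
    bins = np.zeros_like(mag, dtype=int)
    for j in range(mag.shape[1]):
        col = mag[:, j]
        top = col.max()
        if top == 0:
            continue
        norm = col / top
        nz = norm > 0
        bins[nz, j] = np.minimum(
            (np.floor(norm[nz] * (n_bins - 1)) + 1).astype(int), n_bins - 1)
    return pd.DataFrame(bins, index=result.parameters, columns=result.outputs)
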