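"""Assembly and integration of the circuit ODE system.

Each gene j contributes two balances,

    dm_j/dt = r_X,j * u_j - theta_m,j * m_j
    dp_j/dt = r_L,j * w_j - theta_p,j * p_j

where r_X and r_L are the kinetic limits, u_j is the promoter-occupancy
control function evaluated from the instantaneous regulator protein
concentrations, and w_j equals the translational capacity state eps, which
is carried as one extra ODE state with deps/dt = -(0.693 / t_half) * eps.
Constitutive regulator proteins (sigma70) decay first-order with no source.

The system is stiff when degradation rates and promoter weights span
orders of magnitude, so integration defaults to scipy's LSODA with
rtol 1e-6 / atol 1e-8 nM. Small negative integrator excursions are clipped
inside the degradation terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .circuits import CircuitSpec, ParameterSet, apply_parameters
from .kinetics import (TranscriptionParameters, TranslationParameters,
                       coupling_term, transcription_limit, translation_limit,
                       vmax_transcription, vmax_translation)
from .regulation import CAPACITY_DECAY_CONSTANT, promoter_probability

__all__ = ["Trajectory", "build_rhs", "simulate", "area_under_curve",
           "default_grid", "SimulationError"]

DEFAULT_T_END = 16.0  # h
DEFAULT_STEP = 0.01  # h


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails; carries solver diagnostics."""


@dataclass
class Trajectory:
    """Time-indexed concentrations of every model species.

    ``data`` maps species name to an array aligned with ``times``; mRNA
    species are named ``mRNA_<gene>``, proteins carry the gene or
    constitutive species name, and ``capacity`` is the dimensionless
    translational-capacity fraction.
    """

    times: np.ndarray
    data: dict[str, np.ndarray]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        for name, vals in self.data.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.times.shape:
                raise ValueError(f"species '{name}' has {vals.size} values for "
                                 f"{self.times.size} time points")
            self.data[name] = vals

    @property
    def species(self) -> list[str]:
        return list(self.data)

    def __getitem__(self, species: str) -> np.ndarray:
        if species not in self.data:
            raise KeyError(f"species '{species}' not in trajectory "
                           f"(have {self.species})")
        return self.data[species]

    def at(self, species: str, t) -> np.ndarray | float:
        """Linearly interpolate a species onto arbitrary times within range."""
        values = np.interp(t, self.times, self[species])
        return float(values) if np.isscalar(t) else values

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time_h, species, concentration_nM."""
        frames = [
            pd.DataFrame({"time_h": self.times, "species": name,
                          "concentration_nM": vals})
            for name, vals in self.data.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_grid(t_end: float = DEFAULT_T_END, step: float = DEFAULT_STEP) -> np.ndarray:
    n = int(round(t_end / step))
    return np.linspace(0.0, t_end, n + 1)


def build_rhs(spec: CircuitSpec, params: ParameterSet | None = None,
              enable_coupling: bool = False, u_override: dict | None = None):
    """Compile the circuit into a ``f(t, y) -> dy/dt`` evaluator.

    State layout: gene mRNAs, gene proteins, constitutive proteins,
    capacity — the order of ``spec.species_names()``. ``u_override`` pins
    the transcription control value of named genes to a constant, which is
    useful when the promoter state is known to be time-invariant.
    """
    if params is not None:
        spec = apply_parameters(spec, params)
    c = spec.constants
    genes = spec.genes
    n_genes = len(genes)
    const_species = spec.constitutive_species
    u_override = dict(u_override or {})
    unknown = set(u_override) - {g.name for g in genes}
    if unknown:
        raise KeyError(f"u_override names unknown genes: {sorted(unknown)}")

    tx_params, tl_params = [], []
    theta_m, theta_p = [], []
    for g in genes:
        missing = [f for f in ("tx_time_constant", "tl_time_constant")
                   if getattr(g, f) is None]
        if missing:
            raise KeyError(f"gene '{g.name}' is missing {missing}")
        tx_params.append(TranscriptionParameters(
            vmax=vmax_transcription(c.rnap_total, c.tx_elongation_rate,
                                    g.gene_length),
            saturation=c.tx_saturation,
            time_constant=g.tx_time_constant))
        tl_params.append(TranslationParameters(
            vmax=vmax_translation(c.ribosome_total, c.polysome_gain,
                                  c.tl_elongation_rate, g.protein_length),
            saturation=c.tl_saturation,
            time_constant=g.tl_time_constant))
        theta_m.append(g.mrna_deg_modifier * c.mrna_deg_default)
        theta_p.append(g.protein_deg_modifier * c.protein_deg_default)
    theta_const = [s.protein_deg_modifier * c.protein_deg_default
                   for s in const_species]

    gene_concs = np.array([g.gene_conc for g in genes])
    tx_sats = np.array([p.saturation for p in tx_params])
    tx_taus = np.array([p.time_constant for p in tx_params])
    tl_sats = np.array([p.saturation for p in tl_params])
    tl_taus = np.array([p.time_constant for p in tl_params])
    protein_names = [g.name for g in genes] + [s.name for s in const_species]
    decay = CAPACITY_DECAY_CONSTANT / c.capacity_halflife

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        m = y[:n_genes]
        p = y[n_genes:n_genes + len(protein_names)]
        eps = y[-1]
        # clip tiny negative excursions when feeding regulators/degradation
        m_pos = np.maximum(m, 0.0)
        p_pos = np.maximum(p, 0.0)
        regs = dict(zip(protein_names, p_pos))

        dy = np.empty_like(y)
        for j, g in enumerate(genes):
            if g.name in u_override:
                u = u_override[g.name]
            else:
                u = promoter_probability(spec.promoters[g.name], regs,
                                         c.temperature)
            ox = (coupling_term(j, gene_concs, tx_sats, tx_taus)
                  if enable_coupling else 0.0)
            ol = (coupling_term(j, m_pos, tl_sats, tl_taus)
                  if enable_coupling else 0.0)
            r_x = transcription_limit(gene_concs[j], tx_params[j], ox)
            r_l = translation_limit(m_pos[j], tl_params[j], ol)
            dy[j] = r_x * u - theta_m[j] * m_pos[j]
            dy[n_genes + j] = r_l * eps - theta_p[j] * p_pos[j]
        for k, _s in enumerate(const_species):
            i = n_genes + n_genes + k
            dy[i] = -theta_const[k] * p_pos[n_genes + k]
        dy[-1] = -decay * eps
        return dy

    return rhs


def simulate(spec: CircuitSpec, params: ParameterSet | None = None,
             t_end: float = DEFAULT_T_END, output_grid=DEFAULT_STEP,
             initial: dict | None = None, rtol: float = 1e-6,
             atol: float = 1e-8, method: str = "LSODA",
             enable_coupling: bool = False,
             u_override: dict | None = None) -> Trajectory:
    """Integrate the circuit ODEs and return a :class:`Trajectory`.

    ``output_grid`` is either a uniform step (h) or an explicit array of
    output times starting at 0. ``initial`` overrides initial conditions by
    species name; unspecified mRNA/protein states start at 0 (constitutive
    species at their declared concentration) and capacity at 1.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0 (got {t_end})")
    if params is not None:
        spec = apply_parameters(spec, params)
        params = None
    t_eval = (default_grid(t_end, output_grid) if np.isscalar(output_grid)
              else np.asarray(output_grid, dtype=float))

    names = spec.species_names()
    y0 = np.array([spec.initial_value(s) for s in names])
    if initial:
        unknown = set(initial) - set(names)
        if unknown:
            raise KeyError(f"initial conditions name unknown species: "
                           f"{sorted(unknown)}")
        for s, v in initial.items():
            y0[names.index(s)] = v

    rhs = build_rhs(spec, enable_coupling=enable_coupling,
                    u_override=u_override)
    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), y0, method=method,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    data = {name: np.maximum(sol.y[i], 0.0) if name != "capacity" else sol.y[i]
            for i, name in enumerate(names)}
    return Trajectory(times=sol.t, data=data)


def area_under_curve(traj: Trajectory, species: str) -> float:
    """Trapezoidal integral of one species over the full output grid (nM*h)."""
    return float(np.trapezoid(traj[species], traj.times))
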