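"""Control functions for transcription (u) and translation (w).

Transcriptional control follows the statistical-mechanical treatment of
promoter occupancy: each promoter configuration i has a Boltzmann weight
W_i = exp(-dG_i / RT) and a bound fraction f_i given by a Hill function of
its regulator's concentration (f = 1 for configurations with no bound
regulator). The control value is the probability of being in an expressing
configuration,

    u = sum_{i in X} W_i f_i / sum_{j in C} W_j f_j

where X is the expressing subset, C all configurations, and the ground
state contributes weight 1 to the denominator. Repressor-bound
configurations are non-expressing, so they appear only in the denominator
and pull u down as the repressor accumulates.

Translational control reflects the finite lifetime of the extract's
translational machinery: the remaining capacity eps decays exponentially,
eps(t) = exp(-0.693 t / t_half), and w = eps for every translation process.
The 0.693 constant is used as such (rather than ln 2) so that the closed
form and the ODE state match the model definition digit-for-digit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

from .circuits import PromoterModel, R_GAS

__all__ = [
    "TranslationCapacity",
    "hill_fraction",
    "configuration_weight",
    "promoter_probability",
    "capacity_value",
    "CAPACITY_DECAY_CONSTANT",
]

#: Decay constant of the translational-capacity half-life law (kept as the
#: truncated 0.693, not ln 2).
CAPACITY_DECAY_CONSTANT = 0.693

#: |dG| above this (kJ/mol) is clamped to avoid exp overflow in the weights.
MAX_GIBBS_MAGNITUDE = 150.0


@dataclass
class TranslationCapacity:
    """Remaining translational activity: a fraction and its decay half-life."""

    value: float = 1.0
    halflife: float = 4.0  # h

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"capacity value must lie in [0, 1] (got {self.value})")
        if self.halflife <= 0:
            raise ValueError(f"capacity halflife must be > 0 (got {self.halflife})")


def hill_fraction(conc: float, dissociation_constant: float,
                  hill_coefficient: float) -> float:
    """Fraction of bound regulator, c^n / (K^n + c^n), in [0, 1)."""
    if conc < 0:
        raise ValueError(f"concentration must be >= 0 (got {conc})")
    if dissociation_constant <= 0 or hill_coefficient <= 0:
        raise ValueError("dissociation constant and Hill coefficient must be > 0")
    if conc == 0.0:
        return 0.0
    # evaluate via the ratio to stay stable for extreme K or n
    ratio = (conc / dissociation_constant) ** hill_coefficient
    return ratio / (1.0 + ratio)


def configuration_weight(gibbs_energy: float, temperature: float) -> float:
    """Boltzmann weight exp(-dG / RT) of one promoter configuration.

    dG in kJ/mol, temperature in K. Magnitudes beyond 150 kJ/mol are clamped
    with a warning: exp(150 / RT) would overflow a double at reaction
    temperatures.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K (got {temperature})")
    if abs(gibbs_energy) > MAX_GIBBS_MAGNITUDE:
        warnings.warn(
            f"|gibbs_energy| = {abs(gibbs_energy):.3g} kJ/mol clamped to "
            f"{MAX_GIBBS_MAGNITUDE} to avoid overflow", RuntimeWarning)
        gibbs_energy = math.copysign(MAX_GIBBS_MAGNITUDE, gibbs_energy)
    return math.exp(-gibbs_energy / (R_GAS * temperature))


def promoter_probability(model: PromoterModel,
                         regulator_concs: Mapping[str, float],
                         temperature: float) -> float:
    """Probability u in [0, 1] that the promoter is in an expressing state.

    ``regulator_concs`` must supply a concentration (nM) for every regulator
    referenced by the model's configurations.
    """
    numerator = 0.0
    denominator = 0.0
    for conf in model.configurations:
        if conf.is_ground:
            denominator += 1.0
            continue
        w = configuration_weight(conf.gibbs_energy, temperature)
        if conf.binding is None:
            f = 1.0
        else:
            b = conf.binding
            if b.regulator not in regulator_concs:
                raise KeyError(
                    f"no concentration supplied for regulator '{b.regulator}' "
                    f"of configuration '{conf.label}'")
            f = hill_fraction(regulator_concs[b.regulator],
                              b.dissociation_constant, b.hill_coefficient)
        term = w * f
        denominator += term
        if conf.expressing:
            numerator += term
    if denominator == 0.0:
        return 0.0
    return min(numerator / denominator, 1.0)


def capacity_value(t: float, halflife: float) -> float:
    """Closed-form remaining translational capacity exp(-0.693 t / t_half)."""
    if t < 0:
        raise ValueError(f"time must be >= 0 (got {t})")
    if halflife <= 0:
        raise ValueError(f"halflife must be > 0 (got {halflife})")
    return math.exp(-CAPACITY_DECAY_CONSTANT * t / halflife)
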