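"""Kinetic limits of transcription and translation.

The polymerase (or ribosome) is treated as a pseudo-enzyme that binds its
template, elongates, and dissociates. The resulting saturation rate law for
the kinetic limit of transcription of gene j is

    r_X,j = Vmax_X,j * G_j / (tau_X,j * K_X,j + (1 + tau_X,j) * G_j + O_X,j)

with Vmax_X,j = R_X,T * vdot_X / l_G,j, and symmetrically for translation
with mRNA in place of gene template and Vmax_L,j = K_P * R_L,T * vdot_L /
l_P,j. tau is the dimensionless initiation-to-elongation time-constant
ratio: as tau -> 0 the reaction becomes elongation-limited and r -> Vmax;
as the template concentration grows, r -> Vmax / (1 + tau).

O is an optional coupling term expressing competition of the templates for
the shared polymerase/ribosome pool. With it, the rate law is the standard
competitive-binding form

    r_j / Vmax_j = (c_j / K_j tau_j) / (1 + sum_i (1 + tau_i) c_i / K_i tau_i)

For circuits with only a handful of genes the coupling is negligible and
defaults to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TranscriptionParameters",
    "TranslationParameters",
    "vmax_transcription",
    "vmax_translation",
    "transcription_limit",
    "translation_limit",
    "coupling_term",
]


@dataclass
class TranscriptionParameters:
    """Saturation rate-law constants for one gene (nM/h, nM, dimensionless)."""

    vmax: float
    saturation: float
    time_constant: float

    def __post_init__(self):
        if min(self.vmax, self.saturation, self.time_constant) <= 0:
            raise ValueError("transcription parameters must be strictly positive")


@dataclass
class TranslationParameters:
    """Saturation rate-law constants for one message (nM/h, nM, dimensionless)."""

    vmax: float
    saturation: float
    time_constant: float

    def __post_init__(self):
        if min(self.vmax, self.saturation, self.time_constant) <= 0:
            raise ValueError("translation parameters must be strictly positive")


def vmax_transcription(rnap_total: float, elongation_rate: float,
                       gene_length: float) -> float:
    """Maximum transcription rate R_X,T * vdot_X / l_G in nM/h."""
    if gene_length <= 0:
        raise ValueError(f"gene_length must be > 0 (got {gene_length})")
    return rnap_total * elongation_rate / gene_length


def vmax_translation(ribosome_total: float, polysome_gain: float,
                     elongation_rate: float, protein_length: float) -> float:
    """Maximum translation rate K_P * R_L,T * vdot_L / l_P in nM/h."""
    if protein_length <= 0:
        raise ValueError(f"protein_length must be > 0 (got {protein_length})")
    return polysome_gain * ribosome_total * elongation_rate / protein_length


def _saturation_limit(conc: float, vmax: float, K: float, tau: float,
                      coupling: float) -> float:
    if conc < 0:
        raise ValueError(f"template concentration must be >= 0 (got {conc})")
    if coupling < 0:
        raise ValueError(f"coupling term must be >= 0 (got {coupling})")
    denom = tau * K + (1.0 + tau) * conc + coupling
    return vmax * conc / denom if conc > 0 else 0.0


def transcription_limit(gene_conc: float, params: TranscriptionParameters,
                        coupling: float = 0.0) -> float:
    """Kinetic limit of transcription r_X (nM/h) at gene concentration G (nM)."""
    return _saturation_limit(gene_conc, params.vmax, params.saturation,
                             params.time_constant, coupling)


def translation_limit(mrna_conc: float, params: TranslationParameters,
                      coupling: float = 0.0) -> float:
    """Kinetic limit of translation r_L (nM/h) at message concentration m (nM)."""
    return _saturation_limit(mrna_conc, params.vmax, params.saturation,
                             params.time_constant, coupling)


def coupling_term(target_index: int, concentrations, saturations,
                  time_constants) -> float:
    """Competition of template j with the other templates for the shared pool.

    O_j = sum_{i != j} (K_j tau_j / K_i tau_i) * (1 + tau_i) * c_i, in nM.
    Zero for a single-template system.
    """
    c = np.asarray(concentrations, dtype=float)
    K = np.asarray(saturations, dtype=float)
    tau = np.asarray(time_constants, dtype=float)
    if not (c.shape == K.shape == tau.shape) or c.ndim != 1 or c.size < 1:
        raise ValueError("concentrations, saturations, time_constants must be "
                         "equal-length 1-D sequences")
    j = target_index
    if not 0 <= j < c.size:
        raise IndexError(f"target_index {j} out of range for {c.size} templates")
    terms = (K[j] * tau[j] / (K * tau)) * (1.0 + tau) * c
    return float(terms.sum() - terms[j])
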