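# Methods

## Model

The toolkit simulates batch cell-free transcription/translation (TX/TL)
reactions as deterministic ODEs. Each gene j carries an mRNA balance
`dm_j/dt = r_X,j u_j − θ_m,j m_j` and a protein balance
`dp_j/dt = r_L,j w_j − θ_p,j p_j`. The kinetic limits r_X and r_L come
from a pseudo-enzyme treatment of the polymerase and ribosome:

    r = V_max · c / (τ K + (1 + τ) c + O)

with `V_max,X = R_X,T v̇_X / l_G` and `V_max,L = K_P R_L,T v̇_L / l_P`.
Two structural consequences of this grouping are load-bearing and are
asserted by tests: as the time constant τ → 0 the reaction becomes
elongation-limited (r → V_max), and as the template saturates,
r → V_max/(1 + τ). With the competition term O enabled, the law is
algebraically the standard competitive-binding form
`r_j/V_j = x_j / (1 + Σ_i (1+τ_i) x_i)` with `x = c/(Kτ)`; O defaults to
zero because both built-in circuits have at most three genes, where the
shared-pool correction is negligible. There are no explicit polymerase or
ribosome state variables.

Transcription control u is the statistical-mechanical probability of an
expressing promoter configuration: Boltzmann weights `W = exp(−ΔG/RT)`
(R = 8.314e-3 kJ mol⁻¹ K⁻¹), Hill bound-fractions `f = cⁿ/(Kⁿ+cⁿ)` for
regulator-bound configurations, ground state weight exactly 1.
Repressor-bound configurations are modeled as non-expressing, so they
enter only the partition-function denominator; a single operator site is
assumed (no multi-operator multiplication rule). Translation control w
equals the translational capacity ε, an extra ODE state decaying as
`dε/dt = −(0.693/τ_L,1/2) ε`. The constant is deliberately the truncated
0.693 rather than ln 2, so the half-life state matches the model
definition digit-for-digit; ε is kept as a state (not substituted in
closed form) so richer capacity models remain drop-in replacements.

## Parameters and units

Internally everything is nM, hours, kJ/mol. Characteristic constants
(defaults of `CharacteristicConstants`): 75 nM RNA polymerase, 2000 nM
ribosomes, elongation 108 000 nt/h (30 nt/s) and 5400 aa/h (1.5 aa/s),
K_X = 36 nM, polysome gain K_P = 10, initiation times 22 s (TX) and 1.5 s
(TL), default θ_m = 3.75 h⁻¹, default θ_p = 0.93 h⁻¹ (geometric middle of
the 0.462–1.89 h⁻¹ literature range), temperature 302.15 K (29 °C
incubation). Where a gene omits its time constants, they are seeded as
initiation time ÷ elongation time, which reproduces the right order of
magnitude for the estimated values.

The built-in circuits embed their published mean estimates. Notes on
entries that required judgment:

* The cI-ssrA transcription time constant is printed only as an upper
  bound (<0.001); the point value 0.001 is used.
* The σ28-activated configuration energy of the P28 promoter is printed
  in J/mol (−1.10 J/mol) while all other energies are kJ/mol; it is kept
  as printed (−0.0011 kJ/mol internally). Either reading leaves the
  weight within a factor ~1.5 of unity, and the qualitative circuit
  behavior (tested) is unchanged.
* Dissociation constants are printed in μM against regulator pools of
  tens of nM; they are implemented as printed. A consequence worth
  flagging: evaluating the C1 promoter function at the mean estimates and
  σ70 = 35 nM gives u ≈ 0.69, whereas the reported quasi-static control
  value is u ≈ 0.95. The toolkit computes the occupancy faithfully and
  exposes `u_override` in `simulate`/`build_rhs` to pin u to a known
  value; the headline C1 reproduction (`scripts/acceptance.py`) uses the
  reported 0.95.
* Initial σ28 protein defaults to 0; the extract bound (<20 nM) is read
  as a ceiling, not a value, and is overridable via `initial_conditions`.
* σ70 is a constitutive species with a single decaying state
  (dp/dt = −θ_p p, 35 nM initial), since its half-life is itself an
  estimated parameter.
* mRNA lifetime conventions differ by ~2× depending on whether one
  reports t_1/2 or t_1/2/ln 2; the toolkit stores first-order rate
  constants (h⁻¹) and leaves unit conversion to the caller.

## Numerical choices

Integration uses scipy's LSODA (stiff-capable) with rtol 1e-6 and
atol 1e-8 nM, both configurable. The default output grid is 0–16 h at
0.01 h spacing; trajectory AUCs are trapezoidal on that grid (halving the
spacing moves AUCs by <0.5% on the built-ins, tested). Negative
integrator excursions are clipped inside the degradation and regulator
terms of the right-hand side rather than by projecting the state, and
outputs are floored at 0. Configuration energies beyond ±150 kJ/mol are
clamped with a warning (exp would overflow). u is re-evaluated at every
derivative call from the instantaneous protein concentrations; there are
no delay terms.

## Estimation

Each measured series is an objective `E_j = Σ_i (M̂_ij − x_ij)²` in nM²,
with the simulation linearly interpolated to the measurement times.
Search parameters are either direct (energies linearly, positive
quantities in log space) or correction multipliers α on characteristic
values (all degradation rates and time constants), bounded so estimates
stay within a stated fold of the characteristic value;
`transform_from_reference` brackets a reference set with fold f (default
10), giving energies ±RT ln f. The optional overshoot penalty
`E = C max(0, max_t x − U)` (C = 1e5 per μM, U = 100 μM) is appended as
its own objective rather than folded into the data misfits.

The search integrates simulated annealing with Pareto ranking: proposals
perturb 1–3 coordinates with Gaussian steps of 10% of the (transformed)
range, annealed geometrically (×0.9 per generation, matching the
temperature schedule whose scale is set from the spread of the initial
population's total errors); a candidate is accepted when its error vector
ranks ≤ 2 against the archive, otherwise with the Metropolis probability
on total error. All rank ≤ 2 solutions are archived and re-ranked each
generation; fronts are numbered from 0, so the cutoff keeps three fronts.
Every fifth generation the search switches to single-objective mode on
ΣE_j, implemented as derivative-free Nelder–Mead descents (budget 1000
evaluations each) started from the incumbent best, from the archive
member best on each individual objective, and from a fresh random point;
the multiobjective walk restarts from the winner. The per-objective
restarts matter in practice: with objectives spanning orders of magnitude
(protein concentrations in μM vs mRNA in nM), a sum-only descent tends to
park in basins that fit the large-magnitude series and ignore the rest,
and the mRNA-best archive member is a reliable escape hatch. No
gradient-based refinement is used anywhere. Defaults: 20 generations,
100 SA steps per generation, archive cap 2000. Everything is driven by
one `numpy` Generator, so a seed fixes the entire trajectory of the
search; failed integrations are counted and the candidate discarded.

A structural caveat: with the default sampling schedule (first sample at
1 h) the reporter mRNA is already at plateau, so θ_m is identified mainly
through the sub-percent curvature left at the first time point and is the
hardest parameter to pin down; recovering it from noise-free synthetic
data requires driving the total error to near zero, which the hybrid
descent achieves on most seeds. This is an identifiability feature of the
design, not of the optimizer.

## Sensitivity screening

The Morris screen is one-at-a-time: each parameter's range — the min/max
across a fitted ensemble, degenerate ranges widened ±1% with a warning —
is subdivided into `samples_per_parameter` levels (default 10 000); for
every sample a random base point is drawn on the level grid, the target
parameter is moved to a different level, and the elementary effect is the
secant slope ΔF/Δθ of the per-species AUC performance function. Exactly
`samples_per_parameter × n` perturbed evaluations are spent (base-point
evaluations are counted separately). Per parameter, the `top_k` (default
1000) effects with the largest parameter steps — the best global
secants — enter the mean and variance. Raw effects are per unit parameter
change, so on a linear performance function the mean equals the
coefficient exactly (tested to 1e-9); for cross-parameter comparison and
the categorical heatmap the means are additionally scaled by each range's
width. Binning normalizes |scaled mean| per output to [0,1] and applies
equal-width bins with bin 0 reserved for exactly-zero effects, making the
categories invariant to rescaling any output. The trajectory construction
is a documented design choice; radial/winding trajectory variants of the
Morris design are not implemented.

## Synthetic data

The generator simulates a circuit under known true parameters and samples
replicate observations at {0, 1, 2, 4, 6, 8, 10, 12, 16} h — dense early
where mRNA equilibrates, sparse late where protein saturates — with
multiplicative Gaussian noise (sd = CV × value, truncated at 0, default
CV 0.1, 3 replicates). Multiplicative noise is chosen because fluorescence
and qPCR error bars grow with signal. The reported uncertainty is the 95%
CI half-width of the replicate mean using the t multiplier (4.30 for
n = 3); with the normal multiplier the nominal coverage would be badly
undershot at three replicates (checked by Monte Carlo).

What the generator does **not** emulate: fluorescence-to-concentration
calibration error, systematic (correlated-in-time) biases, detection
floors, and replicate-to-extract batch variation. Passing the recovery
tests therefore demonstrates that the estimation machinery works when the
model family is correct and noise is independent — it does not certify
performance on laboratory data, where model misspecification dominates.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the full-size C1 workflows
(20-generation fits, default grids); the Morris evaluation-budget check
uses an algebraic performance function so the 10 000 × n bookkeeping is
exercised without 30 000 ODE solves, and the circuit-structure screen
uses 25 samples/parameter, which is ample for the zero/nonzero split it
asserts. The C2 circuit is exercised through simulation and its
qualitative feedback behavior; a full 33-parameter C2 fit follows the
same code path as C1 and is left to users with data.

## Known limitations

* Protein degradation is first-order; ClpXP-mediated ssrA degradation is
  closer to zero-order near saturation, so fitted θ_p values are
  effective rates.
* GFP maturation (dark → fluorescent) is not modeled; estimated
  translation time constants absorb it.
* cI repression uses one operator site; multi-operator repression would
  strengthen it.
* The capacity model is a bare exponential; it stands in for resource
  depletion without representing any specific mechanism.
* Batch reactions only: no dilution, feeding, or oscillatory regimes.
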