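# Methods

This note documents the models, estimators, numerical choices and known
limitations of `mutcycle`.

## States, tables and the cycle algebra

A protein *state* is an unordered set of point mutations (the wild type
is the empty set); at most one mutation may occupy a (chain, position).
All free energies are in kJ/mol.  A `DDGTable` stores edges
ΔΔG<sub>reference</sub><sup>target</sup> between a reference state and a
strictly larger target state.  Because free energy is a state function,
any chain of edges connecting two states must sum to the same ΔΔG; the
package exploits this in two ways:

* `compose_path` resolves a missing ΔΔG by summing edges along the
  shortest connecting chain (edges may be traversed backwards with
  flipped sign).  Ties between equal-length chains are broken by the
  lexicographic order of the chain's state labels, making the choice
  deterministic.  As a diagnostic it can enumerate all simple chains
  (capped at 5,000) and report the largest disagreement between any two
  chain sums — zero on a thermodynamically consistent table.
* `triple_box` computes the pair coupling in a third-mutation background
  either directly from C-referenced edges or by the decomposition into
  the wild-type coupling plus four C-introduction legs.  The two forms
  are algebraically identical (both reduce to
  G(ABC) − G(AC) − G(BC) + G(C)); the test suite verifies the identity
  to 1e-10 kJ/mol on randomized consistent tables.

**Unfolded-state cancellation.**  ΔΔG values of unfolding may be computed
from the folded-state leg alone under the assumption that mutational
effects are additive in the unfolded state.  The unfolded contribution is
then a per-mutation constant that cancels from every nonadditivity; such
estimates are flagged `offset_relative`, and the offset invariance of δ
is tested exactly.

**Error propagation.**  Uncertainties combine in quadrature under the
assumption of independent table edges.  Propagation operates on the
*unique* edges entering a quantity, each weighted by its net
coefficient: when a composed pathway shares an edge with a
single-mutation term, the shared edge's contributions cancel in value
and therefore contribute no uncertainty.  This keeps quoted δ
uncertainties calibrated (replicate simulations agree with the quoted
quadrature within 20% in the test suite) instead of double-counting
shared legs.  Covariance between genuinely different edges (e.g. legs
sharing equilibrium ensembles) is not modelled.

**Charge-changing mutations** (D/E vs K/R, histidine treated as neutral)
carry a metadata flag (`MutationSpec.is_charge_changing`) but are treated
like any other edge in the table algebra; no charge corrections are
applied.  A pair is called *correlated* when
|δ| > max(1.0 kJ/mol, 2·uncertainty); both constants are arguments.

## Work-based free-energy estimators

A `WorkSet` holds forward (WT→mutant) and reverse (mutant→WT) work
samples, each stored as the work done on the system in that leg's own
direction; estimators negate reverse work internally.  kT uses
k = 0.008314462618 kJ/(mol·K) and the default temperature is 298.15 K.

* **BAR** solves the Bennett self-consistency condition
  Σ<sub>f</sub> f(β(W−ΔG)+M) = Σ<sub>r</sub> f(β(W′+ΔG)−M), with f the
  Fermi function and M = ln(n_f/n_r), by bracketed Brent root-finding on
  [min−10σ, max+10σ] of the pooled work values, tolerance 1e-8 kJ/mol.
  The residual is monotone, so the root is unique.  When the forward and
  negated-reverse samples occupy disjoint ranges the residual is
  numerically flat in the gap and a root finder would silently return an
  arbitrary point; this case raises an explicit overlap error instead.
* **CGI** fits Normal densities to the forward and negated-reverse work
  and returns their intersection: the midpoint of the means for equal
  fitted variances, otherwise the quadratic root lying between the means
  (no such root — possible when the means are close and the variances
  differ — is an explicit failure).
* **Jarzynski** returns −kT·ln⟨e^(−βW)⟩ (log-sum-exp stabilised) for one
  direction, sign-flipped for the reverse.  Its finite-sample bias is
  upward in the forward and downward in the reverse direction, so the
  two one-sided estimates bracket BAR *in expectation*; per replicate
  the ordering is blurred by sampling noise, which is why the test
  asserts the mean gaps over 200 replicates rather than per-replicate
  bracketing.

**Bootstrap errors** resample each direction independently with
replacement (forward indices drawn before reverse each iteration, PCG64
generator) and report the n−1 standard deviation of the re-estimates;
default 100 resamples.  Estimator failure on more than half of the
resamples is an error.

## Synthetic ground truth

The landscape model assigns each state
G(S) = Σ singles + Σ pair couplings inside S + Σ triangular terms whose
pair and third mutation all lie in S, with G(WT) = 0.  A pair coupling c
plants δ<sub>WT</sub><sup>AB</sup> = c; a triangular term t shifts the
coupling in the C background to c + t, so t = −c reproduces a
coupling-erasing third mutation, t of opposite sign beyond −2c an
inverting one, and so on.  Default effect sizes: singles uniform on
±8 kJ/mol (typical point-mutation stability changes), pair couplings and
triangular terms uniform on ±10 kJ/mol, spanning the strongest pair
couplings measured experimentally (≈10.5 kJ/mol).  Work samples are drawn
from the unique per-direction Normal family exactly satisfying the
Crooks relation: forward ~ N(ΔG + βσ²/2, σ²), reverse
~ N(−ΔG + βσ²/2, σ²); this makes analytic checks (closed-form Jarzynski
limit, histogram log-ratio slope β) possible.

What the generator does **not** emulate: force-field energetics,
conformational sampling problems (e.g. glycine backbone flexibility),
non-Gaussian work distributions from fast switching, correlated legs,
and unfolded-state structure.  Passing tests therefore demonstrate the
correctness of the estimators and the cycle algebra, not the accuracy of
any molecular simulation protocol.

## Scans, classification, benchmarking, distances

A positional scan substitutes the 19 non-wild-type residues (by default)
at an external site, computes δ<sub>C</sub><sup>AB</sup> per substitution
via the triple box, and reports the mean unsigned coupling with its
standard error (sample n−1 SD / √n).  Substitutions without table
coverage are excluded and reported, not fatal.  `classify_change` labels
a coupling change as erased / emergent / inverted / amplified / retained
with an additive threshold of 1.0 kJ/mol by default (the order of typical
δ uncertainties); the branches are checked in a fixed order so exactly
one label applies.

Benchmarking reports the average unsigned error, Pearson r, ordinary
least squares of calculated on experimental values (the regression
direction is a package convention), and the fraction of points within
±1 kcal/mol (4.184 kJ/mol) by default.  Zero-variance inputs yield a
typed "undefined" (None / `"undefined"` in JSON) rather than NaN.
Distance stratification uses half-open bins [e_i, e_{i+1}) and flags bins
with fewer than two points as insufficient.

Structures are read from PDB text (gemmi-backed); only ATOM records of
the first model are used, alternate locations resolved by highest
occupancy (ties by altloc letter, blank first), insertion codes appended
to the residue identifier.  Distances: Cα–Cα or minimum over heavy-atom
pairs; `min_heavy` is the default for stratification since it reflects
side-chain proximity.

## Pipeline and determinism

All randomness flows from one top-level seed: per-edge work-generation
and bootstrap seeds are spawned from it via a `SeedSequence` tree in a
fixed (sorted-edge-label) order, so runs with equal configurations are
byte-identical, and adding or removing edges does not perturb other
edges' draws.  Reports contain no timestamps.

Problem sizes used in the shipped checks — 200 seeds × 5,000 work
samples per direction for estimator recovery, 200 planted pairs at 300
work samples per direction (σ = 2 kJ/mol, 50 bootstrap resamples) for
end-to-end recovery, 1,000 random tables for the triple-box identity —
were chosen to give stable statistics at interactive runtimes.

## Known limitations

* Independent-leg quadrature understates errors when legs share sampled
  ensembles; no covariance model is provided.
* BAR variance is bootstrap-only; no analytic (Fisher-information)
  variance estimate is implemented.
* The CGI estimator is undefined when fitted variances differ and the
  means nearly coincide; callers should fall back to BAR.
* PDB support covers single-model ATOM records; mmCIF, assemblies and
  symmetry mates are out of scope.
* The scan assumes the ΔΔG table was produced for the same wild-type
  residue at the scanned position that the caller passes; the table
  itself does not carry that information.
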