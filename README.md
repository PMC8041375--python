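# mutcycle

Thermodynamic-coupling analysis of protein mutations: double-mutant-cycle
nonadditivities, triple-mutant-box decompositions, mutational scans of
third-site effects, and calculation-vs-experiment benchmarking — built on
work-based free-energy estimators and a synthetic ground-truth generator.

## The problem

Two mutations A and B in a protein rarely act independently. With
ΔΔG<sub>WT</sub><sup>X</sup> the change in unfolding free energy when
mutation set X is introduced into the wild type, the **nonadditivity**

δ<sub>WT</sub><sup>AB</sup> = ΔΔG<sub>WT</sub><sup>AB</sup> − ΔΔG<sub>WT</sub><sup>A</sup> − ΔΔG<sub>WT</sub><sup>B</sup>

measures their thermodynamic coupling: δ = 0 means the mutations are
perfectly additive, δ ≠ 0 means they are correlated.  A **triple mutant
box** extends the cycle with an external third mutation C; the coupling in
the C background can be computed either directly,

δ<sub>C</sub><sup>AB</sup> = ΔΔG<sub>C</sub><sup>ABC</sup> − ΔΔG<sub>C</sub><sup>AC</sup> − ΔΔG<sub>C</sub><sup>BC</sup>,

or by the exact state-function decomposition

δ<sub>C</sub><sup>AB</sup> = δ<sub>WT</sub><sup>AB</sup> + ΔΔG<sub>AB</sub><sup>ABC</sup> + ΔΔG<sub>WT</sub><sup>C</sup> − ΔΔG<sub>A</sub><sup>AC</sup> − ΔΔG<sub>B</sub><sup>BC</sup>.

A third mutation can erase, amplify, invert, or create a pair coupling —
even from a distant site — which is why scanning all substitutions at an
external position against a fixed coupled pair (e.g. L37A+G79S in
staphylococcal nuclease) is a core operation here.

The ΔΔG values themselves come from non-equilibrium alchemical
transformations: forward (WT→mutant) and reverse (mutant→WT) work samples
connected by the Crooks fluctuation theorem,
P<sub>f</sub>(W)/P<sub>r</sub>(−W) = e<sup>β(W−ΔG)</sup>.  The package
implements the Bennett acceptance ratio (BAR), the Crooks Gaussian
intersection (CGI) and the one-sided Jarzynski estimators with seeded
bootstrap errors.  In place of molecular-dynamics output, a synthetic
module plants free-energy landscapes with known pairwise and *triangular*
couplings (pair couplings modulated by third-site identity) and draws
exactly Crooks-consistent Gaussian work samples, so every stage of the
pipeline is testable against ground truth.

## Worked example

Draw work samples for a planted ΔG = 5 kJ/mol leg and estimate it back:

```bash
$ mutcycle simulate work --dg 5.0 --sigma 2.0 --n 1000 --seed 7 \
      --out-forward fwd.dat --out-reverse rev.dat
$ mutcycle estimate --forward fwd.dat --reverse rev.dat --method bar \
      --bootstrap 100 --seed 1
{
  "method": "bar",
  "value_kJmol": 4.947829643304871,
  "uncertainty_kJmol": 0.04827507645760514,
  "n_forward": 1000,
  "n_reverse": 1000,
  "temperature_K": 298.15
}
```

BAR recovers the planted 5 kJ/mol within its bootstrap standard error.
Next, plant a landscape whose pair coupling is modulated by a third site
and evaluate the couplings from its ΔΔG table:

```bash
$ mutcycle simulate landscape --sites 6 --pairs 2 --triangles 1 --seed 7 --out model.json
$ mutcycle simulate ddg --model model.json --out ddg.csv
$ mutcycle cycle nonadd --table ddg.csv --pair C5H,W1N
{
  "pair": "C5H+W1N",
  "reference": "WT",
  "delta_kJmol": 0.09096517915906688,
  "uncertainty_kJmol": 0.0
}
$ mutcycle cycle triplebox --table ddg.csv --pair C5H,W1N --third G6V
{
  "pair": "C5H+W1N",
  "third": "G6V",
  "delta_kJmol": 10.000970847846919,
  ...
}
```

In the wild type the pair C5H+W1N is essentially additive
(δ ≈ 0.09 kJ/mol, the planted coupling); in the G6V background the
planted triangular term of 9.91 kJ/mol turns it into a strong coupling
(δ ≈ 10.0 kJ/mol) — an *emergent* coupling controlled by a third residue.
The same operations are available as library calls
(`mutcycle.nonadditivity`, `mutcycle.triple_box`,
`mutcycle.positional_scan`, `mutcycle.compare`, ...), and
`mutcycle pipeline` chains simulate → estimate → cycle end to end from a
single seed.

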