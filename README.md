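# cypene

Multistate reaction energetics of α- and β-pinene hydroxylation by a
cytochrome P450 (CYP) compound-I model: corrected Gibbs free-energy
assembly, Boltzmann conformer populations along the reaction coordinate,
quasi-RRHO thermochemistry, Eyring transition-state-theory kinetics, and
reaction-profile reports and diagrams.

## The problem

CYP monooxygenases hydroxylate hydrocarbons by a two-step radical
mechanism: the iron(IV)-oxo species abstracts a substrate hydrogen
(reactant complex **I** → abstraction TS **II** → carbon radical + Fe–OH
**III**), then the radical rebounds onto the hydroxyl to give the alcohol
(**IV**). Because the iron center has several close-lying spin surfaces
(doublet, quartet, sextet) and pinenes offer many abstraction sites — two
of which bear diastereotopic *cis*/*trans* allylic hydrogens — a single
substrate yields a whole ensemble of competing routes. Which product
dominates is a question of statistics over that ensemble:

- relative stability: ΔG = (G_i − G_ref)·627.5095 kcal/mol,
- equilibrium populations: p_i ∝ exp(−G_i/k_B T),
- kinetics: k = (k_B T/h)·exp(−ΔG‡/RT).

`cypene` implements that post-processing layer for tabulated
stationary-point energies (the DFT calculations themselves are upstream):
it aggregates additive corrections (D4 dispersion, geometric-counterpoise
BSSE, quasi-harmonic entropy) into corrected free energies, computes
populations and barriers, and assembles per-path descriptor tables
(Δ_rE, ΔE‡, Δ_rH, ΔH‡, Δ_rG, ΔG‡, corrected variants, and the
hydroxylation free energy) plus multi-path free-energy diagrams. A
quasi-RRHO thermochemistry module (harmonic-oscillator entropy damped
toward a free rotor below ~100 cm⁻¹) covers the case where only a
frequency list is available. The printed data tables of the underlying
study ship as packaged fixtures, and a seeded synthetic-ensemble generator
with an independent analytic population oracle backs the test suite.

## Worked example

The dominant radical conformers of β-pinene, recomputed from the packaged
coordinate-III free energies at 298.15 K:

```text
$ cypene reproduce-paper --molecule beta
beta-pinene radical ensemble (coordinate III) at 298.15 K:
  alpha-doublet            1.93e-15 %
  alpha-quartet            7.48e-16 %
  delta-trans-doublet      53.4 %
  delta-cis-doublet        46.1 %
  delta-cis-quartet        0.147 %
  delta-trans-quartet      0.322 %
  delta-cis-sextet         0.00209 %
  delta-trans-sextet       0.00685 %
dominant radical: delta-trans-doublet (53.4 %)
```

Hydrogen abstraction funnels into an almost 50:50 mixture of the *trans*
and *cis* delta-site radicals on the doublet surface; every other route is
below half a percent. The same command with `--molecule alpha` gives the
α-pinene ensemble, dominated by the epsilon-site trans-doublet radical
(86.4 %) over its cis partner (13.6 %).

Barriers translate to rates through the Eyring equation:

```text
$ cypene eyring --barrier 10.8 --compare 12.4
k = 7.530211e+04 s^-1 (barrier 10.8 kcal/mol, T 298.15 K)
k(barrier)/k(compare) = 14.887
```

i.e. the fastest abstraction path (ΔG‡ = 10.8 kcal/mol, delta-trans
doublet) outruns the 12.4 kcal/mol cis-doublet path ~15-fold at room
temperature.

Other subcommands: `populations` (Boltzmann table for any stage of a
stationary-point CSV), `thermo` (RRHO / quasi-RRHO corrections from a
frequency list), `profile` (descriptor report + diagram from a
stationary-point table), `simulate` (synthetic ensembles with known
populations), `validate` (schema lint). The same functionality is
available as a library:

```python
from cypene import boltzmann_populations
from cypene.fixtures import ensemble_from_fixture

table = boltzmann_populations(ensemble_from_fixture("beta_coordIII"))
print(table.to_frame().round(3))
```

## Layout

- `cypene.energetics` — domain types (species labels, correction sets,
  stationary points), unit conversion, relative energies
- `cypene.thermochem` — RRHO / quasi-RRHO thermal corrections
- `cypene.statmech` — ensembles, Boltzmann populations, Eyring kinetics
- `cypene.profiles` — reaction paths, descriptors, reports, diagrams
- `cypene.fixtures` / `cypene.synthetic` — packaged study tables and the
  seeded synthetic generator with its analytic oracle
- `cypene.analysis`, `cypene.config`, `cypene.cli` — end-to-end pipeline,
  run configuration, command line

See `docs/methods.md` for the model, parameter defaults, numerical
choices, and known limitations (including two documented inconsistencies
in the printed source tables).
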