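# Methods

## Scope and model

`cypene` post-processes stationary-point energetics for the hydrogen
abstraction and oxygen-rebound ("hydroxylation") chemistry of α- and
β-pinene at a cytochrome P450 (CYP) compound-I model. The electronic
structure itself — geometry optimization, frequencies, dispersion (D4),
geometric-counterpoise BSSE, and continuum solvation — is upstream of this
package: stationary points arrive as tabulated energies (hartree) with the
additive corrections already evaluated. The package owns everything after
that point:

1. **Correction aggregation and relative energies.** A corrected free
   energy is `G_cor = G(E+thermal) + ΔE_disp + ΔE_gCP + ΔE_qh (+ ΔE_solv)`,
   a plain sum of finite terms. Relative energies subtract a reference —
   either the most stable member of the set (first occurrence on ties) or
   an explicitly named species — and convert to kcal/mol with
   1 Eh = 627.5095 kcal/mol. Energies stay in hartree internally; the
   conversion happens once, at the reporting boundary.

2. **Boltzmann conformer populations.** At a reaction-coordinate stage the
   equilibrium mole fraction of conformer *i* is
   `p_i = exp(−(G_i − G_min)/k_B T) / Σ_j exp(−(G_j − G_min)/k_B T)` with
   `k_B = 3.166811563e-6 Eh/K` applied directly to free energies in
   hartree (no per-mole conversion is needed for a ratio). The minimum is
   subtracted before exponentiation so weights never overflow; populations
   are therefore invariant under any uniform shift of the free energies.
   No degeneracy factors are applied: each conformer is one state.

3. **Eyring kinetics.** `k = κ·(k_B T/h)·exp(−ΔG‡/RT)` with κ = 1 by
   default (no tunneling/recrossing correction) and ΔG‡ in kcal/mol.
   `rate_ratio` exposes the prefactor-free ratio
   `exp((ΔG‡₂ − ΔG‡₁)/RT)`.

4. **Quasi-RRHO thermochemistry.** Ideal-gas corrections at (T, P) from a
   harmonic mode list: Sackur–Tetrode translation, rigid-rotor rotation
   with symmetry number, harmonic ZPE and vibrational thermal energy, and
   electronic entropy `k_B·ln g`. Low-frequency torsions are handled by
   damping each mode's harmonic entropy toward a free-rotor entropy,
   `S_mode = w·S_HO + (1−w)·S_FR` with `w(ν) = 1/(1+(ν₀/ν)^α)`; the
   free-rotor moment `μ = h/(8π²cν)` is reduced against an average
   molecular moment, `μ′ = μB_av/(μ+B_av)`. Only the entropy is damped;
   enthalpy stays harmonic. Imaginary modes are dropped with a warning —
   they never contribute.

5. **Reaction profiles.** A path strings stages I (reactant complex), II
   (abstraction TS), III (radical + Fe–OH) and IV (hydroxylated product)
   for one site/spin/stereo route. Δ_r quantities are III−I, barriers are
   II−I, the hydroxylation free energy is IV−I, each in the matching
   energy column (electronic, enthalpy, uncorrected G, corrected G). A
   missing rebound TS is a first-class barrierless segment, not an error:
   at the underlying level of theory that transition state could not be
   located, and hydrogen abstraction is the rate-limiting step. Diagrams
   anchor every path to one global zero, the most stable stage-I structure
   across all paths.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| temperature | 298.15 | K | standard conditions; reproduces the study's printed populations to the printed digit |
| pressure | 1 | atm | ideal-gas standard state for translational entropy |
| hartree→kcal/mol | 627.5095 | kcal·mol⁻¹·Eh⁻¹ | reproduces the printed kcal cells; configurable |
| k_B (hartree scale) | 3.166811563e-6 | Eh·K⁻¹ | CODATA; population exponents |
| ν₀ | 100 | cm⁻¹ | canonical quasi-RRHO crossover: a 100 cm⁻¹ mode is treated half-harmonic, half-free-rotor |
| α | 4 | – | canonical damping sharpness |
| B_av | 1e-44 | kg·m² | canonical average molecular moment for the free-rotor reduction |
| κ (transmission) | 1 | – | no tunneling model is prescribed |
| frequency scaling | none | – | unscaled harmonic frequencies |

All are exposed through `RunConfig` (YAML/JSON, CLI flags take precedence).

## Data and fixtures

The nine printed tables of the study ship as packaged CSVs (ASCII
minus-signs; the loader returns them verbatim with provenance metadata).
Two caveats are encoded in the data rather than hidden:

- **Stage II/III/IV absolute free energies are not printed.** Reaction-path
  fixtures therefore reconstruct them as *stage-I anchor + printed
  descriptor*, and such points carry `note="reconstructed"`. Descriptor
  reports over these paths reproduce the printed descriptor tables by
  construction; the non-trivial, genuinely recomputed results are the
  population tables and the relative-energy tables, which derive from
  printed absolute free energies.
- **One reactant-complex row is internally inconsistent.** In the
  α-pinene coordinate-I table the alpha-quartet free energy implies a
  negligible Boltzmann weight, yet the printed population is 20.9 %. All
  other rows of that table share a single scale factor of ≈1/(1−0.209)
  relative to recomputation — exactly what a mistyped free energy plus
  correct downstream arithmetic would produce. The row is packaged
  verbatim, tagged `suspect=true`, surfaced as an analysis flag, and
  checked via pairwise population ratios (which cancel the bogus
  normalization) rather than per-row percentages.

Three relative-energy cells of the β-pinene bare-system table (zeta and
theta radicals, epsilon-trans hydroxylated product) recompute to within
0.006 kcal/mol of a rounding boundary and round the other way from the
printed digit — the published cells were evidently derived from unrounded
free energies. They are asserted within one unit in the last printed place;
the other 32 cells reproduce exactly at printed precision.

## Synthetic generator

`EnsembleSpec` emulates the *structure* of the study ensembles — a handful
of conformer/spin states separated by gaps of a few kcal/mol at 298.15 K
(uniform, exponential, or explicit gaps; seed-deterministic). It does not
emulate geometries, realistic electronic energies, or correlations between
spin state and stability; passing closed-loop tests therefore demonstrates
the correctness of the population arithmetic, not the realism of any
free-energy surface. The analytic population calculator bundled with the
generator is deliberately a second, naive implementation (direct
exponentials on the kcal scale, no max-subtraction) so it can serve as an
independent oracle; its kT is derived from the same constant pair the main
route uses (`k_B[Eh/K] × 627.5095`), because two routes can only agree to
1e-10 if their constants are mutually consistent. `SpectrumSpec` generates
sorted positive wavenumber lists with at most one leading imaginary mode
(a transition state's signature).

## Numerical choices

- Ties in auto-minimum referencing: first occurrence in input order wins.
- Population shift-invariance holds to 1e-9 (float representation of
  ~2×10³ Eh absolute energies limits it to ~1e-12 in practice).
- The quasi-RRHO high-frequency limit is asserted in absolute terms
  (|S_qRRHO − S_RRHO| < 1e-4·k_B for stiff spectra): the harmonic entropy
  of a stiff mode decays exponentially while the free-rotor admixture falls
  only as (ν₀/ν)^α, so a relative comparison diverges even as both terms
  vanish.
- Report cells round to three significant figures (the typical printed
  precision); machine-readable outputs always carry full precision.
- The g-consistency invariant (`g = g_uncorrected + corrections` within
  1e-9 Eh) is enforced at construction whenever both operands are present.
- SVG diagrams are hand-written polyline documents so that output is
  byte-deterministic for snapshot testing.

## Known limitations and open questions

- No hindered-rotor torsional scans, no anharmonic (VPT2) corrections, no
  concentration standard-state correction, no spin-crossover (MECP) rates:
  crossing between the near-degenerate doublet and quartet surfaces is
  treated qualitatively, as in the source analysis.
- The narrative claim that the delta-trans-doublet abstraction is "three
  and two times faster" than the delta-cis quartet/doublet paths is not
  recoverable from the printed barriers (10.8 vs 13.6/12.4 kcal/mol) under
  the Eyring treatment at 298.15 K — those give ≈113× and ≈15×. The ratio
  machinery is implemented and property-tested; the discrepancy is left as
  a documented open question.
- Thermochemistry is validated by closed-form oracles and property tests,
  not against study numbers: the study prints no frequency lists.
- Bare-species rows carry a nominal doublet multiplicity (the label schema
  admits only the enzyme-complex spin states; the bare radicals genuinely
  are doublets, the closed-shell hydroxylated products reuse the
  placeholder).

## Problem sizes

Everything here is desk-scale: ensembles of 8–10 conformers, 8–10 paths
per molecule, spectra of ≤ 20 modes, and 100-ensemble randomized
cross-checks. The full test suite and the reproduction script each run in
seconds on one CPU.
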