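# Methods

## Scope and model

`polyamine-builder` builds coarse-grained (Martini-3-style) models of
hyperbranched polyethylenimine (PEI).  A PEI molecule is represented as an
acyclic graph of monomer units, one bead per ethylenimine repeat unit,
classified by amine chemistry:

| unit | amine     | valence | neutral bead | charged bead | size  |
|------|-----------|---------|--------------|--------------|-------|
| T    | primary   | 1       | TN6d         | TQ5d         | tiny  |
| L    | secondary | 2       | SN4          | SQ4p         | small |
| D    | tertiary  | 3       | SN3a         | SQ3p         | small |

Bonded interactions are a harmonic bond potential
`V_bond(R) = 1/2 K_bond (R − R_bond)²` and a cosine-harmonic angle potential
`V_angle(θ) = 1/2 K_angle (cos θ − cos θ0)²`; topologies therefore emit
GROMACS bond function 1 and angle function 2.  Nonbonded parameters are never
emitted — they live in the published Martini 3 force-field files, referenced
by an include path in the optional `.top` wrapper.

The degree of branching uses the Hölter measure `DB = 2D/(2D+L)` over
dendritic (D) and linear (L) unit counts.  On any complete tree built from
valences 1/2/3 the handshake lemma forces `count(T) = count(D) + 2`; this
identity is asserted throughout the test suite and is the basis for
reconstructing compositions from partial information (e.g. 4 terminal amines
and DB = 33% fix a 14-mer with D = 2, L = 8).

## Bonded parametrization

Reference bond/angle series (extracted upstream from atomistic simulations by
standard trajectory tools; this package reads plain single-column text) are
histogrammed with Freedman–Diaconis binning, density-normalized, and fitted
with a sum of one to three Gaussians by nonlinear least squares
(`scipy.optimize.curve_fit`, multi-start: smoothed-histogram local maxima
first, quantile seeds as fallback).  The component count is selected by a
BIC-style corrected residual score so single-mode distributions are not
force-split into three components.

Fitting happens in the coordinate where the potential is harmonic — bond
length for bonds, cos θ for angles — because there the Boltzmann weight of
each component is exactly Gaussian with variance `k_B T / K_i` (with `k_B`
taken as the gas constant R = 8.314 J mol⁻¹ K⁻¹ and T defaulting to
298.15 K).  Observed angle series are transformed value-wise to cos θ before
histogramming, which absorbs the sin θ Jacobian exactly.

Peak weights are the analytic Gaussian areas `S_i = A_i σ_i √(2π)`,
normalized: `w_i = S_i / Σ S_i`.  Reduction to a single Martini parameter
excludes components with `K_i < 1` (native units — kJ mol⁻¹ nm⁻² for bonds,
kJ mol⁻¹ for angles, one rule for both kinds) or `w_i < 0.1%`; these barely
affect fit quality but would dominate the harmonic mean.  Surviving weights
are renormalized and

    equilibrium = Σ w_i x0_i        (degrees for angles, averaged after
                                     back-conversion from cos-space)
    1 / K       = Σ w_i / K_i       (weighted harmonic mean)

The harmonic mean guarantees the reduced K lies between the retained
components' extremes; this is property-tested.

Open choices resolved here: weights use analytic areas (not bin-summed
areas), and angle equilibria are averaged in degrees, not in cos θ.  Both are
stated as package conventions; neither changes single-peak results.

## Synthetic reference distributions

The fixture generator inverts the model: components are chosen by weight and
values drawn from the component Gaussian in the harmonic coordinate, with
rejection sampling into the physical range (R > 0; cos θ ∈ [−1, 1]).  The
restriction-by-rejection is exactly the Boltzmann distribution restricted to
physical values, so least-squares fits of the unrestricted Gaussian shape
remain unbiased (the truncation only rescales the amplitude).  What the
generator does **not** emulate: correlations between neighbouring bonds,
anharmonic tails, and the influence of charged groups on the distributions
(the parametrization convention is charge-free; Coulombic terms superpose at
simulation time).  Passing round-trip tests therefore demonstrate estimator
correctness, not force-field accuracy for any particular chemistry.

Round-trip accuracy asserted in tests: equilibria within 1% and force
constants within 10% at n = 10⁵ samples, for K ∈ [500, 20000] kJ mol⁻¹ nm⁻²
(bonds) and K ∈ [10, 500] kJ mol⁻¹ (angles).

## Polymer generator

Growth starts from an initiator bead — a secondary amine with two open
valences — and proceeds breadth-first over a FIFO queue holding one entry per
open valence, so all branches grow in parallel as in the chemical
polymerization.  Per open end, in order:

1. termination draw: with probability `p_term` (default 0.05, per growth
   step) the branch is capped with a terminal unit;
2. otherwise a dendritic unit is added with probability
   `p_D = DB/(2 − DB)` and a linear unit otherwise.

`p_D` is derived from the Hölter relation: additions in ratio
`D : L = p_D : (1 − p_D)` give `2D/(2D+L) = DB` in expectation.  (The
alternative relation `DB/(1−DB) = D/L` is algebraically inconsistent with
the Hölter form by a factor of two and is not used.)

Growth stops when the *projected* mass — placed monomers plus one terminal
cap per remaining open end, at the nominal repeat mass 43.07 Da — reaches the
target; remaining open ends are then capped.  A step adds at most two
monomers to the projected mass, so the default mass tolerance of two monomer
masses is always satisfiable.  If termination exhausts all open ends early
the attempt fails; up to `max_attempts` (default 100) attempts are made
before an error reporting the best attempt's mass.  A single seeded
`numpy.random.Generator` drives one build; ensemble member *i* uses seed
`base + i`.

Finite-size behaviour: the initiator contributes one linear unit regardless
of target, and small targets amplify its weight, so realized mean DB sits
slightly below target for ~30-mers (about 2–3 percentage points at 1.3 kDa
and DB 61.5%) and within half a point at 10 kDa.  This bias is inherent to
initiator-seeded growth, not a calibration artifact.

Coordinates are embedded breadth-first: each child is placed exactly at its
bond type's equilibrium distance from its parent, in a random (seeded)
direction resampled until the angle at the parent exceeds 30° — a geometric
sanity constraint, not an energy minimization.  Bead overlaps are permitted;
relaxing them is the MD engine's soft-core minimization job.  The cubic box
edge is the maximum coordinate extent plus a 2 nm margin.

## Protonation presets

Two preset pH levels set the protonated fraction per amine class:

| class     | pH 7.4 | pH 5.5 |
|-----------|--------|--------|
| primary   | 66%    | 100%   |
| secondary | 33%    | 66%    |
| tertiary  | 0%     | 33%    |

Percentages are taken literally (0.66, 0.33), counts are rounded half-up,
and the protonated sites within a class are chosen uniformly at random with
a stated seed (which sites are protonated is not specified by the preset;
charge-adjacency effects only matter at protonation levels above these
presets and are out of scope).  Charged beads carry +1 e and the bead name
swaps per the table above.  For titratable-bead workflows every unit is
annotated with a pKa: 10.6 for primary amines, 10.2 for secondary and
tertiary.

## File emission

GRO (fixed-column, nm), ITP (`[moleculetype]/[atoms]/[bonds]/[angles]`,
single residue "PEI", atom names = kind letter + index), a per-bead
heavy-atom mapping table (T: N,C; L: C,N,C; D: C,N,C,C) for backmapping, a
SMILES sidecar (one N per monomer, one CC bridge per bond; depth-first from
the lowest-numbered leaf, validity and atom counts are the contract, not
canonicality), and a charge/pKa sidecar.  Outputs are byte-identical across
runs for fixed inputs: titles carry a content hash, never a timestamp.
Topology conservation laws — atoms = monomers, bonds = monomers − 1,
angles = Σ C(degree, 2), Σq = total charge — are asserted over 1000 random
polymers in the acceptance suite.

The shipped `default_param_table()` contains round-number placeholders
(0.33 nm / 8000 kJ mol⁻¹ nm⁻² bonds; 130° / 50 kJ mol⁻¹ angles) so that
generated topologies are syntactically complete; they are not fitted values
and users are expected to regenerate the table from their own atomistic
distributions.

## Analysis conventions

- **N/P ratio**: `copies × N_per_molecule / phosphates`, with one amine
  nitrogen per monomer and phosphates counted as internal phosphodiester
  linkages (nucleotides − 1 per strand; 50 for the 25/27-mer DsiRNA duplex).
  All nitrogens count regardless of protonation (the conventional
  definition); a charged-N-only variant sits behind a flag.  Computed as
  `copies × (N/P)` so linearity in copy number is exact in floating point.
- **Radius of gyration**: `√(Σ mᵢ|rᵢ − r_cm|²/Σ mᵢ)`, mass-weighted by
  Martini size-class masses (tiny 36 Da, small 54 Da) or unweighted.
- **PMF → ΔG**: the binding free energy is the well depth relative to the
  unbound plateau — the curve is shifted so the plateau mean (default
  window: final 20% of the distance range) is zero and the global minimum is
  reported.  A unique global minimum inside the plateau window makes the
  reference ill-posed and raises.  Integrating the area under the curve is a
  recognized alternative reduction; well depth was chosen because it is
  shift-invariant and robust to the choice of upper integration limit.

## Problem sizes and determinism

Default verification runs use ensembles of 200 polymers (at 1.3 and 10 kDa
targets) for branching-recovery checks, 10⁵-sample distributions for fit
round trips, and 1000 small random polymers (0.4–1.8 kDa) for file-format
conservation laws.  Every stochastic path takes an explicit integer seed;
`scripts/acceptance.py --seed N --out f.json` derives all sub-seeds from N
and rewrites the same JSON for the same N.

## Known limitations

- The generator controls DB and MW in expectation; it does not reproduce a
  synthesis-specific molecular-weight distribution or branching correlations
  along the backbone.
- Embedded coordinates satisfy bond lengths only; angles and nonbonded
  geometry are left to the downstream minimizer.
- The parametrization assumes independent 1-D bond/angle distributions;
  cross-correlations are not fitted (no dihedrals or constraints, which the
  PEI model does not use).
- pH handling is limited to the two presets plus static pKa annotation;
  constant-pH / titratable dynamics belong to the MD engine.
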