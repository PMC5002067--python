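# Methods

This note documents the models, conventions and numerical choices behind
`naturalmoves`, what the synthetic fixtures do and do not emulate, and the
known limitations.

## Decomposition and test-case algebra

A decomposition partitions the indexed residues into segments and
residue-level molten zones: the two sets are disjoint and their union covers
every indexed residue (`validate_decomposition` reports `overlap` and
`orphan` violations). In nucleic-acid mode every residue is its own segment,
the residue-level zone set is empty, and molten zones are *atom-level*: the
inter-nucleotide backbone atoms O3′–P–O5′–C5′ between adjacent segments.

The decomposition vector is defined by an ordered list of *toggles*. A
toggle may control several molten zones and/or torsions at once; this is how
the symmetric 5hmC marks on a palindromic duplex enter as single bits (both
strands' C5–C5M torsions are one bit, both C5M–O5 torsions a second, both
mark→guanine zones a third). The default toggle order is molten zones in
chain order followed by torsions in declaration order; the DNA fixture
declares torsion bits first, matching the convention its test-case labels
use. Permanently active zones — including terminal zones, which have only
one flanking segment — carry no bit.

Applying a test case is a union–find fusion: every deactivated zone merges
its flanking segments, transitively, and the zone's own residues (or atoms)
join the fused rigid body. Consequences tested as invariants: flipping any
bit 1→0 never increases the number of effective segments; all-ones yields
one effective segment per declared segment; all-zeros yields one per
maximal zone-connected run.

Enumeration is capped (default 20 bits) and refuses to expand beyond it
rather than silently generating millions of cases.

## Synthetic fixtures

The fixtures are deterministic geometric idealizations, not crystallographic
models. Every "ideal" bond length is the as-built length, so geometry
validation, the energy minimum and the closure targets are mutually
consistent by construction.

**Ideal helix** — a CA trace with rise 1.5 Å, twist 100°, radius 2.3 Å
(giving ≈ 3.8 Å consecutive-CA virtual bonds), decorated with N, C and CB
stubs so it can be coarse-grained.

**Toy groove** — two antiparallel helices (chains A and B) above a rigid
sheet (chain S), with the canonical five-segment layout A1/A2 and B1/B2/B3,
2-residue togglable molten zones at the three kinks and 1-residue permanent
terminal zones. The exact segment boundaries are this package's own choice
(documented in `fixtures.py`), not authoritative. After assembly, chain B is
translated along the inter-helix axis so the measured groove width equals
the configured separation exactly. The sheet is deliberately outside the
decomposition's structure index: it is a fixed environment, which keeps the
canonical decomposition at exactly five segments.

**B-DNA duplex** — a fiber model with rise 3.38 Å and twist 36°. Base atoms
are planar regular-polygon templates placed on exactly zero basepair
parameters: the Watson–Crick atom (purine N1 / pyrimidine N3) sits at
(0, 1.45, 0) in each base frame, so flipping the complementary frame puts
the WC atoms 2.9 Å apart. These templates are self-consistent with the
analysis module's frame fitting — that is the point: the basepair-parameter
oracle (ideal duplex → all zeros; imposed displacements → recovered exactly)
does not depend on reproducing any published standard-base coordinate set.
Backbone atoms lie on a compressed helical path (radius ≈ 9 Å with an
alternating radial zigzag that gives each inter-nucleotide closure chain
≈ 3 Å of slack); backbone bond lengths are therefore shorter than chemical
values, which is irrelevant to the protocol because all ideal lengths are
as-built. A 5hmC mark adds C5M in the base plane, a hydroxyl O on a 70°
cone about the C5–C5M axis at the azimuth closest to (orientation
`"toward"`) or farthest from (`"away"`) the 3′-guanine O6, and an
analytically placed hydroxyl H. The mark requires a 3′-adjacent guanine.

What the fixtures do **not** emulate: crystallographic detail, sequence-
dependent geometry, solvent, counterions, and real force-field energetics.
Tests passing on them certify the *protocol machinery* — the algebra,
closure, sampler statistics and observable conventions — not biological
predictions about MHC II or the Dickerson–Drew dodecamer.

## Energy models

The published case studies used a statistical coarse-grained potential and
Amber-class all-atom force fields; those are outside this package's scope,
and the potentials here are intentionally minimal, swappable stand-ins that
give the sampler a meaningful landscape. Units: kcal/mol, Å, Kelvin, with
k_B = 0.0019872041 kcal/(mol·K).

* **cg3 protein** (`protein_energy_model`): harmonic pseudo-bonds
  k (r − r₀)², k = 20 kcal/mol/Å²; soft-core repulsion
  ε((σ/r)¹² − 1) for r < σ (ε = 1, σ = 4 Å) over all non-bonded pairs ≥ 2
  residues apart (continuous at the cutoff, so the fixed pair list defines
  the potential exactly); Gō-style harmonic wells (k = 0.2) on CA pairs
  within 9 Å of the starting structure. The built state is the minimum;
  concerted segment motion remains cheap.
* **DNA duplex** (`dna_energy_model`): harmonic bonds on the full covalent
  topology (k = 50), Watson–Crick distance wells on the paired N1/N3 atoms
  (k = 5), nearest-neighbour stacking wells on intra-strand C1′–C1′
  distances (k = 2). Minimal, but sufficient for fusing nucleotides or
  freezing the mark's hydroxyl to change basepair-parameter distributions.
* `HarmonicTether` and `CustomTerm` exist for analytically solvable test
  systems (tethers break rigid-motion invariance by design and are not part
  of the default models).

Incremental evaluation: every term computes ΔE from only the sub-terms
touching the moved atoms; the contract (equality with full recomputation to
1e-9) is property-tested over hundreds of random segment moves.

## Chain closure

Closure restores every molten-zone backbone bond to its ideal length after
a segment move, touching only the zone's mobile atoms. The solver is an
iterative forward/backward reaching scheme (FABRIK) over the zone's
backbone chain: each sweep walks the chain once from either end resetting
bond lengths exactly, cost linear in zone size, fully deterministic. This
was chosen over torsion-space cyclic coordinate descent because the zones
in both bundled case studies are short (one to four mobile sites), where
fixed-bond-angle torsional moves have too few degrees of freedom to close
the gap; the reaching scheme maintains precisely the stated contract (bond
lengths within tolerance, default 1e-3 Å; anchors untouched) while leaving
pseudo-bond angles free, which the coarse-grained and simplified-backbone
models do not constrain.

Infeasibility — anchors separated beyond the chain's maximal extension, or
no convergence within `max_iter` (default 200) sweeps — raises a signal and
the sampler **rejects the enclosing move**. Treating unclosable proposals
as zero-probability targets preserves detailed balance; a distorted
structure is never returned. Auxiliary sites riding on a mobile backbone
atom (the N/SC sites of a coarse-grained molten-zone residue) are
translated with their CA. Terminal zones ride rigidly with their single
neighbouring segment: with a free chain end there is no second anchor to
close against, and rigid transport preserves their geometry exactly.

## Sampler

One iteration: draw a generator (uniformly by default; weights are
supported), apply its symmetric proposal, close the flanking zones,
evaluate ΔE incrementally, accept with min(1, exp(−ΔE/k_BT)). Non-finite
ΔE rejects. Proposal symmetry holds by construction: translations are
uniform in a ball, rotation axes uniform on the sphere with uniform angle,
torsions uniform in [−δ, +δ].

Parallel tempering advances independent replicas (one spawned RNG stream
per replica from the master seed, so runs are bit-reproducible) and
attempts deterministic even/odd neighbour sweeps every `exchange_interval`
iterations with swap probability min(1, exp[(β_i − β_j)(E_i − E_j)]),
exchanging configurations. The default ladder is the six-temperature
300–529 K schedule of the protein case study; observables are read from
the 300 K replica. Tracked energies are resynchronized against a full
recomputation at every sampling point to prevent floating-point drift.

Step-size tuning is multiplicative (×0.7 below the target acceptance,
×1.3 far above it) over 250-iteration chunks during a burn-in budget only;
the returned move set is frozen, because continuing adaptation during
production sampling would break detailed balance. The warning for an
unattainable target is based on rates accumulated over the second half of
the budget, where per-chunk rates are too noisy to judge.

Correctness is checked against closed forms: harmonic-tether coordinate
variance = k_BT/k within 5% at 50k iterations (per ladder temperature in a
parallel-tempering run), Metropolis acceptance at ΔE = k_BT ln 2 equal to
½, and a chi-square test (α = 0.01) for transition-count symmetry on a
discretized double well.

Default iteration counts are desk-scale (10⁴) so the suite and examples run
in seconds; production-scale studies of the kind the protocol targets used
10⁶–5×10⁶ iterations and 15–30 independent repeats, which remain a
configuration choice (`SamplerConfig.iterations`, one run per repeat seed).

## Observables

**Groove width** is the distance between the centres of mass (equal site
masses) of two residue ranges flanking the groove.

**Basepair parameters** use fitted base reference frames: the idealized base
template is superposed on the observed ring atoms (Kabsch), giving origin
and axes; the second base's frame is flipped about its x axis so an ideal
pair's frames coincide. The mid-frame is the geodesic midpoint of the two
rotations. Translations (shear, stretch, stagger) are the components of
(o₁ − o₂) in the mid-frame; rotations (buckle, propeller, opening) are the
components of the rotation vector of R₁ᵀR₂ — which are identical in the
mid-frame and frame-1 axis coordinates, since the rotation fixes its own
axis. This axis-angle decomposition differs in detail from the hinge-axis
two-stage decomposition some structural-DNA tools use, but agrees exactly
for pure single-axis displacements (the regime the oracles test: imposed
shear of 1 Å and propeller of 10° are recovered to tolerance) and is
invariant under global rigid motion to 1e-9. Sign convention: parameters
describe the strand-I base relative to the flipped strand-II base.

**KDE**: Gaussian kernels with an *absolute* bandwidth — the kernel
standard deviation in data units, default 0.1 (matching the plotting
convention under which the published distributions were drawn). This is a
small explicit mixture formula rather than `scipy.stats.gaussian_kde`,
whose `bw_method` is a covariance *factor* (relative to the sample standard
deviation) and which rejects zero-variance input; the absolute-bandwidth
semantics and the degenerate single-value case both matter here. The
default grid pads the data range by six bandwidths with spacing ≤ bw/20, so
the density integrates to 1 within 1e-6.

**Summary tables** (`compare_testcases`) report per-label n, mean, median,
variance, Sarle's bimodality coefficient b = (g₁² + 1)/(g₂ + correction)
(sample-corrected; > 5/9 suggests bimodality — a scalar stand-in for the
visual wide/narrow population split) and the pooled-KDE mode.

## Known limitations

* The energy functions are qualitative stand-ins; absolute energetics and
  quantitative reproduction of published distribution shapes are out of
  scope by design.
* Closure leaves molten-zone bond *angles* unconstrained; models that need
  angle restraints should add them as energy terms.
* The B-DNA backbone is geometrically compressed; only base-frame geometry
  is faithful to the zero-parameter construction.
* Base-step (inter-pair) parameters and groove *surface area* are not
  implemented — groove width and the six intra-pair parameters are the
  supported observables.
* PDB files carry no topology; reading a structure for sampling requires
  either a template conformation or the CLI's name-based topology
  inference (cg3 site names or DNA backbone names).
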