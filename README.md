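# naturalmoves

Customized natural-move Monte Carlo (cNMMC): hypothesis-driven conformational
sampling of proteins and DNA along collective degrees of freedom.

## The problem

Functional motions of biomolecules — the narrowing of a peptide-free MHC II
binding groove, the perturbation a 5-hydroxymethylcytosine (5hmC) mark exerts
on its neighbouring basepair — involve concerted rearrangements of whole
structural regions. Sampling them atom by atom is expensive, and worse, it
does not answer the *causal* question: which degrees of freedom are necessary
and sufficient for the motion?

Natural-move Monte Carlo addresses both. A structure Ω = {m₁, …, m_N} is
partitioned into **segments** S₁, …, S_Ns (contiguous residue runs moved as
rigid bodies: three translations + three rotations each) and **molten zones**
(MZ) — the residues (proteins) or backbone atoms (nucleic acids) between
segments, which a linear-complexity chain-closure algorithm rearranges after
every move so the chain never breaks:

    Ωs = ⋃ᵢ Sᵢ,   Ωm = Ω \ Ωs = ⋃ₖ Ω_MZ(k)

Selected bond torsions Ω_φ(l) can be sampled too. The *customized* protocol
makes every such degree of freedom togglable. The binary **decomposition
vector**

    D = { f(Ω_MZ(1)), …, f(Ω_MZ(N_MZ)), g(Ω_φ(1)), …, g(Ω_φ(N_φ)) }

assigns one bit per molten zone (0 fuses the flanking segments into one rigid
body) and per torsion (0 freezes the dihedral). Each of the 2^|D| bit
patterns is one **test case**, written `"010"` etc.; sampling each test case
with Metropolis Monte Carlo (optionally parallel tempering on a temperature
ladder, data collected from the canonical 300 K replica) and comparing the
resulting observable distributions — groove width, basepair helical
parameters (shear, stretch, stagger, buckle, propeller, opening) — turns
"which motions matter?" into a systematic computational experiment.

No external data is needed: the package ships deterministic synthetic
fixtures (ideal α-helices, a toy two-helix groove with the canonical
five-segment decomposition, an idealized B-DNA duplex with optional 5hmC
marks) plus simplified Gō-style / harmonic potentials that make the full
protocol runnable and testable at desk scale.

## Worked example

```python
import naturalmoves as nm

groove = nm.make_toy_groove()           # cg3 conformation + decomposition
d = groove.decomposition
for case in nm.enumerate_test_cases(d):
    eff = nm.apply_test_case(d, case)
    print(case.label, len(eff.effective_segments))
```

prints the full test-case algebra of the five-segment decomposition:

```
000 2    001 3    010 3    011 4
100 3    101 4    110 4    111 5
```

— the all-zeros string welds each helix into one rigid body (2 effective
segments), `010` leaves only the helix-B kink active (3), and all-ones frees
all five segments. Sampling one test case end to end:

```python
eff   = nm.apply_test_case(d, nm.parse_testcase_label("010", d))
model = nm.protein_energy_model(groove.conformation)
ms    = nm.build_moveset(eff, groove.conformation)
ms    = nm.tune_step_sizes(groove.conformation, ms, model, 300.0, budget=2000, seed=1)
cfg   = nm.SamplerConfig(temperatures=(300.0,), iterations=5000, seed=2, sample_interval=25)
traj, stats = nm.run_mc(groove.conformation, ms, model, cfg)
widths = nm.observable_series(traj, lambda c: nm.groove_width(c, groove.groove_a, groove.groove_b))
print(f"acceptance {stats.acceptance_rate:.2f}, width {widths.mean():.2f} ± {widths.std():.2f} Å")
```

```
acceptance 0.41, width 11.51 ± 0.53 Å
```

The acceptance rate is the fraction of Metropolis proposals accepted after
step-size tuning; the groove width fluctuates around the built 12 Å
separation, with the variance controlled by which molten zones the test-case
string activates. The `examples/` directory walks through each capability:
test-case algebra, DNA test-case design with declarative filters, groove
sampling with distribution comparison, and basepair-parameter analysis.

A thin CLI covers shell use:

```sh
cnmmc enumerate --decomposition d.yaml
cnmmc run --structure s.pdb --decomposition d.yaml --testcase 010 \
          --iterations 10000 --seed 7 --out out/
```

## Layout

| path | contents |
| --- | --- |
| `src/naturalmoves/decomposition.py` | segments, molten zones, torsions, test-case algebra |
| `src/naturalmoves/structure.py` | conformations, trajectories, PDB I/O, coarse-graining |
| `src/naturalmoves/fixtures.py` | ideal helix, toy groove, B-DNA duplex + 5hmC marks |
| `src/naturalmoves/energy.py` | swappable simplified potentials |
| `src/naturalmoves/moves.py` | rigid-body / torsion / bend proposal generators |
| `src/naturalmoves/closure.py` | molten-zone chain closure, geometry validation |
| `src/naturalmoves/sampler.py` | Metropolis MC, parallel tempering, step-size tuning |
| `src/naturalmoves/analysis.py` | groove width, basepair parameters, KDE summaries |
| `docs/methods.md` | model assumptions, parameters, numerical choices, limitations |
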