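"""Basepair helical parameters around an epigenetic mark.

Builds the marked duplex, verifies the built geometry scores zero on all six
basepair parameters, then samples test case 001 (hydroxyl frozen in the
guanine-facing orientation, nucleotides moving independently) and reports
the distribution of shear at the basepair 3'-adjacent to the mark and the
mark-to-guanine hydrogen-bond distance.
"""

import numpy as np

import naturalmoves as nm
from naturalmoves.analysis import basepair_parameters, kde_distribution
from naturalmoves.moves import StepConfig

conf = nm.make_bdna("CGCGAATTCGCG", mods=(("A", 9, "toward"), ("B", 9, "toward")))
d = nm.make_bdna_decomposition(conf, marks=(("A", 9), ("B", 9)))
pairs = nm.basepairs(conf)

pair10 = pairs[9]  # G-C pair 3'-adjacent to the A9 mark
params0 = basepair_parameters(conf, pair10)
print("built geometry, basepair 10:", {k: round(v, 6) for k, v in params0.items()})

eff = nm.apply_test_case(d, nm.parse_testcase_label("001", d))
ms = nm.build_moveset(eff, conf, StepConfig(max_trans=0.2, max_rot=2.0))
model = nm.dna_energy_model(conf)
cfg = nm.SamplerConfig(temperatures=(300.0,), iterations=4000, seed=3, sample_interval=20)
traj, stats = nm.run_mc(conf, ms, model, cfg)
print(f"\ntest case 001: acceptance {stats.acceptance_rate:.2f}, {traj.n_frames} frames")

shear = nm.observable_series(traj, lambda c: basepair_parameters(c, pair10)["shear"])
hbond = nm.hbond_distance(traj, ("A", 9, "O5"), ("A", 10, "O6"))
kde = kde_distribution(shear, bandwidth=0.1)
print(f"shear (bp 10): mean {shear.mean():+.3f} A, sd {shear.std():.3f} A, KDE mode {kde.mode:+.3f} A")
print(f"O5...O6 hydrogen-bond distance: mean {hbond.mean():.2f} A, sd {hbond.std():.2f} A")
print("\nAt the built geometry all six parameters are exactly zero; under the")
print("minimal duplex potential thermal sampling lets them drift and spread.")
print("Comparing these distributions across test cases 111/001/000 (and an")
print("unmarked control) is how the mark's structural effect is quantified.")
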