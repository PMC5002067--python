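"""Sampling the toy binding groove under two competing test cases.

Runs tuned Metropolis Monte Carlo at 300 K for test cases 010 (only the
middle molten zone -- the helix-B kink -- active) and 000 (everything
fused), then compares the groove-width distributions.  The active kink lets
helix B bend, so 010 explores a wider range of groove widths than the
fully fused 000 case, which mostly rattles around the built geometry.
Iteration counts here are demonstration-sized; scale them up for smooth
distributions.
"""

import numpy as np

import naturalmoves as nm
from naturalmoves.moves import StepConfig

groove = nm.make_toy_groove(separation=12.0)
conf, d = groove.conformation, groove.decomposition
model = nm.protein_energy_model(conf)

series = {}
for label in ("010", "000"):
    eff = nm.apply_test_case(d, nm.parse_testcase_label(label, d))
    ms = nm.build_moveset(eff, conf, StepConfig(max_trans=1.0, max_rot=10.0))
    ms = nm.tune_step_sizes(conf, ms, model, 300.0, budget=2000, seed=1)
    cfg = nm.SamplerConfig(
        temperatures=(300.0,), iterations=5000, seed=2, sample_interval=25
    )
    traj, stats = nm.run_mc(conf, ms, model, cfg)
    widths = nm.observable_series(
        traj, lambda c: nm.groove_width(c, groove.groove_a, groove.groove_b)
    )
    series[label] = widths[len(widths) // 5 :]
    print(
        f"test case {label}: acceptance {stats.acceptance_rate:.2f}, "
        f"width {widths.mean():.2f} +- {widths.std():.2f} A "
        f"(range {widths.min():.2f}-{widths.max():.2f})"
    )

table = nm.compare_testcases(series)
print("\nper-test-case summary (groove width, A):")
print(table.round(3).to_string())
print("\nA larger variance under 010 shows the kink-mediated flexibility the")
print("binary string switched on; under 000 the groove stays near 12 A.")
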