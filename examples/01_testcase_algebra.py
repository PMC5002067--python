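"""Binary test-case algebra on a two-helix binding groove.

Builds the canonical five-segment decomposition (helix A: A1, A2; helix B:
B1, B2, B3; three togglable molten zones at the helix kinks), enumerates all
2^3 = 8 test cases and shows how each binary string fuses the segments.
A '0' bit deactivates a molten zone, welding its two neighbouring segments
into one rigid body; '1' leaves them independent, with the zone absorbing
the chain break by closure.
"""

import naturalmoves as nm

groove = nm.make_toy_groove()
d = groove.decomposition
print("decomposition:", nm.validate_decomposition(d))
print(f"segments: {[s.id for s in d.segments]}")
print(f"togglable molten zones: {[t.label for t in d.active_toggles]}")
print()
print("test case   #segments   effective segments")
for case in nm.enumerate_test_cases(d):
    eff = nm.apply_test_case(d, case)
    names = ", ".join(s.id for s in eff.effective_segments)
    print(f"   {case.label}          {len(eff.effective_segments)}       {{{names}}}")
print()
print("The all-zeros case leaves one rigid body per helix (2 segments);")
print("the all-ones case frees all five segments to move independently.")
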