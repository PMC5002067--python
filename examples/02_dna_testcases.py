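"""Designing DNA test cases for a 5-hydroxymethylcytosine mark.

The Dickerson-Drew dodecamer (CGCGAATTCGCG) carries symmetric 5hmC marks at
position 9 of both strands, with the hydroxyl oriented toward the
3'-adjacent guanine's O6.  Every nucleotide is its own rigid segment; the
decomposition vector has three bits: the two hydroxyl torsions (C5-C5M and
C5M-O5, toggled jointly for both marks) and the backbone molten zone between
each mark and its 3'-guanine.  Hypothesis-irrelevant cases are filtered out
declaratively, leaving the three cases the study compares.
"""

import naturalmoves as nm

conf = nm.make_bdna("CGCGAATTCGCG", mods=(("A", 9, "toward"), ("B", 9, "toward")))
print(f"duplex: {len(conf.chain_residues('A'))} bp, {conf.n_atoms} atoms")
for chain in ("A", "B"):
    dist = nm.hbond_distance(conf, (chain, 9, "O5"), (chain, 10, "O6"))
    print(f"  {chain}9 hydroxyl O ... {chain}10 guanine O6: {dist:.2f} A")

d = nm.make_bdna_decomposition(conf, marks=(("A", 9), ("B", 9)))
print(f"\ndecomposition vector bits: {[t.label for t in d.active_toggles]}")

cases = nm.enumerate_test_cases(d)
print(f"raw test cases ({len(cases)}): {[c.label for c in cases]}")

kept = nm.dna_filter_testcases(cases, [nm.bits_equal(0, 1)])
print(f"torsion bits equal (mark fully flexible or fully fixed): {[c.label for c in kept]}")

final = nm.dna_filter_testcases(kept, [nm.drop_labels(['110'])])
print(f"drop 110 (equivalent to 000 under the deactivated zone): {[c.label for c in final]}")
print("\n111 = free mark; 001 = frozen hydroxyl; 000 = frozen hydroxyl and")
print("mark welded to the 3'-guanine, emulating the intrastrand hydrogen bond.")
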