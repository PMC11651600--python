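"""Count the motifs that drive degeneracy screening on a classic network.

Run: python examples/01_motif_counts.py
"""

import ergmselect as es

g = es.load_classic("florentine_business")
m = es.motif_summary(g)
mo = es.motif_summary(g, convention="ordered")

print(f"{g.n_nodes} nodes, {g.n_edges} edges")
print(f"unordered: {m.two_stars} two-stars, {m.triangles} triangles")
print(f"ordered (published-table convention): {mo.two_stars} / {mo.triangles}")
# The unordered counts are the ERGM sufficient statistics; published summary
# tables often print the ordered counts, which are exactly twice as large.
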