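"""Recover a known generating model from synthetic data.

Run: python examples/07_synthetic_recovery.py  (~1 minute)
"""

import numpy as np

import ergmselect as es
from ergmselect.selection import CandidateSet

# Simulate a 30-node network from edges + gwesp(0.5) at a transitive regime.
truth = es.ERGMModel.from_endogenous([es.TermSpec("gwesp", decay=0.5)])
theta = np.array([-2.5, 0.8])
g = es.generate_from_ergm(truth, theta, n=30, seed=42)
print("data:", es.motif_summary(g))

cands = CandidateSet(terms=[es.TermSpec("gwesp", decay=0.5), es.TermSpec("isolates")])
sel = es.stochastic_forward_select(g, cands, n_replicates=8, cfg=es.MCMCConfig(seed=7))
for rec in sel.records:
    print(f"{rec.term.name:12s} kept={rec.kept}  (divergent {rec.n_divergent}/{rec.n_replicates})")
# The generating term gwesp survives with a clearly positive 10th-percentile
# relative AIC change; isolates (observed at 0) is removed as degenerate --
# the selection recovers the structure that actually generated the data.
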