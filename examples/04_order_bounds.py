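"""Bound the order parameter of kstar/dsp/esp/nsp from the data.

Run: python examples/04_order_bounds.py  (~1 minute)
"""

import ergmselect as es

g = es.load_classic("florentine_business")
for family in ("kstar", "esp", "dsp", "nsp"):
    b = es.bound_parameter_k(family, g, cfg=es.MCMCConfig(seed=3))
    print(f"{family:6s} upper bound: {b}")
# Orders above the bound yield parameter estimates "at infinity" (the
# observed count sits on the boundary of its attainable range), so the
# candidate set only includes orders up to the bound.
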