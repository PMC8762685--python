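"""Build radial-frequency shapes and measure their geometry.

A genome is 10 (amplitude, phase, gate) triples modulating a 30-px base
circle.  The zero-amplitude genome is a perfect circle; adding one active
frequency adds that many lobes; large amplitudes push the radius negative
and the contour grows internal loops.
"""

import numpy as np

from shapevolve import (
    InitConfig,
    isoperimetric_ratio,
    random_genome,
    synthesize_contour,
)
from shapevolve.genome import RFGenome


def sparse_genome(active, id="demo"):
    amps = np.zeros(10)
    for f, a in active.items():
        amps[f - 1] = a
    return RFGenome(amplitudes=amps, phases=np.full(10, 90.0),
                    gates=np.ones(10, dtype=int), id=id)


circle = synthesize_contour(sparse_genome({}))
four_lobes = synthesize_contour(sparse_genome({4: 25.0}))
loopy = synthesize_contour(sparse_genome({2: 250.0}))
rand = synthesize_contour(random_genome(InitConfig(seed=7)))

for name, c in [("circle", circle), ("4-lobed", four_lobes), ("loopy", loopy), ("random", rand)]:
    ratio = isoperimetric_ratio(c)
    print(f"{name:8s}  simple={str(c.is_simple()):5s}  P^2/A = {ratio:7.3f}")

print(f"\n4*pi = {4 * np.pi:.3f} is the circle's floor; every other simple shape")
print("scores higher, and self-intersecting (loopy) shapes are measured on")
print("their filled raster, so the ratio indexes total contour curvature.")
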