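"""Generate the two 2-D microtubule layouts and compare their crossing maps.

Builds one non-radial (NRS) and one quasi-radial (QRS) network of 80
microtubules in the default 12100 x 7000 nm region and prints where the
track crossings sit along the transport axis.  In the NRS, crossings spread
over the whole region; in the QRS they concentrate in the core disc at the
left-center, which is what lets motors switch tracks early and rarely later.
"""

import numpy as np

from kinnet import generate_nrs, generate_qrs

for name, gen in (("NRS", generate_nrs), ("QRS", generate_qrs)):
    net = gen(80, seed=1)
    xs = np.array([c.point[0] for c in net.crossings])
    print(
        f"{name}: {net.n_mts} MTs, {len(net.crossings)} crossings; "
        f"crossing-x median {np.median(xs):.0f} nm, "
        f"IQR [{np.percentile(xs, 25):.0f}, {np.percentile(xs, 75):.0f}] nm"
    )

print(
    "\nA QRS median far left of the NRS one reflects the quasi-radial core: "
    "track switching is only geometrically available near the start of the run."
)
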