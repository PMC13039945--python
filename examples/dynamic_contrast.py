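"""Simulate a sample with slow, intermediate and fast subcellular motion and
render the dynamic-contrast RGB image.

Three square regions oscillate axially at 2, 20 and 200 Hz; the per-pixel
fluctuation spectra are integrated into the 1-3 / 3-100 / 100-250 Hz bands
mapped to blue, green and red. Each region should come out dominated by the
channel whose band contains its drive frequency.
"""

import numpy as np

from dffocm import dynamic_pipeline, simulate_stack
from dffocm.fixtures import three_band_spec

spec = three_band_spec(seed=0, shape=(64, 64), n_frames=512)
stack = simulate_stack(spec)
image = dynamic_pipeline(stack)

labels = spec.dynamics.region_labels
print("region  drive    mean R     mean G     mean B    dominant")
for region, freq in [(1, 2.0), (2, 20.0), (3, 200.0)]:
    r, g, b = image.rgb[:, labels == region].mean(axis=1)
    dominant = "RGB"[int(np.argmax([r, g, b]))]
    print(f"  {region}    {freq:6.1f} Hz  {r:.3f}      {g:.3f}      {b:.3f}     {dominant}")
driven = image.std_map[labels > 0].mean()
background = image.std_map[labels == 0].mean()
print(f"mean temporal STD, driven regions : {driven:.3g} e-")
print(f"mean temporal STD, background     : {background:.3g} e- "
      f"({driven / background:.0f}x weaker)")
# The dominant channel tracks the band containing each drive frequency:
# 2 Hz -> blue, 20 Hz -> green, 200 Hz -> red. Static background pixels
# retain a small residual STD because per-frame mean normalization couples
# a little of the driven regions' fluctuation into every pixel.
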