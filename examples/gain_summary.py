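"""Summarize a measured chirp-vs-single-frequency gain table.

The benchmark table holds intensity ratios of three chirp TRIPLE difference
traces against their single-frequency counterparts at five spectral
positions (three cells were not measurable).  The mean peak gain translates
into a measurement-time reduction equal to its square, since averaging time
scales inversely with the squared signal amplitude.
"""

import numpy as np

from chirpendor import summarize_gains

gains = np.array([
    [3.5, 4.0, 9.8, np.nan, 4.1],
    [10.2, 8.0, 12.9, 3.7, np.nan],
    [3.0, np.nan, 4.1, 3.3, 2.0],
])

s = summarize_gains(gains)
print(f"{s['n_cells']} measured gain factors, mean {s['mean_rounded']}")
print(f"equivalent measurement-time reduction: {s['time_reduction']}x")
print("(a 2D TRIPLE experiment that would take ~89 days with single-frequency "
      "pulses fits in ~2.7 days with chirped ones)")
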