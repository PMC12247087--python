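"""Predict chirp-broadened spectra of a CuTPP-like sample by convolution.

Full density-matrix simulation is hopeless for a spin system as large as
Cu(II)-tetraphenylporphyrin, but the chirp spectrum is well approximated by
convolving the single-frequency (sf) spectrum with the chirp excitation
profile on a shared 0.1 MHz grid.  This script builds a synthetic sf
spectrum, convolves it with profiles of increasing bandwidth, and prints the
peak gains of the narrow proton line versus the broad copper feature — the
resolution/sensitivity tradeoff in numbers.
"""

import numpy as np

from chirpendor import (
    ChirpSpec, convolve_sf_spectrum, excitation_profile, generate_sf_spectrum,
    offset_correct, peak_gain, Spectrum,
)

sf = offset_correct(generate_sf_spectrum(noise_sigma=0.0))
offsets = np.arange(-5.0, 5.0001, 0.1)

print("bandwidth   1H gain (13.4)   14N gain (23.8)   Cu gain (49.0)")
for bw in (0.5, 2.0, 8.0):
    pulse = ChirpSpec(0.0, bw, 40.0, edge_time=0.2, peak_amplitude=0.1)
    prof = excitation_profile(pulse, offsets)
    chirp = convolve_sf_spectrum(sf, prof)
    # tight search window: the 1H reference line is only 0.3 MHz wide, so a
    # wide window would compare against its near-zero flank
    g = peak_gain(chirp, sf, [13.4, 23.8, 49.0], search_halfwidth=0.1)
    print(f"  {bw:4.1f} MHz      {g[0]:5.2f}            {g[1]:5.2f}            {g[2]:5.2f}")
print("Broad lines keep gaining with bandwidth; narrow lines gain only until "
      "the sweep exceeds their width, then broaden and lose peak height.")
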