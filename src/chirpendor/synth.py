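"""Synthetic single-frequency ENDOR spectra of a CuTPP-like Cu(II) porphyrin.

Cu(II)-tetraphenylporphyrin is a standard test sample for pulse ENDOR: its
X-band Davies ENDOR spectrum combines narrow weakly coupled proton lines
near the proton Larmor frequency, broader strongly coupled nitrogen lines in
the 15-25 MHz region, and very broad copper hyperfine features above 30 MHz,
with a signal-free baseline region up to 95 MHz used for offset correction.
This module builds analytic stand-ins for such spectra (sums of Gaussian or
Lorentzian lines plus seeded noise) so the convolution and gain analyses run
without measured data.  Line positions follow the CuTPP peak pattern; the
widths and amplitudes are plausible choices, not fits to data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum

__all__ = [
    "LineModel",
    "default_cutpp_lines",
    "default_grid",
    "generate_sf_spectrum",
    "offset_correct",
    "BASELINE_WINDOW",
]

#: Signal-free region (MHz) whose mean is used for offset correction.
BASELINE_WINDOW = (92.0, 95.0)


@dataclass(frozen=True)
class LineModel:
    """One spectral line: position and FWHM in MHz, peak amplitude, shape, nucleus tag."""

    position: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"
    label: str = ""

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError("shape must be 'gaussian' or 'lorentzian'")

    def evaluate(self, freqs: np.ndarray) -> np.ndarray:
        x = np.asarray(freqs, dtype=float) - self.position
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-4 * np.log(2) * x**2 / self.fwhm**2)
        g = self.fwhm / 2
        return self.amplitude * g**2 / (x**2 + g**2)


def default_cutpp_lines() -> list[LineModel]:
    """CuTPP-like line set: two narrow 1H lines, two 14N lines, one broad Cu feature."""
    return [
        LineModel(13.4, 0.3, 1.00, "gaussian", "1H"),
        LineModel(15.6, 0.3, 0.80, "gaussian", "1H"),
        LineModel(21.6, 1.5, 0.50, "gaussian", "14N"),
        LineModel(23.8, 1.5, 0.60, "gaussian", "14N"),
        LineModel(49.0, 6.0, 0.25, "gaussian", "63,65Cu"),
    ]


def default_grid(step: float = 0.1, start: float = 8.0, stop: float = 95.0) -> np.ndarray:
    """Uniform RF frequency grid, by default 8-95 MHz in 0.1 MHz steps."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def generate_sf_spectrum(
    lines: list[LineModel] | None = None,
    grid: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> Spectrum:
    """Sum of analytic line shapes on a uniform grid plus seeded Gaussian noise.

    Lines whose center falls inside ``baseline_window`` are rejected, so the
    window stays signal-free (up to noise) and usable for offset correction.
    """
    if lines is None:
        lines = default_cutpp_lines()
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    d = np.diff(grid)
    if d.size == 0 or not np.allclose(d, d[0], rtol=1e-6, atol=0):
        raise ValueError("grid must be uniform")
    lo, hi = baseline_window
    for line in lines:
        if lo <= line.position <= hi:
            raise ValueError(
                f"line at {line.position} MHz lies inside the baseline window "
                f"{baseline_window}"
            )
    signal = np.zeros(grid.size)
    for line in lines:
        signal += line.evaluate(grid)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sigma, grid.size)
    meta = {
        "lines": [
            (ln.position, ln.fwhm, ln.amplitude, ln.shape, ln.label) for ln in lines
        ],
        "noise_sigma": noise_sigma,
        "seed": seed,
        "baseline_window_MHz": baseline_window,
    }
    return Spectrum(grid, signal, meta)


def offset_correct(
    spectrum: Spectrum, baseline_window: tuple[float, float] = BASELINE_WINDOW
) -> Spectrum:
    """Subtract the mean intensity inside the signal-free baseline window.

    Linear and idempotent; the window must contain at least 3 grid points.
    """
    lo, hi = baseline_window
    mask = (spectrum.frequencies >= lo) & (spectrum.frequencies <= hi)
    if mask.sum() < 3:
        raise ValueError("baseline window must contain at least 3 grid points")
    offset = float(spectrum.intensities[mask].mean())
    meta = dict(spectrum.metadata)
    meta["offset_corrected"] = offset
    return Spectrum(spectrum.frequencies.copy(), spectrum.intensities - offset, meta)
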