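"""Frequency-intensity spectrum container and plain-text I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "read_spectrum", "write_spectrum"]


@dataclass
class Spectrum:
    """A real-valued spectrum on a strictly increasing frequency grid (MHz)."""

    frequencies: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.frequencies.ndim != 1 or self.frequencies.size == 0:
            raise ValueError("frequencies must be a non-empty 1-D array")
        if self.frequencies.shape != self.intensities.shape:
            raise ValueError("frequencies and intensities must have equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def step(self) -> float | None:
        """Grid step if the grid is uniform, else None."""
        d = np.diff(self.frequencies)
        if d.size == 0:
            return None
        if np.allclose(d, d[0], rtol=1e-6, atol=0):
            return float(d[0])
        return None

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.frequencies.copy(), self.intensities.copy(), dict(self.metadata)
        )


def write_spectrum(path, spectrum: Spectrum) -> None:
    """Two-column text export (frequency MHz, intensity) with '#' provenance header."""
    header = ["chirpendor spectrum", "frequency_MHz intensity"]
    for k, v in spectrum.metadata.items():
        header.insert(1, f"{k} = {v!r}")
    np.savetxt(
        path,
        np.column_stack([spectrum.frequencies, spectrum.intensities]),
        header="\n".join(header),
    )


def read_spectrum(path) -> Spectrum:
    """Read a two-column frequency/intensity text file ('#' comments ignored)."""
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError("spectrum file must have at least two columns")
    return Spectrum(data[:, 0], data[:, 1])
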