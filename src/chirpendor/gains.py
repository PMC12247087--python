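"""Sensitivity-gain quantification: chirp versus single-frequency spectra.

The payoff of chirped RF excitation is a higher ENDOR signal per shot.  Gains
are quantified as ratios of offset-corrected peak heights (not integrals) at
selected spectral positions, and a table of such gains is summarized by its
arithmetic mean; since signal averaging time scales with the inverse square
of the signal amplitude, a mean peak-height gain g corresponds to a
measurement-time reduction of g**2.
"""

from __future__ import annotations

import math

import numpy as np

from .spectra import Spectrum
from .synth import offset_correct

__all__ = [
    "peak_gain",
    "summarize_gains",
    "read_gain_table",
    "write_gain_table",
    "MISSING",
]

#: Sentinel used for absent cells in delimited gain tables.
MISSING = "-"


def peak_gain(
    test: Spectrum,
    reference: Spectrum,
    positions,
    baseline_window: tuple[float, float] | None = None,
    search_halfwidth: float = 0.5,
) -> np.ndarray:
    """Peak-height ratio test/reference at each requested position.

    Both spectra are offset-corrected first (if ``baseline_window`` is
    given); the reference is interpolated onto the test grid if the grids
    differ.  For each position p the peak location p* is the grid maximum of
    the test spectrum within ``p +/- search_halfwidth`` MHz, and the gain is
    ``test(p*) / reference(p*)``.  A non-positive reference peak raises.
    """
    if baseline_window is not None:
        test = offset_correct(test, baseline_window)
        reference = offset_correct(reference, baseline_window)
    f = test.frequencies
    if reference.frequencies.shape != f.shape or not np.allclose(
        reference.frequencies, f
    ):
        ref_vals = np.interp(f, reference.frequencies, reference.intensities)
    else:
        ref_vals = reference.intensities
    gains = []
    for p in np.atleast_1d(np.asarray(positions, dtype=float)):
        if p < f[0] or p > f[-1]:
            raise ValueError(f"position {p} MHz outside the spectrum grid")
        mask = np.abs(f - p) <= search_halfwidth
        if not mask.any():
            raise ValueError(f"no grid points within {search_halfwidth} MHz of {p}")
        idx = np.flatnonzero(mask)
        i_star = idx[int(np.argmax(test.intensities[idx]))]
        ref_peak = ref_vals[i_star]
        if ref_peak <= 0:
            raise ValueError(
                f"reference intensity at {f[i_star]:.3f} MHz is non-positive"
            )
        gains.append(test.intensities[i_star] / ref_peak)
    return np.asarray(gains)


def summarize_gains(table, square_rounded: bool = True) -> dict:
    """Mean gain and equivalent measurement-time reduction of a gain table.

    ``table`` is any array-like of gain factors with ``nan`` marking missing
    cells; missing cells are ignored.  ``time_reduction`` is the square of
    the mean rounded to one decimal (so a printed mean of 5.7 yields 32.5);
    with ``square_rounded=False`` the unrounded mean is squared instead.
    Both outputs are reported to one decimal.
    """
    values = np.asarray(table, dtype=float).ravel()
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("gain table has no non-missing cells")
    mean = float(values.mean())
    base = round(mean, 1) if square_rounded else mean
    return {
        "mean": mean,
        "mean_rounded": round(mean, 1),
        "time_reduction": round(base**2, 1),
        "n_cells": int(values.size),
    }


def write_gain_table(path, row_labels, col_labels, matrix, delimiter="\t") -> None:
    """Delimited text gain table with labeled rows/columns; nan cells become '-'."""
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write("# chirpendor gain table (rows/cols in MHz)\n")
        fh.write(delimiter.join([""] + [str(c) for c in col_labels]) + "\n")
        for label, row in zip(row_labels, matrix):
            cells = [MISSING if math.isnan(v) else f"{v:g}" for v in row]
            fh.write(delimiter.join([str(label)] + cells) + "\n")


def read_gain_table(path, delimiter="\t"):
    """Read a labeled gain table; returns (row_labels, col_labels, matrix with nan)."""
    rows = []
    row_labels = []
    col_labels = None
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split(delimiter)
            if col_labels is None:
                col_labels = [c for c in cells[1:] if c != ""]
                continue
            row_labels.append(cells[0])
            rows.append(
                [
                    float("nan") if c.strip() in (MISSING, "", "–") else float(c)
                    for c in cells[1 : 1 + len(col_labels)]
                ]
            )
    if col_labels is None:
        raise ValueError("empty gain table")
    return row_labels, col_labels, np.asarray(rows, dtype=float)
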