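"""Convolution-based prediction of chirp-broadened ENDOR spectra.

Time-domain spin simulations become infeasible for spin systems with many
coupled nuclei, but a chirp ENDOR spectrum can be predicted cheaply from a
single-frequency (sf) spectrum: the chirp pulse excites every transition the
sf pulse would, weighted by its inversion profile, so the broadened spectrum
is the discrete convolution of the sf spectrum with the chirp excitation
profile::

    I_chirp(j) = sum_{m=-M}^{M} I_sf(j - m) * E(m)

Both curves must share one frequency resolution (default 0.1 MHz) and the
profile is truncated to a +/- 5 MHz offset window by default.  The sf
spectrum is taken as zero outside its measured range (its flanks are
baseline).  This frequency-domain route deliberately ignores interference
between transitions that share an energy level (relevant for I >= 1 nuclei)
and any residual broadening already present in the sf spectrum.
"""

from __future__ import annotations

import warnings

import numpy as np

from .profiles import ExcitationProfile
from .spectra import Spectrum

__all__ = [
    "resample_to_grid",
    "convolve_sf_spectrum",
    "normalize_spectrum",
]

_STEP_RTOL = 1e-6


def resample_to_grid(spectrum: Spectrum, step: float) -> Spectrum:
    """Linear interpolation onto a uniform grid of the given step.

    The output grid starts at the input's first frequency and spans its range;
    if the input is already uniform at the requested step it is returned
    value-identical.  Non-monotonic input grids are rejected by
    :class:`Spectrum` itself.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    f = spectrum.frequencies
    cur = spectrum.step
    if cur is not None and abs(cur - step) <= _STEP_RTOL * step:
        return spectrum.copy()
    n = int(np.floor((f[-1] - f[0]) / step + 1e-9)) + 1
    grid = f[0] + step * np.arange(n)
    vals = np.interp(grid, f, spectrum.intensities)
    meta = dict(spectrum.metadata)
    meta["resampled_step_MHz"] = step
    return Spectrum(grid, vals, meta)


def _profile_kernel(profile: ExcitationProfile, step: float, window: float):
    """Truncate a profile to |offset| <= window and return (kernel, center index)."""
    p_step = profile.step
    if profile.offsets.size == 1:
        # single-point profile: impulse kernel, no step to compare
        if abs(profile.offsets[0]) > step / 4:
            raise ValueError("single-point profile must sit at zero offset")
        return profile.efficiency.copy(), 0
    if abs(p_step - step) > _STEP_RTOL * step:
        raise ValueError(
            "profile and spectrum must share the same frequency step "
            f"(profile {p_step} vs spectrum {step} MHz); resample first"
        )
    mask = np.abs(profile.offsets) <= window + step / 2
    offs = profile.offsets[mask]
    kern = profile.efficiency[mask]
    if kern.size == 0:
        raise ValueError("profile window contains no points")
    i0 = int(np.argmin(np.abs(offs)))
    if abs(offs[i0]) > step / 4:
        raise ValueError("profile grid must contain the zero offset")
    return kern, i0


def convolve_sf_spectrum(
    sf: Spectrum,
    profile: ExcitationProfile,
    window: float = 5.0,
    normalize: bool = False,
) -> Spectrum:
    """Predict a chirp-broadened spectrum from a single-frequency spectrum.

    ``I_out(j) = sum_m I_sf(j-m) E(m)`` with zero padding outside the sf
    range; the output lives on the sf grid.  ``window`` truncates the
    excitation profile to ``+/- window`` MHz of offset.  With ``normalize``
    the result is scaled to unit maximum afterward, matching how predicted
    and measured chirp spectra are intensity-matched.

    Mismatched frequency steps are rejected rather than silently resampled.
    """
    step = sf.step
    if step is None:
        raise ValueError("sf spectrum must be on a uniform grid; resample first")
    kern, i0 = _profile_kernel(profile, step, window)
    half_span = max(profile.offsets[-1], -profile.offsets[0])
    if 2 * half_span > sf.frequencies[-1] - sf.frequencies[0]:
        warnings.warn(
            "excitation-profile window exceeds the sf spectrum span; "
            "edge regions are dominated by zero padding",
            stacklevel=2,
        )
    full = np.convolve(sf.intensities, kern, mode="full")
    out = full[i0 : i0 + sf.frequencies.size]
    meta = dict(sf.metadata)
    meta["convolved_with"] = repr(profile.spec) if profile.spec is not None else "profile"
    meta["profile_window_MHz"] = window
    result = Spectrum(sf.frequencies.copy(), out, meta)
    if normalize:
        result = normalize_spectrum(result)
    return result


def normalize_spectrum(spectrum: Spectrum) -> Spectrum:
    """Scale to unit maximum; rejects all-zero (or non-positive-max) input."""
    m = float(np.max(spectrum.intensities))
    if m <= 0:
        raise ValueError("cannot normalize a spectrum with non-positive maximum")
    meta = dict(spectrum.metadata)
    meta["normalized"] = True
    return Spectrum(spectrum.frequencies.copy(), spectrum.intensities / m, meta)
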