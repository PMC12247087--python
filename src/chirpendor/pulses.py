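"""Shaped radio-frequency pulse construction.

Two pulse families are supported: rectangular single-frequency pulses and
linearly frequency-swept (chirp) pulses whose amplitude envelope rises and
falls as a quarter period of a sine wave.  Quarter-sine edge smoothing is the
standard way to suppress the sinc wiggles that a hard rectangular envelope
imprints on the excitation profile of an AWG-generated RF pulse.

All frequencies and amplitudes are in MHz (linear frequency units), all times
in microseconds.  Waveforms are real-valued and carry the oscillating carrier
explicitly: ``samples[k] = envelope(t_k) * cos(phase(t_k))`` on a half-open
time grid ``t_k = k * sample_period``.  With this convention a linearly
polarized drive of peak amplitude ``nu2_max`` produces an effective
rotating-frame nutation frequency of ``nu2_max / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "ChirpSpec",
    "RectSpec",
    "Waveform",
    "PulseSpec",
    "sample_chirp",
    "sample_rect",
    "write_waveform",
]

#: Coarsest sample period (us) allowed for waveforms that carry an explicit
#: carrier at <= 100 MHz: >= 2 samples per carrier period with margin.
CARRIER_NYQUIST_PERIOD = 0.005


@dataclass(frozen=True)
class ChirpSpec:
    """Parametric description of a linear-chirp RF pulse with quarter-sine edges.

    Parameters
    ----------
    center_frequency : float
        Carrier / sweep center frequency nu_RF (MHz).
    bandwidth : float
        Full sweep width (MHz); the instantaneous frequency runs linearly
        from ``center - bandwidth/2`` to ``center + bandwidth/2`` over the
        whole pulse.  Zero bandwidth degenerates to a constant-frequency
        pulse with quarter-sine edges.
    duration : float
        Total pulse length t_p (us).
    edge_time : float
        Span of the quarter-sine rise and fall (us).  Default 0.2 us.
    peak_amplitude : float
        Peak drive amplitude nu2_max (MHz, linear-polarization convention;
        effective on-resonance nutation is half this value).
    sample_period : float
        AWG sample period (us).  Default 1 ns.
    """

    center_frequency: float
    bandwidth: float
    duration: float
    edge_time: float = 0.2
    peak_amplitude: float = 0.1
    sample_period: float = 0.001

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be non-negative")
        if self.edge_time < 0:
            raise ValueError("edge_time must be non-negative")
        if 2 * self.edge_time > self.duration:
            raise ValueError("duration must be at least twice the edge time")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be non-negative")

    # sweep rate in MHz/us
    @property
    def sweep_rate(self) -> float:
        return self.bandwidth / self.duration

    def envelope(self, t: np.ndarray) -> np.ndarray:
        """Quarter-sine envelope evaluated at times ``t`` (us from pulse start)."""
        t = np.asarray(t, dtype=float)
        env = np.full(t.shape, self.peak_amplitude)
        te = self.edge_time
        if te > 0:
            rise = t < te
            fall = t > self.duration - te
            env = np.where(
                rise, self.peak_amplitude * np.sin(np.pi * t / (2 * te)), env
            )
            env = np.where(
                fall,
                self.peak_amplitude * np.sin(np.pi * (self.duration - t) / (2 * te)),
                env,
            )
        outside = (t < 0) | (t > self.duration)
        return np.where(outside, 0.0, env)

    def instantaneous_frequency(self, t: np.ndarray) -> np.ndarray:
        """Linear sweep: center - bw/2 at t=0 up to center + bw/2 at t=t_p."""
        t = np.asarray(t, dtype=float)
        return self.center_frequency - self.bandwidth / 2 + self.sweep_rate * t

    def phase(self, t: np.ndarray) -> np.ndarray:
        """Accumulated carrier phase ``2*pi*integral(nu(t'))`` in closed form (rad)."""
        t = np.asarray(t, dtype=float)
        return 2 * np.pi * (
            (self.center_frequency - self.bandwidth / 2) * t
            + 0.5 * self.sweep_rate * t**2
        )


@dataclass(frozen=True)
class RectSpec:
    """Rectangular constant-frequency RF pulse (hard envelope, no edges)."""

    frequency: float
    duration: float
    peak_amplitude: float = 0.1
    sample_period: float = 0.001

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be non-negative")

    @property
    def center_frequency(self) -> float:
        return self.frequency

    @property
    def bandwidth(self) -> float:
        return 0.0

    @property
    def edge_time(self) -> float:
        return 0.0

    def envelope(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        inside = (t >= 0) & (t <= self.duration)
        return np.where(inside, self.peak_amplitude, 0.0)

    def instantaneous_frequency(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.full(t.shape, float(self.frequency))

    def phase(self, t: np.ndarray) -> np.ndarray:
        return 2 * np.pi * self.frequency * np.asarray(t, dtype=float)


PulseSpec = Union[ChirpSpec, RectSpec]


@dataclass
class Waveform:
    """Time-sampled RF drive on a half-open grid ``t_k = k * sample_period``.

    ``samples`` is the real-valued instantaneous drive (envelope times cosine
    carrier), ``envelope`` the amplitude function, ``instantaneous_frequency``
    the linear sweep, all in MHz.
    """

    sample_period: float
    samples: np.ndarray
    envelope: np.ndarray
    instantaneous_frequency: np.ndarray
    spec: PulseSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.envelope = np.asarray(self.envelope, dtype=float)
        self.instantaneous_frequency = np.asarray(
            self.instantaneous_frequency, dtype=float
        )
        if not (
            len(self.samples)
            == len(self.envelope)
            == len(self.instantaneous_frequency)
        ):
            raise ValueError("sample arrays must share one length")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.sample_period

    @property
    def duration(self) -> float:
        return len(self.samples) * self.sample_period


def _n_samples(duration: float, sample_period: float) -> int:
    # half-open grid [0, duration); round protects against float fuzz
    return int(round(duration / sample_period))


def sample_chirp(spec: ChirpSpec) -> Waveform:
    """Sample a quarter-sine-edged linear chirp on the AWG time grid.

    The instantaneous frequency sweeps linearly over the full pulse duration
    (edges included) and the carrier phase is accumulated in closed form, so
    the sampled waveform is exact at every grid point.
    """
    if spec.sample_period > CARRIER_NYQUIST_PERIOD:
        raise ValueError(
            "sample_period must be <= %g us for an explicit carrier"
            % CARRIER_NYQUIST_PERIOD
        )
    n = _n_samples(spec.duration, spec.sample_period)
    t = np.arange(n) * spec.sample_period
    env = spec.envelope(t)
    freq = spec.instantaneous_frequency(t)
    samples = env * np.cos(spec.phase(t))
    return Waveform(spec.sample_period, samples, env, freq, spec=spec)


def sample_rect(spec: RectSpec) -> Waveform:
    """Sample a rectangular single-frequency pulse (cosine carrier)."""
    if spec.sample_period > CARRIER_NYQUIST_PERIOD:
        raise ValueError(
            "sample_period must be <= %g us for an explicit carrier"
            % CARRIER_NYQUIST_PERIOD
        )
    n = _n_samples(spec.duration, spec.sample_period)
    t = np.arange(n) * spec.sample_period
    env = np.full(n, float(spec.peak_amplitude))
    freq = np.full(n, float(spec.frequency))
    samples = env * np.cos(spec.phase(t))
    return Waveform(spec.sample_period, samples, env, freq, spec=spec)


def write_waveform(path, waveform: Waveform, include_iq: bool = False) -> None:
    """Export a waveform as two-column text: time (ns), amplitude (kHz).

    With ``include_iq`` two extra columns hold the complex-envelope I/Q
    components (envelope times cos/sin of the sweep phase relative to the
    center frequency).
    """
    t_ns = waveform.times * 1e3
    amp_khz = waveform.samples * 1e3
    header = ["chirpendor waveform", f"sample_period_us = {waveform.sample_period}"]
    if waveform.spec is not None:
        header.append(f"spec = {waveform.spec!r}")
    cols = [t_ns, amp_khz]
    names = "time_ns amplitude_kHz"
    if include_iq:
        spec = waveform.spec
        if spec is None:
            raise ValueError("I/Q export requires a waveform built from a spec")
        t = waveform.times
        rel_phase = spec.phase(t) - 2 * np.pi * spec.center_frequency * t
        cols += [
            waveform.envelope * np.cos(rel_phase) * 1e3,
            waveform.envelope * np.sin(rel_phase) * 1e3,
        ]
        names += " I_kHz Q_kHz"
    header.append(names)
    np.savetxt(path, np.column_stack(cols), header="\n".join(header))
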