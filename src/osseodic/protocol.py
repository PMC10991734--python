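"""Cyclic loading protocol and the analytic load signal.

The in vitro protocol this package emulates applies a 150 N preload followed by
100 sinusoidal cycles between 150 N and 850 N at 1 Hz, in load control.  Image
acquisition is restricted to three windows (first ten, central ten, last ten
cycles) to bound the amount of data, so the analysis only ever sees frames from
those windows plus the initial unloaded/preload segment.

The signal is fully analytic: cycle ``k`` has its load peak at
``t0 + (k - 1/2)/f`` and its valley at ``t0 + k/f`` (the sinusoid starts from
the valley load, continuous with the preload plateau).  Exact extremum times
are exposed so that peak/valley detection can be validated against the ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidProtocolError

DEFAULT_ACQUISITION_WINDOWS: tuple[tuple[int, int], ...] = ((1, 10), (45, 55), (90, 100))


@dataclass(frozen=True)
class LoadProtocol:
    """Sinusoidal loading protocol in load control.

    Parameters
    ----------
    preload_n:
        Preload plateau force in newton, held before cycling starts.
    load_min_n, load_max_n:
        Valley and peak force of the sinusoid (N).
    frequency_hz:
        Cycling frequency (Hz).
    n_cycles:
        Number of loading cycles.
    sampling_rate_hz:
        Camera frame rate (frames/s).
    acquisition_windows:
        Inclusive cycle ranges that are actually imaged.
    unloaded_duration_s, preload_duration_s:
        Length of the fully unloaded segment (the strain/displacement
        reference) and of the preload plateau.
    """

    preload_n: float = 150.0
    load_min_n: float = 150.0
    load_max_n: float = 850.0
    frequency_hz: float = 1.0
    n_cycles: int = 100
    sampling_rate_hz: float = 100.0
    acquisition_windows: tuple[tuple[int, int], ...] = field(
        default=DEFAULT_ACQUISITION_WINDOWS
    )
    unloaded_duration_s: float = 0.5
    preload_duration_s: float = 2.0

    def __post_init__(self):
        if self.frequency_hz <= 0:
            raise InvalidProtocolError(f"frequency must be positive, got {self.frequency_hz}")
        if self.sampling_rate_hz <= 0:
            raise InvalidProtocolError(
                f"sampling rate must be positive, got {self.sampling_rate_hz}"
            )
        if self.n_cycles < 1:
            raise InvalidProtocolError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if not self.load_min_n < self.load_max_n:
            raise InvalidProtocolError(
                f"load_min ({self.load_min_n}) must be below load_max ({self.load_max_n})"
            )
        for lo, hi in self.acquisition_windows:
            if not (1 <= lo <= hi <= self.n_cycles):
                raise InvalidProtocolError(
                    f"acquisition window ({lo}, {hi}) outside [1, {self.n_cycles}]"
                )

    # -- timing ----------------------------------------------------------
    @property
    def cycles_start_s(self) -> float:
        return self.unloaded_duration_s + self.preload_duration_s

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency_hz

    @property
    def total_duration_s(self) -> float:
        return self.cycles_start_s + self.n_cycles * self.period_s

    def peak_time(self, cycle: int) -> float:
        """Analytic time of the load peak of ``cycle`` (1-based)."""
        return self.cycles_start_s + (cycle - 0.5) * self.period_s

    def valley_time(self, cycle: int) -> float:
        """Analytic time of the load valley terminating ``cycle``."""
        return self.cycles_start_s + cycle * self.period_s

    def acquired_cycles(self) -> list[int]:
        cycles: set[int] = set()
        for lo, hi in self.acquisition_windows:
            cycles.update(range(lo, hi + 1))
        return sorted(cycles)

    # -- analytic load ---------------------------------------------------
    def load_at(self, t: np.ndarray) -> np.ndarray:
        """Analytic load (N) at times ``t`` (s), including the preload ramp-free plateau."""
        t = np.asarray(t, dtype=float)
        mid = 0.5 * (self.load_min_n + self.load_max_n)
        amp = 0.5 * (self.load_max_n - self.load_min_n)
        load = np.where(
            t < self.unloaded_duration_s,
            0.0,
            np.where(
                t < self.cycles_start_s,
                self.preload_n,
                mid - amp * np.cos(2.0 * np.pi * self.frequency_hz * (t - self.cycles_start_s)),
            ),
        )
        return load

    def cycle_index(self, t: np.ndarray) -> np.ndarray:
        """1-based cycle index per sample; 0 for the unloaded/preload segment."""
        t = np.asarray(t, dtype=float)
        rel = (t - self.cycles_start_s) * self.frequency_hz
        idx = np.where(t < self.cycles_start_s, 0, np.floor(rel).astype(int) + 1)
        return np.clip(idx, 0, self.n_cycles)


@dataclass(frozen=True)
class LoadSignal:
    """Sampled load channel with its analytic extremum times."""

    times_s: np.ndarray
    loads_n: np.ndarray
    cycle_index: np.ndarray
    peak_times_s: np.ndarray   # one per cycle, cycle 1 first
    valley_times_s: np.ndarray

    def __post_init__(self):
        if len(self.times_s) != len(self.loads_n):
            raise InvalidProtocolError("load channel length must equal frame count")


def generate_load_signal(
    protocol: LoadProtocol,
    *,
    restrict_to_windows: bool = False,
) -> LoadSignal:
    """Sample the analytic load signal of ``protocol`` on its camera time grid.

    With ``restrict_to_windows`` only the unloaded/preload segment and frames
    whose cycle lies inside an acquisition window are retained, mirroring the
    acquisition protocol.
    """
    dt = 1.0 / protocol.sampling_rate_hz
    n = int(round(protocol.total_duration_s / dt)) + 1
    times = np.arange(n) * dt
    cycles = protocol.cycle_index(times)
    if restrict_to_windows:
        keep = cycles == 0
        for lo, hi in protocol.acquisition_windows:
            keep |= (cycles >= lo) & (cycles <= hi)
        times = times[keep]
        cycles = cycles[keep]
    loads = protocol.load_at(times)
    k = np.arange(1, protocol.n_cycles + 1)
    return LoadSignal(
        times_s=times,
        loads_n=loads,
        cycle_index=cycles,
        peak_times_s=protocol.cycles_start_s + (k - 0.5) * protocol.period_s,
        valley_times_s=protocol.cycles_start_s + k * protocol.period_s,
    )


def event_times(protocol: LoadProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Frame times for the "events" policy: reference, preload, acquired extrema.

    Returns ``(times, cycles)`` where the unloaded reference and preload frames
    carry cycle index 0.  Peak and valley times of acquired cycles fall on the
    camera sampling grid whenever ``sampling_rate_hz / (2 frequency_hz)`` is an
    integer, so the events policy is a strict subsample of the dense policy.
    """
    times = [0.0, protocol.unloaded_duration_s]
    for k in protocol.acquired_cycles():
        times.append(protocol.peak_time(k))
        times.append(protocol.valley_time(k))
        if k > 1:
            # The valley preceding an acquired peak is imaged by the dense
            # policy too (it falls on the first frame of the window's cycle).
            times.append(protocol.valley_time(k - 1))
    t = np.unique(np.asarray(times))
    return t, protocol.cycle_index(t)
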