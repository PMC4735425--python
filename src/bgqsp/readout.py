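"""The in-silico biomarker: LFP proxy, band powers, and the beta/gamma ratio.

The field-potential proxy is the summed synaptic current over all pyramidal
cells — their large number makes them the dominant dipole — recorded per time
step by the circuit simulation.  Band powers are integrals of the one-sided
power spectral density: beta over the operationally widened 12-50 Hz band
(less variable on short simulations than the textbook 10-40 Hz), gamma over
60-100 Hz, with an optional 30-45 Hz low-gamma band.  The beta/gamma power
ratio is the motor-symptom biomarker.

PSD estimation uses Welch's method with 1 s Hann windows and 50% overlap
(falling back to a single full-length window on shorter traces) after
discarding the initial transient; band integrals are Riemann sums of the PSD
bins so that the full-spectrum partition satisfies Parseval's identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "LFPTrace",
    "BandPowerResult",
    "BETA_BAND",
    "GAMMA_BAND",
    "LOW_GAMMA_BAND",
    "lfp_from_simulation",
    "band_power",
    "bg_ratio",
    "evoked_input",
]

BETA_BAND = (12.0, 50.0)
GAMMA_BAND = (60.0, 100.0)
LOW_GAMMA_BAND = (30.0, 45.0)

DEFAULT_TRANSIENT_MS = 500.0
WELCH_WINDOW_MS = 1000.0


@dataclass
class LFPTrace:
    """Summed pyramidal synaptic current per time step (arbitrary units)."""

    values: np.ndarray
    dt: float                    # ms
    transient_discard: float = 0.0   # ms already removed from `values`

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("LFP trace must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("LFP trace contains non-finite values")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt

    @property
    def duration_ms(self) -> float:
        return len(self.values) * self.dt


@dataclass
class BandPowerResult:
    beta: float
    gamma: float
    ratio: float
    low_gamma: float | None = None


def lfp_from_simulation(sim, transient_discard: float = DEFAULT_TRANSIENT_MS) -> LFPTrace:
    """LFP proxy from a simulation record: the summed pyramidal synaptic
    current with the initial transient discarded."""
    values = getattr(sim, "pyr_synaptic_current", None)
    if values is None:
        raise ValueError(
            "simulation record is missing the pyramidal synaptic-current trace"
        )
    dt = sim.dt
    n_skip = int(round(transient_discard / dt))
    if n_skip >= len(values):
        raise ValueError("transient discard leaves no samples")
    return LFPTrace(np.asarray(values)[n_skip:], dt, transient_discard)


def _psd(trace: LFPTrace, method: str = "welch"):
    x = trace.values - trace.values.mean()
    fs = trace.fs
    if method == "welch":
        nperseg = min(int(round(WELCH_WINDOW_MS / trace.dt)), len(x))
        f, p = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                            noverlap=nperseg // 2, detrend="constant")
    elif method == "periodogram":
        f, p = signal.periodogram(x, fs=fs, window="boxcar", detrend="constant")
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    return f, p


def band_power(trace: LFPTrace, lo: float, hi: float,
               method: str = "welch") -> float:
    """Integral of the one-sided PSD between ``lo`` and ``hi`` Hz.

    The integral is a Riemann sum of PSD bins whose centre falls in
    [lo, hi), so that disjoint bands partitioning [0, Nyquist] sum to the
    total variance (Parseval).
    """
    if not lo < hi:
        raise ValueError("band requires lo < hi")
    nyq = trace.fs / 2.0
    if hi > nyq * (1 + 1e-9):
        raise ValueError(f"band edge {hi} Hz beyond Nyquist ({nyq:.1f} Hz)")
    f, p = _psd(trace, method)
    df = f[1] - f[0]
    mask = (f >= lo) & (f < hi)
    # half-weight the DC and Nyquist edge bins so the full partition is exact
    w = np.ones_like(f)
    w[0] = 0.5
    if np.isclose(f[-1], nyq):
        w[-1] = 0.5
    return float(np.sum(p[mask] * w[mask]) * df)


def bg_ratio(trace: LFPTrace, method: str = "welch",
             include_low_gamma: bool = False) -> BandPowerResult:
    """Beta/gamma band-power ratio of an LFP trace (both bands from the same
    PSD estimate).  Scale- and offset-invariant by construction."""
    beta = band_power(trace, *BETA_BAND, method=method)
    gamma = band_power(trace, *GAMMA_BAND, method=method)
    if gamma <= 0.0:
        raise ValueError("zero gamma power: degenerate trace, ratio undefined")
    low = band_power(trace, *LOW_GAMMA_BAND, method=method) if include_low_gamma else None
    return BandPowerResult(beta=beta, gamma=gamma, ratio=beta / gamma,
                           low_gamma=low)


def evoked_input(
    n_bursts: int,
    spikes_per_burst: int,
    seed: int,
    start_ms: float = 600.0,
    period_ms: float = 250.0,
    intra_interval_ms: float = 4.0,
    jitter_ms: float = 1.0,
) -> np.ndarray:
    """Sensory-input bursts onto thalamocortical cells.

    Returns the sorted times (ms) of ``n_bursts * spikes_per_burst`` external
    afferent spikes; the simulator fans each event out to every TC cell
    through AMPA+NMDA synapses.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    times = []
    for b in range(n_bursts):
        t0 = start_ms + b * period_ms
        for k in range(spikes_per_burst):
            t = t0 + k * intra_interval_ms + rng.normal(0.0, jitter_ms)
            times.append(max(t, 0.0))
    return np.sort(np.array(times, dtype=float))
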