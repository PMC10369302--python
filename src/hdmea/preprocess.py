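"""Signal conditioning: block detrending, spike-band and LFP-band filtering,
complex Morlet scalograms, and signal-to-noise ratio.

The conditioning chain for spike analysis is: per-block least-squares offset
correction (500-sample blocks), then a causal 100-3000 Hz band built from a
second-order Butterworth high-pass cascaded with a second-order Bessel
low-pass. LFP band extraction (gamma 30-100 Hz, ripple 150-250 Hz) uses a
zero-phase forward-backward FIR filter instead, so oscillation peak times
are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

DETREND_BLOCK_SAMPLES = 500
SPIKE_BAND_HZ = (100.0, 3000.0)
#: complex Morlet bandwidth parameter (wavenumber)
MORLET_FB = 5.0
#: complex Morlet center frequency parameter
MORLET_FC = 1.0


class ParameterError(ValueError):
    pass


def detrend_blocks(x: np.ndarray, block: int = DETREND_BLOCK_SAMPLES) -> np.ndarray:
    """Subtract a per-block least-squares linear fit (offset correction).

    Within each consecutive ``block``-sample window the degree-1 least-squares
    fit is removed; a trailing partial block is detrended the same way.
    Works on 1-D traces or (electrodes, samples) matrices.
    """
    x = np.asarray(x, dtype=float)
    if block < 2:
        raise ParameterError("block must be >= 2")
    n = x.shape[-1]
    if n == 0:
        return x.copy()
    bp = np.arange(0, n, block)
    # scipy treats bp as segment boundaries for piecewise-linear detrending
    return sps.detrend(x, axis=-1, type="linear", bp=bp)


def spike_band_sos(rate: float, band: tuple[float, float] = SPIKE_BAND_HZ):
    """Second-order sections for the causal spike-band cascade.

    Butterworth order-2 high-pass at ``band[0]`` followed by Bessel order-2
    low-pass at ``band[1]``. If the low corner is at or above Nyquist it is
    clipped to 0.45 * rate with a warning.
    """
    if rate <= 0:
        raise ParameterError("sampling rate must be positive")
    lo, hi = band
    nyq = rate / 2.0
    if hi >= nyq:
        hi = 0.45 * rate
        warnings.warn(
            f"low-pass corner clipped to {hi:.1f} Hz (below Nyquist {nyq:.1f} Hz)",
            stacklevel=2,
        )
    sos_hp = sps.butter(2, lo, btype="highpass", fs=rate, output="sos")
    sos_lp = sps.bessel(2, hi, btype="lowpass", fs=rate, output="sos", norm="mag")
    return np.vstack([sos_hp, sos_lp])


def spike_bandpass(x: np.ndarray, rate: float, band: tuple[float, float] = SPIKE_BAND_HZ) -> np.ndarray:
    """Causal 100-3000 Hz spike-band filter (Butterworth HP + Bessel LP)."""
    sos = spike_band_sos(rate, band)
    return sps.sosfilt(sos, np.asarray(x, dtype=float), axis=-1)


def spike_band_gain(freq: float, rate: float, band: tuple[float, float] = SPIKE_BAND_HZ) -> float:
    """Analytic steady-state magnitude response of the spike-band cascade."""
    sos = spike_band_sos(rate, band)
    _, h = sps.sosfreqz(sos, worN=[2 * np.pi * freq / rate])
    return float(np.abs(h[0]))


def design_fir_bandpass(low: float, high: float, rate: float) -> np.ndarray:
    """Windowed-sinc (Hamming) FIR band-pass taps; odd length 3*rate/low."""
    if not (0 < low < high < rate / 2):
        raise ParameterError(f"invalid band ({low}, {high}) at rate {rate}")
    numtaps = int(round(3 * rate / low))
    numtaps += 1 - numtaps % 2  # force odd for a symmetric (type I) filter
    return sps.firwin(numtaps, [low, high], pass_zero=False, fs=rate, window="hamming")


def zero_phase_band(x: np.ndarray, low: float, high: float, rate: float) -> np.ndarray:
    """Zero-phase FIR band-pass (forward-backward application).

    Preserves the peak times of passband oscillations; used for gamma
    (30-100 Hz) and ripple (150-250 Hz) LFP components.
    """
    taps = design_fir_bandpass(low, high, rate)
    x = np.asarray(x, dtype=float)
    padlen = min(3 * len(taps), x.shape[-1] - 1)
    return sps.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


@dataclass
class Scalogram:
    """Time-frequency magnitude map |W(b, a)| from the continuous wavelet
    transform with a complex Morlet mother wavelet.

    ``magnitude[i, j]`` is |W| at ``frequencies[i]`` (= 1/a) and ``times[j]``
    (= b). ``coi`` flags time-frequency cells whose wavelet support extends
    past the signal edges (cone of influence).
    """

    frequencies: np.ndarray
    times: np.ndarray
    magnitude: np.ndarray
    morlet_bandwidth: float = MORLET_FB
    morlet_center: float = MORLET_FC
    coi: np.ndarray | None = None

    def peak_frequency(self) -> float:
        """Frequency maximizing the time-averaged magnitude."""
        return float(self.frequencies[np.argmax(self.magnitude.mean(axis=1))])


def morlet_wavelet(x: np.ndarray, fb: float = MORLET_FB, fc: float = MORLET_FC) -> np.ndarray:
    """Complex Morlet mother wavelet G(x) = (pi*FB)^-1/2 exp(-x^2/FB) exp(2i*pi*FC*x)."""
    x = np.asarray(x, dtype=float)
    return np.exp(-(x**2) / fb) * np.exp(2j * np.pi * fc * x) / np.sqrt(np.pi * fb)


#: half-width of the truncated wavelet support in scaled units x = (t-b)/a;
#: the Gaussian envelope is exp(-x^2/FB), so at |x|=8 it is < 4e-6 for FB=5
_WAVELET_SUPPORT = 8.0


def morlet_scalogram(
    x: np.ndarray,
    rate: float,
    freq_lo: float = 0.1,
    freq_hi: float = 250.0,
    n_freqs: int = 120,
    fb: float = MORLET_FB,
    fc: float = MORLET_FC,
) -> Scalogram:
    """Scalogram |W(b, a)| with W(b,a) = (1/a) * integral f(t) G((t-b)/a) dt.

    Scales are a = 1/frequency on a logarithmic grid of ``n_freqs`` points
    over [freq_lo, freq_hi]. Discretized by direct convolution with the
    sampled mother wavelet (zero-padded edges); the cone of influence marks
    frames closer to an edge than the truncated wavelet half-support.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if not (0 < freq_lo < freq_hi < rate / 2):
        raise ParameterError("frequency range must lie within (0, rate/2)")
    freqs = np.logspace(np.log10(freq_lo), np.log10(freq_hi), n_freqs)
    dt = 1.0 / rate
    times = np.arange(n) * dt
    mag = np.empty((n_freqs, n))
    coi = np.zeros((n_freqs, n), dtype=bool)
    longest = _WAVELET_SUPPORT / freq_lo
    if n * dt < longest:
        warnings.warn(
            "signal shorter than the longest wavelet support; edge frames flagged",
            stacklevel=2,
        )
    for i, f in enumerate(freqs):
        a = 1.0 / f
        half = _WAVELET_SUPPORT * a  # seconds
        m = int(np.ceil(half / dt))
        tg = np.arange(-m, m + 1) * dt
        kernel = morlet_wavelet(tg / a, fb, fc) * (dt / a)
        w = sps.fftconvolve(x, kernel[::-1], mode="same")
        mag[i] = np.abs(w)
        edge = min(m, n)
        coi[i, :edge] = True
        coi[i, n - edge:] = True
    return Scalogram(frequencies=freqs, times=times, magnitude=mag,
                     morlet_bandwidth=fb, morlet_center=fc, coi=coi)


def compute_snr(x: np.ndarray, quiet_window: tuple[float, float], rate: float) -> float:
    """Signal-to-noise ratio: global max |v| over the noise level of a quiet window.

    The noise level is the standard deviation of the activity-free window
    (matching the rms convention of the hardware noise figure).
    """
    x = np.asarray(x, dtype=float)
    t0, t1 = quiet_window
    if t1 - t0 < 0.1:
        raise ParameterError("quiet window must span at least 0.1 s")
    i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
    if not (0 <= i0 < i1 <= x.size):
        raise ParameterError("quiet window outside the signal")
    peak_idx = int(np.argmax(np.abs(x)))
    if i0 <= peak_idx < i1:
        warnings.warn("quiet window contains the global maximum", stacklevel=2)
    noise = float(np.std(x[i0:i1]))
    if noise == 0:
        raise ParameterError("quiet window has zero variance")
    return float(np.max(np.abs(x))) / noise
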