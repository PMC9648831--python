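"""Line-noise removal, segment extraction, Morlet time-frequency analysis.

The Morlet filter bank uses a fixed cycle count C for all centre
frequencies: at centre frequency f the spectral bandwidth is
``sigma_f = 2 f / C`` and the temporal envelope width is
``sigma_t = 1 / (2 pi sigma_f)``, so ``sigma_t * sigma_f = 1/(2 pi)``
everywhere.  Wavelets are unit-energy (L2-normalised), which makes power
comparable across centre frequencies.

Edge effects: the wavelet envelope at centre frequency f extends about
+-3 sigma_t = +-3C/(4 pi f) seconds; at 1 Hz with C=14 that is ~3.3 s.  A
segment spanning -15 s ... 55 s therefore has a fully valid region of
roughly -11.7 s ... 51.7 s, which contains the 0-30 s analysis span with
ample margin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft
from scipy import signal as sps

from .errors import BoundsError, ConfigurationError
from .simulate import RawRecording

#: Envelope extent (in units of sigma_t) considered affected by the edges.
EDGE_SIGMAS = 3.0


@dataclass(frozen=True)
class MorletParams:
    """Fixed-cycle Morlet filter bank parameters."""

    C: float = 14.0
    freqs: tuple[float, ...] = tuple(float(f) for f in range(1, 121))
    time_resolution: float = 0.05

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigurationError("C (wavelet cycles) must be > 0")
        f = np.asarray(self.freqs)
        if f.size == 0 or (np.diff(f) <= 0).any() or f[0] < 1.0:
            raise ConfigurationError("freqs must be strictly increasing and >= 1 Hz")
        if self.time_resolution <= 0:
            raise ConfigurationError("time_resolution must be > 0")

    def sigma_f(self, f: float | np.ndarray) -> float | np.ndarray:
        """Spectral bandwidth (Hz) at centre frequency f."""
        return 2.0 * np.asarray(f) / self.C

    def sigma_t(self, f: float | np.ndarray) -> float | np.ndarray:
        """Temporal envelope width (s) at centre frequency f."""
        return 1.0 / (2.0 * np.pi * self.sigma_f(f))

    def edge_span(self, f: float | np.ndarray) -> float | np.ndarray:
        """Half-width (s) of the edge-affected region at centre frequency f."""
        return EDGE_SIGMAS * self.sigma_t(f)


@dataclass
class Spectrogram:
    """channels x freqs x time power array (uV^2) on a fixed time grid."""

    power: np.ndarray      # (n_channels, n_freqs, n_times), >= 0
    time_axis: np.ndarray  # seconds relative to the trigger, bin centres
    freq_axis: np.ndarray  # Hz

    def crop(self, t_lo: float, t_hi: float) -> "Spectrogram":
        """Bins whose centre lies in [t_lo, t_hi)."""
        keep = (self.time_axis >= t_lo - 1e-9) & (self.time_axis < t_hi - 1e-9)
        if not keep.any():
            raise BoundsError(f"no time bins in [{t_lo}, {t_hi})")
        return Spectrogram(self.power[:, :, keep], self.time_axis[keep], self.freq_axis)


def bandstop_60hz(rec: RawRecording, lo: float = 58.0, hi: float = 62.0,
                  order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-stop around the 60 Hz mains line.

    Forward-backward filtering (``sosfiltfilt``) keeps the trigger aligned
    (no group delay) and doubles the stop-band attenuation.
    """
    if rec.sampling_rate <= 2 * hi:
        raise ConfigurationError(
            f"sampling_rate {rec.sampling_rate} too low for a {lo}-{hi} Hz stop band")
    sos = sps.butter(order, [lo, hi], btype="bandstop", fs=rec.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal.astype(np.float64), axis=1)
    return dataclasses.replace(rec, signal=filtered.astype(rec.signal.dtype))


def extract_segment(rec: RawRecording, span: tuple[float, float] = (-15.0, 55.0)) -> RawRecording:
    """Slice the samples covering ``span`` (s, relative to trigger)."""
    fs = rec.sampling_rate
    start = rec.trigger_index + int(round(span[0] * fs))
    n = int(round((span[1] - span[0]) * fs))
    if start < 0 or start + n > rec.n_samples:
        raise BoundsError(
            f"span {span} needs samples [{start}, {start + n}) but recording has "
            f"{rec.n_samples}")
    return dataclasses.replace(
        rec, signal=rec.signal[:, start:start + n], trigger_index=rec.trigger_index - start)


def _morlet_wavelet(f: float, params: MorletParams, fs: float) -> np.ndarray:
    """Unit-energy complex Morlet at centre frequency f, sampled at fs."""
    st = float(params.sigma_t(f))
    half = int(np.ceil(5.0 * st * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-t ** 2 / (2 * st ** 2)) * np.exp(2j * np.pi * f * t)
    w /= np.sqrt(np.sum(np.abs(w) ** 2) / fs)  # L2 norm 1 in continuous time
    return w


def morlet_tfr(rec: RawRecording, params: MorletParams = MorletParams()) -> Spectrogram:
    """Morlet wavelet power spectrogram on the 0.05 s time grid.

    Power is the squared magnitude of the complex wavelet convolution,
    sampled at time-bin centres 0.000, 0.050, ... s relative to the trigger
    (extended symmetrically to the segment edges).
    """
    fs = rec.sampling_rate
    nyq = fs / 2.0
    if max(params.freqs) >= nyq:
        raise ConfigurationError(
            f"max analysis frequency {max(params.freqs)} Hz >= Nyquist {nyq} Hz")
    step = params.time_resolution * fs
    if abs(step - round(step)) > 1e-9:
        raise ConfigurationError(
            "time_resolution must be an integer number of samples")
    step = int(round(step))

    # Bin centres on the k*time_resolution grid, relative to the trigger.
    first = -(rec.trigger_index // step)
    n_bins = (rec.n_samples - 1 - rec.trigger_index) // step - first + 1
    bins = first + np.arange(n_bins)
    sample_idx = rec.trigger_index + bins * step
    time_axis = bins * params.time_resolution

    # Frequency-domain filter bank.  The unit-energy Morlet at centre
    # frequency f has the (analytic) spectrum
    #     psi_hat(nu) = (4 pi sigma_t^2)^(1/4) exp(-2 pi^2 sigma_t^2 (nu-f)^2),
    # so filtering is a single FFT of the signal, a Gaussian multiply per
    # centre frequency, and an inverse FFT.  Folding the product spectrum
    # modulo N/step before the inverse FFT yields the convolution exactly at
    # the decimated time-grid samples, which keeps the inverse FFTs short.
    x = rec.signal.astype(np.float32, copy=False)
    n = rec.n_samples
    st_max = float(params.sigma_t(min(params.freqs)))
    pad = 2 * int(np.ceil(5.0 * st_max * fs)) + 1  # kills circular wrap-around
    big_n = spfft.next_fast_len(n + pad)
    big_n = int(np.ceil(big_n / step)) * step
    fold = big_n // step

    spectrum = spfft.fft(x, big_n, axis=1)
    k = np.arange(big_n)
    f_grid = np.where(k <= big_n // 2, k, k - big_n) * (fs / big_n)
    # phase ramp placing output sample 0 at the first requested signal index
    shift = np.exp(2j * np.pi * k * (sample_idx[0] / big_n)).astype(spectrum.dtype)

    power = np.empty((x.shape[0], len(params.freqs), n_bins), dtype=np.float32)
    for i, f in enumerate(params.freqs):
        st = float(params.sigma_t(f))
        gauss = ((4.0 * np.pi * st ** 2) ** 0.25 * np.exp(
            -2.0 * (np.pi * st * (f_grid - f)) ** 2)).astype(power.dtype)
        z = spectrum * (gauss * shift)
        folded = z.reshape(x.shape[0], step, fold).sum(axis=1)
        conv = spfft.ifft(folded, axis=1) / step
        power[:, i, :] = np.abs(conv[:, :n_bins]) ** 2
    return Spectrogram(power=power, time_axis=time_axis,
                       freq_axis=np.asarray(params.freqs, dtype=float))
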