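"""Synthetic cream-application EEG cohorts.

Emulates the acquisition protocol the downstream analysis assumes: 19-channel
scalp EEG at 500 Hz, one trial per cream application, a segment spanning
-15 s ... +55 s around the application-onset trigger, and a 1-9 preference
score per trial.  The signal model is deliberately minimal but spectrally
realistic:

* 1/f^chi Gaussian background synthesised in the frequency domain,
* a Gaussian alpha bump around 10 Hz,
* 60 Hz mains contamination,
* a class-dependent band-power effect: positive-scored trials carry extra
  band-limited noise in ``effect_band`` on ``effect_channels``, gated to the
  0-30 s application window, sized so the expected band power is multiplied
  by ``1 + effect_size``,
* per-trial per-channel multiplicative amplitude variability (log-normal),
  the trial-to-trial band-power fluctuation real EEG always shows; without
  it the per-subject class-conditional means that baseline correction
  divides by would differ only by microscopic estimation noise,
* per-subject per-channel multiplicative gain (log-normal) and additive DC
  offset, which create the cross-subject domain shift that baseline
  correction must undo.

Reproducibility: one master seed; every subject and every trial draws from
its own :class:`numpy.random.SeedSequence` spawned by key, so regenerating a
cohort (in any order) is bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import CHANNELS_19
from .errors import ConfigurationError

#: Continuous band edges (Hz, half-open) used for the injected effect.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "alpha": (7.0, 15.0),
    "beta": (15.0, 33.0),
    "low_gamma": (33.0, 70.0),
    "high_gamma": (70.0, 120.0),
}

POSITIVE_SCORES = (8, 9)
NEGATIVE_SCORES = (1, 2, 3, 4)
MID_SCORES = (5, 6, 7)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults follow the acquisition protocol being emulated: 16 analysable
    subjects, 8 trials each (4 creams x 2 sessions), 500 Hz, segments
    covering -15 s ... 55 s around the trigger.
    """

    n_subjects: int = 16
    n_trials_per_subject: int = 8
    sampling_rate: float = 500.0
    segment_span: tuple[float, float] = (-15.0, 55.0)
    channel_names: tuple[str, ...] = CHANNELS_19
    effect_size: float = 1.0
    effect_band: str = "low_gamma"
    effect_channels: tuple[str, ...] = ("F7", "F8", "T3", "T4")
    subject_gain_sd: float = 0.3
    subject_offset_sd: float = 5.0
    trial_gain_sd: float = 0.2
    line_noise_amp: float = 5.0
    score_model: str = "mixed"  # "mixed" | "positive_only" | "negative_only"
    seed: int = 0
    # Background spectrum shape (uV^2/Hz at 1 Hz; exponent chi; alpha bump).
    background_level: float = 18.0
    spectral_exponent: float = 1.0
    alpha_peak_freq: float = 10.0
    alpha_peak_width: float = 1.5
    alpha_peak_ratio: float = 1.0
    application_span: tuple[float, float] = (0.0, 30.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.n_trials_per_subject < 1:
            raise ConfigurationError("n_trials_per_subject must be >= 1")
        if self.sampling_rate <= 2 * 120.0:
            raise ConfigurationError(
                "sampling_rate must exceed twice the highest analysed frequency (120 Hz)")
        if self.segment_span[1] <= self.segment_span[0]:
            raise ConfigurationError("segment_span must be increasing")
        if self.effect_band not in BAND_EDGES:
            raise ConfigurationError(
                f"effect_band must be one of {sorted(BAND_EDGES)}, got {self.effect_band!r}")
        unknown = set(self.effect_channels) - set(self.channel_names)
        if unknown:
            raise ConfigurationError(f"effect_channels not in channel_names: {sorted(unknown)}")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.score_model not in ("mixed", "positive_only", "negative_only"):
            raise ConfigurationError(f"unknown score_model {self.score_model!r}")


@dataclass
class RawRecording:
    """One trial: a 19 x samples signal (uV) plus its provenance."""

    subject_id: str
    trial_id: int
    cream_id: int
    score: int
    signal: np.ndarray          # (n_channels, n_samples) float32, uV
    sampling_rate: float
    trigger_index: int          # sample index of application onset
    channel_names: tuple[str, ...] = CHANNELS_19

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def time_axis(self) -> np.ndarray:
        """Seconds relative to the trigger for every sample."""
        return (np.arange(self.n_samples) - self.trigger_index) / self.sampling_rate


def _background_psd(freqs: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    """One-sided background PSD (uV^2/Hz): 1/f^chi plus the alpha bump."""
    f = np.maximum(freqs, 1.0)  # flatten below 1 Hz; avoids the DC pole
    psd = cfg.background_level / f ** cfg.spectral_exponent
    peak = cfg.alpha_peak_ratio * cfg.background_level / cfg.alpha_peak_freq ** cfg.spectral_exponent
    psd = psd + peak * np.exp(-0.5 * ((freqs - cfg.alpha_peak_freq) / cfg.alpha_peak_width) ** 2)
    psd[freqs == 0] = 0.0
    return psd


def _synth_from_psd(psd: np.ndarray, n: int, fs: float, rng: np.random.Generator,
                    n_channels: int) -> np.ndarray:
    """Gaussian noise with the given one-sided PSD, by frequency-domain synthesis."""
    scale = np.sqrt(psd * fs * n / 2.0)
    zr = rng.standard_normal((n_channels, scale.size))
    zi = rng.standard_normal((n_channels, scale.size))
    coeffs = scale * (zr + 1j * zi) / np.sqrt(2.0)
    return np.fft.irfft(coeffs, n=n, axis=1)


def _draw_scores(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-trial 1-9 scores.

    ``mixed`` draws positive/negative/mid designations with probabilities
    0.5/0.35/0.15 and redraws until the subject has at least one positive and
    one negative trial, then samples a score uniformly within the designated
    range.  The single-class models force every trial into one range.
    """
    n = cfg.n_trials_per_subject
    if cfg.score_model == "positive_only":
        return rng.choice(POSITIVE_SCORES, size=n)
    if cfg.score_model == "negative_only":
        return rng.choice(NEGATIVE_SCORES, size=n)
    while True:
        kinds = rng.choice(3, size=n, p=[0.5, 0.35, 0.15])
        if (kinds == 0).any() and (kinds == 1).any():
            break
        if n < 2:  # cannot hold both classes; degenerate but legal config
            break
    pools = (POSITIVE_SCORES, NEGATIVE_SCORES, MID_SCORES)
    return np.array([rng.choice(pools[k]) for k in kinds])


def _render_trial(cfg: CohortConfig, trial_seed: np.random.SeedSequence,
                  score: int, gain: np.ndarray, offset: np.ndarray) -> np.ndarray:
    rng = np.random.Generator(np.random.PCG64(trial_seed))
    fs = cfg.sampling_rate
    t0, t1 = cfg.segment_span
    n = int(round((t1 - t0) * fs))
    n_ch = len(cfg.channel_names)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psd = _background_psd(freqs, cfg)

    sig = _synth_from_psd(psd, n, fs, rng, n_ch)

    # 60 Hz mains, random phase per channel
    t = np.arange(n) / fs
    phases = rng.uniform(0, 2 * np.pi, size=n_ch)
    sig += cfg.line_noise_amp * np.sin(2 * np.pi * 60.0 * t[None, :] + phases[:, None])

    # Class effect: band-limited noise with effect_size x the background band
    # power, on the effect channels, gated to the application window.
    if score in POSITIVE_SCORES and cfg.effect_size > 0 and cfg.effect_channels:
        lo, hi = BAND_EDGES[cfg.effect_band]
        band_psd = np.where((freqs >= lo) & (freqs < hi), psd * cfg.effect_size, 0.0)
        idx = [cfg.channel_names.index(c) for c in cfg.effect_channels]
        extra = _synth_from_psd(band_psd, n, fs, rng, len(idx))
        rel_t = t + t0  # seconds relative to trigger
        gate = (rel_t >= cfg.application_span[0]) & (rel_t < cfg.application_span[1])
        sig[idx] += extra * gate[None, :]

    # trial-to-trial amplitude variability (per channel)
    tgain = np.exp(rng.normal(0.0, cfg.trial_gain_sd, size=n_ch))
    return ((gain * tgain)[:, None] * sig + offset[:, None]).astype(np.float32)


def _subject_streams(cfg: CohortConfig, subj_idx: int):
    base = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(subj_idx,))
    rng = np.random.Generator(np.random.PCG64(base))
    gain = np.exp(rng.normal(0.0, cfg.subject_gain_sd, size=len(cfg.channel_names)))
    offset = rng.normal(0.0, cfg.subject_offset_sd, size=len(cfg.channel_names))
    scores = _draw_scores(cfg, rng)
    return gain, offset, scores


def generate_subject(cfg: CohortConfig, subj_idx: int,
                     subject_id: str | None = None) -> list[RawRecording]:
    """All trials for one subject (deterministic in ``cfg.seed`` and index)."""
    gain, offset, scores = _subject_streams(cfg, subj_idx)
    subject_id = subject_id or f"S{subj_idx + 1:02d}"
    recs = []
    trigger = int(round(-cfg.segment_span[0] * cfg.sampling_rate))
    for trial in range(cfg.n_trials_per_subject):
        tseed = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(subj_idx, trial))
        sig = _render_trial(cfg, tseed, int(scores[trial]), gain, offset)
        recs.append(RawRecording(
            subject_id=subject_id,
            trial_id=trial,
            cream_id=trial % 4 + 1,
            score=int(scores[trial]),
            signal=sig,
            sampling_rate=cfg.sampling_rate,
            trigger_index=trigger,
            channel_names=cfg.channel_names,
        ))
    return recs


def generate_cohort(cfg: CohortConfig) -> list[RawRecording]:
    """Generate ``n_subjects x n_trials_per_subject`` recordings."""
    recs: list[RawRecording] = []
    for s in range(cfg.n_subjects):
        recs.extend(generate_subject(cfg, s))
    return recs


def generate_single_class_subject(cfg: CohortConfig, class_label: str,
                                  subj_idx: int = 0,
                                  subject_id: str | None = None) -> list[RawRecording]:
    """A subject whose every trial falls in one class (exclusion fixture)."""
    if class_label not in ("positive", "negative"):
        raise ConfigurationError(f"class_label must be 'positive' or 'negative', got {class_label!r}")
    model = "positive_only" if class_label == "positive" else "negative_only"
    cfg1 = dataclasses.replace(cfg, score_model=model)
    return generate_subject(cfg1, subj_idx, subject_id=subject_id)


# ---------------------------------------------------------------------------
# On-disk container (uncompressed NPZ: deterministic bytes) + CSV manifest.

def save_cohort(recordings: list[RawRecording], path) -> None:
    sig = np.stack([r.signal for r in recordings])
    np.savez(
        path,
        signal=sig,
        subject_id=np.array([r.subject_id for r in recordings]),
        trial_id=np.array([r.trial_id for r in recordings]),
        cream_id=np.array([r.cream_id for r in recordings]),
        score=np.array([r.score for r in recordings]),
        trigger_index=np.array([r.trigger_index for r in recordings]),
        sampling_rate=np.array([r.sampling_rate for r in recordings]),
        channel_names=np.array(list(recordings[0].channel_names)),
    )


def load_cohort(path) -> list[RawRecording]:
    with np.load(path, allow_pickle=False) as z:
        names = tuple(str(c) for c in z["channel_names"])
        sig = z["signal"]
        subject = z["subject_id"]
        trial = z["trial_id"]
        cream = z["cream_id"]
        score = z["score"]
        trig = z["trigger_index"]
        fs = z["sampling_rate"]
        return [
            RawRecording(
                subject_id=str(subject[i]),
                trial_id=int(trial[i]),
                cream_id=int(cream[i]),
                score=int(score[i]),
                signal=sig[i],
                sampling_rate=float(fs[i]),
                trigger_index=int(trig[i]),
                channel_names=names,
            )
            for i in range(sig.shape[0])
        ]


def cohort_manifest(recordings: list[RawRecording]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in recordings],
            "trial_id": [r.trial_id for r in recordings],
            "cream_id": [r.cream_id for r in recordings],
            "score": [r.score for r in recordings],
        }
    )
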