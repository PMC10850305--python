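"""Synthetic EEG case-control cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes rather than biophysical realism: per-channel 1/f background noise;
a high-amplitude slow (1-8 Hz) global field with a bilateral +/- spatial
pattern, which gives every channel a strongly correlated neighbor (so clean
channels pass the neighbor-correlation criterion even after average
referencing) while leaving the beta/gamma bands spatially independent; a
shared posterior alpha rhythm; group-dependent band-limited coherence
injected between chosen channel pairs via a shared additive source;
confounded demographics (sex imbalance differing by group, ~6:1 class
imbalance); and sparse high-amplitude transient artifacts that exercise
the epoch-rejection rules.

Coherence control: for an effect pair the same band-limited source is added
to both channels with a mixing gain ``g`` expressed relative to the
channels' in-band background RMS, giving in-band magnitude coherence of
approximately ``g^2 / (1 + g^2)`` on top of the (group-independent)
baseline - a closed form used by the recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import BandSet
from .montage import CHANNELS, sort_pair
from .types import ParticipantMeta, Recording

#: sign of the slow global field per channel: left hemisphere and midline
#: positive, right hemisphere negative; every channel has a same-sign
#: neighbor, which is what sustains neighbor correlations under average
#: referencing on this sparse montage
_SLOW_FIELD_SIGN = {
    ch: (1.0 if ch in {"Fp1", "F7", "F3", "T3", "C3", "T5", "P3", "O1",
                       "Fz", "Cz", "Pz"} else -1.0)
    for ch in CHANNELS
}

#: relative weight of the shared alpha source per channel (posterior-dominant)
_ALPHA_WEIGHTS = {
    "O1": 1.0, "O2": 1.0,
    "Pz": 0.6, "P3": 0.6, "P4": 0.6, "T5": 0.6, "T6": 0.6,
    "C3": 0.3, "Cz": 0.3, "C4": 0.3,
}
_ALPHA_DEFAULT_WEIGHT = 0.1


@dataclass(frozen=True)
class EffectPair:
    """A channel pair receiving a shared band-limited source per group."""

    ch_a: str
    ch_b: str
    band: str
    gain_case: float
    gain_control: float


@dataclass
class SynthConfig:
    """Cohort generation settings.

    Defaults mirror the study conditions the pipeline targets: ~6:1 class
    imbalance, 5-minute recordings at 256 Hz, sex probabilities 0.87 (case)
    vs 0.714 (control), ages ~36 months (SD 14), and a tens-of-microvolt
    1/f background.
    """

    n_case: int = 246
    n_control: int = 42
    duration_s: float = 300.0
    sample_rate: float = 256.0
    effect_pairs: tuple[EffectPair, ...] = ()
    # background
    bg_exponent: float = 1.0  # PSD ~ 1/f^exponent
    bg_amplitude_uv: float = 20.0  # broadband SD per channel
    bg_white_floor: float = 0.1  # white noise added at this fraction of amplitude
    # slow global field (the spatially structured part of the background)
    slow_field_amp_uv: float = 40.0
    slow_field_lo_hz: float = 1.0
    slow_field_hi_hz: float = 6.0  # below the alpha search band
    slow_field_mod_sd: float = 0.15  # per-channel gain modulation
    # alpha rhythm
    alpha_amp_mean_uv: float = 6.0
    alpha_amp_sd_uv: float = 2.0
    alpha_absent_prob: float = 0.05
    alpha_freq_mean_hz: float = 10.0
    alpha_freq_sd_hz: float = 0.8
    # demographics
    sex_prob_case: float = 0.87
    sex_prob_control: float = 0.714
    age_mean_case: float = 36.4
    age_sd_case: float = 14.0
    age_mean_control: float = 38.7
    age_sd_control: float = 13.9
    optional_missing_rate: float = 0.33
    # artifacts
    artifact_rate_per_min: float = 0.2
    artifact_amp_uv: float = 15000.0
    artifact_width_s: float = 0.5
    seed: int = 0
    bands: BandSet = field(default_factory=BandSet)

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("group counts must be >= 1")
        for p in (self.sex_prob_case, self.sex_prob_control, self.alpha_absent_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        band_names = set(self.bands.names)
        for ep in self.effect_pairs:
            for ch in (ep.ch_a, ep.ch_b):
                if ch not in CHANNELS:
                    raise ValueError(f"effect pair references unknown channel {ch!r}")
            if ep.band not in band_names:
                raise ValueError(f"unknown band {ep.band!r} in effect pair")
            if ep.gain_case < 0 or ep.gain_control < 0:
                raise ValueError("mixing gains must be >= 0")


@dataclass
class GroundTruth:
    """What was injected, for recovery testing."""

    groups: dict[str, int]
    pair_gains: dict[str, list]  # participant -> [(ch_a, ch_b, band, gain), ...]
    affected_features: list[str]


def affected_feature_names(pairs: tuple[EffectPair, ...]) -> list[str]:
    """Coherence features whose group distribution the config truly shifts."""
    out = []
    for ep in pairs:
        if ep.gain_case != ep.gain_control:
            a, b = sort_pair(ep.ch_a, ep.ch_b)
            out.append(f"coh_{ep.band}_{a}_{b}")
    return sorted(set(out))


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def _band_limited_noise(n: int, fs: float, lo: float, hi: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to [lo, hi) Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f >= hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _one_over_f_noise(shape: tuple[int, int], fs: float, exponent: float,
                      white_floor: float, rng: np.random.Generator) -> np.ndarray:
    """Per-row independent 1/f^exponent noise with a white floor, unit SD."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape_f = np.zeros_like(f)
    shape_f[1:] = 1.0 / np.power(f[1:], exponent / 2.0)
    shape_f += white_floor
    shape_f[0] = 0.0
    x = np.fft.irfft(spec * shape_f, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _in_band_rms(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, d=1.0 / fs)
    mask = (f >= lo) & (f < hi)
    # Parseval on the rfft: variance contribution of the selected bins
    power = np.abs(spec[mask]) ** 2
    scale = np.ones(mask.sum())
    scale[(f[mask] > 0) & (f[mask] < fs / 2)] = 2.0
    return float(np.sqrt((power * scale).sum() / x.size**2))


def inject_band_coherence(x: np.ndarray, y: np.ndarray, band: tuple[float, float],
                          gain: float, seed: int | np.random.Generator = 0,
                          sample_rate: float = 256.0):
    """Add one shared band-limited source to both signals.

    The source is unit-variance band-limited Gaussian noise scaled by the
    geometric mean of the two signals' in-band RMS, so ``gain`` is a
    dimensionless mixing strength: in-band magnitude coherence rises from ~0
    toward 1 as ``gain`` grows (about ``g^2/(1+g^2)`` for independent
    backgrounds). ``gain = 0`` returns the inputs unchanged.
    """
    lo, hi = band
    if not (0.5 <= lo < hi <= 42.0):
        raise ValueError(f"band ({lo}, {hi}) outside the 0.5-42 Hz analysis range")
    if gain < 0:
        raise ValueError("gain must be >= 0")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if gain == 0:
        return x.copy(), y.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = _band_limited_noise(x.size, sample_rate, lo, hi, rng)
    scale = np.sqrt(_in_band_rms(x, sample_rate, lo, hi)
                    * _in_band_rms(y, sample_rate, lo, hi))
    if scale == 0:
        scale = 1.0
    return x + gain * scale * s, y + gain * scale * s


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_demographics(config: SynthConfig,
                          rng: np.random.Generator | None = None) -> list[ParticipantMeta]:
    """Draw participant metadata with group-specific sex/age distributions."""
    config.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    metas = []
    for i in range(config.n_case + config.n_control):
        case = i < config.n_case
        pid = f"sub-{i:04d}"
        p_male = config.sex_prob_case if case else config.sex_prob_control
        sex = "male" if rng.random() < p_male else "female"
        mu = config.age_mean_case if case else config.age_mean_control
        sd = config.age_sd_case if case else config.age_sd_control
        age = mu if sd == 0 else _truncated_normal(rng, mu, sd, low=1.0)
        height = _maybe_missing(rng, config.optional_missing_rate,
                                lambda: _truncated_normal(rng, 97.4, 8.3, low=60.0))
        weight = _maybe_missing(rng, config.optional_missing_rate,
                                lambda: _truncated_normal(rng, 15.5, 3.9, low=6.0))
        bmi = None
        if height is not None and weight is not None:
            bmi = weight / (height / 100.0) ** 2
        cars_mu = 32.8 if case else 25.1
        cars = _maybe_missing(rng, 0.06,
                              lambda: _truncated_normal(rng, cars_mu, 6.0, low=10.0))
        iq = _maybe_missing(rng, 0.39,
                            lambda: _truncated_normal(rng, 61.0 if case else 65.0, 9.0, low=40.0))
        metas.append(ParticipantMeta(pid, int(case), sex, age, height, weight,
                                     bmi, cars, iq))
    return metas


def _truncated_normal(rng, mu, sd, low):
    for _ in range(1000):
        v = rng.normal(mu, sd)
        if v > low:
            return float(v)
    return float(low + abs(rng.normal(0, sd)) + 1e-6)


def _maybe_missing(rng, rate, draw):
    return None if rng.random() < rate else draw()


def _generate_recording(pid: str, config: SynthConfig,
                        gains: list, rng: np.random.Generator) -> Recording:
    fs = config.sample_rate
    n = int(round(config.duration_s * fs))
    n_ch = len(CHANNELS)
    x = config.bg_amplitude_uv * _one_over_f_noise(
        (n_ch, n), fs, config.bg_exponent, config.bg_white_floor, rng)

    # slow bilateral field: shared 1-8 Hz source with a +/- spatial pattern
    # (and mild per-channel gain modulation); dominates the 1-20 Hz band so
    # neighboring clean channels stay strongly correlated
    if config.slow_field_amp_uv > 0:
        slow = _band_limited_noise(n, fs, config.slow_field_lo_hz,
                                   config.slow_field_hi_hz, rng)
        mod = 1.0 + config.slow_field_mod_sd * rng.standard_normal(n_ch)
        gains_slow = np.array([_SLOW_FIELD_SIGN[ch] for ch in CHANNELS]) * mod
        x += config.slow_field_amp_uv * gains_slow[:, None] * slow[None, :]

    # shared posterior alpha rhythm
    if rng.random() >= config.alpha_absent_prob:
        amp = max(0.0, rng.normal(config.alpha_amp_mean_uv, config.alpha_amp_sd_uv))
        f0 = rng.normal(config.alpha_freq_mean_hz, config.alpha_freq_sd_hz)
        f0 = float(np.clip(f0, 8.0, 13.0))
        s_alpha = _band_limited_noise(n, fs, f0 - 1.0, f0 + 1.0, rng)
        for i, ch in enumerate(CHANNELS):
            w = _ALPHA_WEIGHTS.get(ch, _ALPHA_DEFAULT_WEIGHT)
            x[i] += amp * w * s_alpha

    # group-dependent coherence injection
    for ch_a, ch_b, band_name, gain in gains:
        band = config.bands[band_name]
        ia, ib = CHANNELS.index(ch_a), CHANNELS.index(ch_b)
        x[ia], x[ib] = inject_band_coherence(
            x[ia], x[ib], (band.lo, band.hi), gain, rng, sample_rate=fs)

    # sparse high-amplitude transients
    n_art = rng.poisson(config.artifact_rate_per_min * config.duration_s / 60.0)
    w = int(round(config.artifact_width_s * fs))
    for _ in range(n_art):
        ch = rng.integers(0, n_ch)
        start = rng.integers(0, max(1, n - w))
        ramp = config.artifact_amp_uv * np.bartlett(w)
        x[ch, start:start + w] += ramp
    return Recording(pid, CHANNELS, fs, x)


def generate_cohort(config: SynthConfig):
    """Generate (recordings, metadata, ground truth) for a full cohort."""
    config.validate()
    root = np.random.SeedSequence([config.seed, 0])
    demo_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    metas = generate_demographics(config, demo_rng)
    child_seeds = root.spawn(len(metas))
    recordings, pair_gains, groups = [], {}, {}
    for meta, seq in zip(metas, child_seeds):
        gains = [(ep.ch_a, ep.ch_b, ep.band,
                  ep.gain_case if meta.group == 1 else ep.gain_control)
                 for ep in config.effect_pairs]
        rng = np.random.default_rng(seq)
        recordings.append(_generate_recording(meta.participant_id, config, gains, rng))
        pair_gains[meta.participant_id] = gains
        groups[meta.participant_id] = meta.group
    gt = GroundTruth(groups, pair_gains, affected_feature_names(config.effect_pairs))
    return recordings, metas, gt
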