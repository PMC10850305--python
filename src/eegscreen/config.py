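"""Pipeline configuration: frequency bands, filter/epoch/rejection settings,
matching and screening constants, classifier settings.

Every analysis constant of the pipeline lives here and can be overridden from
a single YAML document (see :func:`PipelineConfig.from_yaml`). Defaults follow
the study design the pipeline implements: five canonical bands on 0.5-42 Hz,
10-s epochs with 2-s overlap, 7-taper multitaper spectra (0.4 Hz
half-bandwidth), Bonferroni screening at level 0.1, K = 15 features passed to
forward selection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml


@dataclass(frozen=True)
class Band:
    name: str
    lo: float  # Hz, inclusive
    hi: float  # Hz, exclusive


@dataclass(frozen=True)
class BandSet:
    """The five canonical EEG bands; lower-inclusive, upper-exclusive."""

    bands: tuple[Band, ...] = (
        Band("delta", 1.0, 4.0),
        Band("theta", 4.0, 8.0),
        Band("alpha", 8.0, 13.0),
        Band("beta", 13.0, 30.0),
        Band("gamma", 30.0, 42.0),
    )
    total_lo: float = 0.5
    total_hi: float = 42.0

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError("at least one band required")
        prev_hi = None
        for b in self.bands:
            if not (b.lo < b.hi):
                raise ValueError(f"band {b.name}: lo must be < hi")
            if prev_hi is not None and b.lo < prev_hi:
                raise ValueError("bands must be non-overlapping and ordered")
            prev_hi = b.hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)


@dataclass
class FilterConfig:
    notch_hz: float = 50.0
    notch_width_hz: float = 2.0
    bandpass_lo_hz: float = 0.5
    bandpass_hi_hz: float = 42.0

    def validate(self) -> None:
        if not (0 < self.bandpass_lo_hz < self.bandpass_hi_hz):
            raise ValueError("invalid bandpass edges")
        if self.notch_hz <= 0 or self.notch_width_hz <= 0:
            raise ValueError("notch settings must be positive")


@dataclass
class EpochConfig:
    length_s: float = 10.0
    overlap_s: float = 2.0

    def validate(self) -> None:
        if self.length_s <= 0 or not (0 <= self.overlap_s < self.length_s):
            raise ValueError("need 0 <= overlap < length")


@dataclass
class RejectionThresholds:
    """Bad-channel and bad-epoch criteria.

    ``hf_stat`` selects how the high-frequency-noise criterion is measured:
    ``"uv"`` (default) compares each channel's >20 Hz residual SD in
    microvolts directly, removing channels *below* 4.5 uV - i.e. channels
    whose high-frequency content has died (flatlined or over-attenuated),
    while ordinary channels at tens-of-uV amplitudes sit well above it;
    ``"zscore"`` instead compares the residual SD as a robust z-score
    against the other channels (the convention of automated population-
    based cleaning tools). ``hf_rule`` sets the removal direction.
    """

    flat_seconds: float = 5.0
    flat_eps_uv: float = 1e-8  # |successive difference| floor defining "flat"
    hf_noise_sd_uv: float = 4.5
    hf_rule: str = "below"  # "above" | "below"
    hf_stat: str = "uv"  # "zscore" | "uv"
    hf_split_hz: float = 20.0  # residual = signal minus <=20 Hz low-pass
    neighbor_corr_min: float = 0.7
    corr_band_hz: tuple[float, float] = (1.0, 20.0)
    corr_window_s: float = 5.0  # correlation evaluated per window ...
    corr_bad_frac: float = 0.5  # ... removed when > this fraction of windows fail
    ptp_max_uv: float = 10_000.0
    ptp_min_uv: float = 0.1
    min_total_minutes: float = 1.0

    def validate(self) -> None:
        for name in ("flat_seconds", "hf_noise_sd_uv", "neighbor_corr_min",
                     "ptp_max_uv", "ptp_min_uv", "min_total_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.ptp_min_uv < self.ptp_max_uv:
            raise ValueError("ptp_min_uv must be < ptp_max_uv")
        if self.hf_rule not in ("above", "below"):
            raise ValueError("hf_rule must be 'above' or 'below'")
        if self.hf_stat not in ("zscore", "uv"):
            raise ValueError("hf_stat must be 'zscore' or 'uv'")


@dataclass
class MultitaperSpec:
    """DPSS multitaper settings.

    With K tapers the time-half-bandwidth is NW = (K + 1) / 2, so K = 7 on a
    10-s epoch gives NW = 4 and a half-bandwidth of 0.4 Hz.
    """

    n_tapers: int = 7

    def validate(self) -> None:
        if self.n_tapers < 1:
            raise ValueError("n_tapers must be >= 1")

    @property
    def nw(self) -> float:
        return (self.n_tapers + 1) / 2

    def half_bandwidth(self, epoch_length_s: float) -> float:
        """Spectral half-bandwidth in Hz for a given epoch length."""
        return self.nw / epoch_length_s


@dataclass
class AlphaPeakConfig:
    """Posterior alpha-peak presence flag settings (simplified peak search)."""

    search_lo_hz: float = 7.0
    search_hi_hz: float = 13.0
    channels: tuple[str, ...] = ("O1", "O2", "Pz")
    smooth_hz: float = 0.5  # moving-average width applied to the PSD
    prominence_frac: float = 0.25  # peak must exceed trend by this fraction (strict)


@dataclass
class ClassifyConfig:
    top_k: int = 15
    alpha_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    inner_folds: int = 5
    forward_tol: float = 1e-4
    max_missing_frac: float = 0.2  # candidate features missing above this are dropped
    bootstrap_reps: int = 1000
    threshold: float = 0.5  # confusion-matrix probability cut

    def validate(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k (K) must be >= 1")
        if len(self.alpha_grid) == 0 or any(a <= 0 for a in self.alpha_grid):
            raise ValueError("alpha_grid must be non-empty positive")
        if self.bootstrap_reps < 100:
            raise ValueError("bootstrap_reps must be >= 100")


@dataclass
class PipelineConfig:
    """All stage settings plus the root random seed.

    Randomness in every stochastic stage (synthetic data, bootstrap, inner CV
    shuffling) is derived deterministically from ``seed`` via per-stage
    spawning, so identical configs and inputs give identical outputs.
    """

    bands: BandSet = field(default_factory=BandSet)
    filters: FilterConfig = field(default_factory=FilterConfig)
    epochs: EpochConfig = field(default_factory=EpochConfig)
    rejection: RejectionThresholds = field(default_factory=RejectionThresholds)
    multitaper: MultitaperSpec = field(default_factory=MultitaperSpec)
    alpha_peak: AlphaPeakConfig = field(default_factory=AlphaPeakConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    covariates: tuple[str, ...] = ("age_months", "sex")
    matching_method: str = "full_match"  # "full_match" | "ipw"
    alpha_level: float = 0.1  # Bonferroni-adjusted significance level
    logit_eps: float = 1e-6  # boundary nudge before logit transforms
    seed: int = 0

    def validate(self) -> None:
        self.filters.validate()
        self.epochs.validate()
        self.rejection.validate()
        self.multitaper.validate()
        self.classify.validate()
        if self.matching_method not in ("full_match", "ipw"):
            raise ValueError("matching_method must be 'full_match' or 'ipw'")
        if not (0 < self.alpha_level < 1):
            raise ValueError("alpha_level must be in (0, 1)")

    # -- stage-level deterministic seed derivation -------------------------
    def stage_seed(self, stage: str) -> int:
        """A reproducible 31-bit seed for a named stage."""
        h = np.uint64(1469598103934665603)  # FNV-1a
        for b in f"{self.seed}:{stage}".encode():
            h = np.uint64((int(h) ^ b) * 1099511628211 % (1 << 64))
        return int(h % (1 << 31))

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return [conv(x) for x in obj]
            return obj
        return conv(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict = {}
        if "bands" in d:
            bd = d.pop("bands")
            kwargs["bands"] = BandSet(
                bands=tuple(Band(**b) for b in bd.get("bands", [])) or BandSet().bands,
                total_lo=bd.get("total_lo", 0.5),
                total_hi=bd.get("total_hi", 42.0),
            )
        simple = {
            "filters": FilterConfig, "epochs": EpochConfig,
            "rejection": RejectionThresholds, "multitaper": MultitaperSpec,
            "alpha_peak": AlphaPeakConfig, "classify": ClassifyConfig,
        }
        for key, klass in simple.items():
            if key in d:
                sub = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.pop(key).items()}
                kwargs[key] = klass(**sub)
        for key in ("covariates",):
            if key in d:
                d[key] = tuple(d[key])
        kwargs.update(d)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
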