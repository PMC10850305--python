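"""Core in-memory containers: recordings, epochs, participant metadata."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import CHANNELS, normalize_label


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is channels x samples; channel labels are canonical 10-20 names
    (a subset of the 19-channel montage), unique, in montage order or the
    order supplied by the source file.
    """

    participant_id: str
    channels: tuple[str, ...]
    sample_rate: float
    data: np.ndarray
    reference: str = "A1"

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows for {len(self.channels)} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        for ch in self.channels:
            if normalize_label(ch) != ch:
                raise ValueError(f"channel {ch!r} is not a canonical 10-20 label")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)

    def pick(self, channels: list[str] | tuple[str, ...]) -> "Recording":
        idx = [self.channels.index(ch) for ch in channels]
        return replace(self, channels=tuple(channels), data=self.data[idx])


@dataclass
class ParticipantMeta:
    """One participant's metadata row (case/control cohort design)."""

    participant_id: str
    group: int  # case = 1, control = 0
    sex: str  # "male" | "female"
    age_months: float
    height_cm: float | None = None
    weight_kg: float | None = None
    bmi: float | None = None
    cars_total: float | None = None
    iq: float | None = None

    def __post_init__(self) -> None:
        if self.group not in (0, 1):
            raise ValueError("group must be 0 (control) or 1 (case)")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not self.age_months > 0:
            raise ValueError("age_months must be positive")


_META_COLUMNS = [
    "participant_id", "group", "sex", "age_months",
    "height_cm", "weight_kg", "bmi", "cars_total", "iq",
]


def meta_to_frame(metas: list[ParticipantMeta]) -> pd.DataFrame:
    """Participant metadata as a DataFrame indexed by participant_id."""
    rows = [{c: getattr(m, c) for c in _META_COLUMNS} for m in metas]
    df = pd.DataFrame(rows, columns=_META_COLUMNS)
    if df["participant_id"].duplicated().any():
        raise ValueError("duplicate participant ids")
    return df.set_index("participant_id")


def frame_to_meta(df: pd.DataFrame) -> list[ParticipantMeta]:
    out = []
    frame = df.reset_index() if df.index.name == "participant_id" else df
    for _, row in frame.iterrows():
        kwargs = {}
        for c in _META_COLUMNS:
            v = row[c]
            if c in ("height_cm", "weight_kg", "bmi", "cars_total", "iq") and pd.isna(v):
                v = None
            kwargs[c] = v
        kwargs["group"] = int(kwargs["group"])
        kwargs["age_months"] = float(kwargs["age_months"])
        out.append(ParticipantMeta(**kwargs))
    return out


@dataclass
class EpochSet:
    """Fixed-length overlapping EEG segments with rejection provenance.

    ``epochs`` is n_epochs x n_channels x n_samples (microvolts), holding the
    retained epochs only; ``rejected_epochs`` maps original epoch indices to
    the reason they were dropped, and ``removed_channels`` does the same for
    channels excluded before epoching.
    """

    participant_id: str
    epochs: np.ndarray
    epoch_onsets: np.ndarray  # seconds, one per retained epoch
    sample_rate: float
    retained_channels: tuple[str, ...]
    removed_channels: dict[str, str] = field(default_factory=dict)
    rejected_epochs: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.epoch_onsets = np.asarray(self.epoch_onsets, dtype=np.float64)
        self.retained_channels = tuple(self.retained_channels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n_epochs x n_channels x n_samples")
        if self.epochs.shape[1] != len(self.retained_channels):
            raise ValueError("channel axis does not match retained_channels")
        if self.epochs.shape[0] != len(self.epoch_onsets):
            raise ValueError("one onset per retained epoch required")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_length_s(self) -> float:
        return self.epochs.shape[2] / self.sample_rate


@dataclass
class Exclusion:
    """A participant excluded from analysis, with the rule that fired."""

    participant_id: str
    reason: str


def montage_order(channels: list[str] | tuple[str, ...]) -> tuple[str, ...]:
    """Sort a set of canonical labels into fixed montage order."""
    return tuple(ch for ch in CHANNELS if ch in set(channels))
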