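"""Reading and writing recordings, metadata and feature tables.

Raw EEG travels either as EDF (read through mne; written by a minimal
16-bit EDF writer, since EDF is itself a 16-bit format) or as a delimited
text matrix with a small comment header - lossless, diffable, and the
format the synthetic generator emits by default. Metadata and feature
tables are CSV; feature values round-trip at full float64 precision and
missing entries stay empty cells.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import normalize_label
from .types import ParticipantMeta, Recording, frame_to_meta, meta_to_frame


class FormatError(ValueError):
    """Unreadable or malformed input file."""


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def _resolve_channels(labels: list[str]) -> tuple[list[int], list[str], list[str]]:
    idx, canonical, unknown = [], [], []
    for i, lab in enumerate(labels):
        canon = normalize_label(lab)
        if canon is None or canon in canonical:
            unknown.append(lab)
        else:
            idx.append(i)
            canonical.append(canon)
    return idx, canonical, unknown


def read_recording(path, fmt: str | None = None,
                   participant_id: str | None = None) -> Recording:
    """Read one recording from EDF or delimited text (format by extension).

    Channel labels are matched case-insensitively against the 19-channel
    10-20 montage (modern T7/T8/P7/P8 aliases accepted); unrecognized
    channels are dropped with a warning, and montage channels absent from
    the file simply stay absent. A file with no recognized channels is a
    fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        rec = _read_edf(path)
    elif fmt == "delimited":
        rec = _read_delimited(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if participant_id is not None:
        rec = Recording(participant_id, rec.channels, rec.sample_rate,
                        rec.data, rec.reference)
    return rec


def _read_edf(path: Path) -> Recording:
    import mne
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    idx, canonical, unknown = _resolve_channels(list(raw.ch_names))
    if unknown:
        warnings.warn(f"{path.name}: ignoring non-montage channels {unknown}")
    if not canonical:
        raise FormatError(f"{path}: no recognized 10-20 channels")
    data = raw.get_data(picks=idx) * 1e6  # mne loads volts; recordings are uV
    return Recording(path.stem, canonical, float(raw.info["sfreq"]), data)


def _read_delimited(path: Path) -> Recording:
    header: dict[str, str] = {}
    try:
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].partition("=")
                header[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no columns")
    idx, canonical, unknown = _resolve_channels(list(df.columns))
    if unknown:
        warnings.warn(f"{path.name}: ignoring non-montage channels {unknown}")
    if not canonical:
        raise FormatError(f"{path}: no recognized 10-20 channels")
    data = df.iloc[:, idx].to_numpy(float).T
    return Recording(
        header.get("participant_id", path.stem),
        canonical,
        float(header.get("sample_rate_hz", 256.0)),
        data,
        header.get("reference", "A1"),
    )


def write_recording(rec: Recording, path) -> None:
    """Write a recording as delimited text with a comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# participant_id={rec.participant_id}\n")
        fh.write(f"# sample_rate_hz={rec.sample_rate:g}\n")
        fh.write(f"# reference={rec.reference}\n")
        fh.write(",".join(rec.channels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.6f", delimiter=",")


def write_edf(rec: Recording, path) -> None:
    """Write a minimal EDF file (one 1-second data record per second).

    EDF stores 16-bit integers against per-channel physical ranges, so
    amplitudes are quantized to ~3e-5 of the channel's absolute maximum;
    a trailing partial second is dropped.
    """
    path = Path(path)
    fs = rec.sample_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    n_rec = rec.n_samples // spr
    ns = rec.n_channels
    data = rec.data[:, : n_rec * spr]

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    dig_max = 32767
    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(ns), 4),
    ])
    fields = [
        b"".join(pad(ch, 16) for ch in rec.channels),
        b"".join(pad("AgAgCl electrode", 80) for _ in range(ns)),
        b"".join(pad("uV", 8) for _ in range(ns)),
        b"".join(pad(f"{-m:.6g}"[:8], 8) for m in phys_max),
        b"".join(pad(f"{m:.6g}"[:8], 8) for m in phys_max),
        b"".join(pad(str(-dig_max), 8) for _ in range(ns)),
        b"".join(pad(str(dig_max), 8) for _ in range(ns)),
        b"".join(pad("", 80) for _ in range(ns)),
        b"".join(pad(str(spr), 8) for _ in range(ns)),
        b"".join(pad("", 32) for _ in range(ns)),
    ]
    # digitize against the *written* physical range (8-char decimal) so the
    # round trip is exact to 16-bit quantization
    written_max = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    scaled = np.clip(np.round(data / written_max[:, None] * dig_max),
                     -dig_max, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        for r in range(n_rec):
            block = scaled[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_feature_table(df: pd.DataFrame, path) -> None:
    """Features CSV: one row per participant, canonical columns, empty = missing."""
    df.to_csv(path, index=True, index_label="participant_id",
              float_format="%.17g")  # exact float64 round trip


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id",
                       float_precision="round_trip")


def write_metadata(metas: list[ParticipantMeta], path) -> None:
    meta_to_frame(metas).to_csv(path, index=True)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise FormatError(f"{path}: missing participant_id column")
    frame_to_meta(df)  # validates rows
    return df.set_index("participant_id")
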