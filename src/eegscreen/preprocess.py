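"""Preprocessing: filtering, re-referencing, bad-channel removal, epoching,
epoch rejection, and the minimum-retained-length exclusion rule.

The stage order is fixed: 50 Hz notch -> 0.5-42 Hz bandpass -> average
reference -> bad-channel removal -> 10-s epochs with 2-s overlap ->
peak-to-peak epoch rejection -> exclusion of participants with under one
minute of retained data. Bad channels are removed, never interpolated, so
any feature touching a removed channel is missing for that participant.
"""

from __future__ import annotations

import warnings

import numpy as np
from mne.filter import filter_data, notch_filter as _mne_notch

from .config import PipelineConfig, RejectionThresholds
from .montage import NEIGHBORS
from .types import EpochSet, Exclusion, Recording


def notch_filter(rec: Recording, freq: float = 50.0, width: float = 2.0) -> Recording:
    """Zero-phase FIR band-stop around the line frequency.

    On a line-contaminated signal the residual at ``freq`` is attenuated by
    well over 20 dB; the passband is left essentially untouched.
    """
    nyq = rec.sample_rate / 2
    if freq >= nyq:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist {nyq} Hz")
    out = _mne_notch(rec.data.copy(), rec.sample_rate, freqs=freq,
                     notch_widths=width, verbose="error")
    return rec.with_data(out)


def bandpass_filter(rec: Recording, lo: float = 0.5, hi: float = 42.0) -> Recording:
    """Zero-phase FIR bandpass (Hamming design)."""
    nyq = rec.sample_rate / 2
    if not (0 < lo < hi < nyq):
        raise ValueError(f"invalid band ({lo}, {hi}) for Nyquist {nyq} Hz")
    out = filter_data(rec.data.copy(), rec.sample_rate, l_freq=lo, h_freq=hi,
                      verbose="error")
    return rec.with_data(out)


def average_reference(rec: Recording) -> Recording:
    """Re-reference each sample to the instantaneous mean over channels."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(rec.participant_id, rec.channels, rec.sample_rate, out,
                     reference="average")


def _max_flat_run(x: np.ndarray, eps: float) -> int:
    """Longest run of consecutive samples whose successive difference is <= eps."""
    flat = np.abs(np.diff(x)) <= eps
    if not flat.any():
        return 0
    # run-length encode the boolean vector
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = np.r_[0, changes + 1]
    ends = np.r_[changes, flat.size - 1]
    runs = ends - starts + 1
    longest = int(runs[flat[starts]].max())
    return longest + 1  # n flat diffs span n+1 samples


def detect_bad_channels(
    rec: Recording, thr: RejectionThresholds
) -> tuple[tuple[str, ...], dict[str, str]]:
    """Flag channels as bad by flatness, high-frequency noise, or neighbor
    decorrelation; returns (retained, removed-with-reason).

    A channel is removed iff it has a flat run longer than ``flat_seconds``,
    its high-frequency residual noise violates the HF criterion, or its best
    Pearson correlation with any montage neighbor (on 1-20 Hz band-passed
    signals, whole recording) is below ``neighbor_corr_min``. All three
    criteria are evaluated on the input recording; reasons are concatenated
    when several fire.
    """
    fs = rec.sample_rate
    reasons: dict[str, list[str]] = {ch: [] for ch in rec.channels}

    # (a) flat activity
    flat_span = int(round(thr.flat_seconds * fs))
    for i, ch in enumerate(rec.channels):
        if _max_flat_run(rec.data[i], thr.flat_eps_uv) > flat_span:
            reasons[ch].append("flat")

    # (b) high-frequency residual noise
    low = filter_data(rec.data.copy(), fs, l_freq=None, h_freq=thr.hf_split_hz,
                      verbose="error")
    hf_sd = (rec.data - low).std(axis=1)
    if thr.hf_stat == "zscore":
        med = np.median(hf_sd)
        mad = np.median(np.abs(hf_sd - med)) * 1.4826  # normal-consistent MAD
        stat = (hf_sd - med) / mad if mad > 0 else np.zeros_like(hf_sd)
    else:
        stat = hf_sd
    bad_hf = stat > thr.hf_noise_sd_uv if thr.hf_rule == "above" else stat < thr.hf_noise_sd_uv
    for i, ch in enumerate(rec.channels):
        if bad_hf[i]:
            reasons[ch].append("hf_noise")

    # (c) neighbor correlation, evaluated in windows with a majority rule: a
    # channel is decorrelated only when its best neighbor correlation falls
    # below threshold in more than ``corr_bad_frac`` of the windows, so a
    # brief high-amplitude transient (an epoch-rejection matter, not a
    # channel fault) cannot condemn the whole channel
    lo, hi = thr.corr_band_hz
    banded = filter_data(rec.data.copy(), fs, l_freq=lo, h_freq=hi, verbose="error")
    win = max(1, int(round(thr.corr_window_s * fs)))
    n_win = max(1, banded.shape[1] // win)
    fail = np.zeros((len(rec.channels), n_win))
    has_nb = np.zeros(len(rec.channels), dtype=bool)
    nb_indices = []
    for i, ch in enumerate(rec.channels):
        nb_idx = [j for j, other in enumerate(rec.channels)
                  if other in NEIGHBORS[ch] and j != i]
        nb_indices.append(nb_idx)
        has_nb[i] = bool(nb_idx)
    for k in range(n_win):
        seg = banded[:, k * win:(k + 1) * win] if n_win > 1 else banded
        with np.errstate(invalid="ignore"):
            cmat = np.corrcoef(seg)
        for i in range(len(rec.channels)):
            if not has_nb[i]:
                continue  # no neighbors present: criterion void
            best = np.nanmax(cmat[i, nb_indices[i]])
            fail[i, k] = 0.0 if best >= thr.neighbor_corr_min else 1.0
    for i, ch in enumerate(rec.channels):
        if has_nb[i] and fail[i].mean() > thr.corr_bad_frac:
            reasons[ch].append("correlation")

    removed = {ch: "+".join(r) for ch, r in reasons.items() if r}
    retained = tuple(ch for ch in rec.channels if ch not in removed)
    return retained, removed


def make_epochs(rec: Recording, length_s: float = 10.0, overlap_s: float = 2.0) -> EpochSet:
    """Segment a recording into fixed-length overlapping epochs.

    Consecutive onsets are ``length - overlap`` apart; the trailing remainder
    shorter than one epoch is discarded. A recording shorter than one epoch
    yields an empty EpochSet with a warning.
    """
    if not (0 <= overlap_s < length_s):
        raise ValueError("need 0 <= overlap < length")
    n_len = int(round(length_s * rec.sample_rate))
    step = int(round((length_s - overlap_s) * rec.sample_rate))
    if rec.n_samples < n_len:
        warnings.warn(f"recording {rec.participant_id}: shorter than one epoch")
        return EpochSet(rec.participant_id,
                        np.empty((0, rec.n_channels, n_len)),
                        np.empty(0), rec.sample_rate, rec.channels)
    n_epochs = (rec.n_samples - n_len) // step + 1
    starts = np.arange(n_epochs) * step
    epochs = np.stack([rec.data[:, s:s + n_len] for s in starts])
    return EpochSet(rec.participant_id, epochs, starts / rec.sample_rate,
                    rec.sample_rate, rec.channels)


def reject_epochs(es: EpochSet, thr: RejectionThresholds) -> EpochSet:
    """Drop epochs by peak-to-peak amplitude.

    An epoch is rejected iff the maximum over channels of its peak-to-peak
    amplitude exceeds ``ptp_max_uv`` or the minimum over channels falls below
    ``ptp_min_uv``. Idempotent; previously recorded rejections are preserved.
    """
    if es.n_epochs == 0:
        return es
    ptp = es.epochs.max(axis=2) - es.epochs.min(axis=2)  # epochs x channels
    too_big = ptp.max(axis=1) > thr.ptp_max_uv
    too_small = ptp.min(axis=1) < thr.ptp_min_uv
    keep = ~(too_big | too_small)

    # map positions back to original epoch indices (survive re-runs)
    all_idx = sorted(set(range(es.n_epochs + len(es.rejected_epochs)))
                     - set(es.rejected_epochs))
    rejected = dict(es.rejected_epochs)
    for pos in np.flatnonzero(~keep):
        reason = "ptp_max" if too_big[pos] else "ptp_min"
        rejected[all_idx[pos]] = reason
    return EpochSet(es.participant_id, es.epochs[keep], es.epoch_onsets[keep],
                    es.sample_rate, es.retained_channels,
                    dict(es.removed_channels), rejected)


def preprocess_recording(
    rec: Recording, cfg: PipelineConfig
) -> EpochSet | Exclusion:
    """Run the full preprocessing chain on one recording.

    Returns an :class:`Exclusion` when no channels survive bad-channel
    removal or when the retained epochs total less than
    ``min_total_minutes`` (counting each retained epoch at full epoch
    length).
    """
    f = cfg.filters
    out = notch_filter(rec, f.notch_hz, f.notch_width_hz)
    out = bandpass_filter(out, f.bandpass_lo_hz, f.bandpass_hi_hz)
    out = average_reference(out)
    retained, removed = detect_bad_channels(out, cfg.rejection)
    if len(retained) == 0:
        return Exclusion(rec.participant_id, "no channels remain")
    out = out.pick(list(retained))
    es = make_epochs(out, cfg.epochs.length_s, cfg.epochs.overlap_s)
    es = EpochSet(es.participant_id, es.epochs, es.epoch_onsets, es.sample_rate,
                  es.retained_channels, removed, {})
    es = reject_epochs(es, cfg.rejection)
    total_s = es.n_epochs * cfg.epochs.length_s
    if total_s < cfg.rejection.min_total_minutes * 60.0:
        return Exclusion(rec.participant_id, "under 1 min")
    return es
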