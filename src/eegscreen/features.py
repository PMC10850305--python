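"""Extraction of the 1,046-dimensional EEG feature vector.

Per participant: 95 relative band powers (5 bands x 19 channels), 855 band
coherences (5 bands x 171 channel pairs), 95 time-domain statistics (5
statistics x 19 channels) and 1 posterior alpha-presence flag. Power and
time-domain statistics are computed per 10-s epoch and averaged across
epochs; coherence is computed once from cross-spectra pooled over all epochs
and tapers (single-epoch multitaper coherence is strongly biased upward, so
pooling is the stable estimator for the same quantity).

Feature names and their order are canonical and frozen:
``relpower_{band}_{ch}``, then ``coh_{band}_{chA}_{chB}`` with A before B in
montage order, then ``{sampen|skew|kurt|sd|mean}_{ch}``, then
``alpha_present``. Features touching a removed channel are missing (NaN),
never zero-filled.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss
from scipy.spatial import cKDTree

from .config import AlphaPeakConfig, BandSet, MultitaperSpec, PipelineConfig
from .montage import CHANNELS
from .types import EpochSet

STAT_NAMES = ("sampen", "skew", "kurt", "sd", "mean")


def feature_names(bands: BandSet | None = None,
                  channels: tuple[str, ...] = CHANNELS) -> list[str]:
    """The frozen canonical feature-name list (1,046 at full montage)."""
    bands = bands or BandSet()
    names = [f"relpower_{b}_{ch}" for b in bands.names for ch in channels]
    names += [f"coh_{b}_{a}_{c}" for b in bands.names
              for a, c in itertools.combinations(channels, 2)]
    names += [f"{s}_{ch}" for s in STAT_NAMES for ch in channels]
    names.append("alpha_present")
    return names


# ---------------------------------------------------------------------------
# multitaper spectra
# ---------------------------------------------------------------------------

def _taper_spectra(epochs: np.ndarray, fs: float, spec: MultitaperSpec):
    """DPSS-tapered one-sided spectra of each epoch/channel.

    Returns ``(freqs, X)`` with ``X`` of shape
    (n_epochs, n_channels, n_tapers, n_freqs), scaled so that
    ``2 * |X|^2`` is a one-sided PSD in uV^2/Hz on the rfft grid.
    """
    n = epochs.shape[-1]
    if spec.n_tapers >= n:
        raise ValueError("more tapers than samples")
    tapers = dpss(n, spec.nw, Kmax=spec.n_tapers)  # each with unit energy
    freqs = rfftfreq(n, d=1.0 / fs)
    X = rfft(epochs[:, :, None, :] * tapers[None, None, :, :], axis=-1)
    X /= np.sqrt(fs)
    return freqs, X


def multitaper_psd(es: EpochSet, spec: MultitaperSpec | None = None):
    """Per-epoch, per-channel one-sided multitaper PSD (uV^2/Hz).

    Returns ``(freqs, psd)`` with psd of shape (n_epochs, n_channels,
    n_freqs); the grid spacing is ``sample_rate / n_samples``. Integrating
    the PSD over frequency recovers the signal variance (Parseval).
    """
    spec = spec or MultitaperSpec()
    if es.n_epochs == 0:
        raise ValueError("no epochs")
    freqs, X = _taper_spectra(es.epochs, es.sample_rate, spec)
    psd = (np.abs(X) ** 2).mean(axis=2)
    psd *= 2.0
    psd[..., 0] /= 2.0
    if es.epochs.shape[-1] % 2 == 0:
        psd[..., -1] /= 2.0
    return freqs, psd


def _band_masks(freqs: np.ndarray, bands: BandSet):
    masks = {b.name: (freqs >= b.lo) & (freqs < b.hi) for b in bands.bands}
    total = (freqs >= bands.total_lo) & (freqs <= bands.total_hi)
    return masks, total


def relative_band_power(freqs: np.ndarray, psd: np.ndarray,
                        bands: BandSet | None = None) -> dict[str, np.ndarray]:
    """Band power as a fraction of total 0.5-42 Hz power, per channel.

    Normalization is applied within each epoch, then averaged across epochs.
    Channels with zero total power in an epoch give missing values (NaN)
    with a warning.
    """
    bands = bands or BandSet()
    masks, total_mask = _band_masks(freqs, bands)
    total = psd[..., total_mask].sum(axis=-1)  # epochs x channels
    bad = total <= 0
    if bad.any():
        warnings.warn("zero total power in some epochs/channels; values missing")
        total = np.where(bad, np.nan, total)
    out = {}
    for name, mask in masks.items():
        frac = psd[..., mask].sum(axis=-1) / total
        out[name] = np.nanmean(np.where(bad, np.nan, frac), axis=0)
    return out


def band_coherence(es: EpochSet, bands: BandSet | None = None,
                   spec: MultitaperSpec | None = None) -> dict[str, np.ndarray]:
    """Magnitude coherence per band for every unordered channel pair.

    Cross- and auto-spectra are averaged over all tapers and epochs before
    the magnitude ratio ``|S_xy| / sqrt(S_xx S_yy)``; the band value is the
    unweighted mean over in-band frequency bins. Returns, per band, a
    symmetric n_channels x n_channels matrix with unit diagonal.
    """
    bands = bands or BandSet()
    spec = spec or MultitaperSpec()
    if es.n_epochs < 1:
        raise ValueError("coherence needs at least one epoch")
    if len(es.retained_channels) < 2:
        raise ValueError("coherence needs at least two channels")
    if es.n_epochs * spec.n_tapers < 2:
        warnings.warn("single epoch and taper: coherence is degenerate (identically 1)")
    freqs, X = _taper_spectra(es.epochs, es.sample_rate, spec)
    masks, _ = _band_masks(freqs, bands)
    keep = np.zeros(freqs.size, dtype=bool)
    for m in masks.values():
        keep |= m
    Xk = X[..., keep]
    sub = {name: mask[keep] for name, mask in masks.items()}
    n_ch = Xk.shape[1]
    # pooled cross-spectral matrix: channels x channels x freqs
    Z = np.moveaxis(Xk, 1, 0).reshape(n_ch, -1, Xk.shape[-1])
    S = np.einsum("aef,bef->abf", Z, Z.conj()) / Z.shape[1]
    auto = np.real(np.einsum("aaf->af", S))
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        coh_f = np.abs(S) / denom
    out = {}
    for name, m in sub.items():
        c = coh_f[..., m].mean(axis=-1)
        np.fill_diagonal(c, 1.0)
        out[name] = np.clip(c, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# time-domain statistics
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, m)


try:  # numba accelerates the O(n^2) template counting when available
    from numba import njit

    @njit(cache=False, fastmath=False)
    def _sampen_counts(x: np.ndarray, m: int, r: float,
                       order: np.ndarray):  # pragma: no cover
        # templates sorted by first coordinate: pairs further apart than r
        # on that coordinate can be skipped wholesale
        nt = x.size - m
        b = 0
        a = 0
        for oi in range(nt):
            i = order[oi]
            xi = x[i]
            for oj in range(oi + 1, nt):
                j = order[oj]
                if x[j] - xi > r:
                    break
                ok = True
                for k in range(1, m):
                    d = x[i + k] - x[j + k]
                    if d > r or -d > r:
                        ok = False
                        break
                if ok:
                    b += 1
                    d = x[i + m] - x[j + m]
                    if not (d > r or -d > r):
                        a += 1
        return a, b

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -log(A/B) with Chebyshev template matching.

    ``B`` counts pairs of length-``m`` templates within tolerance ``r``
    (default 0.2 x SD of the signal), ``A`` the same for length ``m + 1``;
    self-matches are excluded and both counts use the first ``n - m``
    starting points. A constant signal returns 0 (every template matches at
    both lengths); zero match counts give NaN with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n <= m + 1:
        raise ValueError("signal too short for sample entropy")
    if r is None:
        r = 0.2 * x.std()
    n_templates = n - m
    if r == 0 and np.ptp(x) == 0:
        return 0.0

    if _HAVE_NUMBA:
        xc = np.ascontiguousarray(x)
        order = np.argsort(xc[:n_templates], kind="stable")
        a, b = _sampen_counts(xc, m, r, order)
    else:
        def _pairs(emb: np.ndarray) -> int:
            tree = cKDTree(emb)
            total = tree.count_neighbors(tree, r, p=np.inf)
            return (int(total) - emb.shape[0]) // 2

        b = _pairs(_embed(x, m)[:n_templates])
        a = _pairs(_embed(x, m + 1)[:n_templates])
    if a == 0 or b == 0:
        warnings.warn("sample entropy undefined: zero template matches")
        return float("nan")
    return float(-np.log(a / b))


def time_domain_stats(es: EpochSet) -> dict[str, np.ndarray]:
    """Per-channel sample entropy, skewness, excess kurtosis, SD and mean.

    Each statistic is computed within every epoch and averaged across
    epochs. Skewness and kurtosis use the bias-corrected Fisher conventions.
    """
    if es.n_epochs < 1:
        raise ValueError("no epochs")
    ep = es.epochs
    means = ep.mean(axis=2)
    sds = ep.std(axis=2, ddof=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skews = sstats.skew(ep, axis=2, bias=False)
        kurts = sstats.kurtosis(ep, axis=2, fisher=True, bias=False)
    sampens = np.empty_like(means)
    for e in range(ep.shape[0]):
        for c in range(ep.shape[1]):
            sampens[e, c] = sample_entropy(ep[e, c])
    agg = lambda a: np.nanmean(a, axis=0)
    return {"sampen": agg(sampens), "skew": agg(skews), "kurt": agg(kurts),
            "sd": agg(sds), "mean": agg(means)}


# ---------------------------------------------------------------------------
# alpha-presence flag
# ---------------------------------------------------------------------------

def detect_alpha_presence(freqs: np.ndarray, psd: np.ndarray,
                          cfg: AlphaPeakConfig | None = None) -> int:
    """1 iff the (smoothed) posterior PSD has a distinct 7-13 Hz peak.

    ``psd`` is the epoch-averaged PSD of the posterior channels (mean over
    channels). A local maximum qualifies when it strictly exceeds the local
    1/f trend - the log-log interpolation of the PSD between the search-band
    edges - by more than ``prominence_frac``.
    """
    cfg = cfg or AlphaPeakConfig()
    psd = np.asarray(psd, dtype=np.float64)
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    win = max(1, int(round(cfg.smooth_hz / df)))
    kernel = np.ones(win) / win
    smooth = np.convolve(psd, kernel, mode="same")
    band = (freqs >= cfg.search_lo_hz) & (freqs <= cfg.search_hi_hz)
    idx = np.flatnonzero(band)
    if idx.size < 3:
        return 0
    lo_i, hi_i = idx[0], idx[-1]
    p_lo, p_hi = smooth[lo_i], smooth[hi_i]
    if p_lo <= 0 or p_hi <= 0:
        return 0
    # 1/f trend: straight line between the band edges in log-log coordinates
    lf = np.log(freqs[idx])
    trend = np.exp(np.log(p_lo) + (np.log(p_hi) - np.log(p_lo))
                   * (lf - lf[0]) / (lf[-1] - lf[0]))
    seg = smooth[idx]
    interior = np.arange(1, idx.size - 1)
    is_peak = (seg[interior] > seg[interior - 1]) & (seg[interior] > seg[interior + 1])
    qualifies = seg[interior] > (1.0 + cfg.prominence_frac) * trend[interior]
    return int(bool(np.any(is_peak & qualifies)))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_features(es: EpochSet, cfg: PipelineConfig | None = None) -> pd.Series:
    """Assemble the full named feature vector for one participant.

    Returns a Series over the frozen 1,046-name index; every feature that
    references a removed channel is NaN.
    """
    cfg = cfg or PipelineConfig()
    bands = cfg.bands
    names = feature_names(bands)
    out = pd.Series(np.nan, index=names, name=es.participant_id)
    chs = es.retained_channels
    if es.n_epochs == 0 or len(chs) == 0:
        return out

    freqs, psd = multitaper_psd(es, cfg.multitaper)
    rel = relative_band_power(freqs, psd, bands)
    for b in bands.names:
        for i, ch in enumerate(chs):
            out[f"relpower_{b}_{ch}"] = rel[b][i]

    if len(chs) >= 2:
        coh = band_coherence(es, bands, cfg.multitaper)
        pos = {ch: i for i, ch in enumerate(chs)}
        for b in bands.names:
            mat = coh[b]
            for a, c in itertools.combinations(CHANNELS, 2):
                if a in pos and c in pos:
                    out[f"coh_{b}_{a}_{c}"] = mat[pos[a], pos[c]]

    stats_ = time_domain_stats(es)
    for s in STAT_NAMES:
        for i, ch in enumerate(chs):
            out[f"{s}_{ch}"] = stats_[s][i]

    post = [ch for ch in cfg.alpha_peak.channels if ch in chs] or list(chs)
    pidx = [chs.index(ch) for ch in post]
    mean_psd = psd[:, pidx, :].mean(axis=(0, 1))
    out["alpha_present"] = float(detect_alpha_presence(freqs, mean_psd, cfg.alpha_peak))
    return out


def extract_feature_table(epoch_sets: list[EpochSet],
                          cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Feature extraction for a cohort: participants x 1,046 features."""
    cfg = cfg or PipelineConfig()
    rows = [extract_features(es, cfg) for es in epoch_sets]
    df = pd.DataFrame(rows)
    df.index.name = "participant_id"
    return df
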