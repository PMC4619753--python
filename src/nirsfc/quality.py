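"""Channel and subject quality control.

Two independent checks identify unusable data before connectivity analysis:

* a *motion* check — the moving standard deviation (MSD) of the concentration
  signal within sliding windows; samples whose MSD exceeds
  ``mean(MSD) + T * sd(MSD)`` (default T = 5) are flagged as motion artifacts;
* an *SNR* check — the per-channel mean/sd ratio of the raw optical intensity
  (poor optode-scalp contact gives low SNR) cross-checked against each
  channel's mean absolute correlation with all other channels, since a
  noise-dominated channel correlates with nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConcentrationSeries, RawRecording

__all__ = [
    "ArtifactScan",
    "QCThresholds",
    "QCReport",
    "moving_std",
    "detect_motion",
    "channel_snr",
    "correlation_quality",
    "qc_report",
]


def moving_std(series: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    """Centered sliding-window sample standard deviation.

    Window length is ``round(window_s * fs)`` samples; edge windows are
    truncated (minimum 2 samples) so the output aligns sample-for-sample with
    the input.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 2:
        return np.vstack([moving_std(row, window_s, fs) for row in x])
    if x.size < 2:
        raise ValueError("moving_std needs at least 2 samples")
    n = int(round(window_s * fs))
    if n < 2:
        raise ValueError(f"window of {n} samples too short (need >= 2)")
    n = min(n, x.size)
    half_lo = (n - 1) // 2
    half_hi = n - half_lo
    out = np.empty_like(x)
    if x.size >= n:
        windows = np.lib.stride_tricks.sliding_window_view(x, n)
        out[half_lo:x.size - n + half_lo + 1] = windows.std(axis=1, ddof=1)
    for i in range(half_lo):
        out[i] = x[:max(i + half_hi, 2)].std(ddof=1)
    for i in range(x.size - n + half_lo + 1, x.size):
        lo = min(i - half_lo, x.size - 2)
        out[i] = x[lo:].std(ddof=1)
    return out


@dataclass
class ArtifactScan:
    """Motion-artifact detection result for one recording."""

    msd: np.ndarray  # channels x time
    window_s: float
    threshold_sd: float
    segments: list[list[tuple[int, int]]]  # per channel, [start, end) sample intervals

    def flagged_fraction(self) -> np.ndarray:
        """Per-channel fraction of samples inside flagged segments."""
        n = self.msd.shape[1]
        return np.array([sum(e - s for s, e in segs) / n for segs in self.segments])


def detect_motion(series: np.ndarray, fs: float, window_s: float = 2.0,
                  threshold_sd: float = 5.0,
                  absolute_threshold: float | None = None) -> ArtifactScan:
    """Flag motion artifacts from the moving standard deviation.

    The default rule flags MSD values more than ``threshold_sd`` standard
    deviations above the MSD mean; ``absolute_threshold`` switches to a fixed
    MSD cutoff instead.  Contiguous flagged samples are merged into segments.
    """
    from .preprocess import _flags_to_segments

    x = np.atleast_2d(np.asarray(series, dtype=float))
    msd = moving_std(x, window_s, fs)
    segments = []
    for c in range(x.shape[0]):
        if absolute_threshold is not None:
            thr = absolute_threshold
        else:
            thr = msd[c].mean() + threshold_sd * msd[c].std(ddof=1)
        segments.append(_flags_to_segments(msd[c] > thr, merge_gap=0))
    return ArtifactScan(msd=msd, window_s=window_s, threshold_sd=threshold_sd,
                        segments=segments)


def channel_snr(rec: RawRecording | np.ndarray) -> np.ndarray:
    """Per-channel SNR of the raw intensity: temporal mean / sample sd.

    Zero-variance channels get an infinite-SNR marker with a warning (a flat
    detector reading is not evidence of good contact).
    """
    x = rec.intensity if isinstance(rec, RawRecording) else np.atleast_2d(rec)
    if x.shape[1] < 2:
        raise ValueError("SNR needs at least 2 time points")
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"constant-intensity channels {(np.where(flat)[0] + 1).tolist()} "
            "(1-based): SNR reported as inf")
    with np.errstate(divide="ignore"):
        return np.where(flat, np.inf, mean / np.where(flat, 1.0, sd))


def correlation_quality(conc: ConcentrationSeries | np.ndarray,
                        signal: str = "hbo") -> np.ndarray:
    """Each channel's mean absolute Pearson correlation with all others.

    Channels whose signal barely correlates with the rest of the array are
    low-SNR candidates.  A zero-variance channel has undefined correlations
    and is reported as 0.
    """
    x = conc.signal(signal) if isinstance(conc, ConcentrationSeries) else np.atleast_2d(conc)
    n = x.shape[0]
    if n < 3:
        raise ValueError("correlation quality needs >= 3 channels")
    sd = x.std(axis=1)
    ok = sd > 0
    out = np.zeros(n)
    if ok.sum() >= 2:
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(x)
        r = np.abs(r)
        np.fill_diagonal(r, np.nan)
        r[~ok, :] = np.nan
        r[:, ~ok] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(r, axis=1)
        out[ok] = means[ok]
    if (~ok).any():
        warnings.warn(
            f"zero-variance channels {(np.where(~ok)[0] + 1).tolist()} "
            "(1-based) reported with mean |r| = 0")
    return out


@dataclass
class QCThresholds:
    """Pass/fail cutoffs; all configurable, defaults documented in the docs."""

    snr_min: float = 20.0
    corr_min: float = 0.05
    channel_frac_max: float = 0.2
    time_frac_max: float = 0.2
    window_s: float = 2.0
    threshold_sd: float = 5.0
    motion_signal: str = "hbo"


@dataclass
class QCReport:
    """Combined quality verdict for one subject."""

    subject_id: str
    snr: np.ndarray
    mean_abs_corr: np.ndarray
    motion_fraction: np.ndarray  # per concentration channel
    flagged_channels: dict[int, list[str]]  # 0-based channel -> reasons
    subject_pass: bool
    fail_reasons: list[str]
    thresholds: QCThresholds
    scan: ArtifactScan | None = None

    def to_dataframe(self) -> pd.DataFrame:
        """One row per intensity channel, 1-based ids for reporting."""
        n = len(self.snr)
        mc = self.mean_abs_corr
        mf = self.motion_fraction
        rows = []
        for c in range(n):
            rows.append({
                "channel": c + 1,
                "snr": self.snr[c],
                "mean_abs_corr": mc[c % len(mc)] if len(mc) else np.nan,
                "motion_fraction": mf[c % len(mf)] if len(mf) else np.nan,
                "flags": ";".join(self.flagged_channels.get(c, [])),
            })
        return pd.DataFrame(rows)


def qc_report(rec: RawRecording, conc: ConcentrationSeries,
              thresholds: QCThresholds | None = None) -> QCReport:
    """Run the SNR, correlation and motion checks and combine them.

    A subject fails when the fraction of flagged channels exceeds
    ``channel_frac_max`` or the mean flagged-time fraction exceeds
    ``time_frac_max``.  Every flagged channel carries explicit reasons
    (low-snr, low-correlation, motion).
    """
    thr = thresholds or QCThresholds()
    snr = channel_snr(rec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        corr = correlation_quality(conc, thr.motion_signal)
    scan = detect_motion(conc.signal(thr.motion_signal), conc.sampling_rate,
                         window_s=thr.window_s, threshold_sd=thr.threshold_sd)
    motion_frac = scan.flagged_fraction()

    pairs_per_wl = conc.n_channels
    flagged: dict[int, list[str]] = {}

    def flag(ch: int, reason: str) -> None:
        flagged.setdefault(ch, []).append(reason)

    for c in range(rec.n_channels):
        if snr[c] < thr.snr_min:
            flag(c, "low-snr")
    for p in range(pairs_per_wl):
        if corr[p] < thr.corr_min:
            flag(p, "low-correlation")
        if motion_frac[p] > thr.time_frac_max:
            flag(p, "motion")

    channel_frac = len(flagged) / rec.n_channels
    time_frac = float(motion_frac.mean()) if motion_frac.size else 0.0
    reasons = []
    if channel_frac > thr.channel_frac_max:
        reasons.append(
            f"flagged channel fraction {channel_frac:.2f} > {thr.channel_frac_max}")
    if time_frac > thr.time_frac_max:
        reasons.append(
            f"motion time fraction {time_frac:.2f} > {thr.time_frac_max}")
    return QCReport(subject_id=rec.subject_id, snr=snr, mean_abs_corr=corr,
                    motion_fraction=motion_frac, flagged_channels=flagged,
                    subject_pass=not reasons, fail_reasons=reasons,
                    thresholds=thr, scan=scan)
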