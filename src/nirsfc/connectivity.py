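"""Seed-based and whole-brain functional connectivity with group statistics.

Connectivity between two channels is the temporal correlation of their
hemoglobin concentration series, computed with Pearson's r, Spearman's rank
correlation, or normalized cross-correlation (the signed r at the lag that
maximizes |r| inside a +/-10 s window by default).

Group statistics follow the Fisher-z convention: per-entry maps of the mean
correlation (R map), the mean z = atanh(r) (Z map), its back-transform
tanh(mean z) (Z-to-R map), and the one-sample t statistic of the subject z
values against zero with df = n - 1 and an uncorrected two-sided p value.
Entries with undefined correlations propagate as NaN and are averaged
pairwise-complete, with the contributing subject count reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ConcentrationSeries, ProcRecord

__all__ = [
    "FCResult",
    "GroupMaps",
    "pairwise_fc",
    "seed_fc",
    "whole_brain_fc",
    "fisher_z",
    "z_to_r",
    "group_maps",
]

_METHODS = ("pearson", "spearman", "crosscorr")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    den = np.sqrt((xd @ xd) * (yd @ yd))
    if den == 0:
        return np.nan
    return float(np.clip((xd @ yd) / den, -1.0, 1.0))


def _crosscorr(x: np.ndarray, y: np.ndarray, max_lag: int) -> tuple[float, int]:
    """Signed r at the lag maximizing |r|; ties -> smallest |lag|, then negative.

    Positive lag means y is delayed relative to x: r(l) compares x[:T-l]
    with y[l:].
    """
    best_r, best_lag, best_abs = np.nan, 0, -1.0
    n = x.size
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        if lag >= 0:
            xs, ys = x[:n - lag] if lag else x, y[lag:]
        else:
            xs, ys = x[-lag:], y[:n + lag]
        if xs.size < 3:
            continue
        r = _pearson(xs, ys)
        if np.isnan(r):
            continue
        if abs(r) > best_abs + 1e-15:
            best_r, best_lag, best_abs = r, lag, abs(r)
    return best_r, best_lag


def pairwise_fc(x: np.ndarray, y: np.ndarray, method: str = "pearson",
                fs: float = 1.0, max_lag_s: float = 10.0,
                ) -> tuple[float, float | None]:
    """Correlation between two series; returns ``(r, lag_seconds)``.

    The lag is None except for cross-correlation.  A zero-variance input
    yields an explicit NaN marker, never a silent 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected {_METHODS}")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance series: correlation undefined (NaN)")
        return np.nan, None
    if method == "pearson":
        return _pearson(x, y), None
    if method == "spearman":
        return _pearson(stats.rankdata(x), stats.rankdata(y)), None
    max_lag = int(round(max_lag_s * fs))
    r, lag = _crosscorr(x, y, max_lag)
    return r, lag / fs


@dataclass
class FCResult:
    """A seed vector or whole-brain matrix of connectivity values."""

    values: np.ndarray  # (n,) seed mode or (n, n) whole-brain
    method: str
    signal: str
    seed: int | None = None  # 0-based channel index
    lags: np.ndarray | None = None  # seconds, crosscorr only
    subject_id: str = ""

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _conc_of(rec: ProcRecord | ConcentrationSeries) -> ConcentrationSeries:
    if isinstance(rec, ConcentrationSeries):
        return rec
    if rec.conc is None:
        raise ValueError("record has no concentration data; preprocess first")
    return rec.conc


def seed_fc(rec: ProcRecord | ConcentrationSeries, seed_channel: int,
            method: str = "pearson", signal: str = "hbo",
            max_lag_s: float = 10.0) -> FCResult:
    """Connectivity of one seed channel against every channel (seed itself = 1)."""
    conc = _conc_of(rec)
    x = conc.signal(signal)
    n = x.shape[0]
    if not 0 <= seed_channel < n:
        raise ValueError(f"seed channel {seed_channel} outside 0..{n - 1}")
    values = np.empty(n)
    lags = np.zeros(n) if method == "crosscorr" else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for c in range(n):
            if c == seed_channel and method != "crosscorr":
                values[c] = 1.0
                continue
            r, lag = pairwise_fc(x[seed_channel], x[c], method,
                                 fs=conc.sampling_rate, max_lag_s=max_lag_s)
            values[c] = r
            if lags is not None:
                lags[c] = lag if lag is not None else np.nan
    subject = rec.raw.subject_id if isinstance(rec, ProcRecord) else ""
    return FCResult(values=values, method=method, signal=signal,
                    seed=seed_channel, lags=lags, subject_id=subject)


def whole_brain_fc(rec: ProcRecord | ConcentrationSeries, method: str = "pearson",
                   signal: str = "hbo", max_lag_s: float = 10.0) -> FCResult:
    """Symmetric channels x channels connectivity matrix with unit diagonal."""
    conc = _conc_of(rec)
    x = conc.signal(signal)
    n = x.shape[0]
    if n < 2:
        raise ValueError("whole-brain connectivity needs >= 2 channels")
    if method in ("pearson", "spearman"):
        data = x if method == "pearson" else np.apply_along_axis(stats.rankdata, 1, x)
        sd = data.std(axis=1)
        with np.errstate(invalid="ignore"):
            m = np.corrcoef(data)
        m = np.clip(m, -1.0, 1.0)
        m[sd == 0, :] = np.nan
        m[:, sd == 0] = np.nan
        np.fill_diagonal(m, 1.0)
        m = (m + m.T) / 2.0
        lags = None
    else:
        m = np.ones((n, n))
        lags = np.zeros((n, n))
        max_lag = int(round(max_lag_s * conc.sampling_rate))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for i in range(n):
                for j in range(i + 1, n):
                    if x[i].std() == 0 or x[j].std() == 0:
                        r, lag = np.nan, 0
                    else:
                        r, lag = _crosscorr(x[i], x[j], max_lag)
                    m[i, j] = m[j, i] = r
                    lags[i, j] = lag / conc.sampling_rate
                    lags[j, i] = -lags[i, j]
    subject = rec.raw.subject_id if isinstance(rec, ProcRecord) else ""
    return FCResult(values=m, method=method, signal=signal, lags=lags,
                    subject_id=subject)


def fisher_z(r: np.ndarray | float, clamp: bool = False) -> np.ndarray | float:
    """Variance-stabilizing z = atanh(r); |r| >= 1 errors unless clamped."""
    arr = np.asarray(r, dtype=float)
    if clamp:
        arr = np.clip(arr, -1 + 1e-7, 1 - 1e-7)
    elif np.any(np.abs(arr[np.isfinite(arr)]) >= 1):
        raise ValueError("|r| >= 1: Fisher z undefined (pass clamp=True to clip)")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def z_to_r(z: np.ndarray | float) -> np.ndarray | float:
    """Back-transform tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


@dataclass
class GroupMaps:
    """Elementwise group statistics across subjects' connectivity results."""

    r_map: np.ndarray  # mean r
    z_map: np.ndarray  # mean atanh(r)
    z_to_r_map: np.ndarray  # tanh(z_map)
    t_map: np.ndarray  # one-sample t of subject z values vs 0
    p_map: np.ndarray  # two-sided uncorrected
    n_map: np.ndarray  # subjects contributing per entry
    undefined: np.ndarray  # True where t is undefined (zero variance / n < 2)
    n_subjects: int
    df: int


def group_maps(results: list[FCResult]) -> GroupMaps:
    """R / Z / Z-to-R / T maps across subjects.

    Requires >= 2 subjects with identical channel sets and method.  Unit
    correlations (e.g. the whole-brain diagonal) map to infinite z, so the
    Z-to-R map returns 1 there while the t statistic is marked undefined;
    NaN entries are averaged pairwise-complete.
    """
    if len(results) < 2:
        raise ValueError("group maps need >= 2 subjects")
    shape = results[0].values.shape
    method = results[0].method
    for res in results[1:]:
        if res.values.shape != shape:
            raise ValueError("subjects have mismatched channel sets")
        if res.method != method:
            raise ValueError("subjects mix connectivity methods")
    stack = np.stack([res.values for res in results])  # subjects x ...
    n_map = np.sum(~np.isnan(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r_map = np.nanmean(stack, axis=0)
        z_stack = np.arctanh(np.clip(stack, -1.0, 1.0))
        z_map = np.nanmean(z_stack, axis=0)
        z_to_r_map = np.tanh(z_map)
        z_sd = np.nanstd(z_stack, axis=0, ddof=1)
    n = len(results)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map = z_map / (z_sd / np.sqrt(n_map))
    undefined = ~np.isfinite(t_map) | (n_map < 2)
    t_map = np.where(undefined, np.nan, t_map)
    df = n - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_map = np.where(undefined, np.nan,
                         2 * stats.t.sf(np.abs(np.nan_to_num(t_map)),
                                        np.maximum(n_map - 1, 1)))
    return GroupMaps(r_map=r_map, z_map=z_map, z_to_r_map=z_to_r_map,
                     t_map=t_map, p_map=p_map, n_map=n_map,
                     undefined=undefined, n_subjects=n, df=df)
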