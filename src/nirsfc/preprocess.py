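"""Raw intensity to denoised hemoglobin concentration changes.

The preprocessing chain mirrors standard continuous-wave fNIRS practice:

1. intensity -> optical density, ``OD = -ln(I / mean_t I)`` (natural log; the
   choice of log base only rescales the extinction coefficients);
2. optical density -> HbO/HbR/HbT via the modified Beer-Lambert law,
   ``dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * L * DPF(lambda)``,
   solved as a 2x2 linear system per channel pair and time point;
3. zero-phase Butterworth band-pass (5th-order high-pass then 3rd-order
   low-pass, each applied forward-backward), default band 0.01-0.1 Hz — the
   band of spontaneous hemodynamic fluctuations;
4. linear detrend (ordinary least squares line removal);
5. motion correction, either sliding-standard-deviation detection followed by
   smoothing-spline subtraction, or correlation-based signal improvement
   (CBSI) exploiting the expected HbO-HbR anticorrelation.

Concentrations are expressed in micromol/L with separations in cm and
extinction coefficients in cm^-1 (mol/L)^-1.
"""

from __future__ import annotations

import traceback
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import make_smoothing_spline

from .io import ConcentrationSeries, ProcRecord, ProbeGeometry, RawRecording, read_nirs, write_proc

__all__ = [
    "MBLLParameters",
    "FilterSpec",
    "EXTINCTION_TABLE",
    "default_mbll_parameters",
    "intensity_to_od",
    "od_to_concentration",
    "bandpass_filter",
    "detrend",
    "motion_correct_spline",
    "motion_correct_cbsi",
    "run_preprocessing",
    "DEFAULT_STEPS",
]

# Molar extinction coefficients in cm^-1 (mol/L)^-1, (HbO, HbR), from the
# compiled hemoglobin spectra commonly embedded in CW-NIRS tooling.
EXTINCTION_TABLE: dict[float, tuple[float, float]] = {
    690.0: (276.0, 2051.96),
    830.0: (974.0, 693.04),
}


@dataclass
class MBLLParameters:
    """Modified Beer-Lambert law parameters for one wavelength pair.

    ``extinction[i, :]`` are the (HbO, HbR) extinction coefficients at the
    i-th wavelength; ``dpf`` is the per-wavelength differential pathlength
    factor and ``separation`` the per-channel source-detector distance in cm.
    """

    extinction: np.ndarray  # (2, 2): wavelength x chromophore
    dpf: np.ndarray  # (2,)
    separation: np.ndarray  # (n_channel_pairs,), cm

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float).reshape(2, 2)
        self.dpf = np.asarray(self.dpf, dtype=float).ravel()
        self.separation = np.atleast_1d(np.asarray(self.separation, dtype=float))
        if np.any(self.dpf <= 0):
            raise ValueError("DPF must be positive")
        if np.any(self.separation <= 0):
            raise ValueError("source-detector separation must be positive")
        if abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ValueError("singular extinction matrix: chromophores not separable")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.extinction))


def default_mbll_parameters(probe: ProbeGeometry, dpf: float | Sequence[float] = 6.0,
                            ) -> MBLLParameters:
    """Build MBLL parameters from a probe using the embedded extinction table.

    Wavelengths are matched to the nearest table entry within 15 nm; the DPF
    default of 6.0 at both wavelengths is the conventional adult-head value
    and can be overridden.
    """
    wls = probe.wavelengths
    if len(wls) != 2:
        raise ValueError(f"expected exactly 2 wavelengths, got {len(wls)}")
    eps = np.empty((2, 2))
    for i, wl in enumerate(wls):
        match = min(EXTINCTION_TABLE, key=lambda k: abs(k - wl))
        if abs(match - wl) > 15:
            raise ValueError(
                f"no extinction coefficients within 15 nm of {wl} nm; "
                "supply MBLLParameters explicitly"
            )
        eps[i] = EXTINCTION_TABLE[match]
    dpf_arr = np.asarray(dpf, dtype=float).ravel()
    if dpf_arr.size == 1:
        dpf_arr = np.repeat(dpf_arr, 2)
    pairs = probe.channel_pairs()
    seps = probe.separations
    sep_per_pair = np.array([seps[rows[0]] for rows in pairs])
    return MBLLParameters(extinction=eps, dpf=dpf_arr, separation=sep_per_pair)


def intensity_to_od(rec: RawRecording | np.ndarray) -> np.ndarray:
    """Normalize raw intensity to optical density against its temporal mean.

    ``OD(c, t) = -ln(I(c, t) / mean_t I(c, .))``; a sample equal to its
    channel mean maps to exactly zero, and rescaling a channel by a positive
    constant leaves its OD unchanged.
    """
    intensity = rec.intensity if isinstance(rec, RawRecording) else np.atleast_2d(rec)
    bad = np.where(np.any(intensity <= 0, axis=1))[0]
    if bad.size:
        raise ValueError(
            "nonpositive intensity samples in channels "
            f"{(bad + 1).tolist()} (1-based); cannot take the log"
        )
    mean = intensity.mean(axis=1, keepdims=True)
    return -np.log(intensity / mean)


def od_to_concentration(od: np.ndarray, params: MBLLParameters,
                        probe: ProbeGeometry, time: np.ndarray | None = None,
                        sampling_rate: float | None = None) -> ConcentrationSeries:
    """Invert the modified Beer-Lambert law per channel pair.

    Every source-detector pair must be measured at exactly the two
    wavelengths in ``params``; the 2x2 system is solved for all time points
    at once.  Output units are micromol/L.
    """
    od = np.atleast_2d(np.asarray(od, dtype=float))
    pairs = probe.channel_pairs()
    for rows in pairs:
        if len(rows) != 2:
            sd = probe.meas_list[rows[0], :2]
            raise ValueError(
                f"source {sd[0]}-detector {sd[1]} measured at {len(rows)} "
                "wavelengths; MBLL inversion needs exactly 2"
            )
    n_pairs = len(pairs)
    if params.separation.size == 1:
        sep = np.full(n_pairs, float(params.separation[0]))
    else:
        sep = params.separation
        if sep.size != n_pairs:
            raise ValueError("separation length does not match channel-pair count")
    hbo = np.empty((n_pairs, od.shape[1]))
    hbr = np.empty_like(hbo)
    for p, rows in enumerate(pairs):
        # A @ [dHbO, dHbR] = dOD, with the effective path folded into A
        a = params.extinction * (sep[p] * params.dpf)[:, None]
        sol = np.linalg.solve(a, od[list(rows), :])
        hbo[p], hbr[p] = sol * 1e6  # mol/L -> umol/L
    if time is None:
        if sampling_rate is None:
            raise ValueError("pass either time or sampling_rate")
        time = np.arange(od.shape[1]) / sampling_rate
    fs = sampling_rate if sampling_rate is not None else 1.0 / np.mean(np.diff(time))
    return ConcentrationSeries(hbo=hbo, hbr=hbr, hbt=hbo + hbr, time=time,
                               sampling_rate=fs)


@dataclass
class FilterSpec:
    """Band edges and orders for the zero-phase Butterworth band-pass."""

    low_cut: float = 0.01  # Hz, high-pass edge
    high_cut: float = 0.1  # Hz, low-pass edge
    lp_order: int = 3
    hp_order: int = 5

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.low_cut < self.high_cut < nyq):
            raise ValueError(
                f"band edges must satisfy 0 < {self.low_cut} < {self.high_cut} "
                f"< Nyquist ({nyq} Hz)"
            )


def bandpass_filter(series: np.ndarray, fs: float,
                    spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass, high-pass first then low-pass.

    Each stage is applied forward-backward (``sosfiltfilt``), doubling the
    effective order and cancelling group delay; edges are handled by odd
    reflection padding.  Output length equals input length.
    """
    spec = spec or FilterSpec()
    spec.validate(fs)
    x = np.atleast_2d(np.asarray(series, dtype=float))
    sos_hp = sps.butter(spec.hp_order, spec.low_cut, btype="highpass",
                        fs=fs, output="sos")
    sos_lp = sps.butter(spec.lp_order, spec.high_cut, btype="lowpass",
                        fs=fs, output="sos")
    min_pad = 3 * (2 * max(sos_hp.shape[0], sos_lp.shape[0]) + 1)
    if x.shape[1] <= min_pad:
        raise ValueError(
            f"series of {x.shape[1]} samples too short for filter padding "
            f"({min_pad + 1} required)"
        )
    # the high-pass poles sit close to the unit circle; pad with about three
    # of its time constants so edge transients die inside the padding
    pad = int(min(x.shape[1] - 1, round(3.0 * fs / spec.low_cut)))
    y = sps.sosfiltfilt(sos_hp, x, axis=1, padlen=pad)
    y = sps.sosfiltfilt(sos_lp, y, axis=1, padlen=pad)
    return y if np.ndim(series) > 1 else y[0]


def detrend(series: np.ndarray) -> np.ndarray:
    """Remove the per-channel least-squares straight line."""
    x = np.atleast_2d(np.asarray(series, dtype=float))
    if x.shape[1] < 2:
        raise ValueError("detrend needs at least 2 time points")
    y = sps.detrend(x, axis=1, type="linear")
    return y if np.ndim(series) > 1 else y[0]


def _flags_to_segments(flags: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Merge flagged samples into [start, end) intervals, bridging gaps."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    segments: list[list[int]] = [[int(idx[0]), int(idx[0]) + 1]]
    for i in idx[1:]:
        if i - segments[-1][1] <= merge_gap:
            segments[-1][1] = int(i) + 1
        else:
            segments.append([int(i), int(i) + 1])
    return [tuple(s) for s in segments]


def _trend_value(x: np.ndarray, lo: int, hi: int, at: int) -> float:
    """Least-squares line over x[lo:hi] evaluated at sample ``at``."""
    if hi - lo < 2:
        return float(x[lo]) if hi > lo else 0.0
    idx = np.arange(lo, hi, dtype=float)
    coef = np.polyfit(idx, x[lo:hi], 1)
    return float(np.polyval(coef, at))


def _spline_correct_1d(y: np.ndarray, segments: list[tuple[int, int]],
                       window: int, smoothing: float) -> np.ndarray:
    """Subtract a smoothing spline inside each artifact segment and re-level.

    The corrected segment is anchored to the linear trend of the preceding
    clean window extrapolated across the segment, and all following data are
    shifted so the post-segment signal continues that trend — this removes
    persistent baseline jumps (step artifacts), not just transients.  Trend
    extrapolation rather than raw window means keeps the re-leveling unbiased
    when the underlying signal has slope across the artifact.
    """
    out = y.astype(float).copy()
    n = y.size
    lam = (1.0 - smoothing) / smoothing if smoothing < 1.0 else 0.0
    for start, end in segments:
        seg = out[start:end]
        if end - start >= 4:
            xs = np.arange(start, end, dtype=float)
            try:
                spline = make_smoothing_spline(xs, seg, lam=lam if lam > 0 else None)
                corrected = seg - spline(xs)
            except Exception:
                corrected = seg - seg.mean()
        else:
            corrected = seg - seg.mean()
        if start > 0:
            anchor = _trend_value(out, max(start - window, 0), start, start)
        elif end < n:
            anchor = _trend_value(out, end, min(end + window, n), end)
        else:
            anchor = 0.0
        corrected += anchor - corrected[:min(window, corrected.size)].mean()
        out[start:end] = corrected
        if end < n and start > 0:
            target = _trend_value(out, max(start - window, 0), start, end)
            lead = _trend_value(out, end, min(end + window, n), end)
            out[end:] += target - lead
    return out


def motion_correct_spline(series: np.ndarray, fs: float, window_s: float = 2.0,
                          threshold_sd: float = 5.0, smoothing: float = 0.99,
                          ) -> tuple[np.ndarray, list[list[tuple[int, int]]]]:
    """Detect motion artifacts by moving SD and subtract a spline model.

    Samples whose moving standard deviation exceeds
    ``mean(MSD) + threshold_sd * sd(MSD)`` are flagged, merged into segments
    (gaps up to one window are bridged), modeled with a cubic smoothing
    spline, subtracted, and re-leveled against the adjacent clean baseline.

    Returns the corrected matrix and the per-channel flagged segments.
    """
    from .quality import moving_std

    if not (0 < smoothing <= 1):
        raise ValueError("smoothing parameter must be in (0, 1]")
    x = np.atleast_2d(np.asarray(series, dtype=float))
    window = max(int(round(window_s * fs)), 2)
    out = np.empty_like(x)
    all_segments: list[list[tuple[int, int]]] = []
    for c in range(x.shape[0]):
        y = x[c]
        if np.ptp(y) == 0:
            out[c] = y
            all_segments.append([])
            continue
        msd = moving_std(y, window_s, fs)
        thr = msd.mean() + threshold_sd * msd.std(ddof=1)
        flags = msd > thr
        if flags.all():
            raise ValueError(f"channel {c + 1}: entire series flagged; signal unusable")
        segments = _flags_to_segments(flags, merge_gap=window)
        all_segments.append(segments)
        out[c] = _spline_correct_1d(y, segments, window, smoothing) if segments else y
    if np.ndim(series) == 1:
        return out[0], all_segments
    return out, all_segments


def motion_correct_cbsi(conc: ConcentrationSeries) -> ConcentrationSeries:
    """Correlation-based signal improvement.

    Assumes functional HbO/HbR are anticorrelated while motion moves both the
    same way.  Per channel, with ``alpha = sd(HbO)/sd(HbR)``::

        HbO' = (HbO - alpha * HbR) / 2
        HbR' = -HbO' / alpha

    so the corrected pair is exactly anticorrelated and the shared (motion)
    component cancels.
    """
    hbo, hbr = conc.hbo, conc.hbr
    sd_o = hbo.std(axis=1, ddof=1)
    sd_r = hbr.std(axis=1, ddof=1)
    dead = np.where((sd_r == 0) | (sd_o == 0))[0]
    if dead.size:
        raise ValueError(
            f"constant HbO/HbR in channels {(dead + 1).tolist()} (1-based); "
            "CBSI undefined"
        )
    alpha = (sd_o / sd_r)[:, None]
    hbo_c = (hbo - alpha * hbr) / 2.0
    hbr_c = -hbo_c / alpha
    return conc.replace(hbo=hbo_c, hbr=hbr_c)


# ---------------------------------------------------------------------------
# batch pipeline
# ---------------------------------------------------------------------------

DEFAULT_STEPS: list[tuple[str, dict]] = [
    ("od", {}),
    ("mbll", {}),
    ("bandpass", {"low_cut": 0.01, "high_cut": 0.1}),
    ("detrend", {}),
    ("cbsi", {}),
]


def _apply_conc(rec: ProcRecord, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    if rec.conc is None:
        raise ValueError("concentration not computed yet; run 'od' and 'mbll' first")
    rec.conc = rec.conc.replace(hbo=fn(rec.conc.hbo), hbr=fn(rec.conc.hbr))


def apply_step(rec: ProcRecord, name: str, params: dict) -> None:
    """Apply one named preprocessing step in place and log it."""
    fs = rec.raw.sampling_rate
    if name == "od":
        rec.od = intensity_to_od(rec.raw)
    elif name == "mbll":
        if rec.od is None:
            raise ValueError("run 'od' before 'mbll'")
        mbll = params.get("mbll") or default_mbll_parameters(
            rec.probe, dpf=params.get("dpf", 6.0))
        rec.conc = od_to_concentration(rec.od, mbll, rec.probe,
                                       time=rec.raw.time, sampling_rate=fs)
    elif name == "bandpass":
        spec = FilterSpec(low_cut=params.get("low_cut", 0.01),
                          high_cut=params.get("high_cut", 0.1))
        _apply_conc(rec, lambda m: bandpass_filter(m, fs, spec))
    elif name == "detrend":
        _apply_conc(rec, detrend)
    elif name == "spline":
        def fix(m: np.ndarray) -> np.ndarray:
            corrected, _ = motion_correct_spline(
                m, fs, window_s=params.get("window_s", 2.0),
                threshold_sd=params.get("threshold_sd", 5.0),
                smoothing=params.get("smoothing", 0.99))
            return corrected
        _apply_conc(rec, fix)
    elif name == "cbsi":
        if rec.conc is None:
            raise ValueError("run 'od' and 'mbll' before 'cbsi'")
        rec.conc = motion_correct_cbsi(rec.conc)
    else:
        raise ValueError(f"unknown preprocessing step {name!r}")
    rec.log(name, params)


@dataclass
class BatchResult:
    succeeded: list[str] = field(default_factory=list)
    failed: dict[str, str] = field(default_factory=dict)
    log_path: Path | None = None

    @property
    def ok(self) -> bool:
        return not self.failed and bool(self.succeeded)


def run_preprocessing(input_dir: str | Path, output_dir: str | Path,
                      steps: Sequence[tuple[str, dict]] | None = None,
                      ) -> BatchResult:
    """Apply a preprocessing chain to every ``.nirs`` file in a directory.

    One ``.proc`` file is written per subject; a run log records every step
    and per-subject outcome.  A failing subject is logged and skipped, never
    aborting the batch.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    steps = list(steps) if steps is not None else [(n, dict(p)) for n, p in DEFAULT_STEPS]
    files = sorted(input_dir.glob("*.nirs"))
    if not files:
        raise FileNotFoundError(f"no input data: no .nirs files in {input_dir}")
    output_dir.mkdir(parents=True, exist_ok=True)
    result = BatchResult()
    log_lines = [f"{datetime.now(timezone.utc).isoformat()} preprocess start "
                 f"({len(files)} subjects, steps={[n for n, _ in steps]})"]
    for f in files:
        try:
            rec = ProcRecord(raw=read_nirs(f))
            for name, params in steps:
                apply_step(rec, name, params)
            out = output_dir / (f.stem + ".proc")
            write_proc(rec, out)
            result.succeeded.append(f.stem)
            log_lines.append(f"{datetime.now(timezone.utc).isoformat()} OK {f.name}")
        except Exception as exc:
            result.failed[f.stem] = f"{type(exc).__name__}: {exc}"
            log_lines.append(
                f"{datetime.now(timezone.utc).isoformat()} FAIL {f.name}: "
                f"{type(exc).__name__}: {exc}")
            log_lines.extend("    " + l for l in
                             traceback.format_exc().strip().splitlines()[-2:])
    log_lines.append(
        f"{datetime.now(timezone.utc).isoformat()} preprocess done: "
        f"{len(result.succeeded)} ok, {len(result.failed)} failed")
    result.log_path = output_dir / "preprocess.log"
    result.log_path.write_text("\n".join(log_lines) + "\n")
    return result
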