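"""Synthetic multichannel fNIRS recordings with known ground truth.

The generator emulates a continuous-wave resting-state acquisition — by
default 46 measurement channels at two wavelengths sampled at 25 Hz — so
every pipeline stage can be exercised against a planted truth:

* *block connectivity*: channels are partitioned into blocks; each channel's
  HbO series mixes a shared band-limited (0.01-0.1 Hz) latent source with
  independent band-limited noise, so within-block correlations hit a target
  r while between-block correlations are near zero;
* *physiology*: HbR is a negatively scaled copy of HbO plus independent
  noise, matching the anticorrelation CBSI relies on; a per-channel linear
  drift mimics slow instrumental shifts;
* *artifacts*: step or spike transients injected at known times with a
  returned sample mask, and "dead" channels replaced by white noise at a
  target SNR, reproducing poor optode-scalp contact.

Intensity is produced by the exact forward model of the modified
Beer-Lambert law, ``I = I0 * exp(-eps . dC * L * DPF)``, so inversion round
trips are testable to numerical precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ConcentrationSeries, ProbeGeometry, RawRecording, write_nirs
from .preprocess import MBLLParameters, bandpass_filter, default_mbll_parameters, FilterSpec

__all__ = [
    "SyntheticSpec",
    "make_probe",
    "simulate_concentrations",
    "forward_model",
    "inject_motion",
    "inject_dead_channel",
    "simulate_subject",
    "simulate_group",
]


@dataclass
class SyntheticSpec:
    """Study-design parameters for one synthetic group."""

    n_channels: int = 46
    n_subjects: int = 10
    duration_s: float = 300.0
    sampling_rate: float = 25.0
    n_blocks: int = 2
    within_r: float = 0.8
    between_r: float = 0.0
    band: tuple[float, float] = (0.01, 0.1)  # Hz, latent-source band
    noise_sd: float = 1.0  # relative to unit-variance latent
    hbr_scale: float = 1.0 / 3.0  # HbR = -hbr_scale * HbO + noise
    hbr_noise_sd: float = 0.1
    drift_slope_range: tuple[float, float] = (-0.001, 0.001)  # umol/L per s
    baseline_intensity: float = 1.0e6  # detector units
    amplitude_umol: float = 0.05  # sd of HbO fluctuations in umol/L
    dpf: float = 6.0
    separation_cm: float = 3.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_channels < self.n_blocks:
            raise ValueError("need at least one channel per block")
        if not -1 <= self.between_r <= 1 or not -1 <= self.within_r <= 1:
            raise ValueError("correlation targets must lie in [-1, 1]")
        if self.within_r < 0:
            raise ValueError("within-block target must be nonnegative (mixture model)")
        if self.between_r != 0 and self.between_r > self.within_r:
            raise ValueError("infeasible block design: between-block target "
                             "exceeds within-block target")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))

    def blocks(self) -> list[np.ndarray]:
        """Partition of channel indices into contiguous blocks."""
        return [np.asarray(b) for b in
                np.array_split(np.arange(self.n_channels), self.n_blocks)]


def make_probe(n_channels: int, separation_cm: float = 3.2,
               wavelengths: Sequence[float] = (690.0, 830.0)) -> ProbeGeometry:
    """A simple line layout: one source-detector pair per measurement channel,
    measured at every wavelength (wavelength-major measurement list)."""
    src = np.array([[2.0 * separation_cm * c, 0.0, 0.0] for c in range(n_channels)])
    det = src + np.array([separation_cm, 0.0, 0.0])
    ml = np.array([[c + 1, c + 1, 1, w + 1]
                   for c in range(n_channels) for w in range(len(wavelengths))],
                  dtype=int)
    return ProbeGeometry(source_pos=src, detector_pos=det, meas_list=ml,
                         wavelengths=np.asarray(wavelengths, dtype=float))


def _band_noise(rng: np.random.Generator, n_series: int, n_samples: int,
                fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance noise exactly band-limited to the hemodynamic band.

    Built in the frequency domain (white spectrum restricted to the band) so
    independent series stay uncorrelated — a causal filter's edge transients
    would leak shared slow modes into every series.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError("recording too short for the requested band")
    spec = np.zeros((n_series, freqs.size), dtype=complex)
    n_keep = int(keep.sum())
    spec[:, keep] = (rng.standard_normal((n_series, n_keep))
                     + 1j * rng.standard_normal((n_series, n_keep)))
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_concentrations(spec: SyntheticSpec, seed: int | None = None,
                            ) -> tuple[ConcentrationSeries, np.ndarray]:
    """One subject's concentration series plus the target correlation matrix.

    Channel HbO mixes its block's latent source with weight sqrt(within_r)
    and independent noise with weight sqrt(1 - within_r), both unit-variance
    and band-limited, so the expected within-block Pearson r equals
    ``within_r`` and between-block r is 0 (independent latents).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, t = spec.n_channels, spec.n_samples
    fs = spec.sampling_rate
    blocks = spec.blocks()
    latents = _band_noise(rng, len(blocks), t, fs, spec.band)
    noise = _band_noise(rng, n, t, fs, spec.band)
    w_shared = np.sqrt(spec.within_r)
    w_noise = np.sqrt(max(1.0 - spec.within_r, 0.0))
    hbo = np.empty((n, t))
    target = np.full((n, n), spec.between_r)
    for b, idx in enumerate(blocks):
        hbo[idx] = w_shared * latents[b] + w_noise * noise[idx]
        target[np.ix_(idx, idx)] = spec.within_r
    np.fill_diagonal(target, 1.0)
    hbo *= spec.amplitude_umol
    hbr = -spec.hbr_scale * hbo + \
        spec.hbr_noise_sd * spec.amplitude_umol * rng.standard_normal((n, t))
    time = np.arange(t) / fs
    slopes = rng.uniform(*spec.drift_slope_range, size=n)
    drift = slopes[:, None] * time[None, :]
    hbo = hbo + drift
    hbr = hbr + spec.hbr_scale * drift * rng.uniform(-0.5, 0.5, size=(n, 1))
    return (ConcentrationSeries(hbo=hbo, hbr=hbr, hbt=hbo + hbr, time=time,
                                sampling_rate=fs),
            target)


def forward_model(conc: ConcentrationSeries, probe: ProbeGeometry,
                  mbll: MBLLParameters | None = None,
                  baseline_intensity: float = 1.0e6) -> RawRecording:
    """Generate raw intensity from concentrations via the Beer-Lambert model.

    ``dOD(lambda) = (eps @ dC) * L * DPF`` and ``I = I0 * exp(-dOD)``.
    Inverting with ``intensity_to_od`` + ``od_to_concentration`` recovers the
    input up to one additive constant per channel (the OD step normalizes by
    the temporal mean), so zero-mean inputs round-trip after demeaning.
    """
    mbll = mbll or default_mbll_parameters(probe)
    pairs = probe.channel_pairs()
    if len(pairs) != conc.n_channels:
        raise ValueError("probe pair count does not match concentration channels")
    n_meas = probe.n_measurements
    od = np.empty((n_meas, conc.hbo.shape[1]))
    c_molar = np.stack([conc.hbo, conc.hbr]) * 1e-6  # umol/L -> mol/L
    sep = mbll.separation if mbll.separation.size == len(pairs) \
        else np.full(len(pairs), float(mbll.separation.ravel()[0]))
    for p, rows in enumerate(pairs):
        eff = mbll.extinction * (sep[p] * mbll.dpf)[:, None]  # (wl, chromo)
        od[list(rows), :] = eff @ c_molar[:, p, :]
    intensity = baseline_intensity * np.exp(-od)
    return RawRecording(intensity=intensity, time=conc.time, probe=probe)


def inject_motion(rec: RawRecording, times_s: Sequence[float],
                  amplitude: float, shape: str = "step",
                  duration_s: float = 1.0) -> tuple[RawRecording, np.ndarray]:
    """Add motion transients to the intensity of every channel.

    ``shape='spike'`` adds a boxcar of ``duration_s``; ``shape='step'`` adds
    a persistent offset from the onset to the end of the recording.  The
    amplitude is expressed as a multiple of each channel's temporal standard
    deviation.  Returns the modified recording and a boolean mask of the
    affected samples (for a step: the onset transition window).
    """
    if shape not in ("spike", "step"):
        raise ValueError("shape must be spike or step")
    fs = rec.sampling_rate
    n_t = rec.time.size
    intensity = rec.intensity.copy()
    mask = np.zeros(n_t, dtype=bool)
    sd = rec.intensity.std(axis=1, ddof=1)
    for t0 in times_s:
        i0 = int(round(t0 * fs))
        if not 0 <= i0 < n_t:
            raise ValueError(f"artifact time {t0}s outside the recording")
        width = max(int(round(duration_s * fs)), 1)
        if shape == "spike":
            i1 = min(i0 + width, n_t)
            intensity[:, i0:i1] += (amplitude * sd)[:, None]
            mask[i0:i1] = True
        else:
            intensity[:, i0:] += (amplitude * sd)[:, None]
            mask[i0:min(i0 + width, n_t)] = True
    out = RawRecording(intensity=intensity, time=rec.time, probe=rec.probe,
                       subject_id=rec.subject_id)
    return out, mask


def inject_dead_channel(rec: RawRecording, channel: int, target_snr: float,
                        seed: int = 0) -> RawRecording:
    """Replace one measurement channel with uncorrelated white noise.

    The replacement keeps the channel's original mean level and sets the
    noise sd to ``mean / target_snr``, emulating an optode with poor scalp
    contact.  All other channels are untouched.
    """
    if not 0 <= channel < rec.n_channels:
        raise ValueError(f"channel {channel} outside 0..{rec.n_channels - 1}")
    if target_snr <= 0:
        raise ValueError("target SNR must be positive")
    rng = np.random.default_rng(seed)
    intensity = rec.intensity.copy()
    mean = intensity[channel].mean()
    sd = abs(mean) / target_snr
    noise = mean + sd * rng.standard_normal(rec.time.size)
    # clip at a 1%-of-mean detector floor so the trace stays positive and the
    # log transform downstream remains defined
    intensity[channel] = np.clip(noise, 0.01 * abs(mean), None)
    return RawRecording(intensity=intensity, time=rec.time, probe=rec.probe,
                        subject_id=rec.subject_id)


def simulate_subject(spec: SyntheticSpec, seed: int,
                     subject_id: str = "") -> tuple[RawRecording, np.ndarray]:
    """Concentrations -> forward model for one subject; returns the recording
    and the subject's target correlation matrix."""
    conc, target = simulate_concentrations(spec, seed=seed)
    probe = make_probe(spec.n_channels, spec.separation_cm)
    mbll = default_mbll_parameters(probe, dpf=spec.dpf)
    rec = forward_model(conc, probe, mbll, spec.baseline_intensity)
    rec.subject_id = subject_id
    return rec, target


def simulate_group(spec: SyntheticSpec, out_dir: str | Path,
                   seed: int | None = None) -> Path:
    """Write ``n_subjects`` recordings as .nirs files plus a ground-truth sidecar.

    The sidecar (JSON) records the block partition, per-subject seeds and the
    generator parameters, so downstream recovery tests need no other input.
    Generation is deterministic for a given spec and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                     ss.spawn(spec.n_subjects)]
    for i, sseed in enumerate(subject_seeds):
        sid = f"sub-{i + 1:02d}"
        rec, _ = simulate_subject(spec, seed=sseed, subject_id=sid)
        write_nirs(rec, out_dir / f"{sid}.nirs")
    sidecar = {
        "blocks": [b.tolist() for b in spec.blocks()],
        "within_r": spec.within_r,
        "between_r": spec.between_r,
        "subject_seeds": subject_seeds,
        "n_channels": spec.n_channels,
        "sampling_rate": spec.sampling_rate,
        "duration_s": spec.duration_s,
        "base_seed": base,
    }
    path = out_dir / "ground_truth.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path
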