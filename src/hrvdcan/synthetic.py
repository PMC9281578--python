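"""Synthetic cardiovascular data with the statistical structure the analysis assumes.

Four generators cover the whole pipeline:

* :func:`generate_rr` — RR tachograms with prescribed VLF/LF/HF oscillatory
  power plus a 1/f^beta broadband background, built in the beat domain
  (oscillators sampled at beat onsets).
* :func:`generate_ecg` — a sampled single-lead ECG with one QRS template per
  beat and respiratory amplitude modulation of the QRS.
* :func:`generate_coupled_sbp_rr` — a systolic-pressure series carrying an
  LF oscillation and an RR series coupled to it with a known baroreflex
  gain and delay.
* :func:`generate_cohort` — per-subject index values for a two-group
  (CNTR/T1DM) by two-condition (SUP/HUT) cohort, with published
  mean/SD defaults for all 16 indexes.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import ECGRecord, EvenSeries, NNSeries
from . import spectral

GROUPS = ("CNTR", "T1DM")
CONDITIONS = ("SUP", "HUT")

#: published cohort distribution parameters: index -> {(group, condition): (mean, SD)}
COHORT_DEFAULTS: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    "nni_m":       {("CNTR", "SUP"): (922.0, 147.0), ("CNTR", "HUT"): (737.0, 104.0),
                    ("T1DM", "SUP"): (858.0, 104.0), ("T1DM", "HUT"): (711.0, 99.0)},
    "pnn50_plus":  {("CNTR", "SUP"): (11.2, 9.2), ("CNTR", "HUT"): (4.2, 4.7),
                    ("T1DM", "SUP"): (6.6, 7.3), ("T1DM", "HUT"): (2.7, 3.2)},
    "pnn50_minus": {("CNTR", "SUP"): (11.8, 9.8), ("CNTR", "HUT"): (4.0, 4.6),
                    ("T1DM", "SUP"): (7.1, 8.7), ("T1DM", "HUT"): (2.2, 3.3)},
    "rmssd":       {("CNTR", "SUP"): (50.5, 31.5), ("CNTR", "HUT"): (28.5, 15.3),
                    ("T1DM", "SUP"): (33.1, 21.5), ("T1DM", "HUT"): (21.6, 10.0)},
    "sdnn_i":      {("CNTR", "SUP"): (62.1, 27.8), ("CNTR", "HUT"): (58.0, 20.2),
                    ("T1DM", "SUP"): (44.4, 18.0), ("T1DM", "HUT"): (45.9, 16.2)},
    "tot_p":       {("CNTR", "SUP"): (4591.0, 4180.0), ("CNTR", "HUT"): (3700.0, 2787.0),
                    ("T1DM", "SUP"): (2261.0, 1701.0), ("T1DM", "HUT"): (2270.0, 1459.0)},
    "vlf":         {("CNTR", "SUP"): (1555.0, 1482.0), ("CNTR", "HUT"): (1188.0, 517.4),
                    ("T1DM", "SUP"): (856.0, 547.0), ("T1DM", "HUT"): (895.0, 536.9)},
    "lf":          {("CNTR", "SUP"): (1258.0, 1149.0), ("CNTR", "HUT"): (1793.0, 2168.0),
                    ("T1DM", "SUP"): (672.0, 603.3), ("T1DM", "HUT"): (927.0, 809.9)},
    "hf":          {("CNTR", "SUP"): (1087.0, 1741.0), ("CNTR", "HUT"): (336.0, 331.0),
                    ("T1DM", "SUP"): (459.0, 633.0), ("T1DM", "HUT"): (201.0, 200.0)},
    "lf_hf":       {("CNTR", "SUP"): (2.03, 1.56), ("CNTR", "HUT"): (6.58, 4.24),
                    ("T1DM", "SUP"): (2.45, 1.66), ("T1DM", "HUT"): (6.48, 5.02)},
    "alpha_short": {("CNTR", "SUP"): (0.817, 0.187), ("CNTR", "HUT"): (1.089, 0.159),
                    ("T1DM", "SUP"): (0.898, 0.187), ("T1DM", "HUT"): (1.108, 0.146)},
    "alpha_long":  {("CNTR", "SUP"): (0.856, 0.175), ("CNTR", "HUT"): (0.776, 0.218),
                    ("T1DM", "SUP"): (0.903, 0.140), ("T1DM", "HUT"): (0.836, 0.167)},
    "sampen":      {("CNTR", "SUP"): (1.551, 0.332), ("CNTR", "HUT"): (1.009, 0.323),
                    ("T1DM", "SUP"): (1.520, 0.293), ("T1DM", "HUT"): (1.045, 0.336)},
    "mse_hf":      {("CNTR", "SUP"): (1.540, 0.194), ("CNTR", "HUT"): (1.622, 0.264),
                    ("T1DM", "SUP"): (1.562, 0.204), ("T1DM", "HUT"): (1.609, 0.227)},
    "mse_lf":      {("CNTR", "SUP"): (1.455, 0.254), ("CNTR", "HUT"): (1.373, 0.162),
                    ("T1DM", "SUP"): (1.494, 0.188), ("T1DM", "HUT"): (1.437, 0.232)},
}


def power_law_noise(n: int, beta: float, rng: np.random.Generator,
                    variance: float = 1.0) -> np.ndarray:
    """Gaussian 1/f^beta noise of length ``n`` scaled to ``variance``.

    beta=0 gives white noise, beta=1 pink (the self-similarity typical of
    supine tachograms, alpha near 1), beta=2 Brownian.
    """
    white = rng.standard_normal(n)
    if beta == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** (-beta / 2.0)
        spec = spec * shape
        spec[0] = 0.0
        x = np.fft.irfft(spec, n)
    sd = x.std()
    if sd > 0 and variance > 0:
        x = x * (np.sqrt(variance) / sd)
    elif variance == 0:
        x = np.zeros(n)
    return x


@dataclass
class RRModelConfig:
    """Beat-domain RR tachogram model: three in-band oscillators + 1/f background.

    Powers are in ms^2 *as measured* by the packaged 5-Hz/Welch estimator;
    oscillator amplitudes are pre-compensated for the attenuation of linear
    interpolation at the mean beat rate.
    """

    duration_s: float = 960.0
    mean_nn: float = 900.0
    vlf_power: float = 0.0
    lf_power: float = 0.0
    hf_power: float = 0.0
    vlf_freq: float = 0.02
    lf_freq: float = 0.10
    hf_freq: float = 0.25
    noise_power: float = 0.0
    noise_beta: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.mean_nn <= 0:
            raise ValueError("duration_s and mean_nn must be positive")
        for name in ("vlf_power", "lf_power", "hf_power", "noise_power"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.lf_power > 0 and not (0.04 <= self.lf_freq < 0.15):
            raise ValueError("lf_freq must lie in the LF band [0.04, 0.15)")
        if self.hf_power > 0 and not (0.15 <= self.hf_freq < 0.40):
            raise ValueError("hf_freq must lie in the HF band [0.15, 0.40)")
        if self.vlf_power > 0 and not (0.005 <= self.vlf_freq < 0.04):
            raise ValueError("vlf_freq must lie in the VLF band [0.005, 0.04)")


def generate_rr(config: RRModelConfig) -> NNSeries:
    """Generate an NN series whose Welch band powers match the configured ones.

    Each oscillator contributes amplitude sqrt(2*power)/sinc^2(f*NNI_m) at its
    band frequency; the sinc^2 factor undoes the low-pass effect of linearly
    interpolating a beat-sampled sinusoid onto the uniform analysis grid, so
    the power recovered by :func:`hrvdcan.spectral.nn_band_powers` equals the
    configured power within sampling error.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t_mean = config.mean_nn / 1000.0

    oscillators = []
    for power, freq in ((config.vlf_power, config.vlf_freq),
                        (config.lf_power, config.lf_freq),
                        (config.hf_power, config.hf_freq)):
        if power > 0:
            amp = np.sqrt(2.0 * power) / np.sinc(freq * t_mean) ** 2
            phase = rng.uniform(0, 2 * np.pi)
            oscillators.append((amp, freq, phase))

    if config.noise_power > 0:
        fs_noise = 4.0
        n_noise = int(np.ceil(config.duration_s * fs_noise)) + 8
        noise_grid = power_law_noise(n_noise, config.noise_beta, rng,
                                     variance=config.noise_power)
        noise_t = np.arange(n_noise) / fs_noise
    else:
        noise_grid = noise_t = None

    times, intervals = [], []
    t = 0.0
    floor_ms = 0.25 * config.mean_nn
    while t < config.duration_s:
        nn = config.mean_nn
        for amp, freq, phase in oscillators:
            nn += amp * np.sin(2 * np.pi * freq * t + phase)
        if noise_grid is not None:
            nn += np.interp(t, noise_t, noise_grid)
        nn = max(nn, floor_ms)
        times.append(t)
        intervals.append(nn)
        t += nn / 1000.0
    return NNSeries(np.array(intervals), np.array(times))


def _ricker(t: np.ndarray, width: float) -> np.ndarray:
    """Mexican-hat QRS template, unit peak at t=0."""
    a = (t / width) ** 2
    return (1.0 - a) * np.exp(-a / 2.0)


def generate_ecg(beat_times: np.ndarray, resp_freq: float = 0.25,
                 resp_mod_depth: float = 0.0, fs: float = 1000.0,
                 seed: int = 0, qrs_width: float = 0.012,
                 qrs_amplitude: float = 1.0,
                 noise_sd: float = 0.0) -> ECGRecord:
    """Sampled ECG with one QRS per beat and respiratory amplitude modulation.

    QRS amplitude at beat time t is ``qrs_amplitude * (1 +
    resp_mod_depth*sin(2*pi*resp_freq*t))`` — the mechanism ECG-derived
    respiration exploits.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    if fs < 250:
        raise ValueError("fs must be at least 250 Hz")
    if not (0 <= resp_mod_depth < 1):
        raise ValueError("resp_mod_depth must be in [0, 1)")
    rng = np.random.default_rng(seed)
    duration = (beat_times[-1] if beat_times.size else 0.0) + 0.5
    n = int(np.ceil(duration * fs))
    x = np.zeros(n)
    half = int(round(8 * qrs_width * fs))
    for tb in beat_times:
        amp = qrs_amplitude * (1.0 + resp_mod_depth * np.sin(2 * np.pi * resp_freq * tb))
        i0 = int(round(tb * fs))
        lo, hi = max(0, i0 - half), min(n, i0 + half + 1)
        tt = np.arange(lo, hi) / fs - tb
        x[lo:hi] += amp * _ricker(tt, qrs_width)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)
    return ECGRecord(x, fs=fs)


@dataclass
class BaroCouplingConfig:
    """Linear SBP->RR coupling: an LF pressure oscillation drives RR with known gain.

    ``drive="broadband"`` (default) spreads the pressure oscillation as a
    multi-tone across the whole LF band so the transfer function is
    identified at every LF frequency; ``drive="sine"`` uses a single tone
    at ``sbp_lf_freq``.
    """

    gain: float = 10.0          # ms/mmHg
    delay_s: float = 1.0
    sbp_lf_amplitude: float = 5.0   # mmHg RMS of the LF oscillation
    sbp_lf_freq: float = 0.10       # Hz (tone frequency / band centre)
    rr_noise_sd: float = 0.0        # ms
    sbp_mean: float = 120.0
    mean_nn: float = 900.0
    drive: str = "broadband"
    seed: int = 0

    def validate(self) -> None:
        if self.gain < 0:
            raise ValueError("gain must be nonnegative")
        if not (0.04 <= self.sbp_lf_freq <= 0.15):
            raise ValueError("sbp_lf_freq must lie in the LF band [0.04, 0.15]")
        if self.drive not in ("broadband", "sine"):
            raise ValueError("drive must be 'broadband' or 'sine'")


def generate_coupled_sbp_rr(config: BaroCouplingConfig,
                            duration_s: float = 960.0
                            ) -> tuple[np.ndarray, NNSeries]:
    """Beat-by-beat SBP values (aligned with NN onsets) and the coupled NN series.

    RR(t) = mean_nn + gain * (SBP(t - delay) - sbp_mean) + Gaussian noise.
    """
    config.validate()
    if duration_s < 2 * spectral.WINDOW_S:
        warnings.warn(
            "duration shorter than two Welch windows (240 s); spectral "
            "baroreflex estimates will be unreliable", UserWarning, stacklevel=2)
    rng = np.random.default_rng(config.seed)

    if config.drive == "sine":
        comp_freqs = np.array([config.sbp_lf_freq])
    else:
        lo, hi = spectral.LF_BAND
        comp_freqs = np.linspace(lo, hi, 23)
    comp_amps = np.full(comp_freqs.size,
                        config.sbp_lf_amplitude * np.sqrt(2.0 / comp_freqs.size))
    comp_phases = rng.uniform(0, 2 * np.pi, comp_freqs.size)

    def sbp_at(t: float) -> float:
        return config.sbp_mean + float(
            np.sum(comp_amps * np.sin(2 * np.pi * comp_freqs * t + comp_phases)))

    times, intervals, sbp_vals = [], [], []
    t = 0.0
    floor_ms = 0.25 * config.mean_nn
    while t < duration_s:
        rr = (config.mean_nn
              + config.gain * (sbp_at(t - config.delay_s) - config.sbp_mean))
        if config.rr_noise_sd > 0:
            rr += rng.normal(0.0, config.rr_noise_sd)
        rr = max(rr, floor_ms)
        times.append(t)
        intervals.append(rr)
        sbp_vals.append(sbp_at(t))
        t += rr / 1000.0
    nn = NNSeries(np.array(intervals), np.array(times))
    return np.array(sbp_vals), nn


@dataclass
class CohortConfig:
    """Two-group x two-condition cohort of per-subject index values.

    ``params`` maps index name -> {(group, condition): (mean, SD)}; the
    default is the published cohort table.  ``distribution``:

    * ``"gaussian"`` — Gaussian draws, negative values truncated at 0
      (several indexes have SD comparable to the mean);
    * ``"lognormal-matched"`` — moment-matched log-normal, strictly positive.

    An optional ``correlation`` matrix (indexes x indexes, Gaussian copula)
    introduces inter-index correlation; the default draws independently.
    """

    n_per_group: int = 25
    seed: int = 0
    distribution: str = "gaussian"
    params: dict[str, dict[tuple[str, str], tuple[float, float]]] = field(default_factory=dict)
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.params:
            self.params = COHORT_DEFAULTS
        unknown = set(self.params) - set(COHORT_DEFAULTS)
        if unknown:
            raise ValueError(
                f"unknown index name(s) {sorted(unknown)}; known indexes: "
                f"{sorted(COHORT_DEFAULTS)}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if self.distribution not in ("gaussian", "lognormal-matched"):
            raise ValueError("distribution must be 'gaussian' or 'lognormal-matched'")
        for idx, cells in self.params.items():
            for cell, (_, sd) in cells.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {idx} {cell}")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a long-format cohort table: subject_id, group, condition, index, value."""
    rng = np.random.default_rng(config.seed)
    indexes = list(config.params)
    rows = []
    for group in GROUPS:
        for subj in range(config.n_per_group):
            sid = f"{group}{subj:04d}"
            for cond in CONDITIONS:
                if config.correlation is not None:
                    chol = np.linalg.cholesky(np.asarray(config.correlation))
                    z = chol @ rng.standard_normal(len(indexes))
                else:
                    z = rng.standard_normal(len(indexes))
                for k, idx in enumerate(indexes):
                    cells = config.params[idx]
                    if (group, cond) not in cells:
                        continue
                    mean, sd = cells[(group, cond)]
                    if config.distribution == "gaussian":
                        value = mean + sd * z[k]
                        value = max(value, 0.0)
                    else:  # moment-matched log-normal
                        if sd == 0 or mean <= 0:
                            value = mean
                        else:
                            s2 = np.log1p((sd / mean) ** 2)
                            mu = np.log(mean) - s2 / 2.0
                            value = np.exp(mu + np.sqrt(s2) * z[k])
                    rows.append((sid, group, cond, idx, float(value)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "condition",
                                       "index", "value"])
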