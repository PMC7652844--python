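"""Seeded synthetic EEG cohorts with a known sex effect on beta power.

Each recording is a spatially mixed sum of three zero-mean stationary
components per channel:

* a 1/f**gamma background,
* band-limited alpha (8-12 Hz),
* band-limited beta (12-25 Hz) whose amplitude is ``baseline * beta_factor``.

Subject beta factors are log-normal; the sex difference is a standardized
mean shift (Cohen's d) on the log scale, and pre/post sessions share a
subject-level random effect calibrated to ``session_correlation``. For a
log-scale shift ``d`` the population AUC of any strictly increasing function
of the beta factor is ``Phi(d / sqrt(2))`` (binormal ROC), which pins the
``effect_size`` needed for a target feature AUC.

Spatial structure: channels are mixed through the Cholesky factor of a
distance-dependent correlation matrix ``C_ij = exp(-|p_i - p_j| / length)``
built from the montage geometry, so correlation-based channel rejection is
meaningful on these cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import norm

from .errors import ConfigurationError
from .montage import Montage, standard_montage_1020
from .recording import Recording

ALPHA_BAND = (8.0, 12.0)
BETA_BAND = (12.0, 25.0)
#: four analysis bands, half-open [lo, hi)
BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 25.0)}

#: e-folding length (chord distance) of inter-channel correlation
SPATIAL_LENGTH = 4.0
#: corner below which the 1/f background spectrum is flat
PINK_CORNER_HZ = 0.5


def effect_size_for_auc(auc: float) -> float:
    """Log-scale Cohen's d giving a target binormal feature AUC."""
    if not 0.5 <= auc < 1.0:
        raise ConfigurationError("target AUC must be in [0.5, 1)")
    return float(np.sqrt(2.0) * norm.ppf(auc))


@dataclass(frozen=True)
class BandAmplitudes:
    """Baseline RMS amplitudes (microvolts) of the three generators."""

    background: float = 10.0
    alpha: float = 6.0
    beta: float = 4.0
    gamma: float = 1.0  # spectral slope of the background


@dataclass(frozen=True)
class ArtifactSpec:
    """Rates and magnitudes of injected defects."""

    n_flat: int = 0
    n_decorrelated: int = 0
    n_bursts: int = 0
    flat_duration_s: float = 6.0
    burst_duration_s: float = 0.5
    burst_amplitude: float = 50.0  # multiple of the channel robust scale
    burst_n_channels: int = 3
    margin_s: float = 0.0  # keep artifacts this far from the recording edges

    def __post_init__(self) -> None:
        for name in ("n_flat", "n_decorrelated", "n_bursts"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 134
    n_female: int = 93
    fs: float = 250.0
    duration: float = 600.0
    effect_size: float = effect_size_for_auc(0.75)
    session_correlation: float = 0.88
    band_amplitudes: BandAmplitudes = field(default_factory=BandAmplitudes)
    beta_factor_sigma: float = 0.35  # std of log beta factor
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_female < self.n_subjects:
            raise ConfigurationError("need 0 < n_female < n_subjects")
        if self.fs < 100.0:
            raise ConfigurationError("fs must be >= 100 Hz")
        if self.duration <= 60.0:
            raise ConfigurationError("duration must exceed 60 s")
        if not 0.0 <= self.session_correlation <= 1.0:
            raise ConfigurationError("session_correlation must be in [0, 1]")
        if self.beta_factor_sigma <= 0:
            raise ConfigurationError("beta_factor_sigma must be positive")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    sex: str  # "female" | "male"
    age: int
    beta_factor_pre: float
    beta_factor_post: float

    def __post_init__(self) -> None:
        if self.beta_factor_pre <= 0 or self.beta_factor_post <= 0:
            raise ValueError("beta factors must be positive")


# ---------------------------------------------------------------------------
# analytic spectra

def _component_band_fractions(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Fraction of each generator's variance falling in the four bands.

    Computed from the exact shaping responses (pink spectrum; squared
    magnitude of the zero-phase Butterworth band-passes) on a dense grid.
    """
    fs = config.fs
    f = np.linspace(1e-3, fs / 2.0, 20001)
    df = f[1] - f[0]
    amps = config.band_amplitudes
    spectra = {}
    spectra["background"] = 1.0 / np.maximum(f, PINK_CORNER_HZ) ** amps.gamma
    for name, band in (("alpha", ALPHA_BAND), ("beta", BETA_BAND)):
        sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=f, fs=fs)
        spectra[name] = np.abs(h) ** 4  # forward-backward filtering
    out = {}
    for name, s in spectra.items():
        total = s.sum() * df
        fracs = []
        for lo, hi in BANDS.values():
            m = (f >= lo) & (f < hi)
            fracs.append(s[m].sum() * df / total)
        out[name] = np.asarray(fracs)
    return out


def analytic_relative_beta(beta_factor: float | np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Expected relative beta-band power as a function of the beta factor.

    Strictly increasing in ``beta_factor``; this is the noiseless feature the
    spectral pipeline estimates.
    """
    fr = _component_band_fractions(config)
    amps = config.band_amplitudes
    bf = np.asarray(beta_factor, dtype=float)
    p = (
        amps.background**2 * fr["background"][:, None]
        + amps.alpha**2 * fr["alpha"][:, None]
        + (amps.beta * bf.ravel()[None, :]) ** 2 * fr["beta"][:, None]
    )  # (4 bands, n)
    rel = p[3] / p.sum(axis=0)
    return rel.reshape(bf.shape) if bf.shape else float(rel[0])


# ---------------------------------------------------------------------------
# subject-level structure

def simulate_profiles(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[SubjectProfile]:
    """Draw the subject table: sexes, ages, paired log-normal beta factors."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    sexes = np.array(["female"] * config.n_female + ["male"] * (n - config.n_female))
    ages = rng.integers(18, 66, size=n)
    d, sig, rho = config.effect_size, config.beta_factor_sigma, config.session_correlation
    mu = np.where(sexes == "female", d * sig / 2.0, -d * sig / 2.0)
    z_subj = rng.standard_normal(n)
    z_pre = rng.standard_normal(n)
    z_post = rng.standard_normal(n)
    sr, snr = np.sqrt(rho), np.sqrt(1.0 - rho)
    log_pre = mu + sig * (sr * z_subj + snr * z_pre)
    log_post = mu + sig * (sr * z_subj + snr * z_post)
    return [
        SubjectProfile(
            subject_id=f"S{i:04d}",
            sex=str(sexes[i]),
            age=int(ages[i]),
            beta_factor_pre=float(np.exp(log_pre[i])),
            beta_factor_post=float(np.exp(log_post[i])),
        )
        for i in range(n)
    ]


def factor_table(profiles: list[SubjectProfile], config: SimulationConfig) -> pd.DataFrame:
    """Long-format subject table with factors and noiseless analytic features."""
    rows = []
    for p in profiles:
        for session, bf in (("pre", p.beta_factor_pre), ("post", p.beta_factor_post)):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "session": session,
                    "sex": p.sex,
                    "age": p.age,
                    "beta_factor": bf,
                }
            )
    df = pd.DataFrame(rows)
    df["analytic_rel_beta"] = analytic_relative_beta(df["beta_factor"].to_numpy(), config)
    return df


# ---------------------------------------------------------------------------
# signal synthesis

def _spatial_mixing(montage: Montage, length: float = SPATIAL_LENGTH) -> np.ndarray:
    d = np.linalg.norm(montage.positions[:, None, :] - montage.positions[None, :, :], axis=-1)
    C = np.exp(-d / length)
    return np.linalg.cholesky(C)


def _component_shapes(n_samples: int, fs: float, gamma: float) -> np.ndarray:
    """Amplitude-spectrum shapes of the three generators on the rfft grid.

    Each shape is normalized so that shaped unit-white noise has unit
    time-domain variance. The band-pass shapes are the squared-magnitude
    (zero-phase, forward-backward) responses of 4th-order Butterworth
    filters, applied spectrally.
    """
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shapes = np.empty((3, len(f)))
    shapes[0] = 1.0 / np.maximum(f, PINK_CORNER_HZ) ** (gamma / 2.0)
    shapes[0, 0] = 0.0  # no DC
    for i, band in ((1, ALPHA_BAND), (2, BETA_BAND)):
        sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=f, fs=fs)
        shapes[i] = np.abs(h) ** 2
    # unit time-domain variance: var = (2 / n) * sum(shape^2) for E|W|^2 = n
    norms = np.sqrt(2.0 * (shapes**2).sum(axis=1) / n_samples)
    return shapes / norms[:, None]


def simulate_recording(
    beta_factor: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    montage: Montage | None = None,
    mixing: np.ndarray | None = None,
    shapes: np.ndarray | None = None,
) -> Recording:
    """Synthesize one multichannel recording for a given beta factor.

    All three components are generated spectrally (shaped complex white
    noise, single inverse FFT) and mixed through the montage-geometry
    Cholesky factor.
    """
    montage = montage or standard_montage_1020()
    L = mixing if mixing is not None else _spatial_mixing(montage)
    n_ch = montage.n_channels
    n = int(round(config.duration * config.fs))
    amps = config.band_amplitudes
    if shapes is None:
        shapes = _component_shapes(n, config.fs, amps.gamma)
    weights = np.array([amps.background, amps.alpha, amps.beta * beta_factor])
    nb = shapes.shape[1]
    scale = np.sqrt(n / 2.0)  # E|W|^2 = n, matching an rfft of unit white noise
    spec = np.zeros((n_ch, nb), dtype=complex)
    for w, s in zip(weights, shapes):
        noise = rng.standard_normal((n_ch, 2 * nb)) * scale
        spec += (w * s) * (noise[:, :nb] + 1j * noise[:, nb:])
    src = np.fft.irfft(spec, n=n, axis=1)
    return Recording(data=L @ src, fs=config.fs, labels=montage.labels, montage=montage)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[Recording], list[Recording], pd.DataFrame]:
    """Generate paired pre/post recordings plus the metadata table.

    Deterministic given ``config.seed``. Artifacts from ``config.artifact_spec``
    are injected into every recording; the per-recording ground-truth logs are
    attached to the metadata as an ``artifacts`` column.
    """
    rng = np.random.default_rng(config.seed)
    montage = standard_montage_1020()
    L = _spatial_mixing(montage)
    n = int(round(config.duration * config.fs))
    shapes = _component_shapes(n, config.fs, config.band_amplitudes.gamma)
    profiles = simulate_profiles(config, rng)
    meta = factor_table(profiles, config)
    pre, post, logs = [], [], []
    for p in profiles:
        for session, store in (("pre", pre), ("post", post)):
            bf = p.beta_factor_pre if session == "pre" else p.beta_factor_post
            rec = simulate_recording(bf, config, rng, montage, L, shapes)
            seed = int(rng.integers(0, 2**31 - 1))
            rec, log = inject_artifacts(rec, config.artifact_spec, seed)
            store.append(rec)
            logs.append(log)
    # meta is ordered subject-major then session; logs are produced in that order
    meta = meta.sort_values(["subject_id", "session"], ascending=[True, False], kind="stable")
    meta = meta.reset_index(drop=True)
    meta["artifacts"] = logs
    return pre, post, meta


# ---------------------------------------------------------------------------
# artifact injection

def _robust_scale(x: np.ndarray) -> np.ndarray:
    med = np.median(x, axis=-1, keepdims=True)
    return 1.4826 * np.median(np.abs(x - med), axis=-1)


def inject_artifacts(
    rec: Recording, spec: ArtifactSpec, seed: int
) -> tuple[Recording, list[dict]]:
    """Corrupt a copy of ``rec`` and return it with a ground-truth log.

    Flat channels: a contiguous span held at a constant value.
    Decorrelated channels: the whole channel replaced by independent noise of
    matched scale. Bursts: high-amplitude noise added to a small channel set
    over a short span.
    """
    if spec.n_flat == 0 and spec.n_decorrelated == 0 and spec.n_bursts == 0:
        return rec.copy(), []
    rng = np.random.default_rng(seed)
    out = rec.copy()
    log: list[dict] = []
    n_ch, n = out.n_channels, out.n_samples
    fs = out.fs
    lo = spec.margin_s
    hi = out.duration - spec.margin_s

    def _span(dur: float) -> tuple[int, int]:
        start = rng.uniform(lo, max(lo, hi - dur))
        a = int(round(start * fs))
        b = min(n, a + int(round(dur * fs)))
        return a, b

    bad = rng.choice(n_ch, size=spec.n_flat + spec.n_decorrelated, replace=False)
    flat_ch, dec_ch = bad[: spec.n_flat], bad[spec.n_flat :]
    for ch in flat_ch:
        a, b = _span(spec.flat_duration_s)
        out.data[ch, a:b] = out.data[ch, a]
        log.append({"type": "flat", "channels": [int(ch)], "start_s": a / fs, "end_s": b / fs})
    for ch in dec_ch:
        scale = float(out.data[ch].std())
        noise = rng.standard_normal(n)
        out.data[ch] = noise / noise.std() * scale
        log.append({"type": "decorrelated", "channels": [int(ch)], "start_s": 0.0, "end_s": n / fs})
    scales = _robust_scale(out.data)
    for _ in range(spec.n_bursts):
        chans = np.sort(rng.choice(n_ch, size=spec.burst_n_channels, replace=False))
        a, b = _span(spec.burst_duration_s)
        for ch in chans:
            out.data[ch, a:b] += spec.burst_amplitude * scales[ch] * rng.standard_normal(b - a)
        log.append(
            {"type": "burst", "channels": [int(c) for c in chans], "start_s": a / fs, "end_s": b / fs}
        )
    return out, log


def artifact_log_to_json(log: list[dict]) -> list[dict]:
    """Plain-JSON-serializable copy of an artifact log."""
    return [dict(entry) for entry in log]
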