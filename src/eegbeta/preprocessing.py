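"""Artifact cleaning chain: explicit, individually testable operators.

Stage order (fixed): resample -> trim_edges -> detect_flat_channels ->
highpass -> reject_low_correlation_channels -> asr_calibrate + asr_clean ->
reject_bad_windows -> spherical_interpolate -> rereference_average ->
lowpass_fir. Every stage is deterministic; :func:`preprocess` runs the chain
and keeps a :class:`CleaningReport` audit trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import (
    CalibrationError,
    ConfigurationError,
    EmptyRecordingError,
    InterpolationError,
    PipelineStageError,
    TooShortRecordingError,
    UnsupportedUpsamplingError,
)
from .montage import Montage
from .recording import Recording, SEGMENT_TAG
from .spherical import interpolation_matrix, leave_one_out_operator

_log = logging.getLogger(__name__)

#: annotation tag for windows ASR could not reconstruct (all components rejected)
UNRECONSTRUCTABLE_TAG = "asr_unreconstructable"

# flatness epsilon: relative factor on the channel robust scale, absolute floor
FLAT_EPS_REL = 1e-8
FLAT_EPS_ABS = 1e-10


@dataclass(frozen=True)
class CleaningConfig:
    """Cleaning-chain parameters; defaults follow the published pipeline."""

    target_fs: float = 250.0
    trim_s: float = 30.0
    flat_max_s: float = 5.0
    hp_stop: float = 0.25
    hp_pass: float = 0.75
    corr_threshold: float = 0.75
    corr_window_s: float = 1.0
    asr_std_threshold: float = 5.0
    asr_window_s: float = 0.5
    reject_window_s: float = 1.0
    reject_overlap: float = 0.66
    reject_max_bad: int = 4
    lp_cutoff: float = 40.0

    def __post_init__(self) -> None:
        if not self.hp_stop < self.hp_pass:
            raise ConfigurationError("hp_stop must be below hp_pass")
        if not 0.0 < self.reject_overlap < 1.0:
            raise ConfigurationError("reject_overlap must be in (0, 1)")
        for name in ("target_fs", "flat_max_s", "corr_threshold", "asr_std_threshold",
                     "asr_window_s", "reject_window_s", "lp_cutoff"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass
class CleaningReport:
    """Audit trail of the cleaning chain."""

    flat_channels: list[str] = field(default_factory=list)
    low_correlation_channels: list[str] = field(default_factory=list)
    interpolated_channels: list[str] = field(default_factory=list)
    asr_windows_modified: int = 0
    asr_modified_spans: list[tuple[float, float]] = field(default_factory=list)
    rejected_windows: list[tuple[float, float]] = field(default_factory=list)
    retained_fraction: float = 1.0

    def to_dict(self) -> dict:
        return {
            "flat_channels": list(self.flat_channels),
            "low_correlation_channels": list(self.low_correlation_channels),
            "interpolated_channels": list(self.interpolated_channels),
            "asr_windows_modified": int(self.asr_windows_modified),
            "asr_modified_spans": [list(s) for s in self.asr_modified_spans],
            "rejected_windows": [list(s) for s in self.rejected_windows],
            "retained_fraction": float(self.retained_fraction),
        }


# ---------------------------------------------------------------------------
# elementary operators

def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling down to ``target_fs``."""
    if target_fs > rec.fs:
        raise UnsupportedUpsamplingError(
            f"target_fs {target_fs} exceeds recording rate {rec.fs}"
        )
    if target_fs == rec.fs:
        return rec.copy()
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return Recording(data=data, fs=target_fs, labels=rec.labels, montage=rec.montage)


def trim_edges(rec: Recording, trim_s: float) -> Recording:
    if trim_s == 0:
        return rec.copy()
    k = int(round(trim_s * rec.fs))
    if rec.n_samples <= 2 * k:
        raise TooShortRecordingError(
            f"recording of {rec.duration:.1f} s cannot lose 2 x {trim_s} s"
        )
    return Recording(
        data=rec.data[:, k : rec.n_samples - k].copy(),
        fs=rec.fs,
        labels=rec.labels,
        montage=rec.montage,
    )


def _robust_scale(data: np.ndarray, max_samples: int = 4096) -> np.ndarray:
    """MAD-based robust standard deviation along the last axis.

    Long inputs are strided down to ``max_samples`` points: the estimator's
    Monte-Carlo error is then well below a percent, which is negligible
    against the 5x thresholds it feeds. Deterministic.
    """
    n = data.shape[-1]
    if n > max_samples:
        data = data[..., :: max(1, n // max_samples)]
    med = np.median(data, axis=-1, keepdims=True)
    return 1.4826 * np.median(np.abs(data - med), axis=-1)


def _longest_true_run(mask: np.ndarray) -> int:
    """Length of the longest run of True in a 1-D boolean array."""
    if not mask.any():
        return 0
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int((edges[1::2] - edges[::2]).max())


def detect_flat_channels(rec: Recording, flat_max_s: float = 5.0) -> list[int]:
    """Channels with a flat run longer than ``flat_max_s``.

    A sample pair is "flat" when the successive difference is below
    ``max(FLAT_EPS_REL * robust_scale, FLAT_EPS_ABS)`` for that channel.
    """
    eps = np.maximum(FLAT_EPS_REL * _robust_scale(rec.data), FLAT_EPS_ABS)
    diffs = np.abs(np.diff(rec.data, axis=1))
    out = []
    limit = flat_max_s * rec.fs
    for ch in range(rec.n_channels):
        # a run of r flat diffs spans r+1 samples
        if _longest_true_run(diffs[ch] < eps[ch]) + 1 > limit:
            out.append(ch)
    return out


def highpass(rec: Recording, hp_stop: float = 0.25, hp_pass: float = 0.75) -> Recording:
    """Zero-phase 4th-order Butterworth high-pass.

    The -6 dB point of the forward-backward response sits midway between the
    stop and pass edges (0.5 Hz at the defaults).
    """
    if not 0 < hp_stop < hp_pass:
        raise ConfigurationError("need 0 < hp_stop < hp_pass")
    if hp_pass >= rec.fs / 2:
        raise ConfigurationError("hp_pass must be below Nyquist")
    cutoff = 0.5 * (hp_stop + hp_pass)
    sos = sps.butter(4, cutoff, btype="highpass", fs=rec.fs, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(data=data, fs=rec.fs, labels=rec.labels, montage=rec.montage,
                     annotations=list(rec.annotations))


def _window_stack(data: np.ndarray, starts: np.ndarray, w: int) -> np.ndarray:
    """(n_windows, n_channels, w) view-backed stack of sliding windows."""
    view = np.lib.stride_tricks.sliding_window_view(data, w, axis=1)
    return view[:, starts].transpose(1, 0, 2)


def _window_starts(n: int, w: int, step: int) -> np.ndarray:
    starts = np.arange(0, max(n - w, 0) + 1, step)
    if len(starts) == 0:
        starts = np.array([0])
    if starts[-1] + w < n and n >= w:
        starts = np.append(starts, n - w)
    return starts


def channel_correlation_scores(
    rec: Recording, montage: Montage | None = None, window_s: float = 1.0
) -> np.ndarray:
    """Median windowed correlation of each channel with its spherical-spline
    prediction from all other channels. Scores are clipped at 0."""
    montage = montage or rec.montage
    if montage is None:
        raise ConfigurationError("correlation rejection needs electrode positions")
    if rec.n_channels < 3:
        raise ConfigurationError("need at least 3 channels")
    R = leave_one_out_operator(montage.positions)
    w = int(round(window_s * rec.fs))
    nw = rec.n_samples // w
    if nw == 0:
        raise TooShortRecordingError("recording shorter than one correlation window")
    x = rec.data[:, : nw * w].reshape(rec.n_channels, nw, w)
    p = (R @ rec.data)[:, : nw * w].reshape(rec.n_channels, nw, w)
    xc = x - x.mean(axis=2, keepdims=True)
    pc = p - p.mean(axis=2, keepdims=True)
    num = (xc * pc).sum(axis=2)
    den = np.sqrt((xc**2).sum(axis=2) * (pc**2).sum(axis=2))
    corr = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(np.median(corr, axis=1), 0.0, None)


def reject_low_correlation_channels(
    rec: Recording,
    corr_threshold: float = 0.75,
    montage: Montage | None = None,
    window_s: float = 1.0,
) -> list[int]:
    """Channels whose correlation score falls below ``corr_threshold``.

    Rejection is iterative: the worst sub-threshold channel is removed and
    scores are recomputed without it, so a single grossly decorrelated
    channel cannot drag its neighbours' prediction scores below threshold.
    """
    montage = montage or rec.montage
    if montage is None:
        raise ConfigurationError("correlation rejection needs electrode positions")
    good = list(range(rec.n_channels))
    flagged: list[int] = []
    while len(good) >= 4:
        sub = Recording(
            data=rec.data[good], fs=rec.fs,
            labels=[rec.labels[i] for i in good], montage=montage.subset(good),
        )
        scores = channel_correlation_scores(sub, window_s=window_s)
        worst = int(np.argmin(scores))
        if not scores[worst] < corr_threshold:
            break
        flagged.append(good.pop(worst))
    return sorted(flagged)


# ---------------------------------------------------------------------------
# artifact subspace reconstruction

@dataclass
class ASRModel:
    """Principal axes and robust per-component scales from calibration data."""

    components: np.ndarray  # (n_ch, n_ch), columns are principal axes
    component_scales: np.ndarray  # robust std of each component
    channel_scales: np.ndarray  # robust std of each channel on calibration data
    window_s: float

    @property
    def n_channels(self) -> int:
        return self.components.shape[0]


def asr_calibrate(
    rec: Recording,
    window_s: float = 0.5,
    rms_percentiles: tuple[float, float] = (5.0, 67.0),
    min_calibration_s: float = 30.0,
) -> ASRModel:
    """Fit principal axes and robust component scales on quiet windows.

    Calibration windows are those whose total RMS lies inside
    ``rms_percentiles`` of the window-RMS distribution ("most representative
    part of the signal").
    """
    if rec.duration < min_calibration_s:
        raise CalibrationError(
            f"need >= {min_calibration_s} s for ASR calibration, got {rec.duration:.1f} s"
        )
    w = int(round(window_s * rec.fs))
    step = max(w // 2, 1)
    starts = _window_starts(rec.n_samples, w, step)
    wins = _window_stack(rec.data, starts, w)  # (nw, ch, w)
    rms = np.sqrt((wins**2).mean(axis=(1, 2)))
    lo, hi = np.percentile(rms, rms_percentiles)
    keep = (rms >= lo) & (rms <= hi)
    if not keep.any():
        raise CalibrationError("no calibration windows selected")
    calib = np.concatenate(list(wins[keep]), axis=1)  # (ch, n_calib)
    calib = calib - calib.mean(axis=1, keepdims=True)
    cov = calib @ calib.T / calib.shape[1]
    _, vecs = np.linalg.eigh(cov)
    comps = vecs.T @ calib
    return ASRModel(
        components=vecs,
        component_scales=_robust_scale(comps),
        channel_scales=_robust_scale(calib),
        window_s=window_s,
    )


def _merge_float_spans(spans: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for a, b in spans[1:]:
        if a <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def asr_clean(
    rec: Recording, model: ASRModel, asr_std_threshold: float = 5.0
) -> tuple[Recording, list[tuple[float, float]]]:
    """Reconstruct high-variance subspaces in sliding windows.

    Each window is PCA-decomposed; a window component is rejected when its
    standard deviation exceeds ``asr_std_threshold`` times the calibration
    standard deviation along that same direction (from the robust
    calibration covariance implied by the model). Rejected components are
    zeroed and the window rebuilt from the rest; modified windows are
    blended into the signal by weight-normalized overlap-add with a
    raised-cosine window. Windows in which every component exceeds
    threshold cannot be reconstructed: they are left untouched and
    annotated with :data:`UNRECONSTRUCTABLE_TAG` for downstream rejection.

    Returns the cleaned recording and the merged modified spans (seconds).
    """
    if model.n_channels != rec.n_channels:
        raise ConfigurationError("ASR model channel count does not match recording")
    V = model.components
    cov_cal = (V * model.component_scales**2) @ V.T  # robust calibration covariance
    w = int(round(model.window_s * rec.fs))
    step = max(w // 2, 1)
    starts = _window_starts(rec.n_samples, w, step)
    wins = _window_stack(rec.data, starts, w)  # (nw, ch, w)
    nw, n_ch = len(starts), rec.n_channels
    # prescreen in calibration-whitened coordinates: a window can only have
    # an exceeding component if the whitened variance trace exceeds the
    # squared threshold (lambda_max <= trace), so clean windows skip the
    # per-window eigendecomposition entirely
    whiten = (V / np.maximum(model.component_scales, 1e-300)) @ V.T
    sq = ((whiten @ rec.data) ** 2).sum(axis=0)
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    traces = (csum[starts + w] - csum[starts]) / w
    suspect = np.flatnonzero(traces > asr_std_threshold**2)
    exceed = np.zeros((nw, n_ch), dtype=bool)
    evecs = {}
    if suspect.size:
        sus = wins[suspect]
        centered = sus - sus.mean(axis=2, keepdims=True)
        covs = np.einsum("wct,wdt->wcd", centered, centered) / w
        evals, vecs = np.linalg.eigh(covs)  # batched
        # calibration variance along each window eigendirection
        cal_var = np.einsum("wcj,cd,wdj->wj", vecs, cov_cal, vecs)
        ex = evals > asr_std_threshold**2 * cal_var
        for k, wi in enumerate(suspect):
            exceed[wi] = ex[k]
            evecs[int(wi)] = vecs[k]
    out = rec.copy()
    modified: list[tuple[float, float]] = []
    unrecon: list[tuple[float, float]] = []
    to_fix = {
        int(wi) for wi in np.flatnonzero(exceed.any(axis=1)) if not exceed[wi].all()
    }
    for wi in np.flatnonzero(exceed.all(axis=1)):
        s = int(starts[wi])
        unrecon.append((s / rec.fs, (s + w) / rec.fs))
    if to_fix:
        # overlap-add with a strictly positive raised-cosine window; at 50%
        # overlap interior weights sum to exactly 1, edges are renormalized
        h = np.sin(np.pi * (np.arange(w) + 0.5) / w) ** 2
        acc = np.zeros_like(rec.data)
        wacc = np.zeros(rec.n_samples)
        touched = np.zeros(rec.n_samples, dtype=bool)
        for wi in to_fix:
            s = int(starts[wi])
            touched[s : s + w] = True
            modified.append((s / rec.fs, (s + w) / rec.fs))
        for wi, s in enumerate(starts):
            s = int(s)
            if not touched[s : s + w].any():
                continue
            if wi in to_fix:
                U = evecs[wi][:, ~exceed[wi]]  # retained directions
                seg = U @ (U.T @ wins[wi])
            else:
                seg = rec.data[:, s : s + w]
            acc[:, s : s + w] += h * seg
            wacc[s : s + w] += h
        out.data[:, touched] = acc[:, touched] / wacc[touched]
    out.annotations.extend((a, b, UNRECONSTRUCTABLE_TAG) for a, b in unrecon)
    return out, _merge_float_spans(modified)


# ---------------------------------------------------------------------------
# window rejection

def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for a, b in spans[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def reject_bad_windows(
    rec: Recording,
    window_s: float = 1.0,
    overlap: float = 0.66,
    max_bad: int = 4,
    channel_scales: np.ndarray | None = None,
    bad_rms_factor: float = 5.0,
) -> tuple[Recording, list[tuple[float, float]]]:
    """Delete sliding windows containing more than ``max_bad`` bad channels.

    A channel is bad in a window when its RMS exceeds ``bad_rms_factor``
    times its calibration scale, or when the window overlaps a span ASR
    could not reconstruct. Surviving samples are concatenated; the retained
    contiguous segments are annotated (in the output time base) so spectral
    estimation never bridges a deletion.
    """
    w = int(round(window_s * rec.fs))
    if rec.n_samples < w:
        raise TooShortRecordingError("recording shorter than one rejection window")
    if channel_scales is None:
        channel_scales = _robust_scale(rec.data)
    step = max(int(round(w * (1.0 - overlap))), 1)
    starts = _window_starts(rec.n_samples, w, step)
    wins = _window_stack(rec.data, starts, w)
    rms = np.sqrt((wins**2).mean(axis=2))  # (nw, ch)
    bad = rms > bad_rms_factor * np.asarray(channel_scales)[None, :]
    n_bad = bad.sum(axis=1)
    unrecon = [
        (int(round(a * rec.fs)), int(round(b * rec.fs)))
        for (a, b, tag) in rec.annotations
        if tag == UNRECONSTRUCTABLE_TAG
    ]
    reject = []
    for wi, s in enumerate(starts):
        s = int(s)
        overlaps_unrecon = any(a < s + w and b > s for a, b in unrecon)
        if n_bad[wi] > max_bad or overlaps_unrecon:
            reject.append((s, s + w))
    rejected = _merge_spans(reject)
    if not rejected:
        out = rec.copy()
        return out, []
    keep_mask = np.ones(rec.n_samples, dtype=bool)
    for a, b in rejected:
        keep_mask[a:b] = False
    if not keep_mask.any():
        raise EmptyRecordingError("all windows rejected: retained_fraction = 0")
    # retained contiguous segments, re-expressed in the concatenated time base
    padded = np.concatenate([[False], keep_mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    seg_bounds = list(zip(edges[::2], edges[1::2]))
    annotations = []
    pos = 0
    for a, b in seg_bounds:
        annotations.append((pos / rec.fs, (pos + b - a) / rec.fs, SEGMENT_TAG))
        pos += b - a
    out = Recording(
        data=rec.data[:, keep_mask].copy(),
        fs=rec.fs,
        labels=rec.labels,
        montage=rec.montage,
        annotations=annotations,
    )
    return out, [(a / rec.fs, b / rec.fs) for a, b in rejected]


# ---------------------------------------------------------------------------
# interpolation, referencing, smoothing

def spherical_interpolate(
    rec: Recording, montage: Montage | None = None, channels: list[int] | None = None
) -> Recording:
    """Replace the listed channels with spherical-spline estimates.

    The spline is calibrated on the retained electrodes only.
    """
    montage = montage or rec.montage
    channels = sorted(set(channels or []))
    if not channels:
        return rec.copy()
    if montage is None:
        raise ConfigurationError("interpolation needs electrode positions")
    good = [i for i in range(rec.n_channels) if i not in channels]
    if len(good) < 4:
        raise InterpolationError(
            f"only {len(good)} good electrodes left; spline needs at least 4"
        )
    A = interpolation_matrix(montage.positions[good], montage.positions[channels])
    out = rec.copy()
    out.data[channels] = A @ rec.data[good]
    return out


def rereference_average(rec: Recording) -> Recording:
    out = rec.copy()
    out.data -= out.data.mean(axis=0, keepdims=True)
    return out


def lowpass_fir(rec: Recording, cutoff: float = 40.0, transition_hz: float = 5.0) -> Recording:
    """Zero-phase windowed-sinc (Hamming) low-pass with a fixed transition band."""
    if cutoff >= rec.fs / 2:
        raise ConfigurationError("cutoff must be below Nyquist")
    numtaps = int(np.ceil(3.3 * rec.fs / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length for a symmetric type-I filter
    b = sps.firwin(numtaps, cutoff + transition_hz / 2.0, window="hamming", fs=rec.fs)
    # symmetric (linear-phase) kernel applied once with reflective padding is
    # exactly zero-phase after delay compensation
    half = numtaps // 2
    pad = min(half, rec.n_samples - 1)
    padded = np.concatenate(
        [rec.data[:, pad:0:-1], rec.data, rec.data[:, -2 : -pad - 2 : -1]], axis=1
    )
    data = sps.oaconvolve(padded, b[None, :], mode="same", axes=1)[:, pad:-pad]
    return Recording(data=data, fs=rec.fs, labels=rec.labels, montage=rec.montage,
                     annotations=list(rec.annotations))


# ---------------------------------------------------------------------------
# full chain

def preprocess(rec: Recording, config: CleaningConfig | None = None) -> tuple[Recording, CleaningReport]:
    """Run the full cleaning chain and return the cleaned recording + report."""
    config = config or CleaningConfig()
    report = CleaningReport()
    montage = rec.montage
    if montage is None:
        raise ConfigurationError("preprocess requires a montage on the recording")

    def stage(name, fn, *args, **kwargs):
        _log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as e:  # tag errors with the stage that raised them
            raise PipelineStageError(name, e) from e

    r = stage("resample", resample, rec, config.target_fs)
    r = stage("trim_edges", trim_edges, r, config.trim_s)
    flat = stage("detect_flat_channels", detect_flat_channels, r, config.flat_max_s)
    report.flat_channels = [r.labels[i] for i in flat]
    r = stage("highpass", highpass, r, config.hp_stop, config.hp_pass)

    good = [i for i in range(r.n_channels) if i not in flat]
    sub = Recording(data=r.data[good], fs=r.fs, labels=[r.labels[i] for i in good],
                    montage=montage.subset(good))
    low = stage(
        "reject_low_correlation_channels",
        reject_low_correlation_channels,
        sub, config.corr_threshold, None, config.corr_window_s,
    )
    low_orig = [good[i] for i in low]
    report.low_correlation_channels = [r.labels[i] for i in low_orig]

    removed = sorted(set(flat) | set(low_orig))
    good = [i for i in range(r.n_channels) if i not in removed]
    sub = Recording(data=r.data[good], fs=r.fs, labels=[r.labels[i] for i in good],
                    montage=montage.subset(good))
    model = stage("asr_calibrate", asr_calibrate, sub, config.asr_window_s)
    sub, modified = stage("asr_clean", asr_clean, sub, model, config.asr_std_threshold)
    report.asr_windows_modified = len(modified)
    report.asr_modified_spans = modified

    n_before = sub.n_samples
    sub, rejected = stage(
        "reject_bad_windows",
        reject_bad_windows,
        sub, config.reject_window_s, config.reject_overlap, config.reject_max_bad,
        model.channel_scales,
    )
    report.rejected_windows = rejected
    report.retained_fraction = sub.n_samples / n_before

    # rebuild the full-channel matrix on the retained samples
    keep_annotations = list(sub.annotations)
    full = np.empty((r.n_channels, sub.n_samples))
    full[good] = sub.data
    if removed:
        # removed channels: carry the (high-passed) originals on the retained
        # samples; they are immediately overwritten by interpolation
        if rejected:
            keep = np.ones(n_before, dtype=bool)
            for a, b in rejected:
                keep[int(round(a * r.fs)) : int(round(b * r.fs))] = False
            full[removed] = r.data[np.ix_(removed, np.flatnonzero(keep))]
        else:
            full[removed] = r.data[removed]
    r = Recording(data=full, fs=r.fs, labels=r.labels, montage=montage,
                  annotations=keep_annotations)
    r = stage("spherical_interpolate", spherical_interpolate, r, montage, removed)
    report.interpolated_channels = sorted(
        set(report.flat_channels) | set(report.low_correlation_channels),
        key=r.labels.index,
    )
    r = stage("rereference_average", rereference_average, r)
    r = stage("lowpass_fir", lowpass_fir, r, config.lp_cutoff)
    return r, report
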