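"""Band powers and the relative beta-band power feature.

The PSD estimator is an averaged modified periodogram (2 s Hann segments,
50% overlap, density scaling), computed independently on each retained
segment of a recording so spectra never bridge a rejected window. Band
integration uses a half-open ``[lo, hi)`` convention so the shared band
edges (4, 8, 12 Hz) are counted once and the four relative fractions sum
to 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import EstimationError, UndefinedFeatureError
from .recording import Recording


@dataclass(frozen=True)
class BandScheme:
    delta: tuple[float, float] = (0.5, 4.0)
    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 12.0)
    beta: tuple[float, float] = (12.0, 25.0)

    def __post_init__(self) -> None:
        bands = [self.delta, self.theta, self.alpha, self.beta]
        for lo, hi in bands:
            if not lo < hi:
                raise ValueError("each band must satisfy lo < hi")
        for (a, b), (c, d) in zip(bands, bands[1:]):
            if b != c:
                raise ValueError("bands must be contiguous and ordered")

    @property
    def bands(self) -> dict[str, tuple[float, float]]:
        return {"delta": self.delta, "theta": self.theta, "alpha": self.alpha, "beta": self.beta}


@dataclass(frozen=True)
class PSDParams:
    segment_s: float = 2.0
    overlap: float = 0.5
    window: str = "hann"


@dataclass
class PSDEstimate:
    """Power spectral density per channel (microvolt^2 / Hz)."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def compute_psd(rec: Recording, params: PSDParams | None = None) -> PSDEstimate:
    """Averaged-periodogram PSD respecting rejected-window annotations.

    Each retained segment is estimated independently (Welch); segment
    estimates are averaged weighted by their number of periodogram windows.
    """
    params = params or PSDParams()
    nperseg = int(round(params.segment_s * rec.fs))
    noverlap = int(round(nperseg * params.overlap))
    step = nperseg - noverlap
    segments = [(a, b) for a, b in rec.segments() if b - a >= nperseg]
    total = sum(b - a for a, b in segments)
    if not segments or total < 2 * nperseg:
        raise EstimationError(
            "need at least two PSD segments' worth of retained data"
        )
    acc = None
    weight = 0.0
    freqs = None
    for a, b in segments:
        f, p = sps.welch(
            rec.data[:, a:b], fs=rec.fs, window=params.window,
            nperseg=nperseg, noverlap=noverlap, scaling="density", axis=1,
        )
        n_wins = 1 + (b - a - nperseg) // step
        freqs = f
        acc = p * n_wins if acc is None else acc + p * n_wins
        weight += n_wins
    return PSDEstimate(
        freqs=freqs,
        power=acc / weight,
        metadata={"segment_s": params.segment_s, "overlap": params.overlap,
                  "window": params.window, "n_segments": len(segments)},
    )


def band_power(psd: PSDEstimate, band: tuple[float, float]) -> np.ndarray:
    """Integrated density over ``[lo, hi)`` per channel (rectangle rule)."""
    lo, hi = band
    f = psd.freqs
    df = f[1] - f[0]
    if lo < f[0] - 1e-9 or hi > f[-1] + df + 1e-9:
        raise ValueError(f"band [{lo}, {hi}) outside the frequency grid")
    m = (f >= lo - 1e-9) & (f < hi - 1e-9)
    return psd.power[:, m].sum(axis=1) * df


def band_fractions(psd: PSDEstimate, scheme: BandScheme | None = None) -> np.ndarray:
    """(4, n_channels) relative powers of the four bands; columns sum to 1."""
    scheme = scheme or BandScheme()
    powers = np.stack([band_power(psd, b) for b in scheme.bands.values()])
    denom = powers.sum(axis=0)
    silent = np.flatnonzero(denom <= 0)
    if silent.size:
        raise UndefinedFeatureError(
            f"zero total band power on channel(s) {silent.tolist()}"
        )
    return powers / denom


def relative_beta(psd: PSDEstimate, scheme: BandScheme | None = None) -> np.ndarray:
    """Per-channel beta power divided by the summed four-band power."""
    return band_fractions(psd, scheme)[3]


# ---------------------------------------------------------------------------
# feature table

def feature_columns(labels: tuple[str, ...], absolute: bool = False) -> list[str]:
    prefix = "abs_beta_" if absolute else "rb_"
    return [prefix + lab for lab in labels]


def build_feature_table(
    recordings: list[Recording | None],
    metadata: pd.DataFrame,
    scheme: BandScheme | None = None,
    psd_params: PSDParams | None = None,
    include_absolute: bool = False,
) -> pd.DataFrame:
    """One row per (subject, session) with per-channel relative beta features.

    ``metadata`` rows must align with ``recordings``; a ``None`` recording
    (missing session) yields a row of NaN features, which paired analyses
    must drop explicitly.
    """
    scheme = scheme or BandScheme()
    if len(recordings) != len(metadata):
        raise ValueError("metadata rows must align with recordings")
    labels = next(r.labels for r in recordings if r is not None)
    rb_cols = feature_columns(labels)
    ab_cols = feature_columns(labels, absolute=True)
    rows = []
    for rec, (_, m) in zip(recordings, metadata.iterrows()):
        row = {k: m[k] for k in ("subject_id", "session", "sex", "age") if k in m}
        if rec is None:
            row.update({c: np.nan for c in rb_cols})
            row["mean_rel_beta"] = np.nan
            if include_absolute:
                row.update({c: np.nan for c in ab_cols})
                row["mean_abs_beta"] = np.nan
        else:
            psd = compute_psd(rec, psd_params)
            rb = relative_beta(psd, scheme)
            row.update(dict(zip(rb_cols, rb)))
            row["mean_rel_beta"] = float(rb.mean())
            if include_absolute:
                ab = band_power(psd, scheme.beta)
                row.update(dict(zip(ab_cols, ab)))
                row["mean_abs_beta"] = float(ab.mean())
        rows.append(row)
    return pd.DataFrame(rows)
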