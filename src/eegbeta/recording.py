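"""The in-memory recording container used by every stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage

#: annotation tag marking a contiguous retained segment after window rejection
SEGMENT_TAG = "segment"


@dataclass
class Recording:
    """Channels x samples signal matrix with metadata.

    data is in microvolts; rows correspond 1:1 and in order to ``labels``.
    ``annotations`` is a list of ``(start_s, end_s, tag)`` tuples in the
    recording's own time base.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    montage: Montage | None = None
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("row count must match number of labels")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        self.labels = tuple(self.labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), annotations=list(self.annotations))

    def segments(self) -> list[tuple[int, int]]:
        """Sample spans of retained contiguous segments.

        Returns the spans annotated with :data:`SEGMENT_TAG`, or the whole
        recording when no segmentation annotation is present.
        """
        spans = [
            (int(round(s * self.fs)), int(round(e * self.fs)))
            for (s, e, tag) in self.annotations
            if tag == SEGMENT_TAG
        ]
        if not spans:
            return [(0, self.n_samples)]
        return sorted(spans)
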