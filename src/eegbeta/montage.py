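"""Idealized 10-20 scalp montage on the unit sphere.

Head-centered coordinate frame: +x points to the subject's right, +y to the
front (nasion), +z up through the vertex. Electrodes sit on the unit sphere.

The 10 electrodes of the circumferential ring lie on the equator
(inclination 90 deg) at 36-degree azimuthal steps from the front midline;
Fz/Pz sit 45 deg anterior/posterior of the vertex on the midline, and the
intermediate positions (F3/4, C3/4, P3/4) are great-circle midpoints between
their midline and ring neighbours, following the standard proportional
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: channel order used everywhere downstream
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels with unit-sphere electrode positions."""

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n_channels, 3)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("electrode positions must lie on the unit sphere")
        # pairwise distinct
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-6:
            raise ValueError("electrode positions must be pairwise distinct")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, indices: np.ndarray | list[int]) -> "Montage":
        idx = list(indices)
        return Montage(
            labels=tuple(self.labels[i] for i in idx),
            positions=self.positions[idx],
        )


def _sph(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector from inclination (from +z) and azimuth (from +y toward +x)."""
    th = np.deg2rad(inclination_deg)
    az = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


def _slerp_mid(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Midpoint of the great-circle arc between two unit vectors."""
    m = a + b
    return m / np.linalg.norm(m)


def standard_montage_1020() -> Montage:
    """Build the 19-channel 10-20 montage with unit-sphere coordinates.

    Cz is at the vertex (0, 0, 1); ring electrodes are equatorial.
    """
    p: dict[str, np.ndarray] = {}
    # circumferential ring, equator, 36 deg steps; negative azimuth = left
    ring = {
        "Fp1": -18, "Fp2": 18,
        "F7": -54, "F8": 54,
        "T3": -90, "T4": 90,
        "T5": -126, "T6": 126,
        "O1": -162, "O2": 162,
    }
    for lab, az in ring.items():
        p[lab] = _sph(90.0, az)
    p["Cz"] = _sph(0.0, 0.0)
    p["Fz"] = _sph(45.0, 0.0)
    p["Pz"] = _sph(45.0, 180.0)
    p["F3"] = _slerp_mid(p["Fz"], p["F7"])
    p["F4"] = _slerp_mid(p["Fz"], p["F8"])
    p["C3"] = _slerp_mid(p["Cz"], p["T3"])
    p["C4"] = _slerp_mid(p["Cz"], p["T4"])
    p["P3"] = _slerp_mid(p["Pz"], p["T5"])
    p["P4"] = _slerp_mid(p["Pz"], p["T6"])
    positions = np.stack([p[lab] for lab in CHANNELS_1020])
    return Montage(labels=CHANNELS_1020, positions=positions)
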