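"""Electrode montage container and the built-in 30-channel 10-20 layout.

Positions live on the unit sphere (x = right, y = nasion, z = vertex).
The built-in montage is constructed from the defining geometry of the
international 10-20 system: the outer circumferential ring sits at a polar
angle of 72 deg from the vertex, midline and coronal sites subdivide the
nasion-inion and ear-to-ear great-circle arcs in 10/20 % steps, and the
remaining lateral sites bisect the arc of the coronal circle joining the
ring electrode, the midline electrode, and the mirrored ring electrode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Montage", "load_montage", "hemisphere_of", "DEFAULT30_LABELS"]

DEFAULT30_LABELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "Cz", "C3", "C4", "T7", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P3", "Pz", "P4", "P7", "P8",
    "O1", "Oz", "O2",
]

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|Z|\d+)$")


def hemisphere_of(label: str) -> str:
    """Hemisphere from the 10-20 label suffix: odd digit -> left, even -> right, z -> midline."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse 10-20 electrode label {label!r}")
    suffix = m.group(2)
    if suffix in ("z", "Z"):
        return "midline"
    return "left" if int(suffix) % 2 == 1 else "right"


@dataclass
class Montage:
    """Labelled unit-sphere electrode positions with hemisphere assignment."""

    labels: list[str]
    positions: np.ndarray  # (n, 3), unit norm
    hemisphere: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        if len(set(self.labels)) != len(self.labels):
            dup = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate electrode labels: {dup}")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("electrode position with zero norm cannot be normalized")
        self.positions = self.positions / norms[:, None]
        if not self.hemisphere:
            self.hemisphere = [hemisphere_of(l) for l in self.labels]
        self._index = {l: i for i, l in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def cosine_angles(self) -> np.ndarray:
        """cos of the central angle between every electrode pair (CSD kernel argument)."""
        c = self.positions @ self.positions.T
        return np.clip(c, -1.0, 1.0)

    def subset(self, labels: list[str]) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(list(labels), self.positions[idx].copy())


def _sph(polar_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector; polar from vertex, azimuth from nasion, positive toward the right ear."""
    th = np.deg2rad(polar_deg)
    az = np.deg2rad(azim_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])

def _arc_midpoint(a: np.ndarray, m: np.ndarray, a_mirror: np.ndarray) -> np.ndarray:
    """Midpoint of the minor arc a->m on the circle through a, m and a_mirror."""
    n = np.cross(m - a, a_mirror - a)
    n = n / np.linalg.norm(n)
    d = float(n @ a)
    center = d * n
    rho = np.sqrt(max(1.0 - d * d, 0.0))
    ua = (a - center) / np.linalg.norm(a - center)
    um = (m - center) / np.linalg.norm(m - center)
    mid = ua + um
    mid = mid / np.linalg.norm(mid)
    return center + rho * mid


def _build_default30() -> Montage:
    pos: dict[str, np.ndarray] = {}
    ring = 72.0  # polar angle of the circumferential ring
    # circumferential ring: azimuth steps of 18 deg (5% of the head circumference)
    for label, az in [
        ("Fp1", -18), ("Fp2", 18), ("F7", -54), ("F8", 54),
        ("FT7", -72), ("FT8", 72), ("T7", -90), ("T8", 90),
        ("TP7", -108), ("TP8", 108), ("P7", -126), ("P8", 126),
        ("O1", -162), ("O2", 162), ("Oz", 180),
    ]:
        pos[label] = _sph(ring, az)
    # midline along the nasion-inion great circle
    for label, polar, az in [
        ("Fz", 36, 0), ("FCz", 18, 0), ("Cz", 0, 0), ("CPz", 18, 180), ("Pz", 36, 180),
    ]:
        pos[label] = _sph(polar, az)
    # coronal rows: lateral site bisects the ring-to-midline arc of the row circle
    rows = [("F7", "Fz", "F3", "F8", "F4"),
            ("FT7", "FCz", "FC3", "FT8", "FC4"),
            ("T7", "Cz", "C3", "T8", "C4"),
            ("TP7", "CPz", "CP3", "TP8", "CP4"),
            ("P7", "Pz", "P3", "P8", "P4")]
    for left_ring, mid, left_name, right_ring, right_name in rows:
        pos[left_name] = _arc_midpoint(pos[left_ring], pos[mid], pos[right_ring])
        pos[right_name] = pos[left_name] * np.array([-1.0, 1.0, 1.0])
    positions = np.stack([pos[l] for l in DEFAULT30_LABELS])
    return Montage(list(DEFAULT30_LABELS), positions)


def load_montage(path_or_name: str | Path) -> Montage:
    """Load a montage from a delimited file, or the built-in ``"default30"``.

    File rows are either ``label x y z`` (Cartesian, any radius) or
    ``label polar azimuth`` (degrees; polar from vertex, azimuth from nasion,
    positive to the right). Comma or whitespace delimited; ``#`` comments.
    """
    if str(path_or_name) == "default30":
        return _build_default30()
    path = Path(path_or_name)
    labels: list[str] = []
    vecs: list[np.ndarray] = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = re.split(r"[,\s]+", line)
        if len(fields) == 4:
            vec = np.array([float(v) for v in fields[1:]])
        elif len(fields) == 3:
            vec = _sph(float(fields[1]), float(fields[2]))
        else:
            raise ValueError(
                f"unknown montage row format ({len(fields)} fields): {raw!r}; "
                "expected 'label x y z' or 'label polar azimuth'"
            )
        labels.append(fields[0])
        vecs.append(vec)
    if not labels:
        raise ValueError(f"no electrode rows found in {path}")
    return Montage(labels, np.stack(vecs))
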