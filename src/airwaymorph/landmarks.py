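"""Named anatomical landmark sets.

Landmarks are matched across timepoints by label, never by order.  Labels
follow the convention ``<name>-L`` / ``<name>-R`` for bilateral points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import LandmarkError

__all__ = [
    "LandmarkSet",
    "CRANIAL_BASE_LABELS",
    "MAXILLA_LABELS",
    "MANDIBLE_LABELS",
    "AIRWAY_LABELS",
]

# labels the registration pipeline expects, one bundle per structure
CRANIAL_BASE_LABELS = (
    "frontozygomatic-L",
    "frontozygomatic-R",
    "zygomatic-arch-L",
    "zygomatic-arch-R",
)
MAXILLA_LABELS = (
    "mx-molar-cusp-L",
    "mx-molar-cusp-R",
    "mx-canine-cusp-L",
    "mx-canine-cusp-R",
)
MANDIBLE_LABELS = (
    "md-molar-cusp-L",
    "md-molar-cusp-R",
    "md-canine-cusp-L",
    "md-canine-cusp-R",
)
AIRWAY_LABELS = (
    "pharyngeal-recess-L",
    "pharyngeal-recess-R",
    "interarytenoid-notch",
)


@dataclass
class LandmarkSet:
    """Ordered mapping of unique anatomical labels to 3D points (mm)."""

    points: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for label, xyz in self.points.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise LandmarkError(f"landmark {label!r} is not a finite 3D point")
            if label in clean:
                raise LandmarkError(f"duplicate landmark label {label!r}")
            clean[label] = arr
        self.points = clean
        # bilateral labels must come in pairs
        for label in clean:
            if label.endswith("-L") and label[:-2] + "-R" not in clean:
                raise LandmarkError(f"{label!r} present without right counterpart")
            if label.endswith("-R") and label[:-2] + "-L" not in clean:
                raise LandmarkError(f"{label!r} present without left counterpart")

    @property
    def labels(self) -> tuple:
        return tuple(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.points[label]

    def __contains__(self, label: str) -> bool:
        return label in self.points

    def array(self, labels=None) -> np.ndarray:
        """Coordinates as an (n, 3) array in the given (or stored) label order."""
        labels = self.labels if labels is None else tuple(labels)
        missing = [lb for lb in labels if lb not in self.points]
        if missing:
            raise LandmarkError(
                f"missing landmark labels: {', '.join(missing)}", missing=missing
            )
        return np.array([self.points[lb] for lb in labels])

    def subset(self, labels) -> "LandmarkSet":
        return LandmarkSet({lb: self.points[lb] for lb in labels})

    def transformed(self, transform) -> "LandmarkSet":
        return LandmarkSet(
            {lb: transform.apply(p) for lb, p in self.points.items()}
        )

    def jittered(self, rng: np.random.Generator, sigma: float) -> "LandmarkSet":
        """Add isotropic Gaussian picking noise (mm) to every point."""
        return LandmarkSet(
            {lb: p + rng.normal(0.0, sigma, 3) for lb, p in self.points.items()}
        )

    # -- JSON I/O ({label: [x, y, z]}) --------------------------------------

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({lb: list(map(float, p)) for lb, p in self.points.items()}, fh,
                      indent=1)

    @classmethod
    def from_json(cls, path: str) -> "LandmarkSet":
        with open(path) as fh:
            return cls(json.load(fh))
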