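"""Integer-labeled region-of-interest volumes and the tissue-class label map."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PhantomGeometry

BACKGROUND = "background"
GRAY_MATTER = "gray_matter"
WHITE_MATTER = "white_matter"
VENTRICULAR_CSF = "ventricular_csf"
SUPRASELLAR_CSF = "suprasellar_csf"
OPTIC_NERVE = "optic_nerve"
CHOROID_PLEXUS = "choroid_plexus"

#: Canonical label integers; 0 is always background.
LABELS: dict[str, int] = {
    BACKGROUND: 0,
    GRAY_MATTER: 1,
    WHITE_MATTER: 2,
    VENTRICULAR_CSF: 3,
    SUPRASELLAR_CSF: 4,
    OPTIC_NERVE: 5,
    CHOROID_PLEXUS: 6,
}

TISSUE_CLASSES = tuple(name for name in LABELS if name != BACKGROUND)


@dataclass
class ROIMask:
    """Integer-labeled 3-D volume naming tissue/structure classes.

    ``labels`` holds one integer per voxel; ``label_map`` maps class names to
    those integers (0 = background by convention).
    """

    labels: np.ndarray
    geometry: PhantomGeometry
    label_map: dict[str, int] = field(default_factory=lambda: dict(LABELS))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("ROIMask labels must be a 3-D array")
        if tuple(self.labels.shape) != tuple(self.geometry.shape):
            raise ValueError(
                f"label array shape {self.labels.shape} does not match "
                f"geometry {self.geometry.shape}"
            )

    def region(self, name: str) -> np.ndarray:
        """Boolean mask for one named class."""
        return self.labels == self.label_map[name]

    def present_classes(self) -> list[str]:
        present = set(np.unique(self.labels))
        return [n for n, v in self.label_map.items() if v in present and n != BACKGROUND]

    def counts(self) -> dict[str, int]:
        return {n: int(np.sum(self.labels == v))
                for n, v in self.label_map.items() if n != BACKGROUND}
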