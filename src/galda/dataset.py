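"""Core containers shared by every pipeline stage.

An NMR spectral dataset is a plain (samples x points) intensity matrix tied
to a chemical-shift axis in ppm.  The axis is stored ascending internally;
plotting code flips it to the conventional descending NMR display.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Class labels of the three-group case-control design.
GROUPS = ("C", "PD", "T2D")


@dataclass(frozen=True)
class AcquisitionGrid:
    """Evenly spaced chemical-shift axis.

    Defaults match a 300 MHz urine acquisition: 32,768 points spanning
    -3.313 to 12.706 ppm (about 0.489 milli-ppm per point).
    """

    ppm_start: float = -3.313
    ppm_end: float = 12.706
    n_points: int = 32768

    def __post_init__(self) -> None:
        if not self.ppm_start < self.ppm_end:
            raise ValueError("ppm_start must be < ppm_end")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    def ppm(self) -> np.ndarray:
        """Return the ascending ppm axis."""
        return np.linspace(self.ppm_start, self.ppm_end, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.ppm_end - self.ppm_start) / (self.n_points - 1)


@dataclass
class LabeledSpectraSet:
    """Intensity matrix + ppm axis + class label and patient ID per sample."""

    ppm: np.ndarray
    X: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        n, p = self.X.shape
        if self.ppm.ndim != 1 or self.ppm.size != p:
            raise ValueError(
                f"ppm axis length {self.ppm.size} != {p} spectral points"
            )
        if self.labels.size != n or self.patient_ids.size != n:
            raise ValueError("labels/patient_ids length must match sample count")
        if len(set(self.patient_ids.tolist())) != n:
            raise ValueError("patient_ids must be unique (one spectrum per patient)")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_points(self) -> int:
        return self.X.shape[1]

    def subset(self, indices) -> "LabeledSpectraSet":
        """Row subset (copy), keeping the ppm axis."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            X=self.X[idx].copy(),
            labels=self.labels[idx].copy(),
            patient_ids=self.patient_ids[idx].copy(),
        )

    def class_indices(self) -> dict:
        """Map label -> array of row indices, labels in first-seen order."""
        out: dict = {}
        for i, lab in enumerate(self.labels):
            out.setdefault(lab, []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}


@dataclass
class ProcessedSpectraSet(LabeledSpectraSet):
    """A LabeledSpectraSet after preprocessing.

    ``column_means`` holds the training-partition means used for centering
    (the test-set contract reuses them); ``provenance`` records the applied
    steps in order.
    """

    column_means: np.ndarray | None = None
    provenance: list = field(default_factory=list)

    def subset(self, indices) -> "ProcessedSpectraSet":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            X=self.X[idx].copy(),
            labels=self.labels[idx].copy(),
            patient_ids=self.patient_ids[idx].copy(),
            column_means=None if self.column_means is None else self.column_means.copy(),
            provenance=list(self.provenance),
        )
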