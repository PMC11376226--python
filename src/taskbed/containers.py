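"""Labeled image ensembles and their on-disk container format.

An :class:`ImageEnsemble` is the package's canonical in-memory object: a
stack of 2-D images with a hypothesis label per image (0 = signal absent,
1..J = signal present at location class j), the true signal centre where one
exists, and one or more *variants* of every image (the noiseless target, the
low-dose reconstruction, a denoised estimate, ...), all index-aligned.

Ensembles serialize to either NPZ or HDF5; the generating task description
travels with the file as a JSON attribute so any ensemble is reproducible
from its manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

#: canonical variant names
TARGET = "target"
LOWDOSE = "lowdose"
DENOISED = "denoised"

ABSENT_CENTER = (np.nan, np.nan)


@dataclass
class ImageEnsemble:
    """Index-aligned collection of labeled image variants.

    Parameters
    ----------
    images
        Mapping variant name -> array of shape ``(n, side, side)``.
    labels
        Integer array of shape ``(n,)``; 0 means signal absent.
    signal_centers
        Float array ``(n, 2)`` of (row, col) centres; NaN rows for
        signal-absent images.
    task_manifest
        JSON-serializable description of the generating task/config.
    """

    images: dict[str, np.ndarray]
    labels: np.ndarray
    signal_centers: np.ndarray
    task_manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.signal_centers = np.asarray(self.signal_centers, dtype=np.float64)
        n = self.labels.shape[0]
        if self.signal_centers.shape != (n, 2):
            raise ValueError("signal_centers must have shape (n, 2)")
        for name, arr in self.images.items():
            if arr.ndim != 3 or arr.shape[0] != n:
                raise ValueError(f"variant {name!r} must have shape (n, side, side)")
        absent = self.labels == 0
        if not np.all(np.isnan(self.signal_centers[absent])):
            raise ValueError("label 0 requires an absent (NaN) signal_center")
        if np.any(np.isnan(self.signal_centers[~absent])):
            raise ValueError("label > 0 requires a recorded signal_center")

    # -- basic introspection -------------------------------------------------
    def __len__(self) -> int:
        return int(self.labels.shape[0])

    @property
    def side(self) -> int:
        return next(iter(self.images.values())).shape[1]

    @property
    def n_present(self) -> int:
        return int(np.count_nonzero(self.labels > 0))

    @property
    def n_absent(self) -> int:
        return int(np.count_nonzero(self.labels == 0))

    def variant(self, name: str) -> np.ndarray:
        return self.images[name]

    def present(self, name: str = TARGET) -> np.ndarray:
        return self.images[name][self.labels > 0]

    def absent(self, name: str = TARGET) -> np.ndarray:
        return self.images[name][self.labels == 0]

    def with_variant(self, name: str, arr: np.ndarray) -> "ImageEnsemble":
        """Return a new ensemble sharing labels/centres with one more variant."""
        images = dict(self.images)
        images[name] = np.asarray(arr)
        return ImageEnsemble(images, self.labels, self.signal_centers, dict(self.task_manifest))

    def subset(self, idx: np.ndarray) -> "ImageEnsemble":
        return ImageEnsemble(
            {k: v[idx] for k, v in self.images.items()},
            self.labels[idx],
            self.signal_centers[idx],
            dict(self.task_manifest),
        )

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            with h5py.File(path, "w") as f:
                for name, arr in self.images.items():
                    f.create_dataset(f"pixels/{name}", data=arr)
                f.create_dataset("label", data=self.labels)
                f.create_dataset("signal_center", data=self.signal_centers)
                f.attrs["task_manifest"] = json.dumps(self.task_manifest)
        else:
            np.savez(
                path,
                labels=self.labels,
                signal_centers=self.signal_centers,
                task_manifest=json.dumps(self.task_manifest),
                **{f"pixels_{k}": v for k, v in self.images.items()},
            )

    @classmethod
    def load(cls, path: str | Path) -> "ImageEnsemble":
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            with h5py.File(path, "r") as f:
                images = {k: f[f"pixels/{k}"][...] for k in f["pixels"]}
                return cls(
                    images,
                    f["label"][...],
                    f["signal_center"][...],
                    json.loads(f.attrs["task_manifest"]),
                )
        with np.load(path, allow_pickle=False) as z:
            images = {
                k[len("pixels_"):]: z[k] for k in z.files if k.startswith("pixels_")
            }
            return cls(
                images,
                z["labels"],
                z["signal_centers"],
                json.loads(str(z["task_manifest"])),
            )
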