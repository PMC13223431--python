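"""Volume and manifest I/O plus the training augmentation policy.

Volumes are 3D scalar grids in (depth, height, width) axis order, stored on
disk as NIfTI (via nibabel) and paired with a class label and a patient id.
Manifests are plain CSV files with header ``path,label,patient_id``.

The augmentation policy mirrors standard volumetric training practice for
sequence classification: optional isotropic rescaling of height and width
(depth untouched), zero-padding to at least the crop shape, a random (train)
or center (eval) crop to a fixed shape, and a random left-right mirror flip.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "Manifest",
    "AugmentConfig",
    "read_volume",
    "write_volume",
    "read_manifest",
    "write_manifest",
    "minmax_normalize",
    "augment",
    "split_folds",
]


@dataclass
class Volume:
    """One 3D scan with its class label and originating patient."""

    intensities: np.ndarray  # (depth, height, width)
    label: int = -1
    patient_id: str = ""
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"volume must be 3D (depth, height, width), got {self.intensities.ndim}D"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class Manifest:
    """Ordered record list mapping volume files to labels and patients."""

    records: list[tuple[str, str, str]] = field(default_factory=list)  # path, label, patient
    label_vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self):
        paths = [r[0] for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("duplicate volume paths in manifest")
        vocab = set(self.label_vocabulary)
        for _, label, _ in self.records:
            if label not in vocab:
                raise ValueError(f"label {label!r} not in vocabulary")

    def label_index(self, name: str) -> int:
        return self.label_vocabulary.index(name)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AugmentConfig:
    crop_shape: tuple[int, int, int]
    scale_prob: float = 0.75
    scale_range: tuple[float, float] = (0.8, 1.25)
    flip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.scale_prob <= 1.0 and 0.0 <= self.flip_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi):
            raise ValueError("scale_range must satisfy 0 < low <= high")
        if any(s <= 0 for s in self.crop_shape):
            raise ValueError("crop_shape entries must be positive")


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI file as a Volume in (depth, height, width) order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D image (ndim={data.ndim})")
    zooms = img.header.get_zooms()[:3]
    return Volume(intensities=data, spacing=tuple(float(z) for z in zooms))


def write_volume(v: Volume, path: str | Path) -> None:
    affine = np.eye(4)
    if v.spacing is not None:
        affine[0, 0], affine[1, 1], affine[2, 2] = v.spacing
    img = nib.Nifti1Image(v.intensities.astype(np.float32), affine)
    nib.save(img, str(path))


def read_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    records: list[tuple[str, str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"path", "label", "patient_id"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        for row in reader:
            records.append((row["path"], row["label"], row["patient_id"]))
    vocab = sorted({label for _, label, _ in records})
    return Manifest(records=records, label_vocabulary=vocab)


def write_manifest(m: Manifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "patient_id"])
        writer.writerows(m.records)


def minmax_normalize(intensities: np.ndarray) -> np.ndarray:
    """Rescale one volume to [0, 1]; a constant volume maps to all zeros."""
    lo = intensities.min()
    hi = intensities.max()
    if hi - lo <= 0:
        return np.zeros_like(intensities, dtype=np.float64)
    return (intensities - lo) / (hi - lo)


def _pad_to(arr: np.ndarray, target: tuple[int, int, int]) -> np.ndarray:
    pads = []
    for size, want in zip(arr.shape, target):
        extra = max(want - size, 0)
        pads.append((extra // 2, extra - extra // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, mode="constant")
    return arr


def _crop(arr: np.ndarray, shape: tuple[int, int, int], rng: np.random.Generator | None) -> np.ndarray:
    starts = []
    for size, want in zip(arr.shape, shape):
        slack = size - want
        if rng is None:
            starts.append(slack // 2)
        else:
            starts.append(int(rng.integers(0, slack + 1)))
    sl = tuple(slice(s, s + w) for s, w in zip(starts, shape))
    return arr[sl]


def augment(
    v: Volume,
    cfg: AugmentConfig,
    rng: np.random.Generator | None = None,
    train: bool = True,
) -> Volume:
    """Apply scale / pad / crop / flip; deterministic given the generator state.

    With ``train=False`` (or ``rng=None``) the stochastic steps are skipped and
    the volume is center-cropped, which is the evaluation contract.
    """
    if rng is None:
        train = False
    arr = v.intensities
    if train and cfg.scale_prob > 0 and rng.random() < cfg.scale_prob:
        factor = float(rng.uniform(*cfg.scale_range))
        arr = ndimage.zoom(arr, (1.0, factor, factor), order=1)
    arr = _pad_to(arr, cfg.crop_shape)
    arr = _crop(arr, cfg.crop_shape, rng if train else None)
    if train and cfg.flip_prob > 0 and rng.random() < cfg.flip_prob:
        arr = arr[:, :, ::-1]
    return Volume(
        intensities=np.ascontiguousarray(arr),
        label=v.label,
        patient_id=v.patient_id,
        spacing=v.spacing,
    )


def split_folds(
    m: Manifest, n_folds: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-grouped cross-validation folds.

    Patients are dealt round-robin to folds after grouping by their dominant
    class (class-stratified when patients are single-class) and shuffling
    within each group, so fold patient counts differ by at most one and no
    patient ever appears on both sides of a fold.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    patients: dict[str, list[int]] = {}
    for i, (_, _, pid) in enumerate(m.records):
        patients.setdefault(pid, []).append(i)
    if len(patients) < n_folds:
        raise ValueError(f"need >= {n_folds} patients, have {len(patients)}")

    rng = np.random.default_rng(seed)
    # dominant class per patient for stratification
    def dominant(pid: str) -> str:
        labels = [m.records[i][1] for i in patients[pid]]
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        return max(sorted(counts), key=counts.get)

    by_class: dict[str, list[str]] = {}
    for pid in sorted(patients):
        by_class.setdefault(dominant(pid), []).append(pid)

    fold_of: dict[str, int] = {}
    cursor = 0
    for cls in sorted(by_class):
        group = by_class[cls]
        rng.shuffle(group)
        for pid in group:
            fold_of[pid] = cursor % n_folds
            cursor += 1

    folds = []
    for f in range(n_folds):
        test_idx = np.array(
            sorted(i for pid, fl in fold_of.items() if fl == f for i in patients[pid]),
            dtype=int,
        )
        train_idx = np.array(
            sorted(i for pid, fl in fold_of.items() if fl != f for i in patients[pid]),
            dtype=int,
        )
        folds.append((train_idx, test_idx))
    return folds
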