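"""Reading and writing multimodal volumes and label maps.

A *case* is four co-registered 3-D modality volumes (T1, T2, post-contrast
T1, FLAIR) plus an optional integer label volume over the internal coding
``{0: background, 1: edema, 2: non-enhancing, 3: enhancing}``.  External
codings (e.g. the BraTS convention 1 = non-enhancing, 2 = edema,
4 = enhancing) are handled through explicit mapping tables; nothing in the
package assumes a particular on-disk coding.

Volumes are stored channel-last, ``(X, Y, Z, C)``, with exactly four
channels in canonical modality order.  Voxel indices are 0-based and boxes
are half-open per axis throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

#: canonical channel order
MODALITIES = ("t1", "t2", "t1ce", "flair")

#: internal class coding
BACKGROUND, EDEMA, NON_ENHANCING, ENHANCING = 0, 1, 2, 3
INTERNAL_LABELS = frozenset({0, 1, 2, 3})

#: BraTS-style external coding -> internal classes
BRATS_TO_INTERNAL: dict[int, int] = {0: 0, 1: 2, 2: 1, 4: 3}
INTERNAL_TO_BRATS: dict[int, int] = {0: 0, 2: 1, 1: 2, 3: 4}


@dataclass
class MultiModalVolume:
    """Four-channel intensity grid with spacing and orientation metadata.

    ``intensities`` has shape ``(X, Y, Z, 4)`` with channels in
    :data:`MODALITIES` order.  ``affine`` carries the NIfTI voxel-to-world
    transform opaquely so that a read/write round trip preserves it.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 4 or self.intensities.shape[-1] != len(MODALITIES):
            raise ValueError(
                f"expected (X, Y, Z, 4) intensities, got shape {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]


@dataclass
class LabelVolume:
    """Integer class grid over the internal coding {0, 1, 2, 3}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.all(lab == np.round(lab)):
                raise ValueError("labels must be integers")
            self.labels = lab.astype(np.int16)
        else:
            self.labels = self.labels.astype(np.int16)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3-D label grid, got shape {self.labels.shape}")
        found = set(np.unique(self.labels).tolist())
        bad = found - INTERNAL_LABELS
        if bad:
            raise ValueError(f"unknown label values {sorted(bad)}; expected subset of {{0,1,2,3}}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class CaseRecord:
    """Paths of one case: four modality files plus an optional label file."""

    case_id: str
    modality_paths: Mapping[str, Path]
    label_path: Path | None = None

    def __post_init__(self) -> None:
        missing = [m for m in MODALITIES if m not in self.modality_paths]
        if missing:
            raise ValueError(f"case {self.case_id}: missing modalities {missing}")
        self.modality_paths = {m: Path(self.modality_paths[m]) for m in MODALITIES}
        if self.label_path is not None:
            self.label_path = Path(self.label_path)


def map_labels(grid: np.ndarray, mapping: Mapping[int, int]) -> np.ndarray:
    """Apply an explicit label-code mapping element-wise.

    Every value present in ``grid`` must appear as a key; unknown values are
    a hard error so silent label corruption cannot occur.
    """
    grid = np.asarray(grid)
    found = set(np.unique(grid).tolist())
    unknown = found - set(int(k) for k in mapping)
    if unknown:
        raise ValueError(f"unmapped label values {sorted(unknown)}")
    out = np.empty(grid.shape, dtype=np.int16)
    for src, dst in mapping.items():
        out[grid == src] = dst
    return out


def _check_bijective(mapping: Mapping[int, int], used: set[int]) -> None:
    sub = {k: v for k, v in mapping.items() if k in used}
    if len(set(sub.values())) != len(sub):
        raise ValueError(f"label mapping is not a bijection on the used set {sorted(used)}")


def read_case(
    record: CaseRecord,
    label_mapping: Mapping[int, int] | None = None,
) -> tuple[MultiModalVolume, LabelVolume | None]:
    """Load a case from NIfTI files.

    Parameters
    ----------
    record:
        Paths per modality plus the optional label file.
    label_mapping:
        External-to-internal code table applied to the label grid.  Defaults
        to the identity (files already use the internal coding).

    All five grids must share shape; a mismatch names the offending file.
    """
    channels = []
    ref_shape: tuple[int, ...] | None = None
    ref_affine = None
    spacing = (1.0, 1.0, 1.0)
    for m in MODALITIES:
        path = record.modality_paths[m]
        if not path.exists():
            raise FileNotFoundError(f"case {record.case_id}: missing file {path}")
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float32)
        if ref_shape is None:
            ref_shape = data.shape
            ref_affine = img.affine
            zooms = img.header.get_zooms()[:3]
            spacing = tuple(float(z) for z in zooms)
        elif data.shape != ref_shape:
            raise ValueError(
                f"case {record.case_id}: modality {m} ({path}) has shape "
                f"{data.shape}, expected {ref_shape}"
            )
        channels.append(data)
    volume = MultiModalVolume(
        np.stack(channels, axis=-1), spacing=spacing, affine=np.asarray(ref_affine)
    )

    labels = None
    if record.label_path is not None:
        if not record.label_path.exists():
            raise FileNotFoundError(
                f"case {record.case_id}: missing label file {record.label_path}"
            )
        img = nib.load(str(record.label_path))
        raw = np.asanyarray(img.dataobj)
        if raw.shape != ref_shape:
            raise ValueError(
                f"case {record.case_id}: labels ({record.label_path}) have shape "
                f"{raw.shape}, expected {ref_shape}"
            )
        raw = raw.astype(np.int16)
        if label_mapping is not None:
            raw = map_labels(raw, label_mapping)
        labels = LabelVolume(raw)
    return volume, labels


def write_volume(volume: MultiModalVolume, paths: Mapping[str, Path]) -> None:
    """Write each modality channel to its own NIfTI file."""
    for i, m in enumerate(MODALITIES):
        img = nib.Nifti1Image(volume.intensities[..., i], volume.affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, str(paths[m]))


def write_labels(
    labels: LabelVolume,
    path: Path,
    mapping: Mapping[int, int] | None = None,
    affine: np.ndarray | None = None,
) -> None:
    """Write a label grid, optionally re-coded through ``mapping``.

    ``mapping`` must be a bijection on the label values actually present so
    that composing with its inverse restores the input exactly.
    """
    grid = labels.labels
    if mapping is not None:
        used = set(np.unique(grid).tolist())
        missing = used - set(int(k) for k in mapping)
        if missing:
            raise ValueError(f"mapping omits label values {sorted(missing)} present in grid")
        _check_bijective(mapping, used)
        grid = map_labels(grid, mapping)
    img = nib.Nifti1Image(
        grid.astype(np.int16), np.eye(4) if affine is None else affine
    )
    nib.save(img, str(path))


def write_manifest(records: list[CaseRecord], path: Path) -> None:
    """Serialize case records as a JSON manifest of case_id -> file paths."""
    rows = []
    for r in records:
        row = {"case_id": r.case_id}
        row.update({m: str(p) for m, p in r.modality_paths.items()})
        if r.label_path is not None:
            row["labels"] = str(r.label_path)
        rows.append(row)
    Path(path).write_text(json.dumps(rows, indent=2))


def read_manifest(path: Path) -> list[CaseRecord]:
    rows = json.loads(Path(path).read_text())
    records = []
    for row in rows:
        records.append(
            CaseRecord(
                case_id=row["case_id"],
                modality_paths={m: Path(row[m]) for m in MODALITIES},
                label_path=Path(row["labels"]) if "labels" in row else None,
            )
        )
    return records
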