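"""In-memory containers for 4D voxel time-series data and labeled atlases.

A :class:`Dataset4D` stores the in-mask voxel time-series as a dense
``(n_frames, n_voxels)`` float array, with the 3D boolean mask kept
alongside so the data can be re-inflated to a full grid at any time.
Voxel columns follow C-order flattening of the mask, i.e.
``volume[mask]`` order.  All analysis operations work on this masked 2D
form; NIfTI-1 is used only at the I/O boundary (via nibabel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Dataset4D",
    "LabelAtlas",
    "load_dataset",
    "save_dataset",
    "load_atlas",
    "save_atlas",
]


@dataclass
class Dataset4D:
    """Masked voxel time-series with acquisition metadata.

    Parameters
    ----------
    values : ndarray, shape (n_frames, n_voxels)
        In-mask time-series; column ``j`` is the voxel at
        ``np.argwhere(mask)[j]`` (C order).
    mask : ndarray of bool, shape (nx, ny, nz)
        In-brain voxels.
    tr_s : float
        Repetition time (sampling interval) in seconds.
    voxel_size_mm : float
        Isotropic voxel spacing in millimetres.
    provenance : list of dict
        Ordered, append-only record of operations applied so far.
    """

    values: np.ndarray
    mask: np.ndarray
    tr_s: float
    voxel_size_mm: float = 1.0
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (frames x voxels)")
        if self.values.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"values has {self.values.shape[1]} voxel columns but mask "
                f"selects {int(self.mask.sum())} voxels"
            )
        if self.n_frames < 2:
            raise ValueError("a dataset needs at least 2 frames")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)

    def with_values(self, values: np.ndarray, step: str, **params) -> "Dataset4D":
        """Return a copy with new values and one provenance entry appended."""
        prov = list(self.provenance) + [{"step": step, **params}]
        return replace(self, values=np.asarray(values, dtype=np.float64), provenance=prov)

    def to_volume(self) -> np.ndarray:
        """Inflate to a dense (nx, ny, nz, n_frames) array (zeros off-mask)."""
        vol = np.zeros(self.mask.shape + (self.n_frames,), dtype=np.float64)
        vol[self.mask, :] = self.values.T
        return vol

    @classmethod
    def from_volume(
        cls,
        volume: np.ndarray,
        mask: np.ndarray,
        tr_s: float,
        voxel_size_mm: float = 1.0,
        provenance: list | None = None,
    ) -> "Dataset4D":
        volume = np.asarray(volume, dtype=np.float64)
        mask = np.asarray(mask, dtype=bool)
        if volume.shape[:3] != mask.shape:
            raise ValueError("volume grid does not match mask grid")
        return cls(
            values=volume[mask, :].T,
            mask=mask,
            tr_s=tr_s,
            voxel_size_mm=voxel_size_mm,
            provenance=provenance if provenance is not None else [],
        )


@dataclass
class LabelAtlas:
    """Integer label volume plus the homotopic left/right pairing table.

    ``labels`` is 0 for background; positive integers label regions.
    ``pairs`` has columns ``left_id``, ``right_id``, ``name``.
    """

    labels: np.ndarray
    pairs: pd.DataFrame
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D volume")
        required = {"left_id", "right_id", "name"}
        if not required.issubset(self.pairs.columns):
            raise ValueError(f"pairing table must have columns {sorted(required)}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean brain mask: every labeled voxel."""
        return self.labels > 0

    @property
    def roi_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def roi_name(self, roi_id: int) -> str:
        row = self.pairs[(self.pairs.left_id == roi_id) | (self.pairs.right_id == roi_id)]
        if row.empty:
            raise KeyError(f"ROI id {roi_id} not in pairing table")
        side = "L" if int(row.iloc[0].left_id) == roi_id else "R"
        return f"{row.iloc[0]['name']}_{side}"

    def roi_id(self, name: str) -> int:
        """Resolve a '<region>_L' / '<region>_R' name to its label id."""
        if name.endswith("_L") or name.endswith("_R"):
            base, side = name[:-2], name[-1]
        else:
            raise KeyError(f"ROI name must end in _L or _R, got {name!r}")
        row = self.pairs[self.pairs.name == base]
        if row.empty:
            raise KeyError(f"region {base!r} not in pairing table")
        return int(row.iloc[0].left_id if side == "L" else row.iloc[0].right_id)

    def roi_columns(self, roi_id: int) -> np.ndarray:
        """Column indices (into Dataset4D.values) of one ROI's voxels."""
        return np.flatnonzero(self.labels[self.mask] == roi_id)


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    return aff


def save_dataset(ds: Dataset4D, path: str | Path) -> None:
    """Write a Dataset4D as 4D NIfTI-1 with a JSON provenance sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(ds.to_volume().astype(np.float32), _affine(ds.voxel_size_mm))
    img.header.set_zooms((ds.voxel_size_mm,) * 3 + (ds.tr_s,))
    nib.save(img, path)
    sidecar = {
        "tr_s": ds.tr_s,
        "voxel_size_mm": ds.voxel_size_mm,
        "provenance": ds.provenance,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def load_dataset(path: str | Path, mask: np.ndarray | None = None) -> Dataset4D:
    """Load a 4D NIfTI; if no mask is given, nonzero-variance voxels form it."""
    path = Path(path)
    img = nib.load(path)
    vol = np.asarray(img.dataobj, dtype=np.float64)
    if vol.ndim != 4:
        raise ValueError("expected a 4D NIfTI image")
    zooms = img.header.get_zooms()
    tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    voxel_size = float(zooms[0])
    prov: list = []
    sidecar = path.with_suffix("").with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        tr_s = float(meta.get("tr_s", tr_s))
        voxel_size = float(meta.get("voxel_size_mm", voxel_size))
        prov = meta.get("provenance", [])
    if mask is None:
        mask = vol.std(axis=3) > 0
    return Dataset4D.from_volume(vol, mask, tr_s=tr_s, voxel_size_mm=voxel_size, provenance=prov)


def save_atlas(atlas: LabelAtlas, nifti_path: str | Path, pairs_path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.voxel_size_mm))
    nib.save(img, nifti_path)
    atlas.pairs.to_csv(pairs_path, sep="\t", index=False)


def load_atlas(nifti_path: str | Path, pairs_path: str | Path) -> LabelAtlas:
    img = nib.load(nifti_path)
    labels = np.asarray(img.dataobj).astype(np.int32)
    pairs = pd.read_csv(pairs_path, sep="\t")
    return LabelAtlas(labels=labels, pairs=pairs, voxel_size_mm=float(img.header.get_zooms()[0]))
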