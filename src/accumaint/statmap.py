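"""Minimal 3-D voxel-grid container for statistic maps in MNI millimetres.

A StatMap is a dense float grid with an isotropic-or-not spacing and a
world-space origin (the mm coordinate of voxel (0,0,0)); the affine is
diagonal, which covers the MNI-aligned maps produced and consumed here.
I/O: NIfTI via nibabel when available, and a flat CSV format
(x,y,z,value) that round-trips bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StatMap", "mni_grid"]


@dataclass
class StatMap:
    data: np.ndarray          # (nx, ny, nz) float; NaN encodes missing
    origin_mm: tuple          # world coordinate of voxel (0, 0, 0)
    spacing_mm: tuple         # per-axis voxel size

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("StatMap data must be 3-D")
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        self.spacing_mm = tuple(float(v) for v in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def shape(self):
        return self.data.shape

    def like(self, data: np.ndarray) -> "StatMap":
        return StatMap(data, self.origin_mm, self.spacing_mm)

    # ---- coordinate transforms -------------------------------------------
    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) world coordinates of all voxel centers."""
        axes = [
            self.origin_mm[d] + self.spacing_mm[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def world_to_voxel(self, xyz_mm) -> tuple[int, int, int] | None:
        """Nearest voxel index for a world coordinate; None if outside."""
        idx = []
        for d in range(3):
            i = int(round((xyz_mm[d] - self.origin_mm[d]) / self.spacing_mm[d]))
            if not 0 <= i < self.shape[d]:
                return None
            idx.append(i)
        return tuple(idx)

    def voxel_to_world(self, ijk) -> np.ndarray:
        return np.array(
            [self.origin_mm[d] + self.spacing_mm[d] * ijk[d] for d in range(3)]
        )

    def sphere_indices(self, center_mm, radius_mm: float) -> np.ndarray:
        """(k, 3) indices of voxels whose centers lie within radius of center."""
        lo, hi = [], []
        for d in range(3):
            lo.append(
                max(int(np.floor((center_mm[d] - radius_mm - self.origin_mm[d]) / self.spacing_mm[d])), 0)
            )
            hi.append(
                min(int(np.ceil((center_mm[d] + radius_mm - self.origin_mm[d]) / self.spacing_mm[d])) + 1, self.shape[d])
            )
        if any(l >= h for l, h in zip(lo, hi)):
            return np.empty((0, 3), dtype=int)
        axes = [np.arange(lo[d], hi[d]) for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        centers = self.origin_mm + pts * np.asarray(self.spacing_mm)
        dist2 = np.sum((centers - np.asarray(center_mm, dtype=float)) ** 2, axis=1)
        return pts[dist2 <= radius_mm**2]

    # ---- I/O --------------------------------------------------------------
    def to_csv(self, path) -> None:
        centers = self.voxel_centers().reshape(-1, 3)
        pd.DataFrame(
            {
                "x": centers[:, 0],
                "y": centers[:, 1],
                "z": centers[:, 2],
                "value": self.data.reshape(-1),
            }
        ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "StatMap":
        df = pd.read_csv(path, float_precision="round_trip")
        xs = np.unique(df["x"])
        ys = np.unique(df["y"])
        zs = np.unique(df["z"])

        def _spacing(ax):
            return float(np.diff(ax)[0]) if ax.size > 1 else 1.0

        shape = (xs.size, ys.size, zs.size)
        data = df["value"].to_numpy().reshape(shape)
        return cls(data, (xs[0], ys[0], zs[0]), (_spacing(xs), _spacing(ys), _spacing(zs)))

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.data, affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "StatMap":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
            raise ValueError("only diagonal affines are supported")
        spacing = tuple(np.diag(aff[:3, :3]))
        if any(s < 0 for s in spacing):
            raise ValueError("negative voxel spacing; reorient the image first")
        return cls(np.asarray(img.dataobj, dtype=float), tuple(aff[:3, 3]), spacing)


def mni_grid(spacing_mm: float = 2.0, box=((-78.0, 78.0), (-112.0, 76.0), (-70.0, 86.0))) -> StatMap:
    """Empty MNI-like grid covering a whole-brain bounding box."""
    shape = tuple(int(np.floor((hi - lo) / spacing_mm)) + 1 for lo, hi in box)
    return StatMap(
        np.zeros(shape), tuple(lo for lo, _ in box), (spacing_mm,) * 3
    )
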