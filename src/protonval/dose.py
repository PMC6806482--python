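"""Dose cube container with NPZ persistence and DICOM RT Dose interop.

Doses are absolute (Gy, dose to water) on a regular grid that follows the
same coordinate convention as :class:`~protonval.phantom.VoxelPhantom`:
``origin`` is the center of voxel [0, 0, 0], beam axis +z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DoseCube:
    dose: np.ndarray                    # Gy, shape (nx, ny, nz)
    spacing: np.ndarray                 # mm
    origin: np.ndarray                  # mm, center of voxel [0,0,0]
    engine_tag: str = "apb"             # "apb" | "mc"
    relative_uncertainty: np.ndarray | None = None   # per voxel (MC only)

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.dose < -1e-12):
            raise ValueError("dose must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dose.shape

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def max_dose(self) -> float:
        return float(self.dose.max())

    def interp_points(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the dose at (N, 3) mm positions."""
        pts = np.asarray(points, dtype=float)
        idx = (pts - self.origin) / self.spacing
        out = _trilinear(self.dose, idx)
        return out

    # ---- persistence ------------------------------------------------------

    def save(self, path) -> None:
        arrays = dict(dose=self.dose, spacing=self.spacing, origin=self.origin,
                      engine_tag=np.array(self.engine_tag))
        if self.relative_uncertainty is not None:
            arrays["relative_uncertainty"] = self.relative_uncertainty
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "DoseCube":
        with np.load(path) as z:
            unc = z["relative_uncertainty"] if "relative_uncertainty" in z.files else None
            return cls(dose=z["dose"], spacing=z["spacing"], origin=z["origin"],
                       engine_tag=str(z["engine_tag"]), relative_uncertainty=unc)

    # ---- DICOM RT Dose ----------------------------------------------------

    def to_dicom(self, path) -> None:
        """Write an RT Dose object (GridFrameOffsetVector along z, Gy scaling)."""
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import generate_uid, ExplicitVRLittleEndian

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.2")
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTDOSE"
        ds.SeriesInstanceUID = generate_uid()
        ds.StudyInstanceUID = generate_uid()
        ds.FrameOfReferenceUID = generate_uid()
        ds.DoseUnits = "GY"
        ds.DoseType = "PHYSICAL"
        ds.DoseSummationType = "PLAN"
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.SamplesPerPixel = 1
        ds.BitsAllocated = 32
        ds.BitsStored = 32
        ds.HighBit = 31
        ds.PixelRepresentation = 0
        # DICOM stores frames (z), rows (y), columns (x)
        nx, ny, nz = self.shape
        ds.Columns = nx
        ds.Rows = ny
        ds.NumberOfFrames = nz
        ds.PixelSpacing = [float(self.spacing[1]), float(self.spacing[0])]
        ds.ImagePositionPatient = [float(self.origin[0]), float(self.origin[1]),
                                   float(self.origin[2])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.GridFrameOffsetVector = [float(k * self.spacing[2]) for k in range(nz)]
        scale = self.dose.max() / (2 ** 31 - 1) if self.dose.max() > 0 else 1.0
        ds.DoseGridScaling = scale
        pixels = np.transpose(self.dose / scale, (2, 1, 0)).astype(np.uint32)
        ds.PixelData = pixels.tobytes()
        ds.is_little_endian = True
        ds.is_implicit_VR = False
        pydicom.dcmwrite(path, ds, enforce_file_format=True)

    @classmethod
    def from_dicom(cls, path) -> "DoseCube":
        import pydicom
        ds = pydicom.dcmread(path)
        nz = int(ds.NumberOfFrames)
        ny = int(ds.Rows)
        nx = int(ds.Columns)
        arr = np.frombuffer(ds.PixelData, dtype=np.uint32).reshape(nz, ny, nx)
        dose = np.transpose(arr, (2, 1, 0)).astype(float) * float(ds.DoseGridScaling)
        offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
        dz = float(offsets[1] - offsets[0]) if nz > 1 else 1.0
        spacing = np.array([float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz])
        origin = np.asarray(ds.ImagePositionPatient, dtype=float)
        return cls(dose=dose, spacing=spacing, origin=origin, engine_tag="import")


def _trilinear(grid: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at fractional indices (N, 3); 0 outside."""
    idx = np.atleast_2d(idx)
    shape = np.array(grid.shape)
    out = np.zeros(idx.shape[0])
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    if not np.any(inside):
        return out
    p = idx[inside]
    i0 = np.clip(np.floor(p).astype(int), 0, shape - 2)
    f = p - i0
    acc = np.zeros(p.shape[0])
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1 - f[:, 0]
        for dy in (0, 1):
            wy = f[:, 1] if dy else 1 - f[:, 1]
            for dz in (0, 1):
                wz = f[:, 2] if dz else 1 - f[:, 2]
                acc += wx * wy * wz * grid[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    out[inside] = acc
    return out
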