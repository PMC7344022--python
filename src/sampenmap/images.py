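"""In-memory image containers and NIfTI-1 round-trip helpers.

The containers are thin dataclasses over numpy arrays with the grid
metadata (affine, repetition time) needed to keep files self-describing.
Entropy maps carry a quiet-NaN missing marker in the value lattice plus a
parallel uint8 reason lattice, and both are written to disk so the
encoding round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import GridMismatchError

# Reason codes for undefined entropy-map entries.
REASON_DEFINED = 0
REASON_SHORT_SERIES = 1
REASON_ZERO_VARIANCE = 2
REASON_ZERO_MATCHES = 3
REASON_OUT_OF_MASK = 4

REASON_NAMES = {
    REASON_DEFINED: "defined",
    REASON_SHORT_SERIES: "short-series",
    REASON_ZERO_VARIANCE: "zero-variance",
    REASON_ZERO_MATCHES: "zero-matches",
    REASON_OUT_OF_MASK: "out-of-mask",
}


@dataclass
class Bold4D:
    """A 4D BOLD lattice (x, y, z, t) with grid metadata.

    Parameters
    ----------
    data : 4D float array, time last.
    affine : 4x4 voxel-to-world matrix.
    tr : repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tr: float = 0.72

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Bold4D needs a 4D array, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class EntropyMap3D:
    """Per-voxel sample entropy; NaN where undefined, with reason codes."""

    values: np.ndarray
    reasons: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.reasons = np.asarray(self.reasons, dtype=np.uint8)
        if self.values.shape != self.reasons.shape:
            raise GridMismatchError(
                f"value grid {self.values.shape} != reason grid {self.reasons.shape}"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def undefined_counts(self) -> dict[str, int]:
        """Tally of undefined voxels by reason (out-of-mask excluded)."""
        out: dict[str, int] = {}
        for code in (REASON_SHORT_SERIES, REASON_ZERO_VARIANCE, REASON_ZERO_MATCHES):
            out[REASON_NAMES[code]] = int(np.count_nonzero(self.reasons == code))
        return out


def save_bold(vol: Bold4D, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (vol.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_bold(path) -> Bold4D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.72
    return Bold4D(data=data, affine=img.affine, tr=tr)


def save_entropy_map(emap: EntropyMap3D, values_path, reasons_path) -> None:
    vimg = nib.Nifti1Image(emap.values.astype(np.float64), emap.affine)
    nib.save(vimg, str(values_path))
    rimg = nib.Nifti1Image(emap.reasons.astype(np.uint8), emap.affine)
    nib.save(rimg, str(reasons_path))


def load_entropy_map(values_path, reasons_path) -> EntropyMap3D:
    vimg = nib.load(str(values_path))
    rimg = nib.load(str(reasons_path))
    return EntropyMap3D(
        values=np.asanyarray(vimg.dataobj, dtype=np.float64),
        reasons=np.asanyarray(rimg.dataobj, dtype=np.uint8),
        affine=vimg.affine,
    )
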