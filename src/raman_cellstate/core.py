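"""Core domain types and file I/O for single-cell Raman spectroscopy.

The package works on three in-memory containers:

``Spectrum``
    one intensity trace on a shared ascending wavenumber axis (cm^-1);
``HyperStack``
    a hyperspectral image cube indexed (row, col, band) with an optional
    integer label mask marking cell regions (0 = background substrate,
    k > 0 = cell k);
``SpectraDataset``
    a matrix of per-cell spectra (one row per cell) with class labels,
    the form consumed by the PCA / discriminant stages.

File formats are deliberately plain: two-column CSV for single spectra,
HDF5 or NPZ for cubes and datasets, and an NPZ container with embedded
JSON metadata for fitted models.  All writers are deterministic (no
embedded timestamps) so identical inputs produce bit-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

__all__ = [
    "RamanError",
    "FormatError",
    "ValidationError",
    "AxisRangeError",
    "WavenumberAxis",
    "Spectrum",
    "HyperStack",
    "SpectraDataset",
    "crop_axis",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_hyperstack",
    "write_hyperstack",
    "read_dataset",
    "write_dataset",
    "save_arrays",
    "load_arrays",
]

FORMAT_VERSION = 1


class RamanError(Exception):
    """Base class for errors raised by this package."""


class FormatError(RamanError):
    """A file could not be parsed as the expected format."""


class ValidationError(RamanError):
    """An in-memory object violates a structural invariant."""


class AxisRangeError(RamanError):
    """A wavenumber range selects no bands of the axis."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class WavenumberAxis:
    """Strictly ascending, finite wavenumber axis in cm^-1 (length >= 2)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size < 2:
            raise ValidationError("wavenumber axis must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValidationError("wavenumber axis contains non-finite values")
        if not np.all(np.diff(v) > 0):
            raise ValidationError("wavenumber axis must be strictly ascending")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash(self.values.tobytes())

    def range_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of bands in the half-open interval [lo, hi)."""
        if not lo < hi:
            raise ValueError(f"invalid wavenumber range: lo={lo!r} must be < hi={hi!r}")
        return (self.values >= lo) & (self.values < hi)


@dataclass
class Spectrum:
    """One Raman spectrum: intensities (arbitrary counts) on an axis."""

    axis: WavenumberAxis
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=np.float64)
        if y.ndim != 1 or y.size != len(self.axis):
            raise ValidationError(
                f"intensity length {y.size} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValidationError("spectrum intensities contain non-finite values")
        self.intensity = y


@dataclass
class HyperStack:
    """Hyperspectral image cube (row, col, band) with optional label mask.

    Mask semantics: 0 marks background substrate pixels, positive integer
    k marks the pixels of cell k.  Cell viability judgement is upstream of
    this package — cells are whatever the mask contains.
    """

    axis: WavenumberAxis
    cube: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.cube)
        if c.ndim != 3:
            raise ValidationError("cube must be a 3-D (row, col, band) array")
        if c.shape[2] != len(self.axis):
            raise ValidationError(
                f"cube has {c.shape[2]} bands but axis has {len(self.axis)}"
            )
        self.cube = c
        if self.mask is not None:
            m = np.asarray(self.mask)
            if m.shape != c.shape[:2]:
                raise ValidationError(
                    f"mask shape {m.shape} does not match image shape {c.shape[:2]}"
                )
            if not np.issubdtype(m.dtype, np.integer):
                if not np.array_equal(m, m.astype(np.int64)):
                    raise ValidationError("mask labels must be integers")
                m = m.astype(np.int64)
            if m.min() < 0:
                raise ValidationError("mask labels must be non-negative")
            self.mask = m

    @property
    def shape(self) -> tuple:
        return self.cube.shape

    def cell_labels(self) -> np.ndarray:
        """Sorted positive labels present in the mask (empty if no mask)."""
        if self.mask is None:
            return np.array([], dtype=np.int64)
        labs = np.unique(self.mask)
        return labs[labs > 0]

    def crop(self, lo: float, hi: float) -> "HyperStack":
        """Restrict to bands in [lo, hi); errors if the selection is empty."""
        sel = self.axis.range_mask(lo, hi)
        if not sel.any():
            raise AxisRangeError(f"range [{lo}, {hi}) selects no bands")
        return HyperStack(
            axis=WavenumberAxis(self.axis.values[sel]),
            cube=self.cube[:, :, sel],
            mask=self.mask,
        )


@dataclass
class SpectraDataset:
    """Per-cell spectra matrix with class labels and provenance ids.

    Rows produced by the preprocessing pipeline are SNV-standardized
    (mean 0, population sd 1); the container itself only enforces shape
    consistency so that intermediate (raw) matrices can be carried too.
    """

    X: np.ndarray
    labels: np.ndarray
    cell_ids: list
    axis: WavenumberAxis

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D (n_cells, n_bands) matrix")
        if X.shape[1] != len(self.axis):
            raise ValidationError(
                f"X has {X.shape[1]} bands but axis has {len(self.axis)}"
            )
        labels = np.asarray(self.labels)
        if labels.shape != (X.shape[0],):
            raise ValidationError("labels must have one entry per row of X")
        if len(self.cell_ids) != X.shape[0]:
            raise ValidationError("cell_ids must have one entry per row of X")
        self.X = X
        self.labels = labels

    def __len__(self) -> int:
        return self.X.shape[0]

    def class_names(self) -> list:
        """Distinct labels in order of first appearance."""
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return list(seen)


def crop_axis(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Restrict a spectrum to bands in the half-open interval [lo, hi).

    The half-open convention makes adjacent crops tile without overlap.
    Raises :class:`AxisRangeError` if no band falls in the range.
    """
    sel = s.axis.range_mask(lo, hi)
    if not sel.any():
        raise AxisRangeError(f"range [{lo}, {hi}) selects no bands of the axis")
    meta = dict(s.meta)
    meta["crop_cm1"] = (float(lo), float(hi))
    return Spectrum(
        axis=WavenumberAxis(s.axis.values[sel]),
        intensity=s.intensity[sel],
        meta=meta,
    )


# ---------------------------------------------------------------------------
# spectrum CSV I/O
# ---------------------------------------------------------------------------


def read_spectrum_csv(path) -> Spectrum:
    """Read a two-column delimited text file (wavenumber_cm1, intensity).

    A single non-numeric header line is tolerated.  Rows may appear in any
    wavenumber order; the result is sorted ascending with intensities
    co-permuted.  Raises :class:`FormatError` naming the offending line for
    non-numeric data rows, or if fewer than two data rows are present.
    """
    path = Path(path)
    wn: list = []
    inten: list = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.replace(";", ",").replace("\t", ",").split(",")]
            parts = [p for p in parts if p]
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                w, y = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 and not wn:
                    continue  # header
                raise FormatError(f"{path}:{lineno}: non-numeric row {line!r}") from None
            wn.append(w)
            inten.append(y)
    if len(wn) < 2:
        raise FormatError(f"{path}: needs at least 2 data rows, found {len(wn)}")
    w = np.asarray(wn)
    y = np.asarray(inten)
    order = np.argsort(w, kind="stable")
    return Spectrum(
        axis=WavenumberAxis(w[order]),
        intensity=y[order],
        meta={"source": str(path)},
    )


def write_spectrum_csv(path, s: Spectrum) -> None:
    """Write ``wavenumber_cm1,intensity`` rows at full float precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("wavenumber_cm1,intensity\n")
        for w, y in zip(s.axis.values, s.intensity):
            fh.write(f"{w:.17g},{y:.17g}\n")


# ---------------------------------------------------------------------------
# hyperstack I/O (HDF5 / NPZ)
# ---------------------------------------------------------------------------


def write_hyperstack(path, stack: HyperStack) -> None:
    """Write a stack to ``.h5``/``.hdf5`` (datasets /cube, /axis, /mask) or ``.npz``.

    Array dtypes are preserved so that a round trip is lossless.  HDF5
    datasets are written with ``track_times=False`` for byte-reproducible
    output.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w", track_order=False) as f:
            f.create_dataset("cube", data=stack.cube, track_times=False)
            f.create_dataset("axis", data=stack.axis.values, track_times=False)
            if stack.mask is not None:
                f.create_dataset(
                    "mask", data=stack.mask.astype(np.uint16), track_times=False
                )
    elif path.suffix.lower() == ".npz":
        payload = {"cube": stack.cube, "axis": stack.axis.values}
        if stack.mask is not None:
            payload["mask"] = stack.mask.astype(np.uint16)
        np.savez(path, **payload)
    else:
        raise FormatError(f"unsupported hyperstack extension: {path.suffix!r}")


def read_hyperstack(path) -> HyperStack:
    """Read a stack written by :func:`write_hyperstack` (HDF5 or NPZ)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "axis" not in f:
                raise FormatError(f"{path}: missing required /axis dataset")
            if "cube" not in f:
                raise FormatError(f"{path}: missing required /cube dataset")
            axis = np.asarray(f["axis"])
            cube = np.asarray(f["cube"])
            mask = np.asarray(f["mask"]) if "mask" in f else None
    elif path.suffix.lower() == ".npz":
        with np.load(path) as z:
            if "axis" not in z.files:
                raise FormatError(f"{path}: missing required 'axis' array")
            if "cube" not in z.files:
                raise FormatError(f"{path}: missing required 'cube' array")
            axis = z["axis"]
            cube = z["cube"]
            mask = z["mask"] if "mask" in z.files else None
    else:
        raise FormatError(f"unsupported hyperstack extension: {path.suffix!r}")
    return HyperStack(axis=WavenumberAxis(axis), cube=cube, mask=mask)


# ---------------------------------------------------------------------------
# dataset I/O (HDF5)
# ---------------------------------------------------------------------------


def write_dataset(path, ds: SpectraDataset) -> None:
    """Write a SpectraDataset to HDF5 (/X, /axis, /labels, /cell_ids)."""
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w", track_order=False) as f:
        f.create_dataset("X", data=ds.X, track_times=False)
        f.create_dataset("axis", data=ds.axis.values, track_times=False)
        f.create_dataset(
            "labels",
            data=np.asarray([str(v) for v in ds.labels], dtype=object),
            dtype=str_dt,
            track_times=False,
        )
        f.create_dataset(
            "cell_ids",
            data=np.asarray([str(v) for v in ds.cell_ids], dtype=object),
            dtype=str_dt,
            track_times=False,
        )


def read_dataset(path) -> SpectraDataset:
    with h5py.File(path, "r") as f:
        for key in ("X", "axis", "labels", "cell_ids"):
            if key not in f:
                raise FormatError(f"{path}: missing required /{key} dataset")
        X = np.asarray(f["X"])
        axis = np.asarray(f["axis"])
        labels = np.asarray([v.decode() if isinstance(v, bytes) else str(v) for v in f["labels"]])
        cell_ids = [v.decode() if isinstance(v, bytes) else str(v) for v in f["cell_ids"]]
    return SpectraDataset(X=X, labels=labels, cell_ids=cell_ids, axis=WavenumberAxis(axis))


# ---------------------------------------------------------------------------
# model container (NPZ + embedded JSON metadata)
# ---------------------------------------------------------------------------


def save_arrays(path, meta: dict, arrays: dict) -> None:
    """Persist a model artifact: named arrays plus a JSON metadata block.

    The container is a single NPZ file with a ``format_version`` field in
    the metadata; numpy writes zip members with a fixed timestamp, so the
    output is byte-reproducible.
    """
    meta = dict(meta)
    meta.setdefault("format_version", FORMAT_VERSION)
    payload = {"__meta_json__": np.array(json.dumps(meta, sort_keys=True))}
    for k, v in arrays.items():
        if k.startswith("__"):
            raise ValueError(f"reserved array name: {k!r}")
        payload[k] = np.asarray(v)
    np.savez(path, **payload)


def load_arrays(path):
    """Load (meta, arrays) from a container written by :func:`save_arrays`."""
    with np.load(path, allow_pickle=False) as z:
        if "__meta_json__" not in z.files:
            raise FormatError(f"{path}: not a model container (missing metadata)")
        meta = json.loads(str(z["__meta_json__"]))
        arrays = {k: z[k] for k in z.files if k != "__meta_json__"}
    return meta, arrays
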