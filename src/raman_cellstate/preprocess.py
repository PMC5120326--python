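"""Spectral preprocessing: background subtraction, cell averaging, SNV.

The pipeline mirrors standard single-cell Raman practice:

1. estimate a background spectrum per image as the mean over the 25
   background pixels farthest from any cell region (silica substrate,
   ambient water and detector readout) and subtract it from every pixel;
2. average the pixels of each cell region into one spectrum per cell;
3. standardize every cell spectrum to zero mean and unit standard
   deviation (standard normal variate, SNV).

``build_dataset`` composes the three stages, restricted to a wavenumber
crop (fingerprint region 600-1800 cm^-1 by default), into the
:class:`~raman_cellstate.core.SpectraDataset` the multivariate stages
consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    HyperStack,
    SpectraDataset,
    Spectrum,
    ValidationError,
    WavenumberAxis,
    crop_axis,
)

__all__ = [
    "BackgroundEstimate",
    "estimate_background",
    "subtract_background",
    "average_cell_spectrum",
    "standardize_snv",
    "snv_rows",
    "build_dataset",
]

logger = logging.getLogger(__name__)

#: default fingerprint-region crop (cm^-1, half-open)
DEFAULT_CROP = (600.0, 1800.0)


@dataclass
class BackgroundEstimate:
    """Mean background spectrum and the pixels that produced it."""

    spectrum: Spectrum
    pixel_coords: List[Tuple[int, int]]
    n_pixels: int


def estimate_background(stack: HyperStack, n_pixels: int = 25) -> BackgroundEstimate:
    """Mean spectrum of the ``n_pixels`` background pixels farthest from cells.

    "Far from the cell regions" is made precise as the zero-labeled pixels
    with the greatest Euclidean distance to the nearest nonzero mask pixel
    (distance transform), ties broken in row-major order.  If fewer than
    ``n_pixels`` background pixels exist, all are used and a warning is
    logged.
    """
    if stack.mask is None:
        raise ValidationError("background estimation requires a label mask")
    bg = stack.mask == 0
    if not bg.any():
        raise ValidationError("mask has no background (zero-labeled) pixels")
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")

    if (stack.mask > 0).any():
        # distance from each background pixel to the nearest cell pixel
        dist = ndimage.distance_transform_edt(bg)
    else:
        dist = np.zeros(bg.shape)  # no cells: all background pixels tie

    flat_idx = np.flatnonzero(bg.ravel())
    order = np.argsort(-dist.ravel()[flat_idx], kind="stable")  # row-major ties
    if flat_idx.size < n_pixels:
        logger.warning(
            "only %d background pixels available (requested %d); using all",
            flat_idx.size,
            n_pixels,
        )
    chosen = flat_idx[order[:n_pixels]]
    rows, cols = np.unravel_index(chosen, bg.shape)
    spectra = stack.cube[rows, cols, :]
    mean = spectra.mean(axis=0)
    coords = list(zip(rows.tolist(), cols.tolist()))
    return BackgroundEstimate(
        spectrum=Spectrum(
            axis=stack.axis,
            intensity=mean,
            meta={"role": "background", "n_pixels": len(coords)},
        ),
        pixel_coords=coords,
        n_pixels=len(coords),
    )


def subtract_background(stack: HyperStack, bg: BackgroundEstimate) -> HyperStack:
    """Subtract the background spectrum from every pixel of the stack."""
    if bg.spectrum.axis != stack.axis:
        raise ValidationError("background axis does not match stack axis")
    return HyperStack(
        axis=stack.axis,
        cube=stack.cube - bg.spectrum.intensity,
        mask=stack.mask,
    )


def average_cell_spectrum(stack: HyperStack, cell_label: int) -> Spectrum:
    """Unweighted per-band mean over the pixels carrying ``cell_label``."""
    if stack.mask is None:
        raise ValidationError("cell averaging requires a label mask")
    if cell_label <= 0:
        raise ValueError("cell_label must be a positive integer")
    sel = stack.mask == cell_label
    n = int(sel.sum())
    if n == 0:
        raise ValidationError(f"cell label {cell_label} not present in mask")
    mean = stack.cube[sel].mean(axis=0)
    return Spectrum(
        axis=stack.axis,
        intensity=mean,
        meta={"cell_label": int(cell_label), "n_pixels": n},
    )


def standardize_snv(s: Spectrum, cell_id: Optional[str] = None) -> Spectrum:
    """Standard normal variate: subtract the spectrum mean, divide by its
    population (ddof=0) standard deviation.

    Raises :class:`ValidationError` (naming the cell when known) for
    constant spectra.
    """
    if len(s.axis) < 2:
        raise ValidationError("SNV needs at least 2 bands")
    mu = s.intensity.mean()
    sd = s.intensity.std(ddof=0)
    if sd == 0.0:
        who = cell_id or s.meta.get("cell_label", "<unknown cell>")
        raise ValidationError(f"zero-variance spectrum (cell {who}); cannot standardize")
    meta = dict(s.meta)
    meta["snv"] = True
    return Spectrum(axis=s.axis, intensity=(s.intensity - mu) / sd, meta=meta)


def snv_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise SNV for a matrix of spectra; rejects zero-variance rows."""
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0.0)
    if bad.size:
        raise ValidationError(f"zero-variance spectra at rows {bad.tolist()}")
    return (X - mu) / sd


def build_dataset(
    stacks: Sequence[HyperStack],
    labels: Sequence[Mapping[int, str]],
    crop: Tuple[float, float] = DEFAULT_CROP,
    n_background: int = 25,
) -> SpectraDataset:
    """Run the full preprocessing chain over a list of labeled stacks.

    ``labels[i]`` maps each cell label in ``stacks[i]``'s mask to a class
    name.  Rows are emitted in deterministic order: stack order, then
    ascending cell label; each row is
    ``snv(crop(average(subtract_background(stack))))``.
    """
    if len(stacks) != len(labels):
        raise ValidationError("need one label mapping per stack")
    if not stacks:
        raise ValidationError("no stacks given")
    axis0 = stacks[0].axis
    for i, st in enumerate(stacks):
        if st.axis != axis0:
            raise ValidationError(f"stack {i} axis differs from stack 0 (no resampling in v1)")

    rows, row_labels, cell_ids = [], [], []
    out_axis: Optional[WavenumberAxis] = None
    for i, (st, lab_map) in enumerate(zip(stacks, labels)):
        bg = estimate_background(st, n_pixels=n_background)
        sub = subtract_background(st, bg)
        for cell in st.cell_labels():
            cell = int(cell)
            cid = f"stack{i}:cell{cell}"
            if cell not in lab_map:
                raise ValidationError(f"no class label for {cid}")
            try:
                s = average_cell_spectrum(sub, cell)
                s = crop_axis(s, *crop)
                s = standardize_snv(s, cell_id=cid)
            except ValidationError as e:
                raise ValidationError(f"{cid}: {e}") from e
            if out_axis is None:
                out_axis = s.axis
            rows.append(s.intensity)
            row_labels.append(str(lab_map[cell]))
            cell_ids.append(cid)

    if not rows:
        raise ValidationError("no cells found across the given stacks")
    return SpectraDataset(
        X=np.vstack(rows),
        labels=np.asarray(row_labels),
        cell_ids=cell_ids,
        axis=out_axis,
    )
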