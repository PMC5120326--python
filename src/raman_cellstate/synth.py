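"""Synthetic single-cell Raman data generator.

Emulates the statistical structure the analysis pipeline assumes:

* class-specific Raman bands as Lorentzian lines — a "naive" and an
  "activated" lymphocyte profile sharing common peaks (753 cm^-1
  cytochrome c, 1004 phenylalanine, 1450 CH2 deformation, 1660 amide I,
  2852 lipid CH2, 2956 protein CH3) and differing in amplitude at the
  discriminating bands 1089, 1332, 1375 and 1483 cm^-1 and at 753 cm^-1
  (cytochrome c more abundant in activated cells);
* a smooth low-order polynomial baseline and a silica-substrate profile
  for non-cell pixels;
* a peak-free silent region 1800-2700 cm^-1;
* i.i.d. per-band Gaussian noise;
* disk-shaped cells on a substrate for image simulation;
* convex naive->activated mixtures for activation time courses.

All generators are pure functions of (specification, seed): calling twice
with the same arguments yields bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from numpy.polynomial import polynomial as P

from .core import HyperStack, Spectrum, ValidationError, WavenumberAxis

__all__ = [
    "PeakSpec",
    "ClassProfile",
    "CellSpec",
    "SceneSpec",
    "default_axis",
    "default_profiles",
    "default_substrate",
    "scaled_profiles",
    "profile_mean",
    "simulate_spectrum",
    "simulate_dataset",
    "simulate_hyperstack",
    "simulate_timecourse",
    "SILENT_REGION",
]

#: wavenumber range (cm^-1, half-open) kept free of Raman bands
SILENT_REGION = (1800.0, 2700.0)


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian Raman band: center (cm^-1), HWHM width (cm^-1), amplitude."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValidationError("peak width must be > 0")
        if self.amplitude < 0:
            raise ValidationError("peak amplitude must be >= 0")


@dataclass(frozen=True)
class ClassProfile:
    """Generative profile of one cell class (or of the substrate).

    ``baseline_coeffs`` are ascending polynomial coefficients evaluated on
    the normalized axis coordinate x = (nu - nu_min) / (nu_max - nu_min),
    so baselines stay gentle regardless of the axis range.  ``noise_sd``
    is the per-band additive Gaussian standard deviation.
    """

    name: str
    peaks: Tuple[PeakSpec, ...]
    baseline_coeffs: Tuple[float, ...] = (0.0,)
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if len(self.peaks) < 1:
            raise ValidationError("a class profile needs at least one peak")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        object.__setattr__(self, "peaks", tuple(self.peaks))
        object.__setattr__(self, "baseline_coeffs", tuple(self.baseline_coeffs))


@dataclass(frozen=True)
class CellSpec:
    """A disk-shaped cell: center (row, col), radius in pixels, and state.

    ``state`` is either a class name ("naive"/"activated") or a mixing
    fraction alpha in [0, 1] toward the activated class mean.
    """

    center: Tuple[float, float]
    radius: float
    state: Union[str, float]

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError("cell radius must be > 0")
        if not isinstance(self.state, str):
            a = float(self.state)
            if not 0.0 <= a <= 1.0:
                raise ValidationError(f"mixture fraction must be in [0, 1], got {a}")


@dataclass(frozen=True)
class SceneSpec:
    """Layout of a simulated Raman image: shape, cells, and RNG seed."""

    image_shape: Tuple[int, int]
    cells: Tuple[CellSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        rows, cols = self.image_shape
        for c in self.cells:
            r0, c0 = c.center
            if not (0 <= r0 < rows and 0 <= c0 < cols):
                raise ValidationError(f"cell center {c.center} outside image {self.image_shape}")


def default_axis() -> WavenumberAxis:
    """Default acquisition axis: 600-3100 cm^-1 at 2 cm^-1 spacing.

    The silent region is retained in the axis (peak-free), matching the
    display convention of full-range Raman spectra.
    """
    return WavenumberAxis(np.arange(600.0, 3100.0 + 1.0, 2.0))


# Band table shared by the two cell classes.  Amplitudes are in arbitrary
# units relative to the phenylalanine ring-breathing mode at 1004 cm^-1.
# The discriminating bands (753, 1089, 1332, 1375, 1483 cm^-1) carry the
# naive/activated contrast; all other bands are common.
_BANDS = [
    # (center, hwhm, naive_amp, activated_amp)
    (753.0, 8.0, 0.45, 0.65),   # cytochrome c (higher when activated)
    (1004.0, 6.0, 1.00, 1.00),  # phenylalanine
    (1089.0, 8.0, 0.55, 0.67),  # PO2- / C-C stretch
    (1332.0, 9.0, 0.70, 0.85),  # CH deformation / adenine
    (1375.0, 8.0, 0.45, 0.57),  # thymine/adenine ring
    (1450.0, 9.0, 0.85, 0.85),  # CH2 deformation
    (1483.0, 8.0, 0.50, 0.64),  # guanine/adenine
    (1660.0, 10.0, 0.90, 0.90), # amide I
    (2852.0, 10.0, 1.05, 1.05), # lipid CH2 stretch
    (2956.0, 11.0, 1.25, 1.25), # protein CH3 stretch
]

_CONTRAST_CENTERS = (753.0, 1089.0, 1332.0, 1375.0, 1483.0)


def default_profiles(noise_sd: float = 0.05) -> Tuple[ClassProfile, ClassProfile]:
    """Return the ("naive", "activated") class profiles.

    Both share common bands; they differ at 1089, 1332, 1375, 1483 cm^-1
    and in the 753 cm^-1 cytochrome c amplitude (activated higher).  No
    band lies in the silent region.
    """
    naive = ClassProfile(
        name="naive",
        peaks=tuple(PeakSpec(c, w, a_n) for c, w, a_n, _ in _BANDS),
        baseline_coeffs=(0.25, -0.10, 0.05),
        noise_sd=noise_sd,
    )
    activated = ClassProfile(
        name="activated",
        peaks=tuple(PeakSpec(c, w, a_a) for c, w, _, a_a in _BANDS),
        baseline_coeffs=(0.25, -0.10, 0.05),
        noise_sd=noise_sd,
    )
    return naive, activated


def default_substrate(noise_sd: float = 0.05) -> ClassProfile:
    """Silica-substrate profile for non-cell pixels: broad glass bands and
    a weak high-wavenumber water shoulder over a flat offset."""
    return ClassProfile(
        name="substrate",
        peaks=(
            PeakSpec(800.0, 60.0, 0.50),
            PeakSpec(1060.0, 50.0, 0.35),
            PeakSpec(3050.0, 120.0, 0.25),
        ),
        baseline_coeffs=(0.60, -0.20),
        noise_sd=noise_sd,
    )


def scaled_profiles(
    naive: ClassProfile, activated: ClassProfile, separation: float
) -> Tuple[ClassProfile, ClassProfile]:
    """Scale the between-class amplitude differences by ``separation``.

    Each matched peak pair (a_n, a_a) is replaced by m -/+ separation*(m - a)
    around the pair mean m, so separation=1 reproduces the inputs and
    separation=0 makes the two classes identically distributed.  Profiles
    must carry the same ordered peak centers.
    """
    if len(naive.peaks) != len(activated.peaks) or any(
        p.center != q.center or p.width != q.width
        for p, q in zip(naive.peaks, activated.peaks)
    ):
        raise ValidationError("profiles must share the same ordered peak centers/widths")
    new_n, new_a = [], []
    for p, q in zip(naive.peaks, activated.peaks):
        m = 0.5 * (p.amplitude + q.amplitude)
        new_n.append(replace(p, amplitude=m + separation * (p.amplitude - m)))
        new_a.append(replace(q, amplitude=m + separation * (q.amplitude - m)))
    return (
        replace(naive, peaks=tuple(new_n)),
        replace(activated, peaks=tuple(new_a)),
    )


def _lorentzian(nu: np.ndarray, peak: PeakSpec) -> np.ndarray:
    w2 = peak.width**2
    return peak.amplitude * w2 / ((nu - peak.center) ** 2 + w2)


def profile_mean(profile: ClassProfile, axis: WavenumberAxis) -> np.ndarray:
    """Noise-free expected spectrum: sum of Lorentzians plus baseline."""
    nu = axis.values
    x = (nu - nu[0]) / (nu[-1] - nu[0])
    y = P.polyval(x, profile.baseline_coeffs)
    y = np.broadcast_to(y, nu.shape).astype(np.float64).copy()
    for pk in profile.peaks:
        y += _lorentzian(nu, pk)
    return y


def simulate_spectrum(
    profile: ClassProfile,
    axis: Optional[WavenumberAxis] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Spectrum:
    """Draw one noisy spectrum from a class profile.

    Noise is i.i.d. Gaussian with sd ``profile.noise_sd`` per band.  Pass
    either ``seed`` (deterministic) or an existing ``rng`` stream.
    """
    axis = axis if axis is not None else default_axis()
    if rng is None:
        rng = np.random.default_rng(seed)
    y = profile_mean(profile, axis)
    if profile.noise_sd > 0:
        y = y + rng.normal(0.0, profile.noise_sd, size=y.shape)
    return Spectrum(axis=axis, intensity=y, meta={"profile": profile.name, "seed": seed})


def simulate_dataset(
    profiles: Optional[Tuple[ClassProfile, ClassProfile]] = None,
    n_per_class: Tuple[int, int] = (96, 60),
    separation: float = 1.0,
    axis: Optional[WavenumberAxis] = None,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate raw (unstandardized) per-cell spectra for two classes.

    Returns ``(X, labels)`` with one spectrum per row, ready for the
    preprocessing module.  Default class sizes 96 and 60 mirror the
    supervisor-data scale of a two-population single-cell experiment.
    ``separation`` scales the between-class amplitude contrast; 0 makes
    the classes identically distributed.
    """
    axis = axis if axis is not None else default_axis()
    if profiles is None:
        profiles = default_profiles()
    if min(n_per_class) < 1:
        raise ValidationError("n_per_class entries must be >= 1")
    p1, p2 = scaled_profiles(profiles[0], profiles[1], separation)
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for prof, n in ((p1, n_per_class[0]), (p2, n_per_class[1])):
        mean = profile_mean(prof, axis)
        noise = rng.normal(0.0, prof.noise_sd, size=(n, len(axis)))
        rows.append(mean[None, :] + noise)
        labels.extend([prof.name] * n)
    return np.vstack(rows), np.asarray(labels)


def simulate_hyperstack(
    scene: SceneSpec,
    axis: Optional[WavenumberAxis] = None,
    profiles: Optional[Tuple[ClassProfile, ClassProfile]] = None,
    substrate: Optional[ClassProfile] = None,
) -> HyperStack:
    """Render a scene into a hyperspectral stack with a cell label mask.

    Cells are disjoint disks; each cell pixel's expected spectrum is the
    substrate mean plus its class mean (or the alpha-mixture of the two
    class means, for fractional states) — the substrate signal reaches
    the detector through the focal volume everywhere, which is what makes
    per-image background subtraction meaningful.  Non-cell pixels draw
    from the substrate profile alone.  Per-pixel noise is i.i.d.
    Gaussian.  Mask labels cells 1..N in the listed order.
    """
    axis = axis if axis is not None else default_axis()
    if profiles is None:
        profiles = default_profiles()
    if substrate is None:
        substrate = default_substrate()
    naive, activated = profiles

    for i, a in enumerate(scene.cells):
        for b in scene.cells[i + 1 :]:
            d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d <= a.radius + b.radius:
                raise ValidationError(
                    f"cells at {a.center} and {b.center} overlap (centers {d:.2f} px apart)"
                )

    rows, cols = scene.image_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    mask = np.zeros((rows, cols), dtype=np.int64)
    for k, cell in enumerate(scene.cells, start=1):
        inside = (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2 <= cell.radius**2
        mask[inside] = k

    mean_naive = profile_mean(naive, axis)
    mean_act = profile_mean(activated, axis)

    def cell_mean_and_sd(state) -> Tuple[np.ndarray, float]:
        if isinstance(state, str):
            if state == naive.name:
                return mean_naive, naive.noise_sd
            if state == activated.name:
                return mean_act, activated.noise_sd
            raise ValidationError(f"unknown cell state {state!r}")
        alpha = float(state)
        return (1 - alpha) * mean_naive + alpha * mean_act, naive.noise_sd

    B = len(axis)
    mean_sub = profile_mean(substrate, axis)
    mean_cube = np.empty((rows, cols, B))
    sd_map = np.empty((rows, cols))
    mean_cube[:] = mean_sub
    sd_map[:] = substrate.noise_sd
    for k, cell in enumerate(scene.cells, start=1):
        mu, sd = cell_mean_and_sd(cell.state)
        sel = mask == k
        mean_cube[sel] = mean_sub + mu
        sd_map[sel] = sd

    rng = np.random.default_rng(scene.seed)
    cube = mean_cube + rng.standard_normal((rows, cols, B)) * sd_map[:, :, None]
    return HyperStack(axis=axis, cube=cube, mask=mask)


def simulate_timecourse(
    profiles: Optional[Tuple[ClassProfile, ClassProfile]] = None,
    alphas: Optional[Mapping[float, float]] = None,
    n_per_stage: int = 40,
    axis: Optional[WavenumberAxis] = None,
    seed: int = 0,
) -> Dict[float, np.ndarray]:
    """Simulate raw spectra for activation stages as convex mixtures.

    Each stage's expected spectrum is (1-alpha)*naive_mean + alpha*activated_mean,
    with the per-spectrum noise of :func:`simulate_spectrum`.  The default
    stage map places timepoints at 0, 2, 6, 12 and 24 h with alpha = t/24
    (linear progression toward the fully activated state).
    Returns ``{timepoint_h: X_raw (n_per_stage x n_bands)}``.
    """
    axis = axis if axis is not None else default_axis()
    if profiles is None:
        profiles = default_profiles()
    if alphas is None:
        alphas = {t: t / 24.0 for t in (0.0, 2.0, 6.0, 12.0, 24.0)}
    for t, a in alphas.items():
        if not 0.0 <= float(a) <= 1.0:
            raise ValidationError(f"stage {t}: mixture fraction {a} outside [0, 1]")
    naive, activated = profiles
    mean_n = profile_mean(naive, axis)
    mean_a = profile_mean(activated, axis)
    rng = np.random.default_rng(seed)
    out: Dict[float, np.ndarray] = {}
    for t in sorted(alphas):
        a = float(alphas[t])
        mu = (1 - a) * mean_n + a * mean_a
        noise = rng.normal(0.0, naive.noise_sd, size=(n_per_stage, len(axis)))
        out[float(t)] = mu[None, :] + noise
    return out
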