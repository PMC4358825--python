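"""Synthetic fluorine-19 (and companion proton) phantom images with exact ground truth.

Biological tissue carries no detectable ¹⁹F, so a fluorine image of a labeled-cell
phantom contains only the compartments we place in it: cell pellets, a reference
tube of known ¹⁹F concentration, and optionally an off-resonance compartment that
stands in for isoflurane accumulating in fat.  The signal model is deliberately
simple and is the simulator's contract: the noiseless voxel value is strictly
proportional to the number of ¹⁹F spins in the voxel, scaled by the RF excitation
response at that compartment's chemical-shift offset.  Proportionality with a
single gain shared between pellets and reference tube is exactly the assumption
that makes reference-tube normalization valid, so quantification against these
phantoms is an exact oracle in the noise-free limit.

Noise is Rician, the distribution of a magnitude reconstruction with independent
complex Gaussian channel noise; signal-free regions are Rayleigh.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "VoxelGrid",
    "PelletSpec",
    "ReferenceTubeSpec",
    "OffResonanceCompartment",
    "ExcitationPulse",
    "AcquisitionParams",
    "Image3D",
    "PhantomSpec",
    "excitation_response",
    "voxelize_sphere",
    "voxelize_tube",
    "generate_fluorine_image",
    "generate_proton_image",
    "build_pellet_series",
    "PAPER_PELLET_COUNTS",
    "LOADING_RANGE_SPINS_PER_CELL",
    "DEFAULT_C_REF",
]

#: Pellet sizes of the in-vitro validation series (cells per pellet).
PAPER_PELLET_COUNTS: tuple[int, ...] = (
    200_000, 400_000, 600_000, 800_000, 1_000_000, 2_000_000,
)

#: Observed range of cellular loading, ¹⁹F atoms per cell.
LOADING_RANGE_SPINS_PER_CELL: tuple[float, float] = (8.2e10, 2.4e11)

#: Reference tube concentration used by the quantification chain, spins/μL.
DEFAULT_C_REF: float = 2.6e16

#: Time-bandwidth product of the excitation-pulse model (kHz·ms); fixed so the
#: 1.32 ms plain sinc maps to ≈1.5 kHz and the 0.66 ms filtered sinc to ≈3 kHz.
TIME_BANDWIDTH_PRODUCT: float = 2.0


class GeometryError(ValueError):
    """A compartment does not fit the grid, is empty, or overlaps another."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel grid with physical spacing in mm.

    Voxel indices are 0-based; the world position of a voxel center is
    ``(index + 0.5) * voxel_size_mm``.  The default spacing matches the
    fluorine acquisition resolution of 1×1×2 mm³.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))

    @property
    def voxel_volume_ul(self) -> float:
        """Voxel volume in μL (1 mm³ = 1 μL, so this is just the product of spacings)."""
        return float(np.prod(self.voxel_size_mm))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(d * s for d, s in zip(self.dims, self.voxel_size_mm))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world coordinates (mm) of voxel centers along each axis."""
        cx = (np.arange(self.dims[0]) + 0.5) * self.voxel_size_mm[0]
        cy = (np.arange(self.dims[1]) + 0.5) * self.voxel_size_mm[1]
        cz = (np.arange(self.dims[2]) + 0.5) * self.voxel_size_mm[2]
        return cx[:, None, None], cy[None, :, None], cz[None, None, :]


@dataclass(frozen=True)
class PelletSpec:
    """Spherical cell pellet: ``n_cells`` labeled cells at ``spins_per_cell`` ¹⁹F each."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    n_cells: int
    spins_per_cell: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("pellet radius must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if self.spins_per_cell <= 0:
            raise ValueError("spins_per_cell must be positive")

    @property
    def total_spins(self) -> float:
        return float(self.n_cells) * self.spins_per_cell


@dataclass(frozen=True)
class ReferenceTubeSpec:
    """Cylindrical reference tube (axis along z) of known spin concentration."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    length_mm: float
    concentration_spins_per_ul: float = DEFAULT_C_REF

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.length_mm <= 0:
            raise ValueError("tube radius and length must be positive")
        if self.concentration_spins_per_ul <= 0:
            raise ValueError("reference concentration must be positive")


@dataclass(frozen=True)
class OffResonanceCompartment:
    """Spherical ¹⁹F compartment at a chemical-shift offset (isoflurane stand-in).

    Only excited to the extent the RF pulse's frequency response covers
    ``offset_khz``; the default offset of 1.2 kHz is suppressed by the narrow
    ≈1.5 kHz pulse but excited by the broad ≈3 kHz pulse.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    offset_khz: float = 1.2
    spin_density_spins_per_ul: float = 1.0e16

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("compartment radius must be positive")
        if not math.isfinite(self.offset_khz):
            raise ValueError("offset_khz must be finite")
        if self.spin_density_spins_per_ul <= 0:
            raise ValueError("spin density must be positive")


@dataclass(frozen=True)
class ExcitationPulse:
    """RF excitation pulse, characterized by shape and time-domain FWHM.

    The frequency-response bandwidth follows the fixed time-bandwidth product
    B·T = 2.0 kHz·ms: a long pulse in time is narrow in frequency.  A plain
    (non-filtered) sinc yields an approximately rectangular excitation band;
    Gaussian-filtering the sinc makes the time envelope shorter and the
    frequency response Gaussian and broad.
    """

    shape: str = "plain_sinc"
    time_fwhm_ms: float = 1.32

    def __post_init__(self) -> None:
        if self.shape not in ("plain_sinc", "filtered_sinc"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")
        if self.time_fwhm_ms <= 0:
            raise ValueError("time_fwhm_ms must be positive")

    @property
    def bandwidth_khz(self) -> float:
        return TIME_BANDWIDTH_PRODUCT / self.time_fwhm_ms


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings: noise level, gain, seed, pulse, plus recorded metadata.

    ``gain`` converts spins per voxel to (arbitrary) signal units; ``noise_sd``
    is the per-channel complex Gaussian SD in the same units.  TR/TE/flip/averages
    are recorded for provenance only and do not enter the signal model.
    """

    noise_sd: float = 0.0
    gain: float = 1e-12
    seed: int = 0
    pulse: ExcitationPulse = field(default_factory=ExcitationPulse)
    tr_ms: float = 3.5
    te_ms: float = 1.8
    flip_deg: float = 70.0
    averages: int = 250

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass(frozen=True)
class Image3D:
    """A nonnegative 3D magnitude image on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != tuple(self.grid.dims):
            raise ValueError(
                f"values shape {values.shape} does not match grid dims {self.grid.dims}"
            )
        if np.any(values < 0):
            raise ValueError("magnitude image must be nonnegative")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth scene: pellets + optional reference tube + optional artifact."""

    grid: VoxelGrid
    pellets: tuple[PelletSpec, ...] = ()
    reference: ReferenceTubeSpec | None = None
    off_resonance: OffResonanceCompartment | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pellets", tuple(self.pellets))


def excitation_response(pulse: ExcitationPulse, offset_khz: float) -> float:
    """Normalized magnitude of the pulse's frequency response at an offset.

    ``plain_sinc`` approximates a rectangular passband of full width equal to the
    bandwidth, realized as a sixth-order supergaussian so the roll-off is smooth
    and the half-response point sits exactly at ±bandwidth/2.  ``filtered_sinc``
    is a Gaussian response whose FWHM equals the bandwidth.  The response at
    zero offset is exactly 1.
    """
    b = pulse.bandwidth_khz
    x = abs(float(offset_khz)) / b
    if pulse.shape == "filtered_sinc":
        # Gaussian with FWHM = b: exp(-4 ln2 (f/b)^2)
        return float(math.exp(-4.0 * math.log(2.0) * x * x))
    # plain_sinc: supergaussian "rectangle with smooth roll-off", half power at b/2
    return float(math.exp(-math.log(2.0) * (2.0 * x) ** 6))


def voxelize_sphere(
    grid: VoxelGrid,
    center_mm: tuple[float, float, float],
    radius_mm: float,
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within ``radius_mm`` of the center.

    Raises :class:`GeometryError` if no voxel center falls inside (geometry
    outside the grid, or radius below the grid pitch at an off-center position).
    """
    cx, cy, cz = grid.voxel_centers()
    d2 = (cx - center_mm[0]) ** 2 + (cy - center_mm[1]) ** 2 + (cz - center_mm[2]) ** 2
    mask = d2 <= float(radius_mm) ** 2
    if not mask.any():
        raise GeometryError(
            f"sphere at {center_mm} r={radius_mm} mm contains no voxel centers"
        )
    return mask


def voxelize_tube(grid: VoxelGrid, tube: ReferenceTubeSpec) -> np.ndarray:
    """Boolean mask of a z-axis cylinder (center-inclusion, like the sphere)."""
    cx, cy, cz = grid.voxel_centers()
    radial = (cx - tube.center_mm[0]) ** 2 + (cy - tube.center_mm[1]) ** 2
    axial = np.abs(cz - tube.center_mm[2]) <= tube.length_mm / 2.0
    mask = (radial <= tube.radius_mm**2) & axial
    if not mask.any():
        raise GeometryError("reference tube contains no voxel centers")
    return mask


def _check_fits(grid: VoxelGrid, center: tuple[float, float, float], radius: float,
                half_length_z: float | None = None) -> None:
    ext = grid.extent_mm
    half = (radius, radius, radius if half_length_z is None else half_length_z)
    for c, h, e in zip(center, half, ext):
        if c - h < 0 or c + h > e:
            raise GeometryError(
                f"compartment at {center} (half-extent {half}) exceeds grid extent {ext}"
            )


def _compartment_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Voxelize every compartment and verify pairwise disjointness."""
    masks: dict[str, np.ndarray] = {}
    for i, pellet in enumerate(spec.pellets):
        _check_fits(spec.grid, pellet.center_mm, pellet.radius_mm)
        masks[f"pellet_{i}"] = voxelize_sphere(spec.grid, pellet.center_mm, pellet.radius_mm)
    if spec.reference is not None:
        _check_fits(spec.grid, spec.reference.center_mm, spec.reference.radius_mm,
                    spec.reference.length_mm / 2.0)
        masks["reference"] = voxelize_tube(spec.grid, spec.reference)
    if spec.off_resonance is not None:
        _check_fits(spec.grid, spec.off_resonance.center_mm, spec.off_resonance.radius_mm)
        masks["off_resonance"] = voxelize_sphere(
            spec.grid, spec.off_resonance.center_mm, spec.off_resonance.radius_mm
        )
    names = list(masks)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            if np.any(masks[names[a]] & masks[names[b]]):
                raise GeometryError(f"compartments {names[a]} and {names[b]} overlap")
    return masks


def _apply_rician_noise(clean: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd == 0:
        return clean
    re = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    im = rng.normal(0.0, noise_sd, size=clean.shape)
    return np.hypot(re, im)


def generate_fluorine_image(
    spec: PhantomSpec, acq: AcquisitionParams
) -> tuple[Image3D, dict[str, np.ndarray]]:
    """Simulate a ¹⁹F magnitude image and return it with per-compartment masks.

    Noiseless voxel value = gain × spins-in-voxel × excitation response at the
    compartment offset.  Pellet spins are spread uniformly over the pellet's
    voxels (no sub-voxel partial volume), so compartment sums are conserved
    exactly at σ = 0.  Reference voxels each carry C_ref × voxel-volume spins.
    """
    masks = _compartment_masks(spec)
    clean = np.zeros(spec.grid.dims, dtype=float)
    for i, pellet in enumerate(spec.pellets):
        mask = masks[f"pellet_{i}"]
        spins_per_voxel = pellet.total_spins / int(mask.sum())
        clean[mask] = acq.gain * spins_per_voxel  # on-resonance: response = 1
    if spec.reference is not None:
        spins_per_voxel = spec.reference.concentration_spins_per_ul * spec.grid.voxel_volume_ul
        clean[masks["reference"]] = acq.gain * spins_per_voxel
    if spec.off_resonance is not None:
        comp = spec.off_resonance
        resp = excitation_response(acq.pulse, comp.offset_khz)
        spins_per_voxel = comp.spin_density_spins_per_ul * spec.grid.voxel_volume_ul
        clean[masks["off_resonance"]] = acq.gain * spins_per_voxel * resp
    rng = np.random.default_rng(acq.seed)
    values = _apply_rician_noise(clean, acq.noise_sd, rng)
    return Image3D(spec.grid, values), masks


def generate_proton_image(
    spec: PhantomSpec,
    acq: AcquisitionParams,
    body_center_frac: tuple[float, float, float] = (0.5, 0.5, 0.5),
    body_semiaxes_frac: tuple[float, float, float] = (0.4, 0.4, 0.45),
    tissue_intensity: float = 1000.0,
) -> Image3D:
    """Companion ¹H image: uniform tissue inside a body ellipsoid, zero outside.

    Anatomical overlay background only; no relaxation contrast is modeled.
    """
    grid = spec.grid
    ext = grid.extent_mm
    cx, cy, cz = grid.voxel_centers()
    center = tuple(f * e for f, e in zip(body_center_frac, ext))
    semi = tuple(f * e for f, e in zip(body_semiaxes_frac, ext))
    if any(s <= 0 for s in semi):
        raise GeometryError("body ellipsoid semiaxes must be positive")
    r2 = ((cx - center[0]) / semi[0]) ** 2 + ((cy - center[1]) / semi[1]) ** 2 \
        + ((cz - center[2]) / semi[2]) ** 2
    body = r2 <= 1.0
    if not body.any():
        raise GeometryError("body mask is empty")
    clean = np.where(body, float(tissue_intensity), 0.0)
    rng = np.random.default_rng(acq.seed)
    return Image3D(grid, _apply_rician_noise(clean, acq.noise_sd, rng))


def _default_grid() -> VoxelGrid:
    return VoxelGrid(dims=(32, 32, 16), voxel_size_mm=(1.0, 1.0, 2.0))


def build_pellet_series(
    cell_counts: tuple[int, ...] = PAPER_PELLET_COUNTS,
    spins_per_cell: float = 1.5e11,
    grid: VoxelGrid | None = None,
    pellet_center_mm: tuple[float, float, float] = (10.0, 16.0, 16.0),
    pellet_radius_mm: float = 3.0,
    reference: ReferenceTubeSpec | None = None,
    off_resonance: OffResonanceCompartment | None = None,
) -> list[PhantomSpec]:
    """One phantom per pellet size, sharing geometry and reference tube.

    Defaults reproduce the in-vitro validation series (2×10⁵ … 2×10⁶ cells,
    a single loading value per imaging occasion, one reference tube).
    """
    if any(int(c) <= 0 for c in cell_counts):
        raise ValueError("cell counts must be positive")
    grid = grid or _default_grid()
    if reference is None:
        reference = ReferenceTubeSpec(
            center_mm=(24.0, 16.0, 16.0), radius_mm=2.0, length_mm=16.0,
        )
    specs = []
    for count in cell_counts:
        pellet = PelletSpec(
            center_mm=pellet_center_mm,
            radius_mm=pellet_radius_mm,
            n_cells=int(count),
            spins_per_cell=spins_per_cell,
        )
        specs.append(
            PhantomSpec(grid=grid, pellets=(pellet,), reference=reference,
                        off_resonance=off_resonance)
        )
    return specs


def sample_loading(rng: np.random.Generator) -> float:
    """Draw a per-experiment cellular loading uniformly from the observed range."""
    lo, hi = LOADING_RANGE_SPINS_PER_CELL
    return float(rng.uniform(lo, hi))
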