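"""Synthetic brain geometry: gray-matter mask and planted effect maps.

The atlas is a desk-scale stand-in for a spatially normalized brain: an
ellipsoidal "gray matter" region on a small isotropic grid with an MNI-like
affine (origin at the grid center, mm units).  Pain-responsive anatomy is
emulated by spherical regions carrying a percent-signal-change amplitude per
condition, plus a handful of single-voxel artifacts whose amplitude exceeds
the 3% plausibility bound used by downstream feature reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARTIFACT_BOUND_PCT = 3.0  # plausibility bound for pain-evoked BOLD change


class AtlasError(ValueError):
    """Raised for inconsistent atlas geometry."""


@dataclass(frozen=True)
class RegionEffect:
    """A spherical region with planted per-condition BOLD amplitudes.

    ``amplitude_pain`` / ``amplitude_nonpain`` are percent-signal-change
    units.  ``sign`` is +1 for pain-predictive regions (stronger response to
    painful heat) and -1 for nonpain-predictive ones.  Non-artifact regions
    must stay below the 3% bound; ``artifact=True`` voxels deliberately
    exceed it so the feature-reduction filter has something to remove.
    """

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    amplitude_pain: float
    amplitude_nonpain: float
    artifact: bool = False

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise AtlasError(f"region {self.name!r}: radius_mm must be positive")
        if not self.artifact:
            amax = max(abs(self.amplitude_pain), abs(self.amplitude_nonpain))
            if amax >= ARTIFACT_BOUND_PCT:
                raise AtlasError(
                    f"region {self.name!r}: non-artifact amplitude {amax} exceeds "
                    f"the {ARTIFACT_BOUND_PCT}% plausibility bound; set artifact=True"
                )

    @property
    def sign(self) -> int:
        """+1 if pain-predictive, -1 if nonpain-predictive."""
        return 1 if self.amplitude_pain >= self.amplitude_nonpain else -1


@dataclass(frozen=True)
class Atlas:
    """Gray-matter mask plus per-condition planted effect maps.

    Iterating yields ``(gray_mask, effect_pain, effect_nonpain)`` so the
    atlas unpacks as the bare map triple where that is more convenient.
    """

    gray_mask: np.ndarray          # 3D bool
    effect_pain: np.ndarray        # 3D float, percent units
    effect_nonpain: np.ndarray     # 3D float, percent units
    affine: np.ndarray             # 4x4 voxel->mm
    voxel_mm: float
    regions: tuple[RegionEffect, ...] = field(default=())
    artifact_mask: np.ndarray | None = None

    def __iter__(self):
        return iter((self.gray_mask, self.effect_pain, self.effect_nonpain))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.gray_mask.shape

    @property
    def n_gray(self) -> int:
        return int(self.gray_mask.sum())


def mni_like_affine(grid_shape, voxel_mm: float) -> np.ndarray:
    """Isotropic affine with the mm origin at the grid center."""
    grid_shape = np.asarray(grid_shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (grid_shape - 1) / 2.0
    return affine


def voxel_centers_mm(grid_shape, affine) -> np.ndarray:
    """(nx, ny, nz, 3) array of voxel-center coordinates in mm."""
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij"), axis=-1
    ).astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def sphere_voxels(center_mm, radius_mm, grid_shape, affine) -> np.ndarray:
    """Boolean mask of voxels whose center lies within ``radius_mm`` of center.

    Membership is voxel-center-within-radius (inclusive boundary).
    """
    centers = voxel_centers_mm(grid_shape, affine)
    d2 = ((centers - np.asarray(center_mm, float)) ** 2).sum(axis=-1)
    return d2 <= float(radius_mm) ** 2 + 1e-9


def ellipsoid_mask(grid_shape, affine, semi_axes_mm) -> np.ndarray:
    centers = voxel_centers_mm(grid_shape, affine)
    r = (centers / np.asarray(semi_axes_mm, float)) ** 2
    return r.sum(axis=-1) <= 1.0


DEFAULT_GRID_SHAPE = (32, 38, 32)
DEFAULT_VOXEL_MM = 4.0

# planted-region centers as fractions of the half-extent per axis, so the
# same pain-network layout scales to reduced desk grids
_REGION_FRACTIONS = (
    ("op-left", (-0.77, -0.27, 0.26), 0.5, 0.1),
    ("op-right", (0.77, -0.27, 0.26), 0.5, 0.1),
    ("insula-left", (-0.58, 0.0, 0.19), 0.5, 0.1),
    ("postcentral-right", (0.39, -0.38, 0.71), 0.4, 0.1),
    ("cingulate", (-0.13, 0.57, 0.0), 0.1, 0.5),
)


def default_regions(
    grid_shape=DEFAULT_GRID_SHAPE, voxel_mm: float = DEFAULT_VOXEL_MM
) -> tuple[RegionEffect, ...]:
    """Planted pain-network stand-ins, scaled to the given grid.

    Bilateral parietal-operculum-like spheres, a left anterior-insula-like
    sphere and a contralateral postcentral sphere respond more to painful
    heat; a pregenual-cingulate-like sphere responds more to non-painful
    warmth.  Amplitudes honour the sub-1% scale of pain-evoked BOLD change.
    On the default grid the centers sit at MNI-plausible coordinates (e.g.
    op-left near (-48, -20, 16) mm).
    """
    half_extent = voxel_mm * (np.asarray(grid_shape) - 1) / 2.0
    regions = []
    for name, frac, amp_pain, amp_nonpain in _REGION_FRACTIONS:
        center = tuple(np.round(np.asarray(frac) * half_extent, 1))
        regions.append(RegionEffect(name, center, 8.0, amp_pain, amp_nonpain))
    return tuple(regions)


def make_atlas(
    grid_shape=DEFAULT_GRID_SHAPE,
    voxel_mm: float = DEFAULT_VOXEL_MM,
    regions: tuple[RegionEffect, ...] | list[RegionEffect] | None = None,
    seed: int = 0,
    n_artifact_voxels: int = 5,
    artifact_amplitude: float = 5.0,
) -> Atlas:
    """Build the synthetic gray-matter mask and planted effect maps.

    Parameters
    ----------
    grid_shape, voxel_mm
        Grid geometry; the affine is isotropic and centered (MNI-like).
    regions
        Planted :class:`RegionEffect` spheres; ``None`` uses
        :func:`default_regions`.  Pass ``()`` for a signal-free atlas.
    seed
        Seeds the placement of random artifact voxels.
    n_artifact_voxels, artifact_amplitude
        Number and percent amplitude of planted single-voxel artifacts
        (amplitude applies to both conditions; must exceed 3% to count as
        an artifact, set ``n_artifact_voxels=0`` to disable).

    Returns
    -------
    Atlas
        Unpacks as ``(gray_mask, effect_pain, effect_nonpain)``.
    """
    if voxel_mm <= 0:
        raise AtlasError("voxel_mm must be positive")
    if regions is None:
        regions = default_regions(grid_shape, voxel_mm)
    grid_shape = tuple(int(n) for n in grid_shape)
    affine = mni_like_affine(grid_shape, voxel_mm)
    extent = np.asarray(grid_shape) * voxel_mm
    gray = ellipsoid_mask(grid_shape, affine, semi_axes_mm=0.47 * extent)

    effect_pain = np.zeros(grid_shape)
    effect_nonpain = np.zeros(grid_shape)
    for region in regions:
        sphere = sphere_voxels(region.center_mm, region.radius_mm, grid_shape, affine)
        if not sphere.any():
            raise AtlasError(f"region {region.name!r} lies entirely outside the grid")
        effect_pain[sphere] = region.amplitude_pain
        effect_nonpain[sphere] = region.amplitude_nonpain

    artifact_mask = np.zeros(grid_shape, dtype=bool)
    if n_artifact_voxels > 0:
        if abs(artifact_amplitude) <= ARTIFACT_BOUND_PCT:
            raise AtlasError(
                f"artifact_amplitude must exceed {ARTIFACT_BOUND_PCT}% in magnitude"
            )
        rng = np.random.default_rng(seed)
        # artifacts go in clean gray voxels so they never mask planted signal
        candidates = np.flatnonzero(gray & (effect_pain == 0) & (effect_nonpain == 0))
        chosen = rng.choice(candidates, size=min(n_artifact_voxels, candidates.size), replace=False)
        flat_art = np.zeros(int(np.prod(grid_shape)), dtype=bool)
        flat_art[chosen] = True
        artifact_mask = flat_art.reshape(grid_shape)
        effect_pain[artifact_mask] = artifact_amplitude
        effect_nonpain[artifact_mask] = artifact_amplitude

    return Atlas(
        gray_mask=gray,
        effect_pain=effect_pain,
        effect_nonpain=effect_nonpain,
        affine=affine,
        voxel_mm=float(voxel_mm),
        regions=tuple(regions),
        artifact_mask=artifact_mask,
    )
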