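"""Synthetic calibration and test data.

Everything the pipeline consumes can be generated here with no measured
data: smooth checker reflectances (patches 19-24 form a spectrally flat
gray ramp, mimicking the classic 24-patch checker's neutral row), a
broadband white-light illuminant, camera RGB renderings with an optional
planted distortion, narrow-band target colors rendered from a planted band
model, a checker mosaic image, and a two-region lesion phantom with
hemoglobin-like absorption dips at 415 and 540 nm. All outputs are pure
functions of their configuration: a fixed seed reproduces them bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorimetry import (
    DEFAULT_GRID,
    SPD,
    ColorMatchingFunctions,
    WavelengthGrid,
    cie_1931_cmf,
    spectrum_to_xyz,
    srgb_encode,
    xyz_to_srgb,
)
from .errors import DomainError
from .nbi import BandModel, LorentzianBand, NBITargetSet, render_patch_color

__all__ = [
    "FixtureConfig",
    "GRAY_RAMP",
    "generate_checker_reflectances",
    "generate_wli_illuminant",
    "render_camera_rgb",
    "generate_nbi_targets",
    "generate_checker_image",
    "generate_lesion_phantom",
]

#: Flat reflectance levels of the synthetic gray ramp (patches 19-24),
#: spanning the checker's dynamic range roughly geometrically.
GRAY_RAMP = (0.03, 0.09, 0.19, 0.36, 0.59, 0.90)


@dataclass(frozen=True)
class FixtureConfig:
    """Generator settings; identical config means bitwise-identical outputs."""

    seed: int = 0
    n_gaussians: int = 2
    noise_sd: float = 0.0
    patch_pixels: int = 16
    grid: WavelengthGrid = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.n_gaussians < 1:
            raise DomainError("n_gaussians must be >= 1")
        if self.patch_pixels < 1:
            raise DomainError("patch_pixels must be >= 1")


#: Wavelength windows (center range, σ range) the shared bump basis draws
#: from: blue, red-orange, mid-green, violet. Cycled in order, so the
#: default two bumps sit in the blue and red-orange regions where the
#: checker's chromatic variation lives.
_BUMP_WINDOWS = (
    (435.0, 460.0, 25.0, 45.0),
    (595.0, 630.0, 40.0, 65.0),
    (490.0, 550.0, 30.0, 60.0),
    (405.0, 430.0, 20.0, 40.0),
)


def generate_checker_reflectances(config: FixtureConfig) -> np.ndarray:
    """24 smooth reflectance spectra, shape ``(24, n_wavelengths)``.

    Patches 1-18 are random non-negative combinations of a constant term
    and ``n_gaussians`` Gaussian bumps *shared across patches* (centers and
    widths drawn once per seed from :data:`_BUMP_WINDOWS`), rescaled into
    [0, 1]. Natural surface reflectances are famously low-dimensional; a
    shared (1 + n_gaussians)-function family emulates that structure, and
    with the default ``n_gaussians = 2`` its dimension matches the three
    degrees of freedom a tristimulus measurement can resolve — which is
    what makes the planted calibration/reconstruction chain solvable.
    Patches 19-24 are the flat gray ramp. Additive noise of ``noise_sd``
    (if any) is applied before the final clip to [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    lam = config.grid.wavelengths
    bumps = []
    for k in range(config.n_gaussians):
        lo, hi, s_lo, s_hi = _BUMP_WINDOWS[k % len(_BUMP_WINDOWS)]
        center = rng.uniform(lo, hi)
        sigma = rng.uniform(s_lo, s_hi)
        bumps.append(np.exp(-0.5 * ((lam - center) / sigma) ** 2))
    spectra = np.empty((24, lam.size))
    for i in range(18):
        spectrum = np.full(lam.size, rng.uniform(0.05, 0.35))
        for bump in bumps:
            spectrum = spectrum + rng.uniform(0.0, 0.55) * bump
        peak = spectrum.max()
        if peak > 0.97:  # uniform rescale keeps the spectrum inside the family span
            spectrum *= 0.97 / peak
        spectra[i] = spectrum
    for j, level in enumerate(GRAY_RAMP):
        spectra[18 + j] = level
    if config.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, config.noise_sd, size=spectra.shape)
    return np.clip(spectra, 0.0, 1.0)


def generate_wli_illuminant(grid: WavelengthGrid = DEFAULT_GRID) -> SPD:
    """Smooth broadband white-light SPD with the sRGB (D65) white chromaticity.

    Built from a constant pedestal plus blue (450 nm) and amber (600 nm)
    Gaussian lobes whose weights solve a 3×3 linear system so that a perfect
    reflector lands exactly on the D65 white point — the behaviour of a
    color-balanced endoscopic lamp, and the condition under which flat gray
    patches render as neutral sRGB. Deterministic (no seed); strictly
    positive across the default grid.
    """
    lam = grid.wavelengths
    basis = np.stack(
        [
            np.ones_like(lam),
            np.exp(-0.5 * ((lam - 450.0) / 70.0) ** 2),
            np.exp(-0.5 * ((lam - 600.0) / 90.0) ** 2),
        ]
    )
    cmf = cie_1931_cmf(grid)
    from .colorimetry import D65_WHITE

    weights = np.linalg.solve((basis @ cmf.as_matrix).T, D65_WHITE)
    power = weights @ basis
    if power.min() <= 0:
        raise DomainError("WLI illuminant basis produced non-positive power on this grid")
    return SPD(grid=grid, power=power)


def render_camera_rgb(
    reflectances,
    illuminant: SPD,
    planted_distortion: np.ndarray | None = None,
    cmf: ColorMatchingFunctions | None = None,
) -> tuple[np.ndarray, int]:
    """Simulate the endoscope camera: spectra -> 8-bit sRGB patch colors.

    Each reflectance is integrated to XYZ under ``illuminant``, optionally
    passed through a planted 3×3 distortion (the ground truth a calibration
    test should undo), then sRGB-encoded and quantized to 8 bits. Returns
    the ``(n, 3)`` uint8 array and the count of gamut-clipped channel values.
    """
    if cmf is None:
        cmf = cie_1931_cmf(illuminant.grid)
    xyz = spectrum_to_xyz(reflectances, illuminant, cmf)
    if planted_distortion is not None:
        planted_distortion = np.asarray(planted_distortion, dtype=float)
        if planted_distortion.shape != (3, 3):
            raise DomainError("planted distortion must be a 3x3 matrix")
        xyz = xyz @ planted_distortion.T
    unclipped = xyz_to_srgb(xyz, clip=False)
    n_clipped = int(np.sum((unclipped < 0.0) | (unclipped > 1.0)))
    encoded = xyz_to_srgb(xyz, clip=True)
    rgb = np.round(encoded * 255.0).astype(np.uint8)
    return rgb, n_clipped


def generate_nbi_targets(
    reflectances,
    planted_bands: BandModel,
    cmf: ColorMatchingFunctions | None = None,
) -> NBITargetSet:
    """Target NBI patch colors rendered from a planted band model.

    By construction the objective of ``planted_bands`` against these targets
    is exactly zero, which makes optimizer recovery runs self-validating.
    """
    if cmf is None:
        cmf = cie_1931_cmf()
    lab = render_patch_color(np.atleast_2d(reflectances), planted_bands, cmf)
    if lab.shape[0] != 24:
        raise DomainError(f"expected 24 patch reflectances, got {lab.shape[0]}")
    return NBITargetSet(patch_ids=tuple(range(1, 25)), lab=lab)


def generate_checker_image(
    rgbs, config: FixtureConfig
) -> tuple[np.ndarray, np.ndarray]:
    """4×6 patch mosaic (row-major patch order) plus per-patch region masks.

    Returns ``(image, masks)`` with image shape ``(4p, 6p, 3)`` uint8 and
    masks shape ``(24, 4p, 6p)`` bool partitioning the image exactly.
    """
    rgbs = np.asarray(rgbs)
    if rgbs.shape != (24, 3):
        raise DomainError(f"expected 24 RGB triplets, got shape {rgbs.shape}")
    p = config.patch_pixels
    image = np.zeros((4 * p, 6 * p, 3), dtype=np.uint8)
    masks = np.zeros((24, 4 * p, 6 * p), dtype=bool)
    for idx in range(24):
        r, c = divmod(idx, 6)
        image[r * p : (r + 1) * p, c * p : (c + 1) * p] = rgbs[idx]
        masks[idx, r * p : (r + 1) * p, c * p : (c + 1) * p] = True
    return image, masks


def lesion_reflectances(config: FixtureConfig) -> tuple[np.ndarray, np.ndarray]:
    """Planted (background, lesion) reflectance pair for the phantom.

    The background is spectrally flat; the lesion multiplies it by
    Lorentzian absorption dips at 415 and 540 nm, the hemoglobin peaks, so a
    blue/green-weighted illuminant amplifies the lesion/background contrast.
    """
    lam = config.grid.wavelengths
    background = np.full(lam.size, 0.60)
    dip_415 = 0.60 * 15.0**2 / ((lam - 415.0) ** 2 + 15.0**2)
    dip_540 = 0.45 * 20.0**2 / ((lam - 540.0) ** 2 + 20.0**2)
    lesion = background * np.clip(1.0 - dip_415 - dip_540, 0.0, 1.0)
    return background, lesion


def generate_lesion_phantom(
    config: FixtureConfig,
    illuminant: SPD | None = None,
    cmf: ColorMatchingFunctions | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Two-region phantom image rendered under the WLI illuminant.

    Returns ``(image, masks, spectra)`` where masks has keys ``background``
    and ``lesion`` (disjoint, exhaustive; the lesion is a centered disk) and
    spectra holds the planted reflectance of each region for oracle checks.
    """
    if illuminant is None:
        illuminant = generate_wli_illuminant(config.grid)
    if cmf is None:
        cmf = cie_1931_cmf(config.grid)
    background, lesion = lesion_reflectances(config)
    rgb, _ = render_camera_rgb(
        np.stack([background, lesion]), illuminant, cmf=cmf
    )
    side = 4 * config.patch_pixels
    yy, xx = np.mgrid[0:side, 0:side]
    radius = side / 4.0
    lesion_mask = (yy - side / 2.0) ** 2 + (xx - side / 2.0) ** 2 <= radius**2
    image = np.where(lesion_mask[..., None], rgb[1], rgb[0]).astype(np.uint8)
    masks = {"background": ~lesion_mask, "lesion": lesion_mask}
    spectra = {"background": background, "lesion": lesion}
    return image, masks, spectra
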