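"""Spectral reconstruction: corrected XYZ -> per-pixel reflectance spectra.

The 24 measured checker reflectances are summarized by a mean-centered PCA
basis; the principal-component scores of each patch are then regressed onto
the polynomial expansion of the patch's corrected XYZ, giving a conversion
matrix M. For any new color the reconstructed spectrum is

    R(λ) = mean(λ) + Σ_j [M · V(XYZ_corrected)]_j · component_j(λ)

clipped to [0, 1] at output. Applied per pixel this converts an RGB image
into a hyperspectral cube at the grid resolution (default 1 nm, 401 bands).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .calibration import (
    CorrectionModel,
    VariableExpansion,
    DEFAULT_EXPANSION,
    apply_correction,
    expand_xyz,
)
from .colorimetry import DEFAULT_GRID, WavelengthGrid, srgb_decode, srgb_to_xyz
from .errors import (
    DegenerateVarianceError,
    DomainError,
    GridMismatchError,
    RankDeficiencyError,
    SchemaError,
    UsageError,
)

__all__ = [
    "PCABasis",
    "ConversionModel",
    "SpectralCube",
    "fit_pca",
    "project_scores",
    "fit_conversion_matrix",
    "reconstruct_spectrum",
    "spectrum_rmse",
    "image_to_cube",
]

DEFAULT_N_PC = 12


@dataclass(frozen=True)
class PCABasis:
    """Mean spectrum plus orthonormal principal components of reflectances."""

    grid: WavelengthGrid
    mean_spectrum: np.ndarray
    components: np.ndarray  # (n_pc, n_wavelengths)
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        mean = self.grid.check_length(self.mean_spectrum, "mean_spectrum")
        comps = np.asarray(self.components, dtype=float)
        if comps.ndim != 2 or comps.shape[1] != self.grid.n_samples:
            raise DomainError(
                f"components must be (n_pc, {self.grid.n_samples}), got {comps.shape}"
            )
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if evr.shape != (comps.shape[0],):
            raise DomainError("explained_variance_ratio length != number of components")
        object.__setattr__(self, "mean_spectrum", mean)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "explained_variance_ratio", evr)

    @property
    def n_pc(self) -> int:
        return self.components.shape[0]


@dataclass(frozen=True)
class ConversionModel:
    """Score regression: PC scores = M · V(corrected XYZ)."""

    expansion: VariableExpansion
    M: np.ndarray  # (n_pc, |terms|)

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2 or M.shape[1] != len(self.expansion):
            raise DomainError(
                f"M has shape {M.shape}, expected (n_pc, {len(self.expansion)})"
            )
        if not np.all(np.isfinite(M)):
            raise DomainError("M contains non-finite values")
        object.__setattr__(self, "M", M)


@dataclass(frozen=True)
class SpectralCube:
    """Per-pixel reflectance spectra; axes (row, column, wavelength)."""

    grid: WavelengthGrid
    values: np.ndarray  # (H, W, n_wavelengths)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or values.shape[2] != self.grid.n_samples:
            raise DomainError(
                f"cube values must be (H, W, {self.grid.n_samples}), got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise DomainError("cube contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def save(self, path) -> None:
        np.savez_compressed(
            path, wavelengths_nm=self.grid.wavelengths, reflectance=self.values
        )

    @classmethod
    def load(cls, path) -> "SpectralCube":
        with np.load(path) as archive:
            wl = archive["wavelengths_nm"]
            values = archive["reflectance"]
        step = float(wl[1] - wl[0])
        grid = WavelengthGrid(float(wl[0]), float(wl[-1]), step)
        return cls(grid=grid, values=values)


def fit_pca(spectra, n_pc: int = DEFAULT_N_PC, grid: WavelengthGrid = DEFAULT_GRID) -> PCABasis:
    """Mean-centered PCA of the measured reflectances.

    Components are the right singular vectors of the centered data matrix,
    ordered by decreasing singular value. The per-component sign ambiguity is
    fixed deterministically by making the largest-magnitude coefficient of
    each component positive.
    """
    spectra = grid.check_length(np.atleast_2d(spectra), "spectra")
    n, n_wl = spectra.shape
    max_pc = min(n, n_wl) - 1
    if not (1 <= n_pc <= max_pc):
        raise UsageError(f"n_pc must be in [1, {max_pc}] for {n} spectra, got {n_pc}")
    mean = spectra.mean(axis=0)
    centered = spectra - mean
    total_var = float(np.sum(centered**2))
    if total_var <= 1e-20:
        raise DegenerateVarianceError("spectra are identical; PCA basis undefined")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    components = vt[:n_pc]
    # deterministic sign: largest-|coefficient| entry of each component positive
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(n_pc), idx])
    components = components * signs[:, None]
    evr = s[:n_pc] ** 2 / np.sum(s**2)
    return PCABasis(
        grid=grid,
        mean_spectrum=mean,
        components=components,
        explained_variance_ratio=evr,
    )


def project_scores(basis: PCABasis, spectra) -> np.ndarray:
    """Project spectra onto the basis: scores = components · (R − mean)."""
    spectra = basis.grid.check_length(spectra, "spectra")
    return (spectra - basis.mean_spectrum) @ basis.components.T


def fit_conversion_matrix(
    scores,
    corrected_xyz,
    expansion: VariableExpansion = DEFAULT_EXPANSION,
) -> ConversionModel:
    """Least-squares regression of PC scores on expanded corrected XYZ.

    Each row of M is fit independently (separable least squares); the
    design matrix must be full column rank.
    """
    scores = np.asarray(scores, dtype=float)
    corrected_xyz = np.asarray(corrected_xyz, dtype=float)
    if scores.ndim != 2:
        raise DomainError(f"scores must be (n, n_pc), got {scores.shape}")
    if corrected_xyz.ndim != 2 or corrected_xyz.shape[1] != 3:
        raise DomainError(f"corrected_xyz must be (n, 3), got {corrected_xyz.shape}")
    if scores.shape[0] != corrected_xyz.shape[0]:
        raise DomainError("scores and corrected_xyz have different patch counts")
    design = expand_xyz(corrected_xyz, expansion)
    t = len(expansion)
    rank = np.linalg.matrix_rank(design)
    if rank < t:
        # name the deficient columns: those whose removal does not lower rank
        deficient = [
            i
            for i in range(t)
            if np.linalg.matrix_rank(np.delete(design, i, axis=1)) == rank
        ]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {t}; deficient expansion columns: {deficient}"
        )
    M, *_ = np.linalg.lstsq(design, scores, rcond=None)
    return ConversionModel(expansion=expansion, M=M.T)


def reconstruct_spectrum(
    basis: PCABasis, model: ConversionModel, xyz, clip: bool = True
) -> np.ndarray:
    """Reconstruct reflectance from corrected XYZ (0-100 scale).

    Affine in V(xyz) before clipping: mean + (M·V)ᵀ·components. ``clip=False``
    exposes the raw (possibly out-of-range) spectrum for diagnostics.
    """
    design = expand_xyz(xyz, model.expansion)
    scores = design @ model.M.T
    spectra = basis.mean_spectrum + scores @ basis.components
    if clip:
        spectra = np.clip(spectra, 0.0, 1.0)
    return spectra


def spectrum_rmse(a, b) -> float:
    """Root-mean-square difference between two reflectance spectra."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise GridMismatchError(f"spectra shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def image_to_cube(
    image,
    correction: CorrectionModel,
    basis: PCABasis,
    model: ConversionModel,
) -> SpectralCube:
    """Convert an 8-bit sRGB image to a hyperspectral reflectance cube.

    Per pixel: sRGB decode -> XYZ -> camera correction -> spectral
    reconstruction (clipped to [0, 1]). The computation is vectorized over
    all pixels but follows exactly the scalar single-color path.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise DomainError(f"image must be (H, W, 3), got shape {image.shape}")
    if image.dtype != np.uint8:
        raise DomainError(f"image must be 8-bit (uint8), got dtype {image.dtype}")
    h, w, _ = image.shape
    flat = image.reshape(-1, 3).astype(float) / 255.0
    xyz = srgb_to_xyz(srgb_decode(flat))
    corrected = apply_correction(correction, xyz)
    spectra = reconstruct_spectrum(basis, model, corrected, clip=True)
    return SpectralCube(grid=basis.grid, values=spectra.reshape(h, w, -1))


def _basis_to_dict(basis: PCABasis) -> dict:
    return {
        "grid": {
            "start_nm": basis.grid.start_nm,
            "stop_nm": basis.grid.stop_nm,
            "step_nm": basis.grid.step_nm,
        },
        "mean_spectrum": basis.mean_spectrum.tolist(),
        "components": basis.components.tolist(),
        "explained_variance_ratio": basis.explained_variance_ratio.tolist(),
    }


def _basis_from_dict(doc: dict) -> PCABasis:
    grid = WavelengthGrid(**doc["grid"])
    return PCABasis(
        grid=grid,
        mean_spectrum=np.asarray(doc["mean_spectrum"], dtype=float),
        components=np.asarray(doc["components"], dtype=float),
        explained_variance_ratio=np.asarray(doc["explained_variance_ratio"], dtype=float),
    )


def reconstruction_to_json(basis: PCABasis, model: ConversionModel) -> str:
    """Serialize the PCA basis + conversion matrix to one JSON document."""
    return json.dumps(
        {
            "basis": _basis_to_dict(basis),
            "conversion": {
                "expansion": [list(t) for t in model.expansion.terms],
                "M": model.M.tolist(),
            },
        },
        indent=2,
    )


def reconstruction_from_json(text: str) -> tuple[PCABasis, ConversionModel]:
    try:
        doc = json.loads(text)
        basis = _basis_from_dict(doc["basis"])
        conv = doc["conversion"]
        model = ConversionModel(
            expansion=VariableExpansion(terms=tuple(tuple(t) for t in conv["expansion"])),
            M=np.asarray(conv["M"], dtype=float),
        )
        return basis, model
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"invalid reconstruction model document: {exc}") from exc
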