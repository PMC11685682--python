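"""Camera correction against a 24-patch color checker.

The endoscope camera reports sRGB, which decodes to a camera-side XYZ that is
biased by filter crosstalk, color shift and dark current. The correction stage
regresses the spectrometer-derived XYZ of each checker patch onto a polynomial
expansion of the camera XYZ:

    XYZ_corrected = C · V(XYZ_camera)

where V is a list of monomials in (X, Y, Z)/100 (default: the 11 second-order
terms 1, X, Y, Z, XY, XZ, YZ, X², Y², Z², XYZ) and C is the 3 × |terms|
least-squares coefficient matrix. With 24 patches and 11 terms the fit is
over-determined; the recovered C absorbs the camera's systematic color error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, RankDeficiencyError, SchemaError

__all__ = [
    "VariableExpansion",
    "DEFAULT_EXPANSION",
    "CorrectionModel",
    "expand_xyz",
    "fit_correction",
    "apply_correction",
    "calibration_rmse",
]


@dataclass(frozen=True)
class VariableExpansion:
    """Ordered monomial basis in (X, Y, Z), each term an exponent triple."""

    terms: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        terms = tuple(tuple(int(e) for e in t) for t in self.terms)
        if not terms:
            raise DomainError("expansion must contain at least one term")
        if terms[0] != (0, 0, 0):
            raise DomainError("first expansion term must be the constant (0,0,0)")
        if len(set(terms)) != len(terms):
            raise DomainError("expansion contains duplicate terms")
        if any(len(t) != 3 or min(t) < 0 for t in terms):
            raise DomainError("each term must be a triple of non-negative exponents")
        object.__setattr__(self, "terms", terms)

    def __len__(self) -> int:
        return len(self.terms)


#: 11 second-order terms: constant, linears, cross products, squares, XYZ.
DEFAULT_EXPANSION = VariableExpansion(
    terms=(
        (0, 0, 0),
        (1, 0, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 1, 0),
        (1, 0, 1),
        (0, 1, 1),
        (2, 0, 0),
        (0, 2, 0),
        (0, 0, 2),
        (1, 1, 1),
    )
)

#: Constant plus the three linear terms; useful for identity-map tests.
LINEAR_EXPANSION = VariableExpansion(terms=((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)))


def expand_xyz(xyz, expansion: VariableExpansion = DEFAULT_EXPANSION) -> np.ndarray:
    """Evaluate the monomial basis at XYZ/100; output shape ``(..., |terms|)``.

    Monomials are evaluated on the 0-1 scale (XYZ divided by 100) to keep the
    regression design matrix well conditioned.
    """
    xyz = np.asarray(xyz, dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise DomainError("tristimulus contains non-finite values")
    scaled = xyz / 100.0
    cols = [
        scaled[..., 0] ** a * scaled[..., 1] ** b * scaled[..., 2] ** c
        for (a, b, c) in expansion.terms
    ]
    return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class CorrectionModel:
    """Fitted camera correction: corrected XYZ/100 = C · V(camera XYZ)."""

    expansion: VariableExpansion
    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (3, len(self.expansion)):
            raise DomainError(
                f"C has shape {C.shape}, expected (3, {len(self.expansion)})"
            )
        if not np.all(np.isfinite(C)):
            raise DomainError("C contains non-finite values")
        object.__setattr__(self, "C", C)

    def to_json(self) -> str:
        return json.dumps(
            {
                "expansion": [list(t) for t in self.expansion.terms],
                "C": self.C.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CorrectionModel":
        try:
            doc = json.loads(text)
            expansion = VariableExpansion(terms=tuple(tuple(t) for t in doc["expansion"]))
            return cls(expansion=expansion, C=np.asarray(doc["C"], dtype=float))
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"invalid CorrectionModel document: {exc}") from exc


def fit_correction(
    camera_xyz,
    spectrum_xyz,
    expansion: VariableExpansion = DEFAULT_EXPANSION,
) -> CorrectionModel:
    """Least-squares fit of the correction matrix C over checker patches.

    ``camera_xyz`` comes from the sRGB decoding pipeline, ``spectrum_xyz``
    from integrating the measured patch reflectances under the measurement
    illuminant; both are ``(n, 3)`` on the 0-100 scale. C minimizes
    ‖spectrum_xyz/100 − C·V(camera_xyz)‖² and is deterministic given inputs.
    """
    camera_xyz = np.asarray(camera_xyz, dtype=float)
    spectrum_xyz = np.asarray(spectrum_xyz, dtype=float)
    if camera_xyz.ndim != 2 or camera_xyz.shape[1] != 3:
        raise DomainError(f"camera_xyz must be (n, 3), got {camera_xyz.shape}")
    if spectrum_xyz.shape != camera_xyz.shape:
        raise DomainError(
            f"spectrum_xyz shape {spectrum_xyz.shape} != camera_xyz shape {camera_xyz.shape}"
        )
    if not (np.all(np.isfinite(camera_xyz)) and np.all(np.isfinite(spectrum_xyz))):
        raise DomainError("calibration inputs contain non-finite values")
    n, t = camera_xyz.shape[0], len(expansion)
    if n < t:
        raise RankDeficiencyError(
            f"{n} patches cannot determine {t} expansion coefficients; "
            f"need at least {t} patches"
        )
    design = expand_xyz(camera_xyz, expansion)
    rank = np.linalg.matrix_rank(design)
    if rank < t:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {t} expansion terms; patches are degenerate"
        )
    coeffs, *_ = np.linalg.lstsq(design, spectrum_xyz / 100.0, rcond=None)
    return CorrectionModel(expansion=expansion, C=coeffs.T)


def apply_correction(model: CorrectionModel, xyz) -> np.ndarray:
    """Apply a fitted correction; input and output XYZ on the 0-100 scale."""
    design = expand_xyz(xyz, model.expansion)
    return 100.0 * design @ model.C.T


def calibration_rmse(predicted, reference) -> float:
    """Root-mean-square error pooled over all 3n scalar XYZ components."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise DomainError(
            f"shape mismatch: predicted {predicted.shape} vs reference {reference.shape}"
        )
    if predicted.size == 0:
        raise DomainError("calibration_rmse requires at least one tristimulus pair")
    return float(np.sqrt(np.mean((predicted - reference) ** 2)))
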