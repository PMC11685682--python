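"""Exception hierarchy.

Every contract violation raises a subclass of :class:`NbisimError` so the CLI
can map library failures to nonzero exit codes uniformly.
"""


class NbisimError(Exception):
    """Base class for all package errors."""


class DomainError(NbisimError, ValueError):
    """An input value lies outside the mathematical domain of the operation."""


class GridMismatchError(NbisimError, ValueError):
    """Arrays that must share one wavelength grid do not."""


class DegenerateIlluminantError(NbisimError, ValueError):
    """Illuminant integrates to zero against the luminance observer curve."""


class DegenerateVarianceError(NbisimError, ValueError):
    """Spectra carry no variance; a PCA basis cannot be defined."""


class RankDeficiencyError(NbisimError, ValueError):
    """The regression design matrix is rank deficient."""


class PairingError(NbisimError, ValueError):
    """Patch measurements and targets cannot be matched by patch_id."""


class SchemaError(NbisimError, ValueError):
    """A CSV/JSON/YAML document does not conform to its documented schema."""


class ConfigError(NbisimError, ValueError):
    """Inconsistent pipeline configuration (e.g. models on different grids)."""


class UsageError(NbisimError, ValueError):
    """An argument combination violates the operation's usage contract."""
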