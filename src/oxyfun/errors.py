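"""Exception hierarchy shared across the package."""


class OxyfunError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(OxyfunError):
    """Malformed or inconsistent PDB content; message names the offending line."""


class TagError(OxyfunError):
    """A required role tag (FE2, O_TRANSFER, C_N, ...) is missing or dangling."""


class GeometryError(OxyfunError):
    """Degenerate or impossible geometry (collinear torsion, clash, <3 superposition pairs)."""


class ParameterizationError(OxyfunError):
    """An atom lacks the non-bonded parameters the force field needs."""


class ConstructionError(OxyfunError):
    """A synthetic fixture with the requested properties cannot be built."""


class RangeError(OxyfunError):
    """A requested evaluation point lies outside the sampled data."""


class PlateauError(OxyfunError):
    """A kinetic trace has no detectable absorbance plateau."""


class FitError(OxyfunError):
    """Non-linear regression failed to converge."""
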