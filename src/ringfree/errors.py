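"""Typed exceptions raised across the package."""


class RingfreeError(Exception):
    """Base class for all package errors."""


class PSFParseError(RingfreeError):
    """A PSF file is malformed (missing section, count mismatch, bad line)."""


class PDBError(RingfreeError):
    """PDB coordinates cannot be read or written against the current system."""


class ParameterError(RingfreeError):
    """A parameter file is malformed or a lookup cannot be resolved."""


class ConfigError(RingfreeError):
    """A run-configuration file is missing required keys or has bad values."""


class GeometryError(RingfreeError):
    """Degenerate geometry (zero-area triangle, coplanar stereocenter, ...)."""


class EnergyError(RingfreeError):
    """Energy or force evaluation failed (non-finite value, bad precondition)."""
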