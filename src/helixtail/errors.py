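"""Exception hierarchy for helixtail."""


class HelixtailError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HelixtailError):
    """A trajectory/topology file is malformed or inconsistent."""


class SelectionError(HelixtailError):
    """An atom selection resolves to no atoms or refers to missing names."""


class DegenerateFitError(HelixtailError):
    """Superposition input is degenerate (too few or collinear points)."""


class DegenerateGeometryError(HelixtailError):
    """A torsion/angle is undefined because of collinear atoms."""


class NoCutoffError(HelixtailError):
    """The RMSD histogram is unimodal; no folded/unfolded cutoff exists."""


class InfiniteFreeEnergyError(HelixtailError):
    """p_folded is exactly 0 or 1; the two-state free energy diverges."""


class GenerationError(HelixtailError):
    """The synthetic-conformer generator failed (e.g. no clash-free build)."""


class TemperatureMismatchError(HelixtailError):
    """Two results being compared were computed at different temperatures."""
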