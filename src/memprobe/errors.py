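"""Exception hierarchy for memprobe.

Every error raised by the library derives from :class:`MemprobeError` so
callers (and the CLI) can catch analysis failures without masking bugs.
"""


class MemprobeError(Exception):
    """Base class for all memprobe errors."""


class FormatError(MemprobeError):
    """A structure or table file could not be parsed."""


class EmptyInputError(MemprobeError):
    """An input contained no usable records (e.g. a PDB with zero models)."""


class TopologyMismatchError(MemprobeError):
    """A lipid residue is missing an atom required by its topology."""

    def __init__(self, residue: str, atom: str):
        self.residue = residue
        self.atom = atom
        super().__init__(f"residue {residue!r} is missing required atom {atom!r}")


class MissingReferenceAtomError(MemprobeError):
    """No phosphorus (leaflet reference) atoms found in the frame."""


class MissingProbeError(MemprobeError):
    """The requested probe residue is absent from the frame."""


class InsufficientSpanError(MemprobeError):
    """Trajectory is shorter than the requested analysis window."""


class DegenerateBilayerError(MemprobeError):
    """A leaflet is empty; bilayer metrics are undefined."""


class InvalidGeometryError(MemprobeError):
    """A zero-length vector where a direction is required."""


class EmptySelectionError(MemprobeError):
    """No lipids matched the selection in some frame."""


class ReconstructionError(MemprobeError):
    """C-H vector reconstruction lacks the neighbour carbons it needs."""


class ShortStringError(MemprobeError):
    """String shorter than the smallest k-mer length."""


class EmptySetError(MemprobeError):
    """Overlap coefficient of an empty k-mer set is undefined."""


class ConfigurationError(MemprobeError):
    """Invalid analysis configuration (thresholds, perplexity, windows...)."""


class DegenerateDataError(MemprobeError):
    """Statistical test input carries no information (zero variance, equal means)."""


class NoSignalError(MemprobeError):
    """Image pair has no pixels above the masking threshold."""
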