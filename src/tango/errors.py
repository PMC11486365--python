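"""Exception hierarchy.

All user-facing failures derive from :class:`TangoError` so the CLI can map
them onto a nonzero exit status with a clean message.
"""


class TangoError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(TangoError):
    """Structure file content could not be parsed or serialized."""


class EmptyStructureError(TangoError):
    """The input contains no nucleic-acid residues."""


class SelectionError(TangoError):
    """A model/chain/residue-range selection does not match the structure."""


class ConfigError(TangoError):
    """An invalid parameter combination was requested."""


class BuildError(TangoError):
    """Synthetic chain construction failed (e.g. ring closure residual)."""


class MatrixError(TangoError):
    """A dissimilarity matrix is unusable (undefined entries, wrong shape)."""
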