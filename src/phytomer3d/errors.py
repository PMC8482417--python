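"""Exception hierarchy for phytomer3d.

All package errors derive from :class:`Phytomer3DError` so callers can catch
one base class at CLI boundaries.
"""


class Phytomer3DError(Exception):
    """Base class for all phytomer3d errors."""


class GeometryError(Phytomer3DError):
    """Degenerate or inconsistent geometry (coincident points, bad axes)."""


class OrderingError(Phytomer3DError):
    """Phytomer ordering constraints violated (ear/tassel position etc.)."""


class FormatError(Phytomer3DError):
    """Malformed file or point-set not following the acquisition standard."""


class ConfigurationError(Phytomer3DError):
    """Invalid configuration or parameter combination."""


class SpecificationError(Phytomer3DError):
    """Invalid query/spec passed to a database or assembly operation."""


class RetrievalError(Phytomer3DError):
    """Template retrieval failed (empty database, missing type)."""


class ConnectivityError(Phytomer3DError):
    """Point-cloud neighbourhood graph is disconnected."""


class NumericalError(Phytomer3DError):
    """A linear solve or decomposition failed."""
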