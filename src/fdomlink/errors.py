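"""Exception hierarchy.

Every error raised on a documented contract violation derives from
:class:`FdomlinkError`, so callers can distinguish pipeline failures from
programming bugs.
"""


class FdomlinkError(Exception):
    """Base class for all package errors."""


class FormatError(FdomlinkError):
    """Malformed input file (ragged rows, non-numeric cells, empty file)."""


class GridError(FdomlinkError):
    """Wavelength-grid mismatch or empty intersection."""


class CorrectionError(FdomlinkError):
    """A spectral correction was applied twice or out of order."""


class NormalizationError(FdomlinkError):
    """Raman normalization failed (non-positive Raman area)."""


class ScatterError(FdomlinkError):
    """Scatter excision left an emission scan with nothing to interpolate."""


class TrimError(FdomlinkError):
    """Wavelength trimming produced an empty axis."""


class DomainError(FdomlinkError):
    """Requested wavelengths are outside the available data coverage."""


class RankError(FdomlinkError):
    """Requested model order exceeds what the data can support."""


class ValidationError(FdomlinkError):
    """Split-half validation cannot be performed (too few samples)."""


class UndefinedIndexError(FdomlinkError):
    """An optical index is undefined (zero denominator, trimmed band)."""


class UndefinedDiversityError(FdomlinkError):
    """A diversity index is undefined for the given counts."""


class UndefinedDistanceError(FdomlinkError):
    """A pairwise dissimilarity is undefined (all-zero samples)."""


class UndefinedMetricError(FdomlinkError):
    """A network metric is undefined (e.g. path length on an edgeless graph)."""


class TreeError(FdomlinkError):
    """Invalid phylogeny (unnamed tips, missing taxa)."""


class DegenerateFitError(FdomlinkError):
    """Model fitting is impossible on degenerate data."""


class ConfigError(FdomlinkError):
    """Invalid pipeline configuration (unknown keys, bad values)."""


class DataError(FdomlinkError):
    """Missing or inconsistent pipeline input data."""
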