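"""Exception hierarchy shared across the package."""


class IpacError(Exception):
    """Base class for all package errors."""


class AnnotationParseError(IpacError):
    """Malformed GFF3 input; message names the offending line or feature."""


class ValidationError(IpacError):
    """An input object violates a structural invariant."""


class MissingAnchorError(IpacError):
    """A stop-codon anchor was requested for a gene without a CDS."""


class LookupError_(IpacError):
    """Unknown chromosome or identifier."""


class ParameterError(IpacError):
    """An out-of-range or nonsensical parameter value."""


class PlacementError(IpacError):
    """The simulator could not place a site of the requested class."""


class SamplingError(IpacError):
    """Background sampling is impossible (no intergenic space)."""


class PairingError(IpacError):
    """IPAC records and neighbor contexts are not aligned one-to-one."""
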