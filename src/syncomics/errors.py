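"""Exception hierarchy for syncomics.

Config/usage mistakes raise subclasses of :class:`SyncomicsError`; data-shaped
problems (empty samples, unknown features) get their own classes so the CLI can
distinguish exit codes.
"""


class SyncomicsError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(SyncomicsError):
    """Experimental design violates an invariant (e.g. missing controls)."""


class InvalidCommunityError(SyncomicsError):
    """Community specification violates an invariant."""


class UnsupportedLayerError(SyncomicsError):
    """An omics-layer label is not one of the supported layers."""


class UnknownFeatureError(SyncomicsError):
    """A feature (gene/protein) is absent from the community reference."""


class EmptySampleError(SyncomicsError):
    """A sample has zero total counts where fractions are required."""


class InvalidIntensityError(SyncomicsError):
    """A negative intensity was encountered."""


class InsufficientDataError(SyncomicsError):
    """Too few shared samples/features for the requested statistic."""


class AlignmentError(SyncomicsError):
    """Two matrices do not share the same sample set."""


class PairingError(SyncomicsError):
    """A treated sample lacks its matched control."""


class ConsistencyError(SyncomicsError):
    """Inputs contradict each other (e.g. selected set not within universe)."""
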