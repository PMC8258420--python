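"""Exception hierarchy shared across the toolkit.

Domain errors (anything under :class:`BidsCuratorError`) map to CLI exit
code 1; usage errors are left to click and exit with code 2.
"""


class BidsCuratorError(Exception):
    """Base class for all domain errors raised by this package."""


class StoreError(BidsCuratorError):
    """Project store cannot be read or written (missing index, bad layout)."""


class IntegrityError(StoreError):
    """The stored hierarchy violates a structural invariant.

    The message names the offending container path (e.g. duplicate sibling
    labels).
    """


class NotFoundError(BidsCuratorError):
    """A container, file, or label addressed by the caller does not exist."""


class ImmutableMetadataError(BidsCuratorError):
    """Attempt to overwrite a write-protected metadata namespace.

    The ``dicom_header`` namespace is ground truth extracted from the
    scanner output and is never modified by any curation operation.
    """


class HeuristicError(BidsCuratorError):
    """A heuristic rule file is malformed or incomplete."""


class CurationError(BidsCuratorError):
    """A curation plan cannot be built or applied (e.g. path collisions)."""


class ExportError(BidsCuratorError):
    """A BIDS tree cannot be materialized on disk."""


class ConfigError(BidsCuratorError):
    """A synthetic fixture configuration is invalid."""
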