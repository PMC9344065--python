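"""Exception hierarchy for the codec.

``EncodeError`` covers failures while producing sequences (empty payload,
exhausted seed space); ``DecodeError`` covers failures while recovering bytes
from a pool. CLI commands map these onto exit codes (3 for data/format
problems, 4 for an undecodable pool).
"""


class DnaDropletError(Exception):
    """Base class for all package errors."""


class EncodeError(DnaDropletError):
    """Encoding cannot proceed (bad payload, exhausted seed space, ...)."""


class PoolExhaustedError(EncodeError):
    """A group's constraint-passing fragment pool is too small."""


class DecodeError(DnaDropletError):
    """Decoding cannot recover the payload."""


class RSDecodeError(DecodeError):
    """Reed-Solomon decoding failed (too many errors or inconsistent syndromes)."""


class UncorrectableSequenceError(DecodeError):
    """A sequence could not be restored to a constraint-valid codeword."""


class UnknownIndexError(DecodeError):
    """A sequence's index fragment is not in the reference-order table."""


class UndecodableGroupError(DecodeError):
    """A group's droplets do not reach full GF(2) rank."""


class MissingGroupsError(DecodeError):
    """One or more group ordinals are absent from the pool."""
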