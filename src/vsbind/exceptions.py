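"""Exception hierarchy for vsbind.

All errors derive from :class:`VSBindError` so callers can catch the whole
family; most also derive from ``ValueError`` because they signal bad inputs.
"""


class VSBindError(Exception):
    """Base class for all vsbind errors."""


class DimensionError(VSBindError, ValueError):
    """Invalid vector dimensionality, or operands with mismatched dims."""


class ParameterError(VSBindError, ValueError):
    """A numeric or mode parameter outside its valid range."""


class VocabularyError(VSBindError, KeyError):
    """A token name is missing from the vocabulary (or the vocabulary is empty)."""


class CapacityError(VSBindError, ValueError):
    """A buffer or tag family cannot hold the requested load at this dim."""


class StructureSpecError(VSBindError, ValueError):
    """A chunk layout is malformed (overlaps, bad positions, wrong kind)."""


class EmptyDependencyError(VSBindError, ValueError):
    """Salience filtering removed every token; nothing left to encode."""


class KeyStateError(VSBindError, ValueError):
    """A query key used in the wrong state (double inversion, level mismatch)."""


class CollisionError(VSBindError, RuntimeError):
    """Two stimuli mapped onto one gate trigger; raise the gate frequency."""
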