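"""Exception hierarchy for nsdfkit.

``NSDFError`` is the common base so callers can catch everything from this
package with one clause.  Argument-validation errors also derive from
``ValueError`` so they behave naturally in generic code.
"""


class NSDFError(Exception):
    """Base class for all nsdfkit errors."""


class InvalidArgumentError(NSDFError, ValueError):
    """An argument violates a documented precondition."""


class UnitError(InvalidArgumentError):
    """A unit string does not parse under the supported unit grammar."""


class VariantError(InvalidArgumentError):
    """A storage variant is illegal for the requested data category."""


class ShapeError(InvalidArgumentError):
    """Array shapes are inconsistent with the target dataset or scale."""


class ConflictError(NSDFError):
    """A write conflicts with content already present in the file."""


class StructureError(NSDFError):
    """The file does not have the expected NSDF group layout."""


class FormatError(NSDFError):
    """Stored data violates a format rule (e.g. interior NaN in padding)."""


class BrokenMappingError(NSDFError):
    """A source->data mapping points at a missing or inconsistent node."""


class IncompleteMetadataError(NSDFError):
    """Metadata required to interpret a dataset is absent."""
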