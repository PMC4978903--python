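"""Exception hierarchy.

``CiliamapError`` is the base for everything raised deliberately by this
package, so callers can catch one type at the CLI boundary.
"""


class CiliamapError(Exception):
    """Base class for all errors raised by ciliamap."""


class FormatError(CiliamapError):
    """A file does not conform to the expected interchange format."""


class ModelError(FormatError):
    """A gene model violates its structural invariants (named by gene_id)."""


class ContractError(CiliamapError):
    """An operation was invoked outside its precondition (pipeline misuse)."""


class ConfigError(CiliamapError):
    """A configuration value is missing, inconsistent, or out of range."""


class DataError(CiliamapError):
    """In-memory data violates a domain invariant (bad allele, negative depth, ...)."""


class ReferenceMismatchError(DataError):
    """A variant's REF allele disagrees with the genome sequence at its position."""


class SimulationError(CiliamapError):
    """A simulated cross could not satisfy the study design (e.g. too few assortants)."""
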