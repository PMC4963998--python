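"""Exception hierarchy for smartmeta.

Every user-facing failure raises a subclass of :class:`SmartError` so callers
(and the CLI) can catch one type.
"""


class SmartError(Exception):
    """Base class for all smartmeta errors."""


class TaxonomyParseError(SmartError):
    """Malformed taxonomy TSV row; the message names the line number."""


class TaxonomyConsistencyError(SmartError):
    """Duplicate record ids with conflicting lineages, or a species mapped to
    more than one (genus, class) pair."""


class TaxonomyLookupError(SmartError, KeyError):
    """Record id absent from the taxonomy table."""


class EncodingError(SmartError, ValueError):
    """Non-ACGT character (or wrong length) where a 2-bit encodable k-mer or
    prefix is required."""


class IndexBuildError(SmartError):
    """Reference set cannot be indexed (record missing from taxonomy, empty
    input, no indexable tiles)."""


class IndexIOError(SmartError):
    """Saving or loading a serialized index failed (missing shard file,
    checksum mismatch, malformed manifest)."""


class IndexCompatibilityError(SmartError):
    """Requested parameters do not match the parameters an index was built
    or serialized with."""


class QueryError(SmartError, ValueError):
    """Malformed lookup/search query (wrong k-mer length or alphabet)."""


class SearchInputError(SmartError):
    """Invalid read input to the searcher (e.g. duplicate read ids)."""


class ClassificationError(SmartError):
    """Inconsistent tally / match-set pair, or a matched species without a
    lineage."""


class EvaluationError(SmartError):
    """Truth table and classifications disagree on the read universe."""


class SimulationError(SmartError, ValueError):
    """Invalid community or read-simulation parameters."""
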