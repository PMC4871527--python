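"""Exception hierarchy for the neoburden pipeline."""


class PipelineError(Exception):
    """Base class for all neoburden errors."""


class FormatError(PipelineError):
    """A file does not conform to its declared dialect."""


class ParameterError(PipelineError, ValueError):
    """A parameter is outside its documented domain."""


class CoordinateError(PipelineError):
    """A position falls outside the sequence it indexes."""


class ReferenceMismatchError(PipelineError):
    """The wild-type residue in the protein disagrees with the mutation record."""


class UnresolvableVariantError(PipelineError):
    """A variant cannot be materialized (e.g. frameshift with no tail and no CDS)."""


class CoverageError(PipelineError):
    """Affinity predictions are missing for some (peptide, allele) pairs."""


class ConfigConflictError(PipelineError):
    """Mutually exclusive configuration options were both supplied."""
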