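"""Exception hierarchy shared across the package."""


class FunFamError(Exception):
    """Base class for all package errors."""


class FormatError(FunFamError):
    """Malformed input file (FASTA, OBO, TSV...)."""


class DataError(FunFamError):
    """Input is syntactically fine but scientifically invalid."""


class UsageError(FunFamError):
    """Operation called with arguments outside its contract."""


class IntegrityError(FunFamError):
    """A structural invariant (DAG acyclicity, tree shape) is violated."""


class ModelError(FunFamError):
    """A profile model cannot be built or used."""


class AnnotationError(FunFamError):
    """Annotation transfer is impossible (e.g. no annotated seeds)."""
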