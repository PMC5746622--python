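"""Exception hierarchy shared across the package."""


class SanopsError(Exception):
    """Base class for all package errors."""


class GraphValidationError(SanopsError):
    """A terminology graph violates a structural invariant."""


class LookupError_(SanopsError):
    """A concept, exam code, or fixture name could not be resolved."""


class ClassificationError(SanopsError):
    """No target region is resolvable for an exam mapping."""


class SpecError(SanopsError):
    """A generator or sampler was given an infeasible specification."""
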