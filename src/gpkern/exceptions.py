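"""Exception hierarchy used across the package."""


class GpkernError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(GpkernError, ValueError):
    """A simulation or model configuration violates its invariants."""


class InvalidDesignError(GpkernError, ValueError):
    """A cross/trial design is malformed (e.g. tester and line sets overlap)."""


class ShapeError(GpkernError, ValueError):
    """Dimension mismatch between conforming arrays."""


class AlignmentError(GpkernError, ValueError):
    """Record labels of two objects do not align."""


class MonomorphicLocusError(GpkernError, ValueError):
    """A locus with allele frequency 0 or 1 cannot be coded."""


class DegenerateInputError(GpkernError, ValueError):
    """Input is constant / all-zero / otherwise degenerate for the operation."""


class InvalidKernelError(GpkernError, ValueError):
    """A matrix fails the symmetry/PSD contract for kernels."""


class RecordLookupError(GpkernError, KeyError):
    """A requested record or parent id is unknown."""


class EstimationError(GpkernError, RuntimeError):
    """A model fit failed (singular system, non-finite values)."""


class DivergenceError(GpkernError, RuntimeError):
    """An iterative sampler or optimizer produced non-finite state."""


class ProblemMismatchError(GpkernError, ValueError):
    """A model's data modalities are not allowed by the prediction problem."""
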