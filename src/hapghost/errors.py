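"""Exception hierarchy shared by all hapghost modules."""


class HapghostError(Exception):
    """Base class for all errors raised by hapghost."""


class FormatError(HapghostError):
    """A file does not conform to its declared dialect."""


class ValidationError(HapghostError):
    """Parsed values violate a domain invariant (range, duplication, ...)."""


class UnsupportedPloidyError(FormatError):
    """A VCF genotype is not diploid."""


class DegenerateLocusError(HapghostError):
    """A locus is monomorphic, so LD or association is undefined."""


class DegeneratePredictorError(HapghostError):
    """A regression predictor is constant."""


class ConvergenceError(HapghostError):
    """Iterative fitting failed to converge (e.g. separation in logistic fits).

    Carries the iteration trace of coefficient vectors for diagnosis.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class CollinearityError(HapghostError):
    """The target predictor is (numerically) collinear with the adjustment set."""


class CapacityError(HapghostError):
    """An enumeration would exceed a configured cap (haplotype space, scan size)."""


class EmptyRegionError(HapghostError):
    """A genomic region filter matched no (polymorphic) SNPs."""


class UnknownSnpError(HapghostError, KeyError):
    """A SNP identifier was not found in the dataset."""
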