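"""Exception hierarchy shared across the package."""


class NeoprioError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NeoprioError):
    """A file could not be parsed or failed record-level validation."""


class HgvsParseError(NeoprioError):
    """A protein-level HGVS string could not be parsed at all."""


class UnsupportedVariantClass(NeoprioError):
    """Parseable HGVS, but not a single-residue missense substitution
    (nonsense, frameshift, synonymous, indel, extension)."""


class MissingPredictionError(NeoprioError):
    """A required (peptide, allele) pair is absent from the predictor."""


class MissingControlError(NeoprioError):
    """A plate group lacks the negative-control wells needed for
    background subtraction."""
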