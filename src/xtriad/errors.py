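"""Exception and warning types shared across the package."""


class XTriadError(Exception):
    """Base class for all package-specific errors."""


class MendelianError(XTriadError):
    """Haplotype subtraction produced an allele count outside {0, 1}.

    Signals a genotyping inconsistency; the offending family is reported
    and excluded from the current window.
    """


class MissingGenotypeError(XTriadError):
    """A genotype call required for phasing is missing."""


class NoninformativeFamilyError(XTriadError):
    """All three parental haplotypes are identical; the family carries no signal."""


class DegenerateWindowError(XTriadError):
    """Fewer than two common haplotypes: the likelihood-ratio test is undefined."""


class NonconvergenceError(XTriadError):
    """Newton-Raphson failed to converge within the iteration budget."""


class DimensionError(XTriadError):
    """Coefficient vector length does not match the model columns."""


class ConfigError(XTriadError):
    """Invalid simulation or scan configuration."""


class FormatError(XTriadError):
    """Malformed PED/MAP input line."""


class PedigreeError(XTriadError):
    """Family records cannot be resolved into a father/mother/affected-child triad."""


class SexCodeError(XTriadError):
    """A male carries a heterozygous X call."""


class EmptyPanelError(XTriadError):
    """No SNPs survive filtering."""


class SeparationWarning(UserWarning):
    """A fitted |beta| exceeds 10: monotone likelihood / quasi-separation."""
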