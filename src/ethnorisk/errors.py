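"""Exception hierarchy shared across the package."""


class EthnoriskError(Exception):
    """Base class for all package-specific errors."""


class PanelError(EthnoriskError):
    """Malformed or inconsistent SNP panel definition."""


class FrequencyTableError(EthnoriskError):
    """Invalid genotype-frequency data (schema, range or sum-to-one violations)."""


class UndefinedRelativeRiskError(EthnoriskError):
    """Relative risk undefined because the worldwide denominator frequency is zero."""


class EmptyMatrixError(EthnoriskError):
    """No SNP survived filtering; the relative-risk grid would be empty."""


class DegenerateProfileError(EthnoriskError):
    """A risk profile with fewer than two points has no curve area."""


class ConfigError(EthnoriskError):
    """Invalid run or simulation configuration."""
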