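"""Exception hierarchy shared across the pipeline."""


class TransientPopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TransientPopError):
    """A configuration value is invalid (non-finite, out of range...)."""


class ValidationError(TransientPopError):
    """Input data violate a contract (negative counts, wrong shape...)."""


class ParseError(TransientPopError):
    """A table could not be parsed; the message names the offending row."""


class DegenerateBinError(TransientPopError):
    """A five-year bin has zero population; the country-year is flagged
    for exclusion rather than silently producing NaN rates."""

    def __init__(self, country: str, year: int, bin_index: int):
        self.country = country
        self.year = year
        self.bin_index = bin_index
        super().__init__(
            f"zero population in bin {bin_index} for {country} {year}"
        )


class SeriesLookupError(TransientPopError, KeyError):
    """A referenced country-year does not exist in the dataset."""


class NonPerronError(TransientPopError):
    """The dominant eigenvalue has a non-negligible imaginary part, so the
    matrix cannot be treated as a valid population projection matrix."""
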