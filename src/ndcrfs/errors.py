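"""Exception types shared across the package."""


class InputError(ValueError):
    """Malformed or inconsistent user input (shape mismatches, bad parameters)."""


class DegenerateInputError(InputError):
    """Input is structurally valid but information-theoretically degenerate
    (e.g. a constant class column, or a zero entropy denominator)."""


class UnknownFeatureError(InputError, KeyError):
    """A feature identifier is not present in the dataset / candidate set."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the plain message
        return ValueError.__str__(self)
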