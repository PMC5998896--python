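"""Exception types shared across the package."""


class ScheduleError(ValueError):
    """An event schedule violates its invariants."""


class InvalidHistoryError(ValueError):
    """An evolutionary history is inconsistent with its schedule."""


class EnumerationCapError(ValueError):
    """Exhaustive enumeration would exceed the configured gene cap."""

    def __init__(self, required: int, cap: int):
        self.required = required
        self.cap = cap
        super().__init__(
            f"enumeration requires a gene cap of at least {required}, "
            f"but the cap is {cap}; pass gene_cap={required} to proceed"
        )


class BinMismatchError(ValueError):
    """Predicted distribution bins do not cover the observed histogram."""


class FitError(RuntimeError):
    """No valid optimum could be found."""
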