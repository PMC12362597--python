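"""Exception types shared across the package."""


class FedBatchError(Exception):
    """Base class for all package-specific errors."""


class InfeasibleStrategyError(FedBatchError):
    """A feed strategy cannot be realized under the given constraints.

    Raised e.g. when a linear feed ramp drives the feed rate to zero before
    the target feed volume is delivered, when the quasi-steady-state balance
    would require negative growth, or when a growth-arrested stage has zero
    substrate demand but feed volume left to deliver.
    """


class ConfigError(FedBatchError):
    """Invalid run configuration; ``errors`` lists every failed check."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))
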