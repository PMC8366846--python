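"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input table, tree, or network violates a structural invariant."""


class NetworkStructureError(ValidationError):
    """Raised when a river-network edge list is not a single-outlet dendritic DAG."""
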