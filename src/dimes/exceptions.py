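"""Exception hierarchy for the dimes package."""


class DimesError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DimesError, ValueError):
    """Malformed or inconsistent input (shape, symmetry, finiteness, sign)."""


class InvalidConnectivityError(DimesError, ValueError):
    """Connectivity matrix is not negative semidefinite within tolerance."""

    def __init__(self, worst_eigenvalue: float, tol: float):
        self.worst_eigenvalue = worst_eigenvalue
        super().__init__(
            f"connectivity matrix has a positive eigenvalue {worst_eigenvalue:.6g} "
            f"beyond tolerance {tol:.3g}; the Gaussian model is not normalizable"
        )


class DisconnectedError(DimesError, ValueError):
    """The coupling graph (or observed-pair graph) is not connected."""

    def __init__(self, components, what="coupling graph"):
        self.components = [sorted(c) for c in components]
        super().__init__(
            f"{what} is disconnected into {len(self.components)} components: "
            + "; ".join(str(c[:8]) + ("..." if len(c) > 8 else "") for c in self.components)
        )


class NotRealizableError(DimesError, ValueError):
    """A squared-distance matrix is not realizable by any Gaussian model."""


class ConvergenceError(DimesError, RuntimeError):
    """Optimization diverged; carries the error trace for post-mortem."""

    def __init__(self, message, error_trace):
        self.error_trace = error_trace
        super().__init__(message)


class UnidentifiableError(DimesError, ValueError):
    """The requested quantity is not identifiable from the given data."""
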