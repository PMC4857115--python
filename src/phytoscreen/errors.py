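"""Exception hierarchy shared across the package."""


class PhytoscreenError(Exception):
    """Base class for all package-specific errors."""


class StructureError(PhytoscreenError):
    """A molecular structure string could not be parsed.

    Carries the offending SMILES/pattern so callers can log or report it.
    """

    def __init__(self, structure: str, message: str = "unparseable structure"):
        self.structure = structure
        super().__init__(f"{message}: {structure!r}")


class ConfigurationError(PhytoscreenError):
    """Invalid configuration: missing column, bad pattern, size floor violated."""


class InputError(PhytoscreenError):
    """Structurally valid but unusable input (empty library, empty panel)."""


class ContractViolation(PhytoscreenError):
    """An internal precondition was violated (length mismatch, bad range)."""
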