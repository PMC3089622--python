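"""Exception hierarchy for phyloassembly."""


class PhyloAssemblyError(Exception):
    """Base class for all package errors."""


class NewickParseError(PhyloAssemblyError):
    """Malformed Newick input (includes position information when available)."""


class TreeValidationError(PhyloAssemblyError):
    """A phylogeny violates a structural invariant (duplicate tips, missing
    branch lengths, negative lengths)."""


class UnknownSpeciesError(PhyloAssemblyError, KeyError):
    """A community references a species that is not a tip of the phylogeny."""


class UndefinedStatisticError(PhyloAssemblyError):
    """A statistic is undefined for the given community size (e.g. MNND of a
    monoculture). Callers are expected to exclude such plots explicitly."""


class InfeasibleConstraintError(PhyloAssemblyError):
    """A null-model constraint cannot be satisfied (pool too small, required
    clade absent after exclusions)."""


class SchemaError(PhyloAssemblyError):
    """An input table does not match the expected column schema."""
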