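"""Exception hierarchy for rjtrl."""


class RJTRLError(Exception):
    """Base class for all rjtrl errors."""


class UnsupportedMolecule(RJTRLError):
    """Molecule cannot be represented as a reversible junction tree.

    Raised for macrocycles (rings with more than eight atoms), bridged ring
    pairs sharing more than two atoms, polycyclic systems whose fragment
    adjacency graph is not a tree, unparseable records, and fragments absent
    from an enforced closed vocabulary.
    """


class SiteError(RJTRLError):
    """Shared atoms are incompatible with a site-information record."""


class InvalidAssembly(RJTRLError):
    """Site information is incompatible with the node types during assembly."""


class RangeError(RJTRLError, ValueError):
    """Index outside a categorical space (word ids, site codes)."""


class ScoreError(RJTRLError):
    """A reward descriptor could not be computed."""


class AdapterError(RJTRLError):
    """An external docking engine failed."""
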