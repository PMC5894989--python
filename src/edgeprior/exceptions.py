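"""Exception hierarchy for edgeprior.

All package errors derive from :class:`EdgePriorError` so callers (and the
CLI) can distinguish validation failures from programming errors.
"""


class EdgePriorError(Exception):
    """Base class for all edgeprior errors."""


class TreeError(EdgePriorError):
    """Malformed, unparsable, or structurally invalid phylogeny."""


class SchemaError(EdgePriorError):
    """Tabular input violates its schema (missing columns, duplicates...)."""


class NotScorableError(EdgePriorError):
    """Red List category carries no Global Endangerment weight (DD/NE/EX/EW)."""


class UnimputableError(EdgePriorError):
    """Missing species with no present congener or confamiliar to impute from."""

    def __init__(self, species):
        self.species = sorted(species)
        super().__init__(
            "no present congener or confamiliar to impute from: "
            + ", ".join(self.species)
        )
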