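"""Exception types shared across the package."""


class EndescaleError(Exception):
    """Base class for package-specific errors."""


class EmptyCommunityError(EndescaleError, ValueError):
    """Raised when every taxon rasterizes to an empty range."""


class EmptySurfaceError(EndescaleError, ValueError):
    """Raised when an operation needs at least one occupied cell."""


class NewickParseError(EndescaleError, ValueError):
    """Raised on malformed Newick input or missing branch lengths."""


class NotUltrametricError(EndescaleError, ValueError):
    """Raised when a tree fails the ultrametricity tolerance."""
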