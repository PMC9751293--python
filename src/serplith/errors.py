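"""Exception types shared across the package."""


class SerplithError(Exception):
    """Base class for all package-specific errors."""


class MissingSpeciesError(KeyError, SerplithError):
    """A reaction references a species absent from the constants table."""

    def __init__(self, species: str):
        super().__init__(species)
        self.species = species

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"species {self.species!r} is not in the constants table"


class BalanceError(ValueError, SerplithError):
    """A reaction fails element or charge balance."""


class MissingConcentrationError(KeyError, SerplithError):
    """A solute participating in a reaction has no concentration in the
    site conditions (solutes never silently default to unit activity)."""

    def __init__(self, species: str, site: str):
        super().__init__(species)
        self.species = species
        self.site = site

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"no concentration for {self.species!r} in conditions for "
            f"site {self.site!r}"
        )


class ConfigError(ValueError, SerplithError):
    """Invalid or inconsistent configuration."""


class MotifParseError(ValueError, SerplithError):
    """Malformed motif pattern text."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position
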