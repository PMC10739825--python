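"""Exception hierarchy for derivid."""


class DerividError(Exception):
    """Base class for all derivid errors."""


class ParseError(DerividError):
    """A SMILES (or other structure input) could not be parsed."""


class UnknownElementError(DerividError):
    """A formula references an element missing from the mass table."""


class UnknownFixtureError(DerividError):
    """An unknown built-in fixture set was requested."""


class FormatError(DerividError):
    """An interchange file is malformed; the message names the line."""


class SiteOverflowError(DerividError):
    """Partial-product enumeration would exceed the reactive-site cap."""
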