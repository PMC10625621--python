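"""Exception hierarchy shared across the package."""


class NetcontrastError(Exception):
    """Base class for all package-specific errors."""


class CatalogFormatError(NetcontrastError):
    """A mutation-catalog file is malformed (missing column, bad dialect)."""


class EmptyCatalogError(NetcontrastError):
    """A mutation-catalog file contains no data rows."""


class InsufficientDataError(NetcontrastError):
    """Too few observations for the requested statistical test."""


class SeedError(NetcontrastError):
    """No usable seed genes in the reference network."""


class PipelineError(NetcontrastError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
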