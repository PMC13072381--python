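"""Exception hierarchy shared across the pipeline stages."""


class SpecklemapError(Exception):
    """Base class for all package errors."""


class CatalogError(SpecklemapError, KeyError):
    """Unknown genetic-model code requested from the segregation catalog."""


class ContractError(SpecklemapError, ValueError):
    """An operation precondition was violated."""


class DependencyError(SpecklemapError):
    """A pipeline stage is missing an upstream artifact."""

    def __init__(self, stage: str, artifact: str):
        self.stage = stage
        self.artifact = artifact
        super().__init__(
            f"stage '{stage}' requires missing upstream artifact '{artifact}'"
        )


class StageError(SpecklemapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
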