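"""Exception hierarchy for facesym."""


class FacesymError(Exception):
    """Base class for all facesym errors."""


class MissingLandmarkError(FacesymError):
    """A required landmark is absent from a landmark set."""

    def __init__(self, landmark: str, condition: str | None = None):
        self.landmark = landmark
        self.condition = condition
        where = f" in condition {condition}" if condition else ""
        super().__init__(f"missing landmark '{landmark}'{where}")


class GeometryError(FacesymError):
    """Degenerate or impossible landmark geometry."""


class SchemaError(FacesymError):
    """A landmark or metadata file does not match the documented schema."""


class ModelError(FacesymError):
    """A statistical model cannot be fitted on the given input."""
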