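"""Exception hierarchy for the wbdwi pipeline."""


class WbdwiError(Exception):
    """Base class for all pipeline errors."""


class ShapeMismatchError(WbdwiError):
    """Volumes that must share a grid do not."""


class MetadataError(WbdwiError):
    """A volume is missing required spatial metadata (spacing)."""


class ManifestError(WbdwiError):
    """Cohort manifest is malformed; message aggregates all problems found."""


class LabelError(ManifestError):
    """A response label is not one of the Lugano categories."""


class EmptyCohortError(ManifestError):
    """A cohort with zero patients was requested or loaded."""


class ParameterError(WbdwiError):
    """An operation was called with inconsistent parameters."""


class EmptyReferenceError(WbdwiError):
    """No positive voxels exist to define a threshold reference intensity."""


class EmptyMaskError(WbdwiError):
    """A threshold mask selected zero valid voxels."""


class UndersizeError(WbdwiError):
    """Too few observations for the requested statistic."""


class SingleClassError(WbdwiError):
    """ROC analysis requires both response classes to be present."""
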