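"""Exception hierarchy for the OCT pipeline."""


class OctliverError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(OctliverError, ValueError):
    """Invalid parameter value (non-positive dimension, bad rate, ...)."""


class FormatError(OctliverError, ValueError):
    """Missing or malformed container metadata."""


class IntegrityError(OctliverError, ValueError):
    """Container contents disagree with their metadata."""


class AllColumnsRemovedError(OctliverError, ValueError):
    """Every column of a B-scan was flagged as a reflection artifact.

    Caught by the C-scan pipeline and converted into a B-scan QC flag.
    """


class InfeasibleSplitError(OctliverError, ValueError):
    """A class has too few C-scans to build the requested CV plan."""


class LeakageError(OctliverError, ValueError):
    """Tiles of one C-scan appear in more than one partition of a run."""


class TrainingDataError(OctliverError, ValueError):
    """A training or validation partition does not contain both classes."""


class CompletenessError(OctliverError, ValueError):
    """A report is missing expected cross-validation runs."""
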