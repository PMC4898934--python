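"""Exception hierarchy and machine-readable failure codes.

Every per-cell quantification stage raises a subclass of
:class:`AnalysisError`; the pipeline maps each to a short failure code so a
single bad movie never aborts a batch.
"""


class AnalysisError(Exception):
    """Base class for quantification failures on a single cell/movie."""

    code = "analysis_error"


class ConfigurationError(AnalysisError):
    """Invalid preset or run configuration (e.g. movie too short for events)."""

    code = "configuration_error"


class OutOfBoundsError(AnalysisError):
    """A spot centroid falls outside the image during rendering."""

    code = "out_of_bounds"


class NoNEBDError(AnalysisError):
    """Geminin trace never crosses half-maximum with persistence."""

    code = "no_nebd"


class NoAnaphaseError(AnalysisError):
    """No frame qualifies as anaphase onset (poleward movement)."""

    code = "no_anaphase"


class NoMetaphaseError(AnalysisError):
    """Centroid spread never collapses onto a metaphase plate."""

    code = "no_metaphase"


class UndefinedScoreError(AnalysisError):
    """Clusteredness is undefined (no above-threshold kinetochore pixels)."""

    code = "undefined_score"


class InsufficientFootageError(AnalysisError):
    """Movie ends before the anaphase-error assessment offset."""

    code = "insufficient_footage"


class DegenerateSeriesWarning(UserWarning):
    """A series to be normalized is constant; all-zero output returned."""
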