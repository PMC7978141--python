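"""Exception hierarchy for montage design and evaluation."""


class TBAMontageError(Exception):
    """Base class for all package errors."""


class DomainError(TBAMontageError):
    """A scalp point lies outside the valid CPC domain (below the fiducial band,
    or farther than the snap tolerance from the surface)."""


class PoleDegeneracyError(TBAMontageError):
    """A CPC coordinate is undefined because the query point coincides with, or is
    collinear with, the anchoring fiducials (the poles of the parameterization)."""


class ConfigurationError(TBAMontageError):
    """Invalid user configuration: bad mesh/fiducials, optode counts exceeding the
    holder, degenerate population parameters, and similar."""


class VocabularyError(TBAMontageError):
    """An ROI label is not part of the atlas label vocabulary."""


class PlacementInfeasibleError(TBAMontageError):
    """The montage footprint does not fit on the valid scalp domain at the
    requested center/orientation."""


class ArrangementInfeasibleError(TBAMontageError):
    """No feasible arrangement exists: empty effective-location set, empty search
    space, or every sampled placement infeasible."""


class NumericalError(TBAMontageError):
    """An iterative routine (CPC inversion, grid relaxation) failed to converge."""
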