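"""Exception hierarchy for morphomap."""


class MorphomapError(Exception):
    """Base class for all morphomap errors."""


class OrientationError(MorphomapError, ValueError):
    """A deformation tensor reverses orientation (det F <= 0)."""


class DegenerateDeformationError(MorphomapError, ValueError):
    """A deformation tensor is singular or numerically near-singular."""


class IdentifiabilityError(MorphomapError, ValueError):
    """The landmark configuration cannot identify the model (e.g. collinear)."""


class OutOfDomainError(MorphomapError, ValueError):
    """A query point lies outside the lattice or field support."""


class ParameterError(MorphomapError, ValueError):
    """An invalid hyperparameter or configuration value."""
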