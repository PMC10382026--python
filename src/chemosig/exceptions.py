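"""Exception hierarchy."""


class ChemosigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChemosigError, ValueError):
    """Invalid simulation or pipeline configuration."""


class InputError(ChemosigError, ValueError):
    """Malformed or inconsistent user input (matrices, labels, files)."""


class AssemblyError(ChemosigError):
    """Candidate-panel assembly produced an empty or unusable panel."""


class ModelError(ChemosigError):
    """Classifier could not be fit (e.g. fewer than 3 usable genes)."""


class EvaluationError(ChemosigError):
    """Evaluation impossible (e.g. single-class cohort)."""
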