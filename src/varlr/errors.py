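"""Exception hierarchy.

Every externally visible failure mode has a distinct, named error so callers
(and the CLI) can categorize what went wrong.
"""


class VarlrError(Exception):
    """Base class for all package errors."""


class OntologyError(VarlrError):
    """Structural problem in the ontology graph or its annotations."""


class CyclicOntologyError(OntologyError):
    """The 'is a' relation contains a cycle; closures would not terminate."""


class UnknownTermError(OntologyError, KeyError):
    """A term ID was requested that does not exist in the graph."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return Exception.__str__(self)


class NoPhenotypesError(VarlrError):
    """No usable phenotype terms remain after resolution against the graph."""


class MissingSampleError(VarlrError):
    """A sample named in the pedigree/config is absent from the VCF."""


class PedigreeError(VarlrError):
    """Malformed PED input or no identifiable proband."""


class CalibrationError(VarlrError):
    """Posterior calibration cannot be fit (class too small or degenerate)."""


class ConfigError(VarlrError):
    """Invalid run configuration."""
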