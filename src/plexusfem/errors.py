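"""Exception hierarchy for the plexus FEM pipeline."""


class PlexusError(Exception):
    """Base class for all pipeline errors."""


class GeometryInfeasibleError(PlexusError):
    """The requested anatomy cannot be realised as a valid planar domain.

    Raised e.g. when two root strips overlap on the cord surface or a
    root pair fails to converge into its trunk.  The message names the
    offending roots.
    """


class MeshError(PlexusError):
    """Mesh generation or validation failed (tagged with the region)."""


class RankDeficiencyError(PlexusError):
    """The constrained stiffness matrix is singular (rigid-body modes remain)."""


class SolverError(PlexusError):
    """Linear solve failed or produced non-finite results."""


class TaggingError(PlexusError):
    """A named node/edge set required by post-processing is empty or missing."""
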