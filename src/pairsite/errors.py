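"""Exception types shared across the package."""


class PairsiteError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(PairsiteError):
    """A PDB file could not be read or contained no usable residues."""


class EmptySelectionError(PairsiteError):
    """A chain filter matched no residues."""


class FeatureError(PairsiteError):
    """A node- or edge-feature computation failed for a residue."""


class GraphError(PairsiteError):
    """A residue graph could not be constructed."""


class DegenerateGeometryError(FeatureError):
    """Backbone atoms are missing or collinear; no plane normal exists."""


class EmbeddingError(PairsiteError):
    """An embedding provider failed to produce vectors."""


class SamplingError(PairsiteError):
    """Negative downsampling is impossible (e.g. no positive pairs)."""


class SyntheticSpecError(PairsiteError):
    """A synthetic-complex specification is geometrically infeasible."""
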