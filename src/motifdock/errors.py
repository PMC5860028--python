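"""Exception hierarchy shared across the docking pipeline."""


class MotifDockError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MotifDockError, ValueError):
    """Bad user input: illegal motif characters, mismatched shapes, unknown residues."""


class EmptyStructureError(MotifDockError):
    """A structure file contained no usable ATOM records."""


class MissingBackboneError(MotifDockError):
    """A residue window lacks one of the N, CA, C, O backbone atoms."""


class GridFitError(MotifDockError):
    """Atoms fall outside the energy grid, or the ligand cannot fit without wrap-around."""


class EmptyLibraryError(MotifDockError):
    """The motif search produced zero fragments even after all generalization moves.

    Carries the iteration ``history`` (pattern rendering, match count) so the
    caller can see how the search progressed before failing.
    """

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = list(history or [])
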