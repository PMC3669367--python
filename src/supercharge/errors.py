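"""Exception hierarchy for the supercharge package."""


class SuperchargeError(Exception):
    """Base class for all package errors."""


class ParseError(SuperchargeError):
    """A structure file could not be parsed into a usable model."""


class StructureError(SuperchargeError):
    """A structure is empty or otherwise invalid after filtering."""


class LookupSiteError(SuperchargeError, KeyError):
    """A referenced residue site does not exist in the structure."""


class UsageError(SuperchargeError, ValueError):
    """Invalid combination of options or an invalid precondition."""


class UndefinedValueError(SuperchargeError):
    """A per-residue metric is undefined for this residue (e.g. glycine AvNAPSA)."""


class ValidationError(SuperchargeError):
    """Input data (resfile, fixture spec, comparison inputs) failed validation."""


class UnreachableChargeError(SuperchargeError):
    """The requested net charge cannot be reached.

    Attributes
    ----------
    best_achievable : int
        The most extreme net charge the available moves can reach.
    final_refweights : dict | None
        For energy-mode ramps, the reference energies at the iteration cap.
    """

    def __init__(self, message, best_achievable, final_refweights=None):
        super().__init__(message)
        self.best_achievable = best_achievable
        self.final_refweights = final_refweights


class SearchSpaceError(SuperchargeError):
    """Exhaustive enumeration refused because the search space is too large."""
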