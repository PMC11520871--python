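"""Exception hierarchy for traumacast."""


class TraumacastError(Exception):
    """Base class for all traumacast errors."""


class ValidationError(TraumacastError):
    """A record, rule set, or scenario failed validation."""


class EmptySelectionError(TraumacastError):
    """Wave selection found no eligible record; the sample contributes nothing."""


class MetaAnalysisError(TraumacastError):
    """Meta-analysis could not be run (e.g. fewer than two pooled samples)."""


class DerivationError(TraumacastError):
    """Group-estimate derivation failed (missing source, bad mode...)."""


class CycleError(DerivationError):
    """Borrow/average dependencies contain a cycle."""


class ScenarioError(TraumacastError):
    """An exposure scenario is malformed or infeasible."""
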