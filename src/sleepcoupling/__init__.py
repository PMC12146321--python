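"""Sleep-stage-stratified brain-heart-gut coupling analysis.

Quantifies the coupling of brain (EEG band power), heart (HRV spectral power)
and gut (bowel-sound band power) activity across sleep stages with the maximal
information coefficient, together with a synthetic polysomnography generator
that injects known, stage-dependent cross-system coupling for validation.
"""

from .mic import MICParams, MICResult, compute_mic, exhaustive_mic_oracle

__version__ = "0.1.0"

__all__ = [
    "MICParams",
    "MICResult",
    "compute_mic",
    "exhaustive_mic_oracle",
    "SleepCouplingModel",
]


def __getattr__(name):  # lazy: the model facade pulls in the heavy signal stack
    if name in ("SleepCouplingModel", "SleepCouplingResults"):
        from . import model

        return getattr(model, name)
    raise AttributeError(name)
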