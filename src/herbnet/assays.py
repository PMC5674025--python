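"""Small closed-form quantities used in downstream study reports.

Conventions: the caliper tumor-volume formula assumes width <= length;
relative qPCR expression follows the double-delta-Ct rule with the
difference taken treated-minus-control, so a *lower* treated dCt (more
transcript) yields a fold change above 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError


@dataclass(frozen=True)
class QpcrSample:
    """Cycle thresholds for a target gene and its housekeeping control."""

    ct_target: float
    ct_housekeeping: float

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target), ("ct_housekeeping", self.ct_housekeeping)):
            if not (v > 0 and v == v and v != float("inf")):
                raise DomainError(f"{name} must be finite and positive, got {v}")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_housekeeping


def tumor_volume(width: float, length: float) -> float:
    """Caliper volume in mm^3: width^2 x length / 2."""
    if width < 0 or length < 0:
        raise DomainError("width and length must be non-negative")
    return width**2 * length / 2.0


def ddct_fold_change(treated: QpcrSample, control: QpcrSample) -> float:
    """Relative expression 2^-(dCt_treated - dCt_control)."""
    return 2.0 ** -(treated.dct - control.dct)


def wound_healing_rate(width_0: float, width_t: float) -> float:
    """Fraction of the original wound distance recovered at time t."""
    if width_0 <= 0:
        raise DomainError("original wound width must be positive")
    if width_t < 0 or width_t > width_0:
        raise DomainError("recovered width outside [0, width_0] (wound grew?)")
    return (width_0 - width_t) / width_0
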