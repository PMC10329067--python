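"""Tetramer-staining positivity rule for CD8+ T-cell priming readouts.

A culture primed against a candidate peptide is called positive when the
percentage of tetramer-positive cells among CD8+ cells exceeds 1% (strict
by default) and is at least threefold the negative-control percentage
(non-strict by default; the control is a peptide the responder cells were
never primed for). A zero control satisfies the fold condition vacuously.
Both comparators are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .errors import ValidationError


@dataclass
class TetramerReadout:
    """One peptide's tetramer-staining result."""

    peptide: str
    pct_tetramer_pos: float
    pct_negative_control: float
    n_wells_positive: int = 0
    n_wells_total: int = 0

    def __post_init__(self) -> None:
        for name in ("pct_tetramer_pos", "pct_negative_control"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"{name} must lie in [0, 100], got {v} for {self.peptide}")
        if self.n_wells_positive > self.n_wells_total:
            raise ValidationError(
                f"n_wells_positive > n_wells_total for {self.peptide}")


def tetramer_call(readout: TetramerReadout, config: PipelineConfig) -> bool:
    """Apply the > 1% floor and the threefold-over-control rule."""
    signal = readout.pct_tetramer_pos
    control = readout.pct_negative_control
    if config.tetramer_floor_strict:
        floor_ok = signal > config.tetramer_min_pct
    else:
        floor_ok = signal >= config.tetramer_min_pct
    threshold = config.tetramer_fold * control
    fold_ok = signal > threshold if config.tetramer_fold_strict else signal >= threshold
    return bool(floor_ok and fold_ok)
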