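"""Quantitation helpers for confirmatory assays: qPCR and mRNA stability.

Relative expression follows the 2^-ddCt convention (target Ct normalized to a
housekeeping gene, then to an unstimulated reference sample).  mRNA decay is
the ratio of transcript level after one hour of transcription blockade
(actinomycin D) to the level at blockade onset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CtRecord:
    """Threshold cycles of the target and housekeeping gene in one sample."""

    sample_id: str
    target_ct: float
    housekeeping_ct: float

    def __post_init__(self) -> None:
        for name in ("target_ct", "housekeeping_ct"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.housekeeping_ct


def ddct_relative_expression(sample: CtRecord, reference: CtRecord) -> float:
    """Relative expression 2^-((dCt_sample) - (dCt_reference)).

    The reference measured against itself gives exactly 1.
    """
    return 2.0 ** -(sample.delta_ct - reference.delta_ct)


def mrna_decay_ratio(level_after, level_before):
    """Transcript level after / before transcription blockade.

    Accepts scalars or array-likes (broadcast elementwise).  Values in (0, 1]
    indicate decay; ratios above 1 are anomalous and logged, not rejected.
    """
    after = np.asarray(level_after, dtype=float)
    before = np.asarray(level_before, dtype=float)
    if (after <= 0).any() or (before <= 0).any():
        raise ValueError("mRNA levels must be strictly positive")
    ratio = after / before
    n_anomalous = int((ratio > 1).sum())
    if n_anomalous:
        logger.warning(
            "%d decay ratio(s) above 1 (apparent gain under transcription block)",
            n_anomalous,
        )
    return float(ratio) if ratio.ndim == 0 else ratio


def is_significant_fold(relative_expression: float, fold_threshold: float = 2.0) -> bool:
    """Flag a relative-expression change beyond the fold-significance band."""
    if relative_expression <= 0:
        raise ValueError("relative expression must be positive")
    if not fold_threshold > 1:
        raise ValueError("fold_threshold must be > 1")
    return (
        relative_expression >= fold_threshold
        or relative_expression <= 1 / fold_threshold
    )
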