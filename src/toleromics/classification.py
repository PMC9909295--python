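"""Per-gene response classification for tolerized macrophages.

The central idea: a gene's response to a *secondary* stimulation must be judged
against the expression it already carries over from the *primary* (tolerizing)
stimulation, not only against naive cells.  For one gene, one timepoint and one
stimulation sequence A1 -> A2, four RPM values are needed:

    baseline   0  -> 0    unstimulated cells
    primary    0  -> A2   naive response to the second agonist
    residual   A1 -> 0    carry-over from the tolerizing stimulation
    secondary  A1 -> A2   response of tolerized cells

Five fold-ratio indices are derived and a deterministic rule table assigns one
of eight per-timepoint subclasses; the pair of timepoint calls is then rolled
up into an overall tolerizeable (T) / non-tolerizeable (NT) assessment, with
the sustained-expression (SE) and normo/hyper-inducible (NH) NT subcategories.
A fold difference greater than ``fold_threshold`` (default 2) counts as a real
change; all "more than"-type comparisons are strict, their complements
non-strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .counts_io import RpmMatrix
from .design import Condition, Stimulus, Timepoint


class TimepointCall(str, Enum):
    """Per-timepoint response subclass."""

    UNINDUCIBLE = "uninducible"
    HYPOINDUCIBLE = "hypoinducible"
    NORMOINDUCIBLE = "normoinducible"
    HYPERINDUCIBLE = "hyperinducible"
    LATE = "late"
    HYPERINDUCIBLE_2 = "hyperinducible-2"
    DE_NOVO = "de-novo"
    UNRESPONSIVE = "unresponsive"


class Tolerance(str, Enum):
    T = "T"
    NT = "NT"
    UNCLASSIFIED = "unclassified"


class Subcategory(str, Enum):
    SE = "SE"
    NH = "NH"
    OTHER_NT = "other-NT"
    NONE = "none"


#: subclasses that make a gene NT when present at >= 1 timepoint
NT_CALLS = frozenset(
    {
        TimepointCall.HYPOINDUCIBLE,
        TimepointCall.NORMOINDUCIBLE,
        TimepointCall.HYPERINDUCIBLE,
        TimepointCall.HYPERINDUCIBLE_2,
        TimepointCall.DE_NOVO,
    }
)
#: subclasses a T gene may show at the *other* timepoint
T_COMPANION_CALLS = frozenset(
    {TimepointCall.UNINDUCIBLE, TimepointCall.UNRESPONSIVE, TimepointCall.LATE}
)


@dataclass(frozen=True)
class ResponseQuad:
    """The four RPM values one classification needs (all > 0)."""

    baseline: float
    primary: float
    residual: float
    secondary: float

    def __post_init__(self) -> None:
        for name in ("baseline", "primary", "residual", "secondary"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class RatioIndices:
    """The five fold-ratio indices.

    ``i_sec_vs_base == i_secondary * i_residual`` holds exactly by algebra.
    """

    i_primary: float  # primary / baseline: naive inducibility
    i_residual: float  # residual / baseline: carry-over from 1st stimulation
    i_secondary: float  # secondary / residual: response on top of carry-over
    i_sec_vs_prim: float  # secondary / primary
    i_sec_vs_base: float  # secondary / baseline


@dataclass
class ClassificationConfig:
    """Tunable parameters of the rule engine.

    fold_threshold: fold ratio above which a difference counts (> 1).
    baseline_mode: "time_matched" uses the 0->0 library of the same timepoint;
        "pooled" uses the geometric mean of the 1 h and 4 h 0->0 libraries.
    se_requires_both_1h: strict reading of SE criterion (i) — both the 1 h
        residual and the 1 h secondary expression must exceed
        fold_threshold x baseline (a lenient either/or mode when False).
    repressed_flag: annotate genes whose naive response is below
        1/fold_threshold at either timepoint.
    """

    fold_threshold: float = 2.0
    baseline_mode: str = "time_matched"
    se_requires_both_1h: bool = True
    repressed_flag: bool = True

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValueError("fold_threshold must be > 1")
        if self.baseline_mode not in ("time_matched", "pooled"):
            raise ValueError("baseline_mode must be 'time_matched' or 'pooled'")


@dataclass(frozen=True)
class GeneCall:
    """Full classification of one gene for one stimulation sequence."""

    call_1h: TimepointCall
    call_4h: TimepointCall
    overall: Tolerance
    subcategory: Subcategory
    repressed: bool = False


def ratio_indices(quad: ResponseQuad) -> RatioIndices:
    """Compute the five fold-ratio indices from a response quad."""
    return RatioIndices(
        i_primary=quad.primary / quad.baseline,
        i_residual=quad.residual / quad.baseline,
        i_secondary=quad.secondary / quad.residual,
        i_sec_vs_prim=quad.secondary / quad.primary,
        i_sec_vs_base=quad.secondary / quad.baseline,
    )


def classify_timepoint(
    quad: ResponseQuad, cfg: ClassificationConfig | None = None
) -> TimepointCall:
    """Assign one of the eight per-timepoint subclasses.

    Rule order: (1) a gene is primary-inducible when the naive response
    exceeds the fold threshold; (2) primary-inducible genes are uninducible
    when the secondary response (over the residual level) does not exceed the
    threshold, otherwise hypo-/normo-/hyperinducible according to whether the
    secondary fold is weaker than, comparable to, or stronger than the primary
    fold (the threshold band defines "comparable"); (3) genes not
    primary-inducible but elevated in the residual culture are late, or
    hyperinducible-2 when restimulation raises them further; (4) the remainder
    are inducible de novo when only the full sequence induces them, else
    unresponsive.
    """
    cfg = cfg or ClassificationConfig()
    theta = cfg.fold_threshold
    idx = ratio_indices(quad)
    if idx.i_primary > theta:
        if idx.i_secondary <= theta:
            return TimepointCall.UNINDUCIBLE
        ratio_of_folds = idx.i_secondary / idx.i_primary
        if ratio_of_folds < 1 / theta:
            return TimepointCall.HYPOINDUCIBLE
        if ratio_of_folds > theta:
            return TimepointCall.HYPERINDUCIBLE
        return TimepointCall.NORMOINDUCIBLE
    if idx.i_residual > theta:
        if idx.i_secondary > theta:
            return TimepointCall.HYPERINDUCIBLE_2
        return TimepointCall.LATE
    if idx.i_secondary > theta and idx.i_sec_vs_base > theta:
        return TimepointCall.DE_NOVO
    return TimepointCall.UNRESPONSIVE


def is_sustained_expression(
    quad_1h: ResponseQuad,
    quad_4h: ResponseQuad,
    cfg: ClassificationConfig | None = None,
) -> bool:
    """Sustained-expression (SE) pattern over the 1 h / 4 h quad pair.

    (i) 1 h after reculture the expression carried over from the tolerizing
    stimulation exceeds fold_threshold x baseline (with or without the second
    agonist; the strict default requires both); (ii) without agonist it falls
    more than fold_threshold-fold between 1 h and 4 h; (iii) with agonist it
    is sustained at 4 h within the fold_threshold band of the 1 h carry-over.
    """
    cfg = cfg or ClassificationConfig()
    theta = cfg.fold_threshold
    res_1h_up = quad_1h.residual > theta * quad_1h.baseline
    sec_1h_up = quad_1h.secondary > theta * quad_1h.baseline
    crit_i = (res_1h_up and sec_1h_up) if cfg.se_requires_both_1h else (
        res_1h_up or sec_1h_up
    )
    crit_ii = quad_4h.residual < quad_1h.residual / theta
    sustained = quad_4h.secondary / quad_1h.residual
    crit_iii = (1 / theta) < sustained < theta
    return crit_i and crit_ii and crit_iii


def overall_call(
    call_1h: TimepointCall,
    call_4h: TimepointCall,
    quad_1h: ResponseQuad,
    quad_4h: ResponseQuad,
    cfg: ClassificationConfig | None = None,
) -> GeneCall:
    """Roll the two timepoint calls up into the overall T/NT assessment.

    NT: any response to secondary stimulation (hypo-, normo-, hyper-,
    hyperinducible-2 or de novo) at >= 1 timepoint, irrespective of the other.
    T: uninducible at both timepoints, or at one with unresponsive/late at the
    other.  Genes matching neither rule (e.g. unresponsive at both timepoints)
    stay unclassified-for-tolerance rather than being forced into T.
    """
    cfg = cfg or ClassificationConfig()
    calls = (call_1h, call_4h)
    if any(c in NT_CALLS for c in calls):
        overall = Tolerance.NT
        if is_sustained_expression(quad_1h, quad_4h, cfg):
            sub = Subcategory.SE
        elif any(
            c in (TimepointCall.NORMOINDUCIBLE, TimepointCall.HYPERINDUCIBLE)
            for c in calls
        ):
            sub = Subcategory.NH
        else:
            sub = Subcategory.OTHER_NT
    elif TimepointCall.UNINDUCIBLE in calls and all(
        c in T_COMPANION_CALLS for c in calls
    ):
        overall, sub = Tolerance.T, Subcategory.NONE
    else:
        overall, sub = Tolerance.UNCLASSIFIED, Subcategory.NONE
    theta = cfg.fold_threshold
    repressed = cfg.repressed_flag and (
        quad_1h.primary / quad_1h.baseline < 1 / theta
        or quad_4h.primary / quad_4h.baseline < 1 / theta
    )
    return GeneCall(call_1h, call_4h, overall, sub, repressed)


# ---------------------------------------------------------------------------
# Whole-matrix classification


def _condition_values(rpm: RpmMatrix, cond: Condition) -> np.ndarray:
    libs = rpm.libraries_for(cond)
    if not libs:
        raise ValueError(f"RPM matrix has no library for condition {cond.label}")
    if len(libs) == 1:
        return rpm.rpm[libs[0]].to_numpy(dtype=float)
    # replicate libraries for one condition: geometric mean
    return np.exp(np.log(rpm.rpm[libs].to_numpy(dtype=float)).mean(axis=1))


def _baseline_values(
    rpm: RpmMatrix, timepoint: Timepoint, cfg: ClassificationConfig
) -> np.ndarray:
    if cfg.baseline_mode == "time_matched":
        return _condition_values(
            rpm, Condition(Stimulus.NONE, Stimulus.NONE, timepoint)
        )
    b1 = _condition_values(rpm, Condition(Stimulus.NONE, Stimulus.NONE, Timepoint.H1))
    b4 = _condition_values(rpm, Condition(Stimulus.NONE, Stimulus.NONE, Timepoint.H4))
    return np.sqrt(b1 * b4)


def sequence_quads(
    rpm: RpmMatrix,
    a1: Stimulus,
    a2: Stimulus,
    cfg: ClassificationConfig | None = None,
) -> dict[Timepoint, pd.DataFrame]:
    """Per-timepoint table of (baseline, primary, residual, secondary) values."""
    cfg = cfg or ClassificationConfig()
    out = {}
    for t in Timepoint:
        out[t] = pd.DataFrame(
            {
                "baseline": _baseline_values(rpm, t, cfg),
                "primary": _condition_values(rpm, Condition(Stimulus.NONE, a2, t)),
                "residual": _condition_values(rpm, Condition(a1, Stimulus.NONE, t)),
                "secondary": _condition_values(rpm, Condition(a1, a2, t)),
            },
            index=rpm.gene_ids,
        )
    return out


INDEX_COLUMNS = ["i_primary", "i_residual", "i_secondary", "i_sec_vs_prim", "i_sec_vs_base"]


def classify_sequence(
    rpm: RpmMatrix,
    a1: Stimulus,
    a2: Stimulus,
    cfg: ClassificationConfig | None = None,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Classify every gene for the stimulation sequence ``a1 -> a2``.

    Returns one row per gene with the timepoint calls, the overall T/NT
    assessment, the NT subcategory, the five indices at each timepoint and a
    REPRESSED flag.  ``genes`` optionally restricts to a filtered subset.
    The table carries ``attrs['coverage']``: the fraction of classified genes
    receiving an overall T or NT assessment.
    """
    cfg = cfg or ClassificationConfig()
    quads = sequence_quads(rpm, a1, a2, cfg)
    gene_ids = rpm.gene_ids
    if genes is not None:
        keep = gene_ids.isin(set(genes))
        gene_ids = gene_ids[keep]
        quads = {t: df.loc[gene_ids] for t, df in quads.items()}

    rows = []
    for i, gene in enumerate(gene_ids):
        q1 = ResponseQuad(*quads[Timepoint.H1].iloc[i])
        q4 = ResponseQuad(*quads[Timepoint.H4].iloc[i])
        c1 = classify_timepoint(q1, cfg)
        c4 = classify_timepoint(q4, cfg)
        call = overall_call(c1, c4, q1, q4, cfg)
        row = {
            "gene_id": gene,
            "sequence": f"{a1.value}->{a2.value}",
            "call_1h": c1.value,
            "call_4h": c4.value,
            "overall": call.overall.value,
            "subcategory": call.subcategory.value,
            "repressed": call.repressed,
        }
        for t, q in (("1h", q1), ("4h", q4)):
            idx = ratio_indices(q)
            for col in INDEX_COLUMNS:
                row[f"{col}_{t}"] = getattr(idx, col)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene_id")
    n = len(table)
    table.attrs["coverage"] = (
        float((table["overall"] != Tolerance.UNCLASSIFIED.value).sum() / n) if n else 0.0
    )
    table.attrs["config"] = {
        "fold_threshold": cfg.fold_threshold,
        "baseline_mode": cfg.baseline_mode,
        "se_requires_both_1h": cfg.se_requires_both_1h,
        "comparisons": "strict '>' for fold differences, non-strict complement",
    }
    return table


def foster_nt_criterion(
    rpm: RpmMatrix,
    a1: Stimulus,
    a2: Stimulus,
    timepoint: Timepoint = Timepoint.H4,
    cfg: ClassificationConfig | None = None,
) -> set[str]:
    """Single-timepoint NT definition of earlier tolerance studies.

    Among genes primary-inducible at ``timepoint``, selects those whose
    expression after secondary stimulation is equal to or greater than after
    primary stimulation (secondary / primary >= 1, boundary inclusive).  It
    ignores the residual expression carried over from the tolerizing stimulus,
    and therefore overestimates the set of genuinely responsive genes.
    """
    cfg = cfg or ClassificationConfig()
    baseline = _baseline_values(rpm, timepoint, cfg)
    primary = _condition_values(rpm, Condition(Stimulus.NONE, a2, timepoint))
    secondary = _condition_values(rpm, Condition(a1, a2, timepoint))
    inducible = primary / baseline > cfg.fold_threshold
    selected = inducible & (secondary / primary >= 1.0)
    return set(rpm.gene_ids[selected])


def class_members(table: pd.DataFrame, cls: str) -> set[str]:
    """Gene ids of one class in a classification table (T, NT, SE, NH...)."""
    if cls in (Tolerance.T.value, Tolerance.NT.value):
        return set(table.index[table["overall"] == cls])
    if cls in (Subcategory.SE.value, Subcategory.NH.value, Subcategory.OTHER_NT.value):
        return set(table.index[table["subcategory"] == cls])
    raise ValueError(f"unknown gene class: {cls!r}")
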