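"""Independent oracles used by the test suite.

These re-derive expected results through a different route than the library
(closed forms, literal transcriptions of verbal rules) and must stay
independent of the code paths they check.
"""

from __future__ import annotations


def rule_table_oracle(baseline: float, primary: float, residual: float,
                      secondary: float, theta: float = 2.0) -> str:
    """Literal transcription of the verbal subclassification rules.

    Deliberately structured as a flat decision list over the raw RPM values
    (no shared helpers with the library).
    """
    induced_by_primary = primary > theta * baseline
    induced_on_restim = secondary > theta * residual
    elevated_after_reculture = residual > theta * baseline
    if induced_by_primary:
        if not induced_on_restim:
            return "uninducible"
        primary_fold = primary / baseline
        secondary_fold = secondary / residual
        if secondary_fold * theta < primary_fold:
            return "hypoinducible"
        if secondary_fold > primary_fold * theta:
            return "hyperinducible"
        return "normoinducible"
    if elevated_after_reculture:
        if induced_on_restim:
            return "hyperinducible-2"
        return "late"
    if induced_on_restim and secondary > theta * baseline:
        return "de-novo"
    return "unresponsive"


def overall_oracle(call_1h: str, call_4h: str) -> str:
    """Literal transcription of the verbal T / NT definitions."""
    nt = {"hypoinducible", "normoinducible", "hyperinducible",
          "hyperinducible-2", "de-novo"}
    if call_1h in nt or call_4h in nt:
        return "NT"
    pair = {call_1h, call_4h}
    if "uninducible" in pair and pair <= {"uninducible", "unresponsive", "late"}:
        return "T"
    return "unclassified"


def chi2_closed_form(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square on a 2x2 table, N(ad-bc)^2 / product of margins."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom
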