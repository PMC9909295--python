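"""TFBS and gene-set enrichment between two gene classes (typically T vs NT).

The enrichment score for a transcription-factor binding site (or any gene set)
between gene sets 1 and 2 is

    ES = log2((n1 + 0.5) / (N1 + 0.5)) - log2((n2 + 0.5) / (N2 + 0.5)),

where n1/n2 are genes carrying the site and N1/N2 the set sizes; the +0.5
offsets keep ES finite at zero counts.  Significance is a Pearson chi-square
on the 2x2 presence table.  Binding-site presence derives from a precomputed
gene x TF similarity-score table (scores in [0, 1], e.g. a CiiiDER export):
a site is present when its score reaches a cutoff, and the cutoff is chosen
automatically from a grid in [0.85, 1] where the T-vs-NT difference is most
significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reproducibility import chi2_2x2

DEFAULT_CUTOFF_GRID = tuple(np.round(np.arange(0.85, 1.0 + 1e-9, 0.01), 2))


@dataclass
class BindingTable:
    """Gene x transcription-factor matrix of TFBS similarity scores.

    Score 0 denotes complete mismatch (or absence of any candidate site),
    score 1 an exact match to the ideal binding sequence.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.empty:
            raise ValueError("binding table is empty")
        v = self.scores.to_numpy(dtype=float)
        if ((v < 0) | (v > 1)).any():
            raise ValueError("binding scores must lie in [0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def tf_ids(self) -> list[str]:
        return list(self.scores.columns)


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    n1: int
    N1: int
    n2: int
    N2: int
    es: float
    chi2: float
    p_value: float
    tested: bool
    cutoff: float = float("nan")


def _validate_counts(n1: int, N1: int, n2: int, N2: int) -> None:
    if min(n1, N1, n2, N2) < 0:
        raise ValueError("counts must be non-negative")
    if N1 < 1 or N2 < 1:
        raise ValueError("set sizes must be >= 1")
    if n1 > N1 or n2 > N2:
        raise ValueError("n must not exceed its set size N")


def enrichment_score(n1: int, N1: int, n2: int, N2: int) -> float:
    """Log2 proportion-difference score with +0.5 offsets (finite for n = 0)."""
    _validate_counts(n1, N1, n2, N2)
    return math.log2((n1 + 0.5) / (N1 + 0.5)) - math.log2((n2 + 0.5) / (N2 + 0.5))


def enrichment_test(
    n1: int, N1: int, n2: int, N2: int, yates: bool = False
) -> tuple[float, float, bool]:
    """Pearson chi-square on {(n1, N1-n1), (n2, N2-n2)}.

    Returns (chi2, p_value, tested); a zero-margin table is skipped with
    tested=False and (0.0, 1.0).
    """
    _validate_counts(n1, N1, n2, N2)
    if (n1 + n2 == 0) or ((N1 - n1) + (N2 - n2) == 0):
        return 0.0, 1.0, False
    chi2, p = chi2_2x2(n1, N1 - n1, n2, N2 - n2, yates=yates)
    return chi2, p, True


def scan_cutoff(
    binding: BindingTable,
    set1: Iterable[str],
    set2: Iterable[str],
    grid: Sequence[float] = DEFAULT_CUTOFF_GRID,
    min_presence: float = 0.10,
    min_es: float = 1.0,
    max_p: float = 0.01,
    yates: bool = False,
) -> pd.DataFrame:
    """Per-TF enrichment of set1 vs set2 at the most significant score cutoff.

    For each TF and each cutoff in ``grid``, presence is score >= cutoff
    (inclusive); the reported cutoff minimizes the chi-square p-value, ties
    broken toward the largest (most stringent) cutoff.  The
    ``passes_filters`` column applies the reporting filters: site present in
    at least ``min_presence`` of one set, ES > ``min_es`` and p < ``max_p``
    (evaluated at the chosen cutoff).
    """
    set1, set2 = set(set1), set(set2)
    if not set1 or not set2:
        raise ValueError("gene sets must be non-empty")
    universe = set(binding.gene_ids)
    missing = (set1 | set2) - universe
    if missing:
        raise ValueError(
            f"{len(missing)} genes absent from the binding table, "
            f"e.g. {sorted(missing)[:3]}"
        )
    if not len(grid):
        raise ValueError("cutoff grid is empty")
    grid_arr = np.asarray(sorted(grid), dtype=float)
    s1 = binding.scores.loc[sorted(set1)].to_numpy(dtype=float)
    s2 = binding.scores.loc[sorted(set2)].to_numpy(dtype=float)
    N1, N2 = len(set1), len(set2)
    rows = []
    for j, tf in enumerate(binding.tf_ids):
        # presence counts per cutoff, vectorized over the grid
        n1_grid = (s1[:, j][:, None] >= grid_arr[None, :]).sum(axis=0)
        n2_grid = (s2[:, j][:, None] >= grid_arr[None, :]).sum(axis=0)
        stats_grid = [
            enrichment_test(int(n1), N1, int(n2), N2, yates=yates)
            for n1, n2 in zip(n1_grid, n2_grid)
        ]
        p_grid = np.array([s[1] for s in stats_grid])
        # min p; among ties, the largest cutoff
        best = len(p_grid) - 1 - int(np.argmin(p_grid[::-1]))
        n1, n2 = int(n1_grid[best]), int(n2_grid[best])
        chi2, p, tested = stats_grid[best]
        es = enrichment_score(n1, N1, n2, N2)
        passes = (
            (n1 / N1 >= min_presence or n2 / N2 >= min_presence)
            and es > min_es
            and tested
            and p < max_p
        )
        rows.append(
            {
                "tf_id": tf,
                "cutoff": float(grid_arr[best]),
                "n1": n1,
                "N1": N1,
                "n2": n2,
                "N2": N2,
                "es": es,
                "chi2": chi2,
                "p_value": p,
                "tested": tested,
                "passes_filters": passes,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["p_value", "tf_id"])
        .set_index("tf_id")
    )


def set_overrepresentation(
    gene_set: Iterable[str],
    class_a: Iterable[str],
    class_b: Iterable[str],
    set_id: str = "gene_set",
    yates: bool = False,
) -> EnrichmentResult:
    """Over-representation of a named gene set in class_a vs class_b."""
    gene_set, class_a, class_b = set(gene_set), set(class_a), set(class_b)
    if class_a & class_b:
        raise ValueError("gene classes overlap; they must be disjoint")
    if not class_a or not class_b:
        raise ValueError("gene classes must be non-empty")
    n1, N1 = len(gene_set & class_a), len(class_a)
    n2, N2 = len(gene_set & class_b), len(class_b)
    chi2, p, tested = enrichment_test(n1, N1, n2, N2, yates=yates)
    return EnrichmentResult(
        set_id=set_id,
        n1=n1,
        N1=N1,
        n2=n2,
        N2=N2,
        es=enrichment_score(n1, N1, n2, N2),
        chi2=chi2,
        p_value=p,
        tested=tested,
    )


def read_binding_table(path: str | Path) -> BindingTable:
    """Tab-separated gene x TF similarity-score matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return BindingTable(scores=df.astype(float))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets
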