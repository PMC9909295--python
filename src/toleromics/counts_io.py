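"""Count-table I/O, transcript aggregation, gene filtering and RPM scaling.

Raw inputs are tab-separated tables (first column: gene or transcript id, one
column per library) together with a sample sheet mapping each library to its
experimental condition.  Counts for transcript variants of one gene are summed,
genes are filtered by abundance (and optionally to a protein-coding list), and
reads-per-million (RPM) values are computed after replacing zero counts with
ones so that every downstream fold ratio is defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import Condition, Stimulus, Timepoint

logger = logging.getLogger(__name__)

SAMPLE_SHEET_COLUMNS = [
    "library_id",
    "experiment_id",
    "first_stimulus",
    "second_stimulus",
    "timepoint",
]


@dataclass
class CountMatrix:
    """Raw integer counts (genes x libraries) for one experiment.

    ``counts`` is a DataFrame indexed by gene id with one column per library;
    ``conditions`` maps each library id to its :class:`Condition`.
    """

    counts: pd.DataFrame
    conditions: dict[str, Condition]
    experiment_id: str = "exp1"

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise ValueError("count matrix is empty")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate gene ids, e.g. {dup}")
        missing = [l for l in self.counts.columns if l not in self.conditions]
        if missing:
            raise ValueError(f"libraries without a condition: {missing}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    def libraries_for(self, condition: Condition) -> list[str]:
        return [l for l in self.counts.columns if self.conditions[l] == condition]


@dataclass
class RpmMatrix:
    """Reads-per-million values, all strictly positive by construction."""

    rpm: pd.DataFrame
    conditions: dict[str, Condition]
    experiment_id: str = "exp1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rpm.empty:
            raise ValueError("RPM matrix is empty")
        if (self.rpm.to_numpy() <= 0).any():
            raise ValueError("RPM values must be strictly positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.rpm.index

    def libraries_for(self, condition: Condition) -> list[str]:
        return [l for l in self.rpm.columns if self.conditions[l] == condition]


@dataclass
class GeneFilterSpec:
    """Abundance / annotation filter for genes.

    A gene is retained when, in every experiment (or any, if
    ``require_all_experiments`` is false), at least ``min_libraries`` libraries
    show at least ``min_raw_count`` raw counts — the boundary is inclusive —
    and, when ``coding_gene_list`` is given, the gene is on that list.
    """

    min_raw_count: int = 50
    min_libraries: int = 1
    require_all_experiments: bool = True
    coding_gene_list: set[str] | None = None

    def __post_init__(self) -> None:
        if self.min_raw_count < 0:
            raise ValueError("min_raw_count must be >= 0")
        if self.min_libraries < 1:
            raise ValueError("min_libraries must be >= 1")


def aggregate_transcripts_to_genes(
    transcript_counts: CountMatrix, transcript_to_gene: Mapping[str, str]
) -> CountMatrix:
    """Sum counts of transcript variants belonging to the same gene.

    Transcripts absent from the mapping are dropped (with a logged count);
    their reads are excluded from library totals.
    """
    if not transcript_to_gene:
        raise ValueError("transcript-to-gene mapping is empty")
    mapped = transcript_counts.counts.index.isin(transcript_to_gene.keys())
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        logger.warning(
            "dropping %d transcripts absent from the transcript-to-gene mapping",
            n_unmapped,
        )
    sub = transcript_counts.counts.loc[mapped]
    gene_index = sub.index.map(transcript_to_gene.__getitem__)
    summed = sub.groupby(gene_index, sort=True).sum()
    summed.index.name = transcript_counts.counts.index.name
    return CountMatrix(
        counts=summed,
        conditions=dict(transcript_counts.conditions),
        experiment_id=transcript_counts.experiment_id,
    )


def filter_genes(
    counts_per_experiment: Sequence[CountMatrix], spec: GeneFilterSpec | None = None
) -> set[str]:
    """Select genes by raw abundance across experiments and by annotation."""
    spec = spec or GeneFilterSpec()
    if not counts_per_experiment:
        raise ValueError("no count matrices given")
    universe = counts_per_experiment[0].counts.index
    for cm in counts_per_experiment[1:]:
        if not universe.equals(cm.counts.index):
            raise ValueError("count matrices do not share the same gene universe")
    per_exp = []
    for cm in counts_per_experiment:
        n_passing = (cm.counts >= spec.min_raw_count).sum(axis=1)
        per_exp.append(n_passing >= spec.min_libraries)
    ok = pd.concat(per_exp, axis=1)
    keep = ok.all(axis=1) if spec.require_all_experiments else ok.any(axis=1)
    genes = set(universe[keep])
    if spec.coding_gene_list is not None:
        genes &= set(spec.coding_gene_list)
    return genes


def compute_rpm(counts: CountMatrix) -> RpmMatrix:
    """Reads-per-million with zero counts replaced by ones beforehand.

    Library totals are taken after the zero replacement, so every column sums
    to exactly 1e6 and every entry is strictly positive.
    """
    c = counts.counts.to_numpy(dtype=float)
    c_prime = np.where(c == 0, 1.0, c)
    totals = c_prime.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("library with non-positive total after zero replacement")
    rpm = pd.DataFrame(
        1e6 * c_prime / totals,
        index=counts.counts.index,
        columns=counts.counts.columns,
    )
    return RpmMatrix(
        rpm=rpm,
        conditions=dict(counts.conditions),
        experiment_id=counts.experiment_id,
        metadata={"zero_replacement": "zeros->1 before totals", "scale": 1e6},
    )


def cross_experiment_correlation(rpm1: RpmMatrix, rpm2: RpmMatrix) -> pd.Series:
    """Pearson correlation of log2 RPM between synonymous libraries.

    Libraries are paired by condition; returns one coefficient per condition
    present in both experiments, indexed by the condition label.
    """
    if not rpm1.rpm.index.equals(rpm2.rpm.index):
        raise ValueError("RPM matrices do not share the same gene universe")
    out: dict[str, float] = {}
    for cond in sorted(set(rpm1.conditions.values()) & set(rpm2.conditions.values())):
        libs1 = rpm1.libraries_for(cond)
        libs2 = rpm2.libraries_for(cond)
        for l1, l2 in zip(libs1, libs2):
            x = np.log2(rpm1.rpm[l1].to_numpy())
            y = np.log2(rpm2.rpm[l2].to_numpy())
            out[cond.label] = float(np.corrcoef(x, y)[0, 1])
    if not out:
        raise ValueError("no pairable conditions between the two experiments")
    return pd.Series(out, name="pearson_r_log2rpm")


# ---------------------------------------------------------------------------
# Tab-separated I/O


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a genes-x-libraries TSV, first column as index, '#' lines skipped."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise ValueError(f"empty table: {path}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet is missing column(s): {', '.join(missing)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sheet.to_csv(path, sep="\t", index=False)


def _condition_from_row(row: pd.Series) -> Condition:
    return Condition(
        Stimulus(row["first_stimulus"]),
        Stimulus(row["second_stimulus"]),
        Timepoint(row["timepoint"]),
    )


def load_count_matrices(
    counts_path: str | Path, samples_path: str | Path
) -> list[CountMatrix]:
    """Load one :class:`CountMatrix` per experiment listed in the sample sheet."""
    table = read_table(counts_path)
    sheet = read_sample_sheet(samples_path)
    unknown = [l for l in sheet["library_id"] if l not in table.columns]
    if unknown:
        raise ValueError(f"sample sheet lists libraries absent from counts: {unknown}")
    matrices = []
    for exp_id, grp in sheet.groupby("experiment_id", sort=True):
        conditions = {
            row["library_id"]: _condition_from_row(row) for _, row in grp.iterrows()
        }
        matrices.append(
            CountMatrix(
                counts=table[list(conditions)],
                conditions=conditions,
                experiment_id=str(exp_id),
            )
        )
    return matrices


def read_transcript_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: transcript id, gene id."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("transcript-to-gene mapping needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_gene_list(path: str | Path) -> set[str]:
    """One gene identifier per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}
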