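"""Synthetic two-experiment count matrices with known gene archetypes.

The generator emulates the 18-condition x 2-experiment design with genes drawn
from response archetypes (tolerized, sustained-expression, normo-/hyper-
inducible, late, hyperinducible-2, de novo, constitutive, low-expressed).
Counts follow a gamma-Poisson (negative-binomial) model,
variance = mu + dispersion * mu^2, around per-condition expected means

    mu[g, l] = base[g] * fold[archetype(g), condition(l)]
               * size_factor[l] * 2^eps[g, experiment(l)],

where base[g] is a per-gene log-normal baseline (a gene property shared by
both experiments) and eps a per-gene, per-experiment log2-normal factor shared
across all libraries of that experiment — producing the strong but imperfect
cross-experiment correlations typical of replicate experiments from one donor.

Because read depth is what it is, induced genes take up library share at the
expense of everything else; to keep the designed fold profiles exact on the
RPM scale, the large constitutive background archetype absorbs that extra
transcript mass (its expected fold is lowered per condition so that the
expected library total is identical in every condition).  Archetype fold
profiles are built from the classifier's fold threshold theta with wide
margins, so each archetype lands strictly inside its intended rule region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .classification import Subcategory, TimepointCall, Tolerance
from .counts_io import SAMPLE_SHEET_COLUMNS, CountMatrix
from .design import Condition, Stimulus, Timepoint, all_conditions


class Archetype(str, Enum):
    TOLERIZED = "tolerized"
    SUSTAINED = "sustained"
    NORMO_NT = "normo-nt"
    HYPER_NT = "hyper-nt"
    LATE = "late"
    HYPER2 = "hyper2"
    DE_NOVO = "de-novo"
    CONSTITUTIVE = "constitutive"
    LOW_EXPRESSED = "low-expressed"


@dataclass(frozen=True)
class ArchetypeProfile:
    """Expected fold over baseline for each of the 18 conditions.

    ``baseline_weight`` scales the archetype's baseline mean relative to
    ``SimulationSpec.baseline_mean`` (induced immune genes sit below, the
    housekeeping background above, the transcriptome-average expression).
    """

    name: Archetype
    fold_profile: Mapping[Condition, float]
    baseline_weight: float = 1.0

    def __post_init__(self) -> None:
        missing = [c.label for c in all_conditions() if c not in self.fold_profile]
        if missing:
            raise ValueError(f"{self.name}: fold profile missing {missing}")
        if any(f <= 0 for f in self.fold_profile.values()):
            raise ValueError(f"{self.name}: folds must be positive")


def _profile(
    name: Archetype,
    primary: float,
    residual_1h: float,
    residual_4h: float,
    secondary_1h: float,
    secondary_4h: float,
    weight: float,
) -> ArchetypeProfile:
    """Fold profile from the five response parameters, agonist-symmetric.

    Baseline conditions get fold 1, naive stimulation ``primary``, reculture
    without agonist the residual folds, and any tolerize-then-restimulate
    combination (homologous or cross) the secondary folds.
    """
    folds: dict[Condition, float] = {}
    for c in all_conditions():
        if c.first is Stimulus.NONE and c.second is Stimulus.NONE:
            f = 1.0
        elif c.first is Stimulus.NONE:
            f = primary
        elif c.second is Stimulus.NONE:
            f = residual_1h if c.timepoint is Timepoint.H1 else residual_4h
        else:
            f = secondary_1h if c.timepoint is Timepoint.H1 else secondary_4h
        folds[c] = f
    return ArchetypeProfile(name=name, fold_profile=folds, baseline_weight=weight)


def default_archetype_profiles(theta: float = 2.0) -> dict[Archetype, ArchetypeProfile]:
    """Archetype fold profiles with >= theta-fold margins to every rule boundary.

    ``strong`` (theta^4, 16 at the default threshold) is the canonical induced
    fold; ``mid`` (theta^2) a clearly elevated but sub-maximal level.
    """
    if not theta > 1:
        raise ValueError("theta must be > 1")
    strong = theta**4
    mid = theta**2
    return {
        # induced by naive stimulation, carry-over decays, no secondary response
        Archetype.TOLERIZED: _profile(Archetype.TOLERIZED, strong, mid, mid, mid, mid, 1.0),
        # carry-over stays high at 1 h, collapses without agonist by 4 h,
        # but restimulation sustains it at the 1 h level
        Archetype.SUSTAINED: _profile(
            Archetype.SUSTAINED, strong, strong, mid, strong, strong, 1.0
        ),
        # responds to restimulation with the same fold as naive cells
        Archetype.NORMO_NT: _profile(
            Archetype.NORMO_NT, strong, mid, mid, strong * mid, strong * mid, 1.0
        ),
        # responds to restimulation theta^2-fold stronger than naive cells
        Archetype.HYPER_NT: _profile(
            Archetype.HYPER_NT, strong, mid, mid, strong * mid**2, strong * mid**2, 1.0
        ),
        # not induced acutely, high only after 24 h + reculture
        Archetype.LATE: _profile(Archetype.LATE, 1.0, strong, strong, strong, strong, 1.0),
        # late gene pushed further up by restimulation
        Archetype.HYPER2: _profile(
            Archetype.HYPER2, 1.0, strong, strong, strong * mid, strong * mid, 1.0
        ),
        # induced only by the full tolerize-then-stimulate sequence
        Archetype.DE_NOVO: _profile(Archetype.DE_NOVO, 1.0, 1.0, 1.0, strong, strong, 1.0),
        # flat housekeeping background carrying most of the library mass
        Archetype.CONSTITUTIVE: _profile(
            Archetype.CONSTITUTIVE, 1.0, 1.0, 1.0, 1.0, 1.0, 60.0
        ),
        # flat and below the abundance filter
        Archetype.LOW_EXPRESSED: _profile(
            Archetype.LOW_EXPRESSED, 1.0, 1.0, 1.0, 1.0, 1.0, 0.015
        ),
    }


#: classification outcome each archetype is built to produce (homologous sequence)
EXPECTED_CALLS: dict[Archetype, tuple[TimepointCall, TimepointCall, Tolerance, Subcategory]] = {
    Archetype.TOLERIZED: (
        TimepointCall.UNINDUCIBLE, TimepointCall.UNINDUCIBLE, Tolerance.T, Subcategory.NONE,
    ),
    Archetype.SUSTAINED: (
        TimepointCall.UNINDUCIBLE, TimepointCall.HYPOINDUCIBLE, Tolerance.NT, Subcategory.SE,
    ),
    Archetype.NORMO_NT: (
        TimepointCall.NORMOINDUCIBLE, TimepointCall.NORMOINDUCIBLE, Tolerance.NT, Subcategory.NH,
    ),
    Archetype.HYPER_NT: (
        TimepointCall.HYPERINDUCIBLE, TimepointCall.HYPERINDUCIBLE, Tolerance.NT, Subcategory.NH,
    ),
    Archetype.LATE: (
        TimepointCall.LATE, TimepointCall.LATE, Tolerance.UNCLASSIFIED, Subcategory.NONE,
    ),
    Archetype.HYPER2: (
        TimepointCall.HYPERINDUCIBLE_2, TimepointCall.HYPERINDUCIBLE_2,
        Tolerance.NT, Subcategory.OTHER_NT,
    ),
    Archetype.DE_NOVO: (
        TimepointCall.DE_NOVO, TimepointCall.DE_NOVO, Tolerance.NT, Subcategory.OTHER_NT,
    ),
    Archetype.CONSTITUTIVE: (
        TimepointCall.UNRESPONSIVE, TimepointCall.UNRESPONSIVE,
        Tolerance.UNCLASSIFIED, Subcategory.NONE,
    ),
    Archetype.LOW_EXPRESSED: (
        TimepointCall.UNRESPONSIVE, TimepointCall.UNRESPONSIVE,
        Tolerance.UNCLASSIFIED, Subcategory.NONE,
    ),
}

DEFAULT_N_GENES: dict[Archetype, int] = {
    Archetype.TOLERIZED: 300,
    Archetype.SUSTAINED: 150,
    Archetype.NORMO_NT: 80,
    Archetype.HYPER_NT: 50,
    Archetype.LATE: 200,
    Archetype.HYPER2: 50,
    Archetype.DE_NOVO: 50,
    Archetype.CONSTITUTIVE: 1000,
    Archetype.LOW_EXPRESSED: 120,
}


@dataclass
class SimulationSpec:
    """Study conditions of a simulated two-experiment run.

    baseline_mean: expected baseline count of an average-weight gene.
    baseline_log2_sd: per-gene log-normal spread of baselines (gene property,
        shared between experiments).
    dispersion: negative-binomial overdispersion (variance = mu + d * mu^2);
        0 degenerates to Poisson.
    between_experiment_sd: log2 sd of the per-gene experiment factor.
    library_size_factors: optional depth multiplier per library id.
    theta: fold threshold the archetype profiles are built against.
    """

    n_genes_per_archetype: Mapping[Archetype, int] = field(
        default_factory=lambda: dict(DEFAULT_N_GENES)
    )
    baseline_mean: float = 300.0
    baseline_log2_sd: float = 1.0
    dispersion: float = 0.01
    between_experiment_sd: float = 0.25
    library_size_factors: Mapping[str, float] | None = None
    theta: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0 or self.between_experiment_sd < 0 or self.baseline_log2_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        n_total = sum(self.n_genes_per_archetype.values())
        if n_total <= 0:
            raise ValueError("at least one gene must be requested")
        if any(n < 0 for n in self.n_genes_per_archetype.values()):
            raise ValueError("gene counts must be non-negative")


def build_design(experiment_ids: tuple[str, str] = ("exp1", "exp2")) -> pd.DataFrame:
    """Sample sheet covering all 18 conditions in each of two experiments."""
    rows = []
    for exp in experiment_ids:
        for c in all_conditions():
            rows.append(
                {
                    "library_id": f"{exp}_{c.first.value}-{c.second.value}_{c.timepoint.value}",
                    "experiment_id": exp,
                    "first_stimulus": c.first.value,
                    "second_stimulus": c.second.value,
                    "timepoint": c.timepoint.value,
                }
            )
    return pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)


def _buffered_folds(
    spec: SimulationSpec, profiles: dict[Archetype, ArchetypeProfile]
) -> dict[Archetype, dict[Condition, float]]:
    """Lower the constitutive folds so expected library mass is constant.

    For each condition c the extra expected mass contributed by responsive
    genes, sum_g w[g] * (fold[g, c] - 1), is subtracted from the constitutive
    pool: its fold becomes b_c = 1 - extra_c / constitutive_mass.
    """
    n = spec.n_genes_per_archetype
    const_mass = n.get(Archetype.CONSTITUTIVE, 0) * profiles[
        Archetype.CONSTITUTIVE
    ].baseline_weight
    folds = {a: dict(profiles[a].fold_profile) for a in n}
    if const_mass == 0:
        return folds
    for c in all_conditions():
        extra = sum(
            n[a] * profiles[a].baseline_weight * (profiles[a].fold_profile[c] - 1.0)
            for a in n
            if a is not Archetype.CONSTITUTIVE
        )
        b = 1.0 - extra / const_mass
        if b <= 0.05:
            raise ValueError(
                "constitutive background too small to absorb induced transcript "
                f"mass at condition {c.label} (buffer fold {b:.3f})"
            )
        folds[Archetype.CONSTITUTIVE][c] = b
    return folds


def generate_counts(
    spec: SimulationSpec | None = None,
) -> tuple[CountMatrix, CountMatrix, pd.Series]:
    """Simulate both experiments; returns (exp1, exp2, truth labels).

    Output is bitwise-reproducible for a fixed spec (including its seed).
    """
    spec = spec or SimulationSpec()
    profiles = default_archetype_profiles(spec.theta)
    unknown = [a for a in spec.n_genes_per_archetype if a not in profiles]
    if unknown:
        raise ValueError(f"no profile for archetype(s): {unknown}")
    folds = _buffered_folds(spec, profiles)
    rng = np.random.default_rng(spec.seed)

    archetypes: list[Archetype] = []
    for a in Archetype:  # fixed enum order for reproducibility
        archetypes.extend([a] * spec.n_genes_per_archetype.get(a, 0))
    n_genes = len(archetypes)
    gene_ids = [f"SIMG{i:05d}" for i in range(n_genes)]
    truth = pd.Series([a.value for a in archetypes], index=gene_ids, name="archetype")

    weights = np.array([profiles[a].baseline_weight for a in archetypes])
    base = (
        spec.baseline_mean
        * weights
        * 2.0 ** rng.normal(0.0, spec.baseline_log2_sd, size=n_genes)
    )

    sheet = build_design()
    matrices = []
    for exp_id, grp in sheet.groupby("experiment_id", sort=True):
        eps = 2.0 ** rng.normal(0.0, spec.between_experiment_sd, size=n_genes)
        cols = {}
        conditions = {}
        for _, row in grp.iterrows():
            lib = row["library_id"]
            cond = Condition(
                Stimulus(row["first_stimulus"]),
                Stimulus(row["second_stimulus"]),
                Timepoint(row["timepoint"]),
            )
            conditions[lib] = cond
            size = 1.0
            if spec.library_size_factors is not None:
                size = float(spec.library_size_factors.get(lib, 1.0))
            mu = base * eps * size
            mu = mu * np.array([folds[a][cond] for a in archetypes])
            if spec.dispersion == 0:
                cols[lib] = rng.poisson(mu)
            else:
                r = 1.0 / spec.dispersion
                p = r / (r + mu)
                cols[lib] = rng.negative_binomial(r, p)
        counts = pd.DataFrame(cols, index=gene_ids, dtype=np.int64)
        counts.index.name = "gene_id"
        matrices.append(
            CountMatrix(counts=counts, conditions=conditions, experiment_id=str(exp_id))
        )
    return matrices[0], matrices[1], truth
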