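"""Synthetic-data generators with the statistical structure the analysis
stages assume, so every stage runs and is testable at desk scale.

Three generators: fragment-analysis trace cohorts (per-cell Poisson step
model of repeat expansion aggregated into peak-height histograms),
negative-binomial count matrices for the four genotype groups with planted
dysregulated / rescued / exacerbated gene classes, and per-mouse staining
intensities linearly coupled to true expansion indices. All are pure
functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import GENOTYPE_GROUPS, CountMatrix, SampleMeta
from .instability import PeakTrace

__all__ = [
    "TraceSimParams",
    "CountSimParams",
    "TruthLabels",
    "simulate_trace_cohort",
    "simulate_count_matrix",
    "simulate_intensities",
]

GENE_CLASSES = (
    "null",
    "q111_up",
    "q111_down",
    "ko_up",
    "ko_down",
    "rescued_up",
    "rescued_down",
    "exacerbated",
)


@dataclass(frozen=True)
class TraceSimParams:
    """Per-cell expansion model: a cell is stable with probability
    ``stable_fraction``, otherwise gains ``step_size`` repeat units per event
    with the event count Poisson(rate * age). The analytic expected index is
    ``(1 - stable_fraction) * rate * age_months * step_size``.
    """

    n_mice_per_group: int = 5
    genotype_rate: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 2.0, "KO": 1.6}
    )
    age_months: float = 5.0
    stable_fraction: float = 0.0
    n_cells: int = 10_000
    modal_repeat: int = 111
    height_noise_cv: float = 0.0
    step_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(rate < 0 for rate in self.genotype_rate.values()):
            raise ValueError("expansion rates must be nonnegative")
        if not 0.0 <= self.stable_fraction <= 1.0:
            raise ValueError("stable_fraction must be in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.height_noise_cv < 0:
            raise ValueError("height_noise_cv must be nonnegative")
        if self.step_size < 1:
            raise ValueError("step_size must be >= 1")

    def expected_index(self, genotype: str) -> float:
        return (
            (1.0 - self.stable_fraction)
            * self.genotype_rate[genotype]
            * self.age_months
            * self.step_size
        )


@dataclass(frozen=True)
class CountSimParams:
    """Planted-class NB count design over the four genotype groups.

    ``fractions`` allocates genes to effect classes (remainder is null).
    Rescued genes are shifted by +/- ``lfc_magnitude`` (log2) in the
    disease/wild-type group only and fully revert to baseline in the
    double mutant; exacerbated genes shift a further ``lfc_magnitude`` in
    the same direction in the double mutant (total 2x).
    """

    n_genes: int = 2000
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {g: 8 for g in GENOTYPE_GROUPS}
    )
    baseline_mean_log: tuple[float, float] = (7.0, 1.5)
    dispersion: float = 0.1
    fractions: Mapping[str, float] = field(default_factory=dict)
    lfc_magnitude: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - {
            "q111_up",
            "q111_down",
            "ko_up",
            "ko_down",
            "rescued",
            "exacerbated",
        }
        if unknown:
            raise ValueError(f"unknown fraction keys: {sorted(unknown)}")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be nonnegative")
        if sum(self.fractions.values()) > 1.0 + 1e-12:
            raise ValueError("fractions must sum to <= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if self.lfc_magnitude <= 0:
            raise ValueError("lfc_magnitude must be positive")
        missing = set(GENOTYPE_GROUPS) - set(self.group_sizes)
        if missing:
            raise ValueError(f"group_sizes missing groups: {sorted(missing)}")


@dataclass(frozen=True)
class TruthLabels:
    """Ground truth emitted alongside simulated data."""

    gene_class: Mapping[str, str] | None = None
    mouse_expected_index: Mapping[str, float] | None = None
    mouse_genotype: Mapping[str, str] | None = None

    def genes_of_class(self, label: str) -> tuple[str, ...]:
        if self.gene_class is None:
            raise ValueError("no gene labels present")
        return tuple(g for g, c in self.gene_class.items() if c == label)

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.gene_class), "class": list(self.gene_class.values())}
        )


def simulate_trace_cohort(
    params: TraceSimParams,
) -> tuple[list[PeakTrace], TruthLabels]:
    """Simulate one fragment-analysis trace per mouse across genotype groups."""
    rng = np.random.default_rng(params.seed)
    traces: list[PeakTrace] = []
    expected: dict[str, float] = {}
    genotype: dict[str, str] = {}
    for geno in params.genotype_rate:
        lam = params.genotype_rate[geno] * params.age_months
        for i in range(params.n_mice_per_group):
            mouse_id = f"{geno}_m{i + 1:02d}"
            unstable = rng.random(params.n_cells) >= params.stable_fraction
            changes = np.zeros(params.n_cells, dtype=np.int64)
            changes[unstable] = (
                rng.poisson(lam, size=int(unstable.sum())) * params.step_size
            )
            lengths, counts = np.unique(
                params.modal_repeat + changes, return_counts=True
            )
            heights = counts.astype(float)
            if params.height_noise_cv > 0:
                sigma2 = np.log1p(params.height_noise_cv**2)
                heights = heights * rng.lognormal(
                    mean=-sigma2 / 2.0,
                    sigma=np.sqrt(sigma2),
                    size=heights.size,
                )
            traces.append(
                PeakTrace(mouse_id, dict(zip(lengths.tolist(), heights)))
            )
            expected[mouse_id] = params.expected_index(geno)
            genotype[mouse_id] = geno
    return traces, TruthLabels(
        mouse_expected_index=expected, mouse_genotype=genotype
    )


_CLASS_SHIFTS: dict[str, dict[str, float]] = {
    # per-class multiplier of lfc_magnitude, keyed by genotype group
    "q111_up": {"Q111_WT": 1, "Q111_KO": 1},
    "q111_down": {"Q111_WT": -1, "Q111_KO": -1},
    "ko_up": {"WT_KO": 1, "Q111_KO": 1},
    "ko_down": {"WT_KO": -1, "Q111_KO": -1},
    "rescued_up": {"Q111_WT": 1},
    "rescued_down": {"Q111_WT": -1},
    "exacerbated_up": {"Q111_WT": 1, "Q111_KO": 2},
    "exacerbated_down": {"Q111_WT": -1, "Q111_KO": -2},
}


def simulate_count_matrix(
    params: CountSimParams,
) -> tuple[CountMatrix, SampleMeta, TruthLabels]:
    """Simulate NB counts with planted effect classes for the four groups.

    Library sizes are equal in expectation (no per-sample depth factor).
    Exacerbated genes alternate between up and down disease directions but
    share the single ``exacerbated`` truth label.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes

    labels = np.array(["null"] * n, dtype=object)
    cursor = 0
    spans: dict[str, int] = {}
    for key in ("q111_up", "q111_down", "ko_up", "ko_down", "rescued", "exacerbated"):
        spans[key] = int(round(params.fractions.get(key, 0.0) * n))
    for key, count in spans.items():
        if cursor + count > n:
            raise ValueError("fractions allocate more genes than available")
        if key == "rescued":
            half = count // 2
            labels[cursor : cursor + half] = "rescued_up"
            labels[cursor + half : cursor + count] = "rescued_down"
        else:
            labels[cursor : cursor + count] = key
        cursor += count

    base_log2 = rng.normal(
        params.baseline_mean_log[0], params.baseline_mean_log[1], size=n
    )
    base_log2 = np.clip(base_log2, 2.0, 14.0)

    shift = np.zeros((n, len(GENOTYPE_GROUPS)))
    group_pos = {g: j for j, g in enumerate(GENOTYPE_GROUPS)}
    exacerbated_parity = 0
    for i in range(n):
        label = labels[i]
        if label == "null":
            continue
        key = label
        if label == "exacerbated":
            key = "exacerbated_up" if exacerbated_parity == 0 else "exacerbated_down"
            exacerbated_parity ^= 1
        for group, mult in _CLASS_SHIFTS[key].items():
            shift[i, group_pos[group]] = mult * params.lfc_magnitude

    sample_ids: list[str] = []
    meta_rows = []
    columns = []
    for group in GENOTYPE_GROUPS:
        size = params.group_sizes[group]
        htt, hdac = group.split("_")
        for j in range(size):
            sid = f"{group}_s{j + 1:02d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "htt_genotype": htt,
                    "hdac_genotype": hdac,
                    "sex": "M" if j % 2 == 0 else "F",
                    "batch": "b1",
                }
            )
            columns.append(group_pos[group])

    mu = 2.0 ** (base_log2[:, None] + shift[:, np.asarray(columns)])
    if params.dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / params.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    matrix = CountMatrix(
        [f"gene{i + 1:05d}" for i in range(n)], sample_ids, counts
    )
    meta = SampleMeta(pd.DataFrame(meta_rows))
    truth = TruthLabels(
        gene_class=dict(zip(matrix.gene_ids, labels.tolist()))
    )
    return matrix, meta, truth


def simulate_intensities(
    true_indices: Mapping[str, float],
    intercept: float,
    slope: float,
    noise_sd: float,
    seed: int = 0,
) -> dict[str, float]:
    """intensity = intercept + slope * index + Normal(0, noise_sd), per mouse."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    mice = sorted(true_indices)
    noise = rng.normal(0.0, noise_sd, size=len(mice)) if noise_sd > 0 else (
        np.zeros(len(mice))
    )
    return {
        m: intercept + slope * true_indices[m] + float(e)
        for m, e in zip(mice, noise)
    }
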