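"""Somatic repeat-instability quantification from fragment-analysis traces.

A trace is a histogram of peak heights over integer repeat lengths (one per
sample, exported from fragment-analysis software as a long-format TSV). The
expansion index summarizes the mean positive repeat-length change across the
cell population: each peak strictly right of the modal (main) allele is
height-normalized against (main allele + all expansion peaks) and weighted
by its repeat-unit distance from the main allele. Peaks left of the main
allele (contractions) enter neither the numerator nor the denominator.

Also houses the survival-adjusted colony-count fold change used by the
selectable cell-based contraction assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .stats_core import GroupComparison, two_sample_ttest

__all__ = [
    "PeakTrace",
    "ExpansionResult",
    "ContractionAssayRecord",
    "read_peak_table",
    "call_main_allele",
    "expansion_index",
    "instability_group_compare",
    "contraction_fold_change",
]


@dataclass(frozen=True)
class PeakTrace:
    """One sample's fragment-analysis profile: repeat length -> peak height."""

    sample_id: str
    peaks: Mapping[int, float]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"trace {self.sample_id!r} has no peaks")
        for length, height in self.peaks.items():
            if int(length) != length:
                raise ValueError(f"non-integer repeat length {length!r}")
            if height < 0:
                raise ValueError(
                    f"negative height {height} at repeat {length} "
                    f"in {self.sample_id!r}"
                )
        if not any(h > 0 for h in self.peaks.values()):
            raise ValueError(
                f"trace {self.sample_id!r} has no peak with positive height"
            )


@dataclass(frozen=True)
class ExpansionResult:
    """Modal allele, per-peak contributions, and the scalar expansion index.

    ``contributions`` holds ``(d_i, h_i)`` pairs: the positive repeat-unit
    change from the modal allele and the normalized height of each counted
    expansion peak. The index is ``sum(h_i * d_i)``.
    """

    sample_id: str
    modal_repeat: int
    index: float
    contributions: tuple[tuple[int, float], ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class ContractionAssayRecord:
    condition: str
    positive_colonies: int
    plated_cells: int
    plating_efficiency: float
    survival_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.positive_colonies < 0:
            raise ValueError("positive_colonies must be nonnegative")
        if self.plated_cells <= 0:
            raise ValueError("plated_cells must be positive")
        if not 0.0 < self.plating_efficiency <= 1.0:
            raise ValueError("plating_efficiency must be in (0, 1]")
        if not 0.0 < self.survival_fraction <= 1.0:
            raise ValueError("survival_fraction must be in (0, 1]")

    @property
    def adjusted_rate(self) -> float:
        """Colonies per plated, survival-adjusted cell."""
        return self.positive_colonies / (
            self.plated_cells * self.plating_efficiency * self.survival_fraction
        )


def read_peak_table(
    path: str | Path,
    fragment_size_offset: float | None = None,
    bp_per_repeat: float = 3.0,
) -> list[PeakTrace]:
    """Read a long-format peak TSV into one :class:`PeakTrace` per sample.

    Expects columns ``sample_id``, ``height`` and either ``repeat_units`` or
    ``fragment_size``. With ``fragment_size``, an explicit base-pair offset
    must be supplied and lengths are converted as
    ``round((fragment_size - offset) / bp_per_repeat)``; the conversion must
    land on integers. Zero-height rows are dropped; duplicated
    (sample, repeat) rows are an error.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "height" not in df.columns:
        raise ValueError("peak table needs 'sample_id' and 'height' columns")
    if "repeat_units" in df.columns:
        repeats = df["repeat_units"].astype(float)
    elif "fragment_size" in df.columns:
        if fragment_size_offset is None:
            raise ValueError(
                "fragment_size column requires an explicit fragment_size_offset"
            )
        repeats = (df["fragment_size"].astype(float) - fragment_size_offset) / (
            bp_per_repeat
        )
        repeats = repeats.round()
    else:
        raise ValueError(
            "peak table needs a 'repeat_units' or 'fragment_size' column"
        )
    if ((repeats % 1) != 0).any():
        raise ValueError("repeat units must be integers after conversion")
    heights = df["height"].astype(float)
    if (heights < 0).any():
        raise ValueError("negative peak heights in table")

    tidy = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "repeat": repeats.astype(int),
            "height": heights,
        }
    )
    dup = tidy.duplicated(subset=["sample_id", "repeat"])
    if dup.any():
        rows = tidy.loc[dup, ["sample_id", "repeat"]].to_records(index=False)
        raise ValueError(f"duplicated (sample, repeat) rows: {list(rows)!r}")
    tidy = tidy[tidy["height"] > 0]

    traces = []
    for sample_id, grp in tidy.groupby("sample_id", sort=True):
        traces.append(
            PeakTrace(
                sample_id=str(sample_id),
                peaks=dict(zip(grp["repeat"], grp["height"])),
            )
        )
    return traces


def call_main_allele(trace: PeakTrace) -> int:
    """Repeat length of the highest peak; ties resolve to the smaller length."""
    best_len: int | None = None
    best_height = -1.0
    for length in sorted(trace.peaks):
        h = trace.peaks[length]
        if h > best_height:
            best_height = h
            best_len = length
    assert best_len is not None
    return int(best_len)


def expansion_index(
    trace: PeakTrace, min_relative_height: float = 0.0
) -> ExpansionResult:
    """Mean positive repeat-length change of a trace's cell population.

    Peaks strictly right of the modal allele whose height relative to the
    modal peak is >= ``min_relative_height`` form the expansion set. Each is
    normalized by (modal height + sum of expansion heights) and weighted by
    its repeat distance; the weighted sum is the index. Default threshold 0
    counts every expansion peak.
    """
    if not 0.0 <= min_relative_height <= 1.0:
        raise ValueError("min_relative_height must be in [0, 1]")
    modal = call_main_allele(trace)
    main_height = trace.peaks[modal]
    expansion = {
        length: h
        for length, h in trace.peaks.items()
        if length > modal and h > 0 and h / main_height >= min_relative_height
    }
    denom = main_height + sum(expansion.values())
    contributions = tuple(
        (length - modal, h / denom) for length, h in sorted(expansion.items())
    )
    index = sum(d * h for d, h in contributions)
    return ExpansionResult(trace.sample_id, modal, index, contributions)


def instability_group_compare(
    results_a: Sequence[ExpansionResult],
    results_b: Sequence[ExpansionResult],
    variance_mode: str = "pooled",
) -> GroupComparison:
    """Unpaired t-test on per-mouse expansion indices of two genotype groups."""
    return two_sample_ttest(
        [r.index for r in results_a],
        [r.index for r in results_b],
        variance_mode=variance_mode,
    )


def contraction_fold_change(
    records: Sequence[ContractionAssayRecord], reference_condition: str
) -> dict[str, float]:
    """Survival-adjusted colony rates expressed as fold change over a control.

    Rates for replicate records of the same condition are averaged before the
    ratio is taken. The reference condition maps to exactly 1.0.
    """
    by_condition: dict[str, list[float]] = {}
    for rec in records:
        by_condition.setdefault(rec.condition, []).append(rec.adjusted_rate)
    if reference_condition not in by_condition:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    ref_rate = sum(by_condition[reference_condition]) / len(
        by_condition[reference_condition]
    )
    if ref_rate == 0.0:
        raise ZeroDivisionError(
            f"reference condition {reference_condition!r} has zero adjusted rate"
        )
    folds = {
        cond: (sum(rates) / len(rates)) / ref_rate
        for cond, rates in by_condition.items()
    }
    folds[reference_condition] = 1.0
    return folds


def write_expansion_results(
    results: Sequence[ExpansionResult], path: str | Path
) -> None:
    """Write a per-sample TSV (sample_id, modal_repeat, index)."""
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "modal_repeat": [r.modal_repeat for r in results],
            "index": [r.index for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
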