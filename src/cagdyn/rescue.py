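"""Downstream DEG calculus: directional overlaps, rescue classification,
gene-set permutation, cross-study concordance, and Fisher enrichment.

The central questions: of the genes dysregulated by the disease allele,
which are counter-regulated by the knockout (opposite-direction overlap),
which of those are normalized back to wild-type level (rescued), and does a
fixed gene set show a systematically reduced absolute log2 fold-change of
the disease allele in the knockout background (relative-impact permutation
test)?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import SampleMeta
from .stats_core import FisherResult, bh_adjust, fisher_one_sided, two_sample_ttest

__all__ = [
    "DirectionalOverlap",
    "RescueResult",
    "PermutationResult",
    "ConcordanceResult",
    "directional_overlap",
    "overlap_fisher",
    "rescue_classify",
    "relative_impact_permutation",
    "cross_study_concordance",
    "geneset_enrichment",
    "read_gmt",
]

ThresholdMode = Literal["nominal_p", "fdr"]

CELLS = ("up_up", "up_down", "down_up", "down_down")


@dataclass(frozen=True)
class DirectionalOverlap:
    """Genes significant in two DEG tables, split by log2fc sign agreement.

    Cell keys are ``"<sign in A>_<sign in B>"``; e.g. ``"up_down"`` holds
    genes up-regulated in table A and down-regulated in table B. Genes with
    a zero log2 fold-change in either table are excluded from the four cells
    and reported separately.
    """

    alpha: float
    counts: Mapping[str, int]
    genes: Mapping[str, tuple[str, ...]]
    zero_lfc_genes: tuple[str, ...] = ()

    @property
    def n_total_overlap(self) -> int:
        return sum(self.counts.values())

    def opposite_genes(self) -> tuple[str, ...]:
        return self.genes["up_down"] + self.genes["down_up"]

    def same_genes(self) -> tuple[str, ...]:
        return self.genes["up_up"] + self.genes["down_down"]


@dataclass(frozen=True)
class RescueResult:
    """Partition of the overlap genes by the normalization criterion.

    ``rescued_opposite_up``: up by the disease allele, down by the knockout,
    endpoint-equalized. ``rescued_opposite_down``: the mirror image. All
    remaining overlap genes land in ``not_normalized``.
    """

    rescued_opposite_up: tuple[str, ...]
    rescued_opposite_down: tuple[str, ...]
    not_normalized: tuple[str, ...]
    endpoint_p: Mapping[str, float] = field(default_factory=dict)

    @property
    def n_rescued(self) -> int:
        return len(self.rescued_opposite_up) + len(self.rescued_opposite_down)

    @property
    def n_total(self) -> int:
        return self.n_rescued + len(self.not_normalized)


@dataclass(frozen=True)
class PermutationResult:
    set_size: int
    universe_size: int
    n_perm: int
    observed_stat: int
    null_mean: float
    null_quantiles: Mapping[str, float]
    p_empirical: float
    seed: int


@dataclass(frozen=True)
class ConcordanceResult:
    threshold_mode: str
    n_both_up: int
    n_both_down: int
    n_opposite: int

    @property
    def n_common(self) -> int:
        return self.n_both_up + self.n_both_down + self.n_opposite


def _sig_column(deg: pd.DataFrame, threshold_mode: ThresholdMode) -> pd.Series:
    col = {"nominal_p": "p", "fdr": "fdr"}.get(threshold_mode)
    if col is None:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    if col not in deg.columns:
        raise ValueError(f"DEG table lacks a {col!r} column")
    return deg[col]


def directional_overlap(
    deg_a: pd.DataFrame,
    deg_b: pd.DataFrame,
    alpha: float = 0.05,
    threshold_mode: ThresholdMode = "nominal_p",
) -> DirectionalOverlap:
    """Split genes significant in both tables into four sign cells."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    sig_a = deg_a.index[_sig_column(deg_a, threshold_mode) < alpha]
    sig_b = deg_b.index[_sig_column(deg_b, threshold_mode) < alpha]
    common = sig_a.intersection(sig_b)

    lfc_a = deg_a.loc[common, "log2fc"]
    lfc_b = deg_b.loc[common, "log2fc"]
    zero = (lfc_a == 0.0) | (lfc_b == 0.0)
    genes: dict[str, tuple[str, ...]] = {}
    for cell in CELLS:
        sa, sb = cell.split("_")
        mask = (
            ((lfc_a > 0) if sa == "up" else (lfc_a < 0))
            & ((lfc_b > 0) if sb == "up" else (lfc_b < 0))
            & ~zero
        )
        genes[cell] = tuple(common[mask])
    return DirectionalOverlap(
        alpha=alpha,
        counts={cell: len(g) for cell, g in genes.items()},
        genes=genes,
        zero_lfc_genes=tuple(common[zero]),
    )


def overlap_fisher(
    deg_a: pd.DataFrame,
    deg_b: pd.DataFrame,
    direction: Literal["any", "same", "up_up", "down_down", "opposite"] = "any",
    alpha: float = 0.05,
    threshold_mode: ThresholdMode = "nominal_p",
) -> FisherResult:
    """One-sided over-representation test of the (directional) DEG overlap.

    The universe is the intersection of the genes analyzed in both tables;
    the query is table A's significant genes (restricted by direction), the
    draw is table B's.
    """
    universe = deg_a.index.intersection(deg_b.index)
    if len(universe) == 0:
        raise ValueError("empty shared gene universe")
    a = deg_a.loc[universe]
    b = deg_b.loc[universe]
    sig_a = _sig_column(a, threshold_mode) < alpha
    sig_b = _sig_column(b, threshold_mode) < alpha

    if direction == "any":
        dir_ok = pd.Series(True, index=universe)
    elif direction == "same":
        dir_ok = np.sign(a["log2fc"]) == np.sign(b["log2fc"])
    elif direction == "opposite":
        dir_ok = np.sign(a["log2fc"]) == -np.sign(b["log2fc"])
    elif direction in ("up_up", "down_down"):
        sign = 1.0 if direction == "up_up" else -1.0
        dir_ok = (np.sign(a["log2fc"]) == sign) & (np.sign(b["log2fc"]) == sign)
    else:
        raise ValueError(f"unknown direction {direction!r}")

    k = int((sig_a & sig_b & dir_ok).sum())
    return fisher_one_sided(k, int(sig_a.sum()), int(sig_b.sum()), len(universe))


def rescue_classify(
    expr: pd.DataFrame,
    meta: SampleMeta,
    overlap: DirectionalOverlap,
    alpha: float = 0.05,
    endpoint_groups: tuple[str, str] = ("WT_WT", "Q111_KO"),
) -> RescueResult:
    """Split the overlap genes into rescued vs. not-normalized.

    For every overlap gene, an unpaired two-sided t-test compares normalized
    log expression between the wild-type endpoint and the double-mutant
    endpoint. Opposite-direction overlap genes whose endpoint difference is
    not significant (p > alpha) are rescued; everything else (same-direction
    genes, or opposite-direction genes that remain different) is
    not_normalized. The result partitions the overlap exactly.
    """
    groups = meta.group_of(expr.columns)
    cols_wt = np.asarray(groups == endpoint_groups[0])
    cols_mut = np.asarray(groups == endpoint_groups[1])
    for g, cols in zip(endpoint_groups, (cols_wt, cols_mut)):
        if cols.sum() < 2:
            raise ValueError(f"endpoint group {g!r} has fewer than 2 samples")

    missing = [
        g
        for cell in CELLS
        for g in overlap.genes[cell]
        if g not in expr.index
    ]
    if missing:
        raise ValueError(f"overlap genes absent from expression matrix: {missing}")

    endpoint_p: dict[str, float] = {}
    rescued_up: list[str] = []
    rescued_down: list[str] = []
    not_normalized: list[str] = list(overlap.zero_lfc_genes)
    for cell in CELLS:
        opposite = cell in ("up_down", "down_up")
        for gene in overlap.genes[cell]:
            values = expr.loc[gene].to_numpy(dtype=float)
            p = two_sample_ttest(values[cols_wt], values[cols_mut]).p_two_sided
            endpoint_p[gene] = p
            if opposite and p > alpha:
                (rescued_up if cell == "up_down" else rescued_down).append(gene)
            else:
                not_normalized.append(gene)
    return RescueResult(
        tuple(rescued_up), tuple(rescued_down), tuple(not_normalized), endpoint_p
    )


def relative_impact_permutation(
    lfc_wt_background: Mapping[str, float],
    lfc_ko_background: Mapping[str, float],
    gene_set: Sequence[str],
    n_perm: int = 100_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for reduced absolute log2 fold-change in a gene set.

    A gene shows reduction when ``|lfc_ko| < |lfc_wt|`` (strict; ties count
    as no reduction). The observed statistic is the number of set genes with
    reduction; each of ``n_perm`` draws takes ``|set|`` genes without
    replacement from the shared universe and recomputes it. The empirical p
    is ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = sorted(set(lfc_wt_background) & set(lfc_ko_background))
    gene_set = list(gene_set)
    missing = sorted(set(gene_set) - set(universe))
    if missing:
        raise ValueError(f"set genes outside the shared universe: {missing}")
    if len(set(gene_set)) != len(gene_set):
        raise ValueError("gene_set contains duplicates")
    if len(universe) <= len(gene_set):
        raise ValueError("universe must be larger than the gene set")

    reduced = np.array(
        [abs(lfc_ko_background[g]) < abs(lfc_wt_background[g]) for g in universe]
    )
    set_idx = np.array([universe.index(g) for g in gene_set])
    observed = int(reduced[set_idx].sum())

    rng = np.random.default_rng(seed)
    k = len(gene_set)
    n_univ = len(universe)
    if k * (k - 1) <= n_univ:
        # Uniform k-subsets per draw via vectorized rejection sampling: draw
        # k indices with replacement, redraw any row containing a duplicate.
        picks = rng.integers(0, n_univ, size=(n_perm, k))
        while True:
            ordered = np.sort(picks, axis=1)
            bad = (np.diff(ordered, axis=1) == 0).any(axis=1)
            if not bad.any():
                break
            picks[bad] = rng.integers(0, n_univ, size=(int(bad.sum()), k))
        null = reduced[picks].sum(axis=1)
    else:
        # dense draws: random-key top-k selection, chunked to bound memory
        null = np.empty(n_perm, dtype=np.int64)
        chunk = max(1, min(n_perm, int(2e7) // max(n_univ, 1)))
        filled = 0
        while filled < n_perm:
            m = min(chunk, n_perm - filled)
            keys = rng.random((m, n_univ))
            picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
            null[filled : filled + m] = reduced[picks].sum(axis=1)
            filled += m
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    qs = np.quantile(null, [0.5, 0.95, 0.99])
    return PermutationResult(
        set_size=k,
        universe_size=n_univ,
        n_perm=n_perm,
        observed_stat=observed,
        null_mean=float(null.mean()),
        null_quantiles={"q50": qs[0], "q95": qs[1], "q99": qs[2]},
        p_empirical=p,
        seed=seed,
    )


def cross_study_concordance(
    deg_a: pd.DataFrame,
    deg_b: pd.DataFrame,
    threshold_mode: ThresholdMode = "fdr",
    alpha: float = 0.05,
) -> ConcordanceResult:
    """Direction agreement of genes significant in two studies."""
    overlap = directional_overlap(deg_a, deg_b, alpha, threshold_mode)
    return ConcordanceResult(
        threshold_mode=threshold_mode,
        n_both_up=overlap.counts["up_up"],
        n_both_down=overlap.counts["down_down"],
        n_opposite=overlap.counts["up_down"] + overlap.counts["down_up"],
    )


def read_gmt(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = tuple(dict.fromkeys(fields[2:]))
    return sets


def geneset_enrichment(
    query: Sequence[str],
    background: Sequence[str],
    sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Query-vs-background over-representation across a gene-set collection.

    Per set: a one-sided Fisher test on (query ∩ set) against the background
    universe; BH adjustment across the tested sets. Sets with no background
    member are skipped with a warning.
    """
    bg = set(map(str, background))
    q = [str(g) for g in query]
    offenders = sorted(set(q) - bg)
    if offenders:
        raise ValueError(f"query genes absent from background: {offenders}")
    qset = set(q)

    rows = []
    for name, members in sets.items():
        in_bg = bg & set(map(str, members))
        if not in_bg:
            warnings.warn(
                f"gene set {name!r} has no background member; skipped",
                stacklevel=2,
            )
            continue
        res = fisher_one_sided(
            len(qset & in_bg), len(qset), len(in_bg), len(bg)
        )
        rows.append(
            {
                "set": name,
                "overlap": res.overlap_k,
                "set_size_in_background": res.draw_size_n,
                "p": res.p_one_sided,
            }
        )
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size_in_background", "p"]
    ).set_index("set")
    table["fdr"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table
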