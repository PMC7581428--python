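"""Count-matrix filtering, normalization, PCA, and genotype-contrast DE tests.

The study design has four genotype groups formed by crossing a disease
(``Q111`` vs ``WT``) allele with a striatal deacetylase knockout (``KO`` vs
``WT``); five fixed pairwise contrasts between those groups are tested per
gene. The default test is an in-repo negative-binomial log-linear model with
a likelihood-ratio chi-square (df = 1), using gene-wise method-of-moments
dispersions shrunk 50/50 toward a fitted mean-dispersion trend. A plain
linear model on log-CPM is available as a cross-check (``method="logcpm-lm"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .stats_core import bh_adjust

__all__ = [
    "CountMatrix",
    "SampleMeta",
    "FilterConfig",
    "ContrastSpec",
    "CONTRASTS",
    "GENOTYPE_GROUPS",
    "read_counts_tsv",
    "read_meta_tsv",
    "filter_genes",
    "normalize_log_cpm",
    "pca_samples",
    "de_test",
]

GENOTYPE_GROUPS = ("WT_WT", "WT_KO", "Q111_WT", "Q111_KO")

# group_a vs group_b (group_b is the baseline of the log2 fold-change)
CONTRASTS: dict[int, tuple[str, str]] = {
    1: ("WT_KO", "WT_WT"),
    2: ("Q111_KO", "Q111_WT"),
    3: ("Q111_WT", "WT_WT"),
    4: ("Q111_KO", "WT_KO"),
    5: ("Q111_KO", "WT_WT"),
}

_DISPERSION_FLOOR = 1e-4


@dataclass(frozen=True)
class ContrastSpec:
    id: int
    group_a: str
    group_b: str

    @classmethod
    def from_id(cls, contrast_id: int) -> "ContrastSpec":
        if contrast_id not in CONTRASTS:
            raise ValueError(f"unknown contrast id {contrast_id}; valid: 1-5")
        a, b = CONTRASTS[contrast_id]
        return cls(contrast_id, a, b)


class CountMatrix:
    """Genes x samples matrix of nonnegative integer counts."""

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene identifiers must be unique")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample identifiers must be unique")
        self.gene_ids = list(map(str, gene_ids))
        self.sample_ids = list(map(str, sample_ids))
        self.counts = counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.sample_ids
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            [g for g, k in zip(self.gene_ids, keep) if k],
            self.sample_ids,
            self.counts[keep.astype(bool)],
        )


class SampleMeta:
    """Per-sample genotype/sex/batch annotations backed by a data frame."""

    REQUIRED = ("sample_id", "htt_genotype", "hdac_genotype")

    def __init__(self, table: pd.DataFrame) -> None:
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        table = table.copy()
        table["sample_id"] = table["sample_id"].astype(str)
        if table["sample_id"].duplicated().any():
            raise ValueError("duplicated sample_id rows in metadata")
        bad_htt = set(table["htt_genotype"]) - {"Q111", "WT"}
        bad_hdac = set(table["hdac_genotype"]) - {"KO", "WT"}
        if bad_htt or bad_hdac:
            raise ValueError(
                f"invalid genotypes: htt={bad_htt or '{}'} hdac={bad_hdac or '{}'}"
            )
        table["group"] = (
            table["htt_genotype"].astype(str)
            + "_"
            + table["hdac_genotype"].astype(str)
        )
        self.table = table.set_index("sample_id", drop=False)

    def group_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        return self.table.loc[list(sample_ids), "group"].to_numpy()

    def covariate(self, name: str, sample_ids: Sequence[str]) -> np.ndarray:
        if name not in self.table.columns:
            raise ValueError(f"unknown covariate {name!r}")
        return self.table.loc[list(sample_ids), name].astype(str).to_numpy()


@dataclass(frozen=True)
class FilterConfig:
    min_count: int = 6
    min_gene_length_nt: int | None = 250
    excluded_biotypes: frozenset[str] = field(
        default_factory=lambda: frozenset({"tRNA", "rRNA"})
    )

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        df.index.astype(str).tolist(),
        df.columns.astype(str).tolist(),
        df.to_numpy(),
    )


def read_meta_tsv(path: str | Path) -> SampleMeta:
    return SampleMeta(pd.read_csv(path, sep="\t"))


def filter_genes(
    counts: CountMatrix,
    meta: SampleMeta,
    cfg: FilterConfig = FilterConfig(),
    annotation: pd.DataFrame | None = None,
) -> CountMatrix:
    """Detection filter plus optional length/biotype filters.

    A gene is detected if it has at least ``cfg.min_count`` counts in *every*
    sample of at least one genotype group. When an annotation table
    (columns ``gene_id``, ``length_nt``, ``biotype``) is supplied, genes
    shorter than ``min_gene_length_nt`` or of an excluded biotype are also
    removed; genes absent from the annotation are kept.
    """
    groups = meta.group_of(counts.sample_ids)
    keep = np.zeros(len(counts.gene_ids), dtype=bool)
    for group in np.unique(groups):
        cols = groups == group
        keep |= (counts.counts[:, cols] >= cfg.min_count).all(axis=1)

    if annotation is not None:
        for col in ("gene_id", "length_nt", "biotype"):
            if col not in annotation.columns:
                raise ValueError(f"annotation missing column {col!r}")
        ann = annotation.set_index(annotation["gene_id"].astype(str))
        lengths = ann["length_nt"].reindex(counts.gene_ids)
        biotypes = ann["biotype"].reindex(counts.gene_ids)
        if cfg.min_gene_length_nt is not None:
            keep &= ~(lengths < cfg.min_gene_length_nt).to_numpy(dtype=bool)
        keep &= ~biotypes.isin(cfg.excluded_biotypes).to_numpy(dtype=bool)
    return counts.subset_genes(keep)


def normalize_log_cpm(counts: CountMatrix) -> pd.DataFrame:
    """log2(1e6 * count / library_size + 1), genes x samples."""
    lib = counts.counts.sum(axis=0).astype(float)
    if np.any(lib <= 0):
        empty = [s for s, size in zip(counts.sample_ids, lib) if size <= 0]
        raise ValueError(f"empty libraries: {empty}")
    cpm = counts.counts * (1e6 / lib)
    return pd.DataFrame(
        np.log2(cpm + 1.0), index=counts.gene_ids, columns=counts.sample_ids
    )


def pca_samples(
    log_matrix: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene-centered PCA of samples.

    Returns (sample scores, per-component variance fractions). Components
    are ordered by decreasing variance; fractions sum to <= 1 when fewer
    components than the matrix rank are requested.
    """
    if log_matrix.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    x = log_matrix.to_numpy(dtype=float)
    centered = (x - x.mean(axis=1, keepdims=True)).T  # samples x genes
    total_var = float((centered**2).sum())
    if total_var == 0.0:
        raise ValueError("constant matrix: principal components undefined")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = len(s) if n_components is None else min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    fractions = (s[:k] ** 2) / (s**2).sum()
    return (
        pd.DataFrame(
            scores,
            index=log_matrix.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        fractions,
    )


# --- negative-binomial machinery ------------------------------------------
# NB parameterized by mean mu and dispersion alpha: Var = mu + alpha * mu^2.


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood; y, mu are (G, n), alpha is (G, 1)."""
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-12)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


def _fit_nb_mean(
    y: np.ndarray, size: np.ndarray, alpha: np.ndarray, n_iter: int = 60
) -> np.ndarray:
    """MLE of beta in mu_ij = size_j * exp(beta_i), fixed dispersion.

    Fisher scoring, vectorized over genes. ``y`` is (G, n), ``size`` (n,),
    ``alpha`` (G, 1). Rows with all-zero counts get beta = -inf (mu -> 0).
    """
    total = y.sum(axis=1)
    with np.errstate(divide="ignore"):
        beta = np.log(np.maximum(total, 1e-8) / size.sum())
    zero_rows = total == 0
    for _ in range(n_iter):
        mu = size[None, :] * np.exp(beta)[:, None]
        denom = 1.0 + alpha * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        np.clip(step, -5.0, 5.0, out=step)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    beta[zero_rows] = -np.inf
    return beta


def estimate_dispersions(
    counts: np.ndarray, groups: np.ndarray, n_bins: int = 20
) -> np.ndarray:
    """Gene-wise moment dispersions shrunk toward a fitted mean trend.

    Counts are library-size-scaled, group means removed, and the moment
    estimate (var - mean) / mean^2 computed per gene. A trend
    ``alpha(mu) = c0 + c1/mu`` is least-squares fit to per-bin means of the
    raw (unclipped) estimates over mean-expression bins; the final value is
    the 50/50 blend of the clipped gene-wise estimate and the trend, floored
    at 1e-4.
    """
    lib = counts.sum(axis=0).astype(float)
    scaled = counts * (lib.mean() / lib)
    n = counts.shape[1]
    levels = np.unique(groups)
    resid_ss = np.zeros(counts.shape[0])
    for g in levels:
        cols = groups == g
        block = scaled[:, cols]
        resid_ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(
            axis=1
        )
    dof = max(n - len(levels), 1)
    s2 = resid_ss / dof
    mu = scaled.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mu) / mu**2
    raw[~np.isfinite(raw)] = 0.0

    ok = mu > 0
    if ok.sum() >= 10:
        order = np.argsort(mu[ok])
        mu_ok, raw_ok = mu[ok][order], raw[ok][order]
        edges = np.array_split(np.arange(mu_ok.size), min(n_bins, mu_ok.size))
        bin_mu = np.array([mu_ok[idx].mean() for idx in edges])
        bin_alpha = np.array([raw_ok[idx].mean() for idx in edges])
        design = np.column_stack([np.ones_like(bin_mu), 1.0 / bin_mu])
        coef, *_ = np.linalg.lstsq(design, bin_alpha, rcond=None)
        with np.errstate(divide="ignore"):
            trend = coef[0] + coef[1] / np.maximum(mu, 1e-12)
        trend = np.clip(trend, _DISPERSION_FLOOR, None)
    else:
        trend = np.full(counts.shape[0], np.clip(raw.mean(), 0.01, None))

    alpha = 0.5 * np.clip(raw, 0.0, None) + 0.5 * trend
    return np.clip(alpha, _DISPERSION_FLOOR, None)


def _design_matrices(
    group_ind: np.ndarray, covariate_arrays: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Full (intercept + group + covariates) and reduced (no group) designs.

    Raises on a covariate collinear with the design built so far, naming it.
    """
    n = group_ind.size
    cols_red: list[np.ndarray] = [np.ones(n)]
    for name, values in covariate_arrays.items():
        levels = np.unique(values)
        base_rank = np.linalg.matrix_rank(np.column_stack(cols_red))
        new_cols = [
            (values == lvl).astype(float) for lvl in levels[1:]
        ]  # drop-first coding
        candidate = np.column_stack(cols_red + new_cols)
        if np.linalg.matrix_rank(candidate) < base_rank + len(new_cols):
            raise ValueError(
                f"covariate {name!r} is collinear with the design "
                "(confounded with group or a prior covariate)"
            )
        cols_red.extend(new_cols)
    reduced = np.column_stack(cols_red)
    full = np.column_stack([reduced, group_ind.astype(float)])
    if np.linalg.matrix_rank(full) < reduced.shape[1] + 1:
        raise ValueError("genotype group is confounded with the covariates")
    return full, reduced


def _fit_nb_glm_ll(
    y: np.ndarray, design: np.ndarray, offset: np.ndarray, alpha: float
) -> tuple[np.ndarray, float]:
    """Single-gene NB GLM fit (IRLS/Fisher scoring); returns (beta, loglik)."""
    n, p = design.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8)) - offset.mean()
    for _ in range(100):
        eta = design @ beta + offset
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha * mu)
        wx = design * w[:, None]
        # Fisher scoring step: (X' W X)^-1 X' (y - mu)/(1 + alpha mu)
        step = np.linalg.lstsq(
            design.T @ wx, design.T @ ((y - mu) / (1.0 + alpha * mu)), rcond=None
        )[0]
        beta = beta + np.clip(step, -5, 5)
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = design @ beta + offset
    mu = np.exp(np.clip(eta, -30, 30))
    ll = float(
        _nb_loglik(y[None, :], mu[None, :], np.array([[alpha]]))[0]
    )
    return beta, ll


def de_test(
    counts: CountMatrix,
    meta: SampleMeta,
    contrast: ContrastSpec | int,
    covariates: Sequence[str] | None = None,
    method: str = "nb-lrt",
) -> pd.DataFrame:
    """Per-gene differential expression for one genotype-group contrast.

    Returns a table indexed by gene with columns ``log2fc`` (group_a over
    group_b), ``p``, ``fdr`` (BH within this contrast), and
    ``mean_log_expression`` (mean log2-CPM over the contrast samples), plus a
    ``degenerate`` flag for genes with identical counts in every sample.

    ``method="nb-lrt"`` (default) fits a per-gene negative-binomial
    log-linear model with library-size offsets and tests the group term with
    a likelihood-ratio chi-square (df = 1). ``method="logcpm-lm"`` runs an
    ordinary linear model on log2-CPM with a t-test on the group term.
    """
    if isinstance(contrast, int):
        contrast = ContrastSpec.from_id(contrast)
    if method not in ("nb-lrt", "logcpm-lm"):
        raise ValueError(f"unknown method {method!r}")

    groups_all = meta.group_of(counts.sample_ids)
    sel = np.isin(groups_all, [contrast.group_a, contrast.group_b])
    for g in (contrast.group_a, contrast.group_b):
        if (groups_all == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    sample_ids = [s for s, keep in zip(counts.sample_ids, sel) if keep]
    y = counts.counts[:, sel].astype(float)
    groups = groups_all[sel]
    is_a = groups == contrast.group_a

    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("contrast contains an empty library")
    logcpm = np.log2(y * (1e6 / lib) + 1.0)
    mean_log_expr = logcpm.mean(axis=1)
    degenerate = (y == y[:, :1]).all(axis=1)

    cov_arrays: dict[str, np.ndarray] = {}
    for name in covariates or ():
        cov_arrays[name] = meta.covariate(name, sample_ids)

    if method == "logcpm-lm":
        lfc, p = _logcpm_lm(logcpm, is_a, cov_arrays)
    else:
        lfc, p = _nb_lrt(y, lib, is_a, groups, cov_arrays)

    lfc = np.where(degenerate, 0.0, lfc)
    p = np.where(degenerate, 1.0, p)
    converged = np.isfinite(p)
    fdr = np.full(p.shape, np.nan)
    fdr[converged] = bh_adjust(p[converged])
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "fdr": fdr,
            "mean_log_expression": mean_log_expr,
            "degenerate": degenerate,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )


def _nb_lrt(
    y: np.ndarray,
    lib: np.ndarray,
    is_a: np.ndarray,
    groups: np.ndarray,
    cov_arrays: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    alpha = estimate_dispersions(y.astype(np.int64), groups)[:, None]
    size = lib / lib.mean()

    if not cov_arrays:
        beta_a = _fit_nb_mean(y[:, is_a], size[is_a], alpha)
        beta_b = _fit_nb_mean(y[:, ~is_a], size[~is_a], alpha)
        beta_0 = _fit_nb_mean(y, size, alpha)
        mu_full = np.empty_like(y)
        mu_full[:, is_a] = size[is_a][None, :] * np.exp(beta_a)[:, None]
        mu_full[:, ~is_a] = size[~is_a][None, :] * np.exp(beta_b)[:, None]
        mu_red = size[None, :] * np.exp(beta_0)[:, None]
        ll_full = _nb_loglik(y, mu_full, alpha)
        ll_red = _nb_loglik(y, mu_red, alpha)
        with np.errstate(invalid="ignore"):
            lfc = (beta_a - beta_b) / np.log(2.0)
        lfc[~np.isfinite(lfc)] = 0.0
        stat = np.maximum(2.0 * (ll_full - ll_red), 0.0)
        p = stats.chi2.sf(stat, df=1)
        return lfc, p

    full, reduced = _design_matrices(is_a, cov_arrays)
    offset = np.log(size)
    lfc = np.zeros(y.shape[0])
    p = np.full(y.shape[0], np.nan)
    for i in range(y.shape[0]):
        yi = y[i]
        if yi.sum() == 0:
            lfc[i], p[i] = 0.0, 1.0
            continue
        a_i = float(alpha[i, 0])
        beta_f, ll_f = _fit_nb_glm_ll(yi, full, offset, a_i)
        _, ll_r = _fit_nb_glm_ll(yi, reduced, offset, a_i)
        stat = max(2.0 * (ll_f - ll_r), 0.0)
        lfc[i] = beta_f[-1] / np.log(2.0)
        p[i] = stats.chi2.sf(stat, df=1)
    return lfc, p


def _logcpm_lm(
    logcpm: np.ndarray, is_a: np.ndarray, cov_arrays: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    full, _ = _design_matrices(is_a, cov_arrays)
    n, q = full.shape
    pinv = np.linalg.pinv(full)
    coef = logcpm @ pinv.T  # (G, q)
    resid = logcpm - coef @ full.T
    dof = n - q
    sigma2 = (resid**2).sum(axis=1) / dof
    xtx_inv = np.linalg.inv(full.T @ full)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[-1, -1], 1e-300))
    t = coef[:, -1] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    zero_var = sigma2 <= 1e-300
    p[zero_var & (np.abs(coef[:, -1]) < 1e-12)] = 1.0
    p[zero_var & (np.abs(coef[:, -1]) >= 1e-12)] = 0.0
    return coef[:, -1], p
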