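"""Per-image nuclear-staining quantifications summarized per mouse and
related to somatic expansion indices."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .stats_core import (
    CorrelationResult,
    GroupComparison,
    pearson_correlation,
    two_sample_ttest,
)

__all__ = [
    "ImageQuant",
    "MousePhenotype",
    "read_image_quant_tsv",
    "summarize_intensity",
    "phenotype_group_compare",
    "correlate_intensity_expansion",
]


@dataclass(frozen=True)
class ImageQuant:
    """One image's staining quantification for one mouse.

    ``integrated_intensity`` is summed over all stain-positive nuclei in the
    image; ``n_total_nuclei`` counts all (histone-positive) nuclei and is the
    normalizer. ``n_inclusions`` is only recorded for inclusion-stage mice.
    """

    mouse_id: str
    image_id: str
    integrated_intensity: float
    n_positive_nuclei: int
    n_total_nuclei: int
    n_inclusions: int | None = None

    def __post_init__(self) -> None:
        if self.integrated_intensity < 0:
            raise ValueError(f"negative intensity in image {self.image_id!r}")
        if self.n_positive_nuclei > self.n_total_nuclei:
            raise ValueError(
                f"image {self.image_id!r}: positive nuclei exceed total"
            )
        if self.n_inclusions is not None and self.n_inclusions < 0:
            raise ValueError("n_inclusions must be nonnegative")


@dataclass(frozen=True)
class MousePhenotype:
    mouse_id: str
    mean_intensity_per_nucleus: float
    pct_nuclei_with_inclusion: float | None = None
    n_images: int = 0


def read_image_quant_tsv(path: str | Path) -> list[ImageQuant]:
    df = pd.read_csv(path, sep="\t")
    required = {
        "mouse_id",
        "image_id",
        "integrated_intensity",
        "n_positive_nuclei",
        "n_total_nuclei",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"image table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        n_incl = getattr(row, "n_inclusions", None)
        records.append(
            ImageQuant(
                mouse_id=str(row.mouse_id),
                image_id=str(row.image_id),
                integrated_intensity=float(row.integrated_intensity),
                n_positive_nuclei=int(row.n_positive_nuclei),
                n_total_nuclei=int(row.n_total_nuclei),
                n_inclusions=None if pd.isna(n_incl) else int(n_incl),
            )
        )
    return records


def summarize_intensity(images: Sequence[ImageQuant]) -> list[MousePhenotype]:
    """Per-image intensity per nucleus, averaged (unweighted) per mouse.

    The inclusion percentage, when recorded, is computed per image as
    ``100 * n_inclusions / n_total_nuclei`` and averaged the same way.
    """
    per_mouse: dict[str, list[ImageQuant]] = {}
    for img in images:
        if img.n_total_nuclei <= 0:
            raise ValueError(
                f"image {img.image_id!r} of mouse {img.mouse_id!r} "
                "has zero total nuclei"
            )
        per_mouse.setdefault(img.mouse_id, []).append(img)

    phenotypes = []
    for mouse_id in sorted(per_mouse):
        imgs = per_mouse[mouse_id]
        per_image = [i.integrated_intensity / i.n_total_nuclei for i in imgs]
        with_incl = [i for i in imgs if i.n_inclusions is not None]
        pct = (
            sum(100.0 * i.n_inclusions / i.n_total_nuclei for i in with_incl)
            / len(with_incl)
            if with_incl
            else None
        )
        phenotypes.append(
            MousePhenotype(
                mouse_id=mouse_id,
                mean_intensity_per_nucleus=sum(per_image) / len(per_image),
                pct_nuclei_with_inclusion=pct,
                n_images=len(imgs),
            )
        )
    return phenotypes


def phenotype_group_compare(
    pheno_a: Sequence[MousePhenotype],
    pheno_b: Sequence[MousePhenotype],
    variance_mode: str = "pooled",
) -> GroupComparison:
    """Unpaired t-test on per-mouse mean intensity between two groups."""
    return two_sample_ttest(
        [p.mean_intensity_per_nucleus for p in pheno_a],
        [p.mean_intensity_per_nucleus for p in pheno_b],
        variance_mode=variance_mode,
    )


def correlate_intensity_expansion(
    expansion_by_mouse: Mapping[str, float],
    intensity_by_mouse: Mapping[str, float],
) -> CorrelationResult:
    """Pearson correlation of per-mouse expansion index vs. mean intensity."""
    unpaired = sorted(
        set(expansion_by_mouse).symmetric_difference(intensity_by_mouse)
    )
    if unpaired:
        raise ValueError(f"mice without both measures: {unpaired}")
    mice = sorted(expansion_by_mouse)
    if len(mice) < 3:
        raise ValueError("need at least 3 paired mice")
    return pearson_correlation(
        [expansion_by_mouse[m] for m in mice],
        [intensity_by_mouse[m] for m in mice],
    )
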