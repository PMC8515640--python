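"""Expression metrics: upper-quartile normalisation, AEL and the τ index.

Per-sample FPKM values are scaled so every sample's upper quartile of
nonzero values is equal (upper-quartile normalisation).  Samples are then
collapsed to one component per tissue — mean over technical replicates
within each biological replicate, median over biological replicates.  From
the component vector of a gene:

* AEL, the average expression level, is the arithmetic mean of the
  components;
* τ, the tissue-specificity index, is ``sum(1 - x_i) / (N - 1)`` where
  ``x_i`` are the components divided by the maximal component and ``N`` is
  the number of components.  τ is 0 for perfectly uniform expression and 1
  for single-tissue expression.

Both are only computed when at least one component is >= 0.5 (below that
the profile is considered too weakly expressed to classify).  N is taken
from the profile length, so profiles with other tissue designs work too.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats import TISSUES, ExpressionTable, SampleRecord

__all__ = [
    "upper_quartile_normalize",
    "tissue_components",
    "compute_ael",
    "compute_tau",
    "high_variation_filter",
    "assign_tissue_class",
    "profile_table",
    "MIN_COMPONENT",
]

#: AEL/τ are only defined when some component reaches this FPKM level.
MIN_COMPONENT = 0.5


def upper_quartile_normalize(table: ExpressionTable) -> ExpressionTable:
    """Scale each sample by its 75th percentile of nonzero values.

    Values are divided by the per-sample nonzero upper quartile (linear
    interpolation between order statistics) and multiplied by the mean of
    those quartiles over samples, which preserves the overall scale.
    Afterwards every sample's nonzero upper quartile equals that common
    factor.
    """
    values = table.values
    q75 = {}
    for col in values.columns:
        nz = values[col].to_numpy()
        nz = nz[nz > 0]
        if nz.size == 0:
            raise ValueError(f"all-zero sample: {col}")
        q75[col] = float(np.quantile(nz, 0.75))
    factor = float(np.mean(list(q75.values())))
    scaled = values.copy()
    for col in values.columns:
        scaled[col] = values[col] * (factor / q75[col])
    return ExpressionTable(values=scaled, gene_kind=dict(table.gene_kind))


def tissue_components(
    table: ExpressionTable,
    samples: Sequence[SampleRecord],
    tissues: Sequence[str] = TISSUES,
) -> pd.DataFrame:
    """Collapse samples to one component per tissue.

    Technical replicates are averaged within each biological replicate,
    then the median is taken across biological replicates (even counts use
    the mean of the two middle values).  Tissues with no samples yield NaN
    components; genes with any NaN component have an incomplete profile
    and are excluded from AEL/τ downstream.
    """
    values = table.values
    by_sample = {s.sample_id: s for s in samples}
    unknown = [c for c in values.columns if c not in by_sample]
    if unknown:
        raise ValueError(f"matrix samples missing from sheet: {unknown}")
    comp = pd.DataFrame(index=values.index, columns=list(tissues), dtype=float)
    for tissue in tissues:
        cols_by_bio: dict[int, list[str]] = {}
        for col in values.columns:
            s = by_sample[col]
            if s.tissue == tissue:
                cols_by_bio.setdefault(s.bio_rep, []).append(col)
        if not cols_by_bio:
            comp[tissue] = np.nan
            continue
        bio_means = pd.DataFrame(
            {bio: values[cols].mean(axis=1) for bio, cols in cols_by_bio.items()}
        )
        comp[tissue] = bio_means.median(axis=1)
    return comp


def compute_ael(components: Sequence[float]) -> float:
    """Average expression level: mean of the profile components.

    Returns NaN (gene skipped) when no component reaches ``MIN_COMPONENT``
    or the profile is incomplete.
    """
    arr = np.asarray(components, dtype=float)
    if np.isnan(arr).any() or arr.max(initial=0.0) < MIN_COMPONENT:
        return float("nan")
    return float(arr.mean())


def compute_tau(components: Sequence[float]) -> float:
    """Tissue-specificity index τ = Σ(1 − x_i)/(N − 1), x_i = comp_i / max.

    Defined under the same condition as AEL; NaN otherwise.
    """
    arr = np.asarray(components, dtype=float)
    if np.isnan(arr).any() or arr.max(initial=0.0) < MIN_COMPONENT:
        return float("nan")
    x = arr / arr.max()
    n = arr.size
    return float(np.sum(1.0 - x) / (n - 1))


def high_variation_filter(
    table: ExpressionTable, keep_fraction: float = 0.75
) -> set[str]:
    """Retain the top ``keep_fraction`` of genes by expression variation.

    The variation statistic is the variance of log2(x+1) across samples.
    Genes at or above the (1 − keep_fraction) quantile of the statistic are
    kept, ties inclusive, so at least ``keep_fraction`` of genes survive.
    ``keep_fraction=0.25`` gives the stricter above-75th-percentile reading.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    logv = np.log2(table.values.to_numpy(dtype=float) + 1.0)
    stat = logv.var(axis=1, ddof=1)
    if keep_fraction == 1.0:
        return set(table.values.index)
    cut = float(np.quantile(stat, 1.0 - keep_fraction))
    return {g for g, s in zip(table.values.index, stat) if s >= cut}


def assign_tissue_class(
    components: Sequence[float],
    tau: float,
    tissues: Sequence[str] = TISSUES,
    tau_threshold: float = 0.9,
) -> str:
    """Tissue label for a specific gene (τ >= threshold), else "broad".

    The label is the tissue of the maximal component; exact ties go to the
    first tissue in the fixed order, with a warning.
    """
    if math.isnan(tau) or tau < tau_threshold:
        return "broad"
    arr = np.asarray(components, dtype=float)
    imax = int(np.argmax(arr))
    if int(np.sum(arr == arr[imax])) > 1:
        warnings.warn(
            "tied maximal components; assigning first tissue in fixed order",
            stacklevel=2,
        )
    return tissues[imax]


def profile_table(
    table: ExpressionTable,
    samples: Sequence[SampleRecord],
    tissues: Sequence[str] = TISSUES,
    tau_threshold: float = 0.9,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-gene profile summary: components, AEL, τ and tissue class.

    Genes whose AEL/τ condition is unmet carry NaN metrics and class
    "undefined"; defined genes below the τ threshold are "broad".
    """
    if normalize:
        table = upper_quartile_normalize(table)
    comp = tissue_components(table, samples, tissues=tissues)
    out = comp.copy()
    aels, taus, classes = [], [], []
    for _, row in comp.iterrows():
        vec = row.to_numpy(dtype=float)
        ael = compute_ael(vec)
        tau = compute_tau(vec)
        aels.append(ael)
        taus.append(tau)
        if math.isnan(tau):
            classes.append("undefined")
        else:
            classes.append(
                assign_tissue_class(vec, tau, tissues=tissues, tau_threshold=tau_threshold)
            )
    out["AEL"] = aels
    out["tau"] = taus
    out["tissue_class"] = classes
    return out
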