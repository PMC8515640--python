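"""Summary tables with explicit numerator/denominator provenance.

Every percentage printed by the pipeline is reproducible from the stored
numerator and denominator under half-up rounding at the stored precision.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .orthology import round_half_up

__all__ = ["percent", "catalogue_summary", "category_summary"]


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Half-up rounded percentage with explicit provenance in the caller."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def catalogue_summary(
    per_species: Mapping[str, Mapping[str, int]], ndigits: int = 2
) -> pd.DataFrame:
    """Per-species collected/unique counts, grand totals and fold variation.

    ``per_species`` maps species -> {"collected": int, "unique": int}.  The
    fold ratio is max unique over min unique, half-up at ``ndigits``.
    """
    if not per_species:
        raise ValueError("no species catalogues")
    rows = [
        {
            "species": sp,
            "n_collected": int(c["collected"]),
            "n_unique": int(c["unique"]),
        }
        for sp, c in sorted(per_species.items())
    ]
    df = pd.DataFrame(rows)
    uniques = df["n_unique"]
    total_row = {
        "species": "TOTAL",
        "n_collected": int(df["n_collected"].sum()),
        "n_unique": int(uniques.sum()),
    }
    df = pd.concat([df, pd.DataFrame([total_row])], ignore_index=True)
    df.attrs["fold_variation"] = round_half_up(
        uniques.max() / uniques.min(), ndigits
    )
    return df


def category_summary(
    labels: Mapping[str, str],
    pool: Mapping[str, str] | None = None,
    non_conserved_label: str = "non_conserved",
    ndigits: int = 1,
) -> pd.DataFrame:
    """Counts and percent shares of focal lncRNAs per conservation category.

    ``labels`` maps lncRNA id -> category label.  ``pool`` optionally maps
    raw labels to a pooled label (e.g. the two deepest categories combined
    into "Ultra"); pooled rows are appended after the raw rows.  Shares
    carry their numerator and denominator as columns.
    """
    if not labels:
        raise ValueError("no focal lncRNAs")
    total = len(labels)
    counts: dict[str, int] = {}
    for lab in labels.values():
        counts[lab] = counts.get(lab, 0) + 1
    rows = [
        {
            "category": lab,
            "count": n,
            "total": total,
            "share_pct": percent(n, total, ndigits),
        }
        for lab, n in sorted(counts.items())
    ]
    if pool:
        pooled: dict[str, int] = {}
        for lab, n in counts.items():
            if lab in pool:
                pooled[pool[lab]] = pooled.get(pool[lab], 0) + n
        for lab, n in sorted(pooled.items()):
            rows.append(
                {
                    "category": lab,
                    "count": n,
                    "total": total,
                    "share_pct": percent(n, total, ndigits),
                }
            )
    n_conserved = sum(
        n for lab, n in counts.items() if lab != non_conserved_label
    )
    df = pd.DataFrame(rows)
    df.attrs["n_conserved"] = n_conserved
    df.attrs["conserved_share_pct"] = percent(n_conserved, total, ndigits)
    return df
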