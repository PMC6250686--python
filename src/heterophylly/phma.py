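"""Trend classification of RNAs across the four ordered leaf stages.

An RNA whose stage-mean expression moves monotonically across the ordered
stages Li -> La -> Ov -> Bo mirrors the leaf index, which itself decreases
strictly over that order.  The trend labels are:

* ``CLI`` — consistent with the leaf index: stage means strictly
  decreasing from Li to Bo;
* ``OLI`` — opposite the leaf index: stage means strictly increasing;
* ``none`` — anything else.

A trend-labelled RNA whose Li-versus-Bo contrast is also significant is a
heterophyll-morphogenesis-associated (PHMA) RNA.  The PHMA set is therefore
always a subset of the significant set of the Bo/Li contrast.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .morphometrics import STAGE_ORDER

TREND_LABELS = ("CLI", "OLI", "none")


def trend_label(
    means: Sequence[float], rel_tolerance: float = 0.0
) -> str:
    """Trend label of one RNA from its stage means in Li,La,Ov,Bo order.

    With ``rel_tolerance`` t = 0 (default) monotonicity is strict.  With
    t > 0 a step may go the "wrong" way by up to a relative factor (1 + t)
    before it breaks the trend, so near-ties do not disqualify an RNA.
    """
    means = np.asarray(means, dtype=float)
    if means.ndim != 1 or means.size < 4:
        raise ValueError(f"need the 4 ordered stage means, got {means.size}")
    if rel_tolerance < 0:
        raise ValueError("rel_tolerance must be >= 0")
    t = rel_tolerance
    prev, nxt = means[:-1], means[1:]
    decreasing = bool(np.all(nxt < prev * (1.0 + t)))
    increasing = bool(np.all(nxt * (1.0 + t) > prev))
    if decreasing and not increasing:
        return "CLI"
    if increasing and not decreasing:
        return "OLI"
    return "none"


def trend_labels(
    stage_means: pd.DataFrame, rel_tolerance: float = 0.0
) -> pd.Series:
    """Vector of trend labels from a stage-mean table (columns Li,La,Ov,Bo)."""
    missing = [s for s in STAGE_ORDER if s not in stage_means.columns]
    if missing:
        raise ValueError(f"stage-mean table is missing stages: {missing}")
    ordered = stage_means[list(STAGE_ORDER)]
    return pd.Series(
        [trend_label(row, rel_tolerance) for row in ordered.to_numpy()],
        index=stage_means.index,
        name="trend",
    )


def phma_classify(
    trends: pd.Series | Mapping[str, str],
    de_li_bo: pd.Series | Mapping[str, float],
    rna_class: str = "mRNA",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """PHMA records: trend label plus the Li-versus-Bo significance gate.

    ``is_phma`` is true exactly when the trend is CLI or OLI *and* the RNA's
    Bo/Li p-value is below ``alpha``.  Every trend-labelled RNA must have a
    p-value; extra p-values are ignored.
    """
    trends = pd.Series(trends) if not isinstance(trends, pd.Series) else trends
    de_li_bo = pd.Series(de_li_bo) if not isinstance(de_li_bo, pd.Series) else de_li_bo
    missing = trends.index.difference(de_li_bo.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} RNAs have a trend but no Li-vs-Bo p-value, "
            f"e.g. {missing[0]!r}"
        )
    bad = set(trends) - set(TREND_LABELS)
    if bad:
        raise ValueError(f"unknown trend labels: {sorted(bad)}")
    pvals = de_li_bo.reindex(trends.index)
    records = pd.DataFrame(
        {
            "rna_class": rna_class,
            "trend": trends,
            "pvalue_li_bo": pvals,
            "is_phma": (trends != "none") & (pvals < alpha),
        }
    )
    records.index.name = "rna_id"
    return records


def phma_summary(records: pd.DataFrame) -> pd.DataFrame:
    """CLI / OLI / total counts of PHMA RNAs per RNA class.

    ``total`` is always ``CLI + OLI``; a ``grand`` row sums over classes.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["CLI", "OLI", "total"])
    phma = records[records["is_phma"]]
    counts = (
        phma.groupby("rna_class")["trend"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["CLI", "OLI"], fill_value=0)
    )
    counts["total"] = counts["CLI"] + counts["OLI"]
    counts.loc["grand"] = counts.sum()
    return counts
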