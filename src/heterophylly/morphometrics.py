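"""Leaf morphometrics: leaf index and heterophyll shape classification.

*Populus euphratica* produces four leaf shapes in turn as trees mature —
linear (Li), lanceolate (La), ovate (Ov) and broad-ovate (Bo).  The shapes
are defined by the leaf index LI = leaf length / leaf width:

    Li : LI >= 5
    La : 5 > LI >= 2
    Ov : 2 > LI >= 1
    Bo : LI < 1

A sample (one bud) contributes several juvenile leaves; its leaf index is
the arithmetic mean of the per-leaf length/width ratios, *not* the ratio of
mean length to mean width.  The two conventions disagree whenever leaf sizes
vary within a bud, and only the per-leaf-ratio convention is consistent with
published reference measurements for this species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Developmental stage order: juvenile -> mature, leaf index decreasing.
STAGE_ORDER: tuple[str, ...] = ("Li", "La", "Ov", "Bo")

#: Lower-inclusive LI thresholds: label of li is the first interval it falls in.
SHAPE_THRESHOLDS: tuple[tuple[str, float], ...] = (
    ("Li", 5.0),
    ("La", 2.0),
    ("Ov", 1.0),
    ("Bo", 0.0),
)


class OrderingWarning(UserWarning):
    """Stage-mean leaf index is not strictly decreasing in stage order."""


@dataclass(frozen=True)
class LeafMeasurement:
    """One leaf: length and width in centimetres (both > 0)."""

    length_cm: float
    width_cm: float

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise ValueError(
                f"leaf measurements must be positive, got "
                f"L={self.length_cm}, W={self.width_cm}"
            )

    @property
    def leaf_index(self) -> float:
        return self.length_cm / self.width_cm


def leaf_index_stats(
    leaves: Sequence[LeafMeasurement | tuple[float, float]],
) -> tuple[float, float, float]:
    """Mean length, mean width and mean leaf index of a bud's leaves.

    The mean leaf index is the arithmetic mean of per-leaf L/W ratios.

    Parameters
    ----------
    leaves
        Non-empty sequence of ``LeafMeasurement`` or ``(length_cm, width_cm)``
        pairs, all entries positive.

    Returns
    -------
    (mean_length_cm, mean_width_cm, mean_li)
    """
    if len(leaves) == 0:
        raise ValueError("cannot compute leaf index of an empty leaf list")
    ms = [m if isinstance(m, LeafMeasurement) else LeafMeasurement(*m) for m in leaves]
    lengths = np.array([m.length_cm for m in ms])
    widths = np.array([m.width_cm for m in ms])
    return float(lengths.mean()), float(widths.mean()), float((lengths / widths).mean())


def classify_shape(li: float) -> str:
    """Shape class of a leaf index: one of ``Li``, ``La``, ``Ov``, ``Bo``.

    Boundaries are lower-inclusive: 5.0 -> Li, 2.0 -> La, 1.0 -> Ov.
    """
    if not np.isfinite(li) or li <= 0:
        raise ValueError(f"leaf index must be a positive real, got {li!r}")
    for label, lower in SHAPE_THRESHOLDS:
        if li >= lower:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def summarize_samples(
    leaf_table: pd.DataFrame, sample_sheet: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-sample morphometry from a leaf-level table.

    Parameters
    ----------
    leaf_table
        Columns ``sample_id``, ``length_cm``, ``width_cm`` (one row per leaf).
    sample_sheet
        Optional columns ``sample_id``, ``group``; attaches the declared
        stage label of each sample.

    Returns
    -------
    DataFrame indexed by ``sample_id`` with ``mean_length_cm``,
    ``mean_width_cm``, ``mean_li``, ``shape_class`` and (if a sample sheet
    was given) ``stage``.
    """
    required = {"sample_id", "length_cm", "width_cm"}
    missing = required - set(leaf_table.columns)
    if missing:
        raise ValueError(f"leaf table is missing columns: {sorted(missing)}")
    if (leaf_table[["length_cm", "width_cm"]] <= 0).any().any():
        raise ValueError("leaf table contains non-positive measurements")
    g = leaf_table.groupby("sample_id", sort=False)
    out = pd.DataFrame(
        {
            "mean_length_cm": g["length_cm"].mean(),
            "mean_width_cm": g["width_cm"].mean(),
            "mean_li": g.apply(
                lambda d: float((d["length_cm"] / d["width_cm"]).mean()),
                include_groups=False,
            ),
            "n_leaves": g.size(),
        }
    )
    out["shape_class"] = out["mean_li"].map(classify_shape)
    if sample_sheet is not None:
        stages = sample_sheet.set_index("sample_id")["group"]
        unknown = out.index.difference(stages.index)
        if len(unknown):
            raise ValueError(f"samples missing from sample sheet: {list(unknown)}")
        out["stage"] = stages.reindex(out.index)
    return out


def assign_groups(
    samples: pd.DataFrame,
    stage_col: str = "stage",
    li_col: str = "mean_li",
    on_violation: str = "warn",
) -> pd.Categorical:
    """Ordered stage factor (Li < La < Ov < Bo) for a sample table.

    Validates that the stage-mean leaf index strictly decreases in stage
    order; a violation raises :class:`OrderingWarning` (or ``ValueError``
    with ``on_violation="error"``).

    Returns an ordered :class:`pandas.Categorical` aligned with ``samples``;
    its category codes are the stage indices 0..k used by trend detection.
    """
    if on_violation not in {"warn", "error", "ignore"}:
        raise ValueError(f"unknown on_violation mode {on_violation!r}")
    stages = samples[stage_col]
    present = [s for s in STAGE_ORDER if s in set(stages)]
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage labels: {sorted(unknown)}")
    if len(present) < 2:
        raise ValueError("need at least two distinct stages to order groups")
    stage_means = samples.groupby(stage_col)[li_col].mean().reindex(present)
    diffs = np.diff(stage_means.to_numpy())
    if not np.all(diffs < 0):
        msg = (
            "stage-mean leaf index is not strictly decreasing in stage order: "
            + ", ".join(f"{s}={m:.3g}" for s, m in stage_means.items())
        )
        if on_violation == "error":
            raise ValueError(msg)
        if on_violation == "warn":
            warnings.warn(msg, OrderingWarning, stacklevel=2)
    return pd.Categorical(stages, categories=present, ordered=True)
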