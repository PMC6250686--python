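"""Count normalization, abundance units and differential expression.

The expression layer follows the classical bulk RNA-seq recipe for small
replicated designs:

* **median-of-ratios size factors** — each sample's factor is the median,
  over genes detected in every sample, of that sample's count divided by
  the gene's geometric mean across samples;
* **method-of-moments NB dispersion** — with counts modelled as negative
  binomial, Var = mu + alpha * mu^2, alpha is estimated from the pooled
  within-group mean and variance of normalized counts and floored at 1e-8;
* **Wald test on the log fold change** — the difference of log stage means
  is divided by its delta-method standard error and referred to a
  t distribution with ``n_a + n_b - 2`` degrees of freedom, a small-sample
  reference that keeps the test near-nominal at three replicates per group.

The four developmental stages yield six pairwise contrasts, conventionally
labelled A-F in the order La/Li, Ov/Li, Bo/Li, Ov/La, Bo/La, Bo/Ov.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .morphometrics import STAGE_ORDER

RNA_CLASSES = ("mRNA", "miRNA", "lncRNA", "circRNA")

#: The six stage contrasts in conventional order, keyed by their letter.
CONTRAST_LABELS: tuple[tuple[str, tuple[str, str]], ...] = (
    ("A", ("Li", "La")),
    ("B", ("Li", "Ov")),
    ("C", ("Li", "Bo")),
    ("D", ("La", "Ov")),
    ("E", ("La", "Bo")),
    ("F", ("Ov", "Bo")),
)

DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Non-negative integer counts of one RNA class over grouped samples.

    Attributes
    ----------
    counts
        DataFrame, RNAs on rows, samples on columns.
    groups
        Mapping sample id -> stage label; every sample column must appear.
    rna_class
        One of ``mRNA``, ``miRNA``, ``lncRNA``, ``circRNA``.
    """

    counts: pd.DataFrame
    groups: pd.Series
    rna_class: str = "mRNA"

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.rna_class!r}")
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(dict(self.groups))
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a stage label: {sorted(missing)}")
        self.groups = self.groups.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate RNA or sample identifiers in count matrix")

    @property
    def stages(self) -> list[str]:
        """Stages present, in canonical Li < La < Ov < Bo order."""
        present = set(self.groups)
        return [s for s in STAGE_ORDER if s in present]

    def samples_of(self, stage: str) -> list[str]:
        return list(self.groups.index[self.groups == stage])


def size_factors(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    Only genes with strictly positive counts in every sample (non-zero
    geometric mean) enter the median.  Raises if no such gene exists.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in all samples; median-of-ratios "
            "size factors are undefined (try filtering samples or pooling)"
        )
    sub = arr[allpos]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(
    matrix: CountMatrix | pd.DataFrame, factors: pd.Series
) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    if (factors <= 0).any():
        raise ValueError("size factors must all be positive")
    return counts / factors.reindex(counts.columns)


def stage_means(normalized: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-RNA arithmetic mean of normalized counts within each stage.

    Columns are the stages present, in canonical order.
    """
    groups = groups.reindex(normalized.columns)
    present = [s for s in STAGE_ORDER if s in set(groups)]
    return pd.DataFrame(
        {s: normalized.loc[:, groups[groups == s].index].mean(axis=1) for s in present}
    )


def normalize_and_basemean(
    matrix: CountMatrix, factors: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized counts plus per-RNA stage means in one call."""
    if factors is None:
        factors = size_factors(matrix)
    normalized = normalize_counts(matrix, factors)
    return normalized, stage_means(normalized, matrix.groups)


def abundance(
    counts: pd.DataFrame,
    unit: str,
    lengths: Mapping[str, int] | pd.Series | None = None,
) -> pd.DataFrame:
    """Length/depth-normalized abundance in FPKM, TPM or RPM.

    FPKM = count * 1e9 / (length_nt * column_total); TPM rescales the
    per-length rate so each column sums to 1e6; RPM = count * 1e6 /
    column_total (no length term — the unit used for back-splice junction
    reads).  FPKM and TPM require a transcript length for every row.
    """
    unit = unit.upper()
    if unit not in {"FPKM", "TPM", "RPM"}:
        raise ValueError(f"unknown abundance unit {unit!r}")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    if unit == "RPM":
        return counts * 1e6 / totals
    if lengths is None:
        raise ValueError(f"{unit} requires transcript lengths")
    lengths = pd.Series(lengths) if not isinstance(lengths, pd.Series) else lengths
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing lengths for {len(missing)} RNAs, e.g. {missing[0]!r}")
    lens = lengths.reindex(counts.index).astype(float)
    if (lens <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if unit == "FPKM":
        return counts.mul(1e9).div(lens, axis=0).div(totals, axis=1)
    rate = counts.div(lens, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def estimate_dispersion(
    normalized: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str],
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-RNA NB dispersion alpha for a two-stage contrast.

    Method of moments on normalized counts: with the within-group sample
    variances pooled across the two stages and mu the mean over all contrast
    samples, ``alpha = max((s2 - mu) / mu^2, floor)``.  Requires at least
    two replicates per stage.
    """
    groups = groups.reindex(normalized.columns)
    parts = []
    for stage in contrast:
        cols = groups.index[groups == stage]
        if len(cols) < 2:
            raise ValueError(
                f"stage {stage!r} has {len(cols)} replicate(s); "
                "dispersion estimation needs at least 2"
            )
        parts.append(normalized.loc[:, cols])
    s2 = sum(p.var(axis=1, ddof=1) for p in parts) / len(parts)
    mu = pd.concat(parts, axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    return alpha.clip(lower=floor).fillna(floor).rename("dispersion")


def de_test(
    matrix: CountMatrix,
    stage_a: str,
    stage_b: str,
    alpha_level: float = 0.05,
    pseudocount: float = 1.0,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test of ``stage_b`` versus ``stage_a``.

    Returns a DataFrame with one row per RNA: ``basemean`` (mean normalized
    count over the contrast samples), ``log2fc`` = log2((mean_b + c) /
    (mean_a + c)) with pseudocount c, ``pvalue`` from a two-sided Wald test
    of the log-mean difference (t reference, ``n_a + n_b - 2`` df),
    ``dispersion`` and the boolean ``significant`` at ``alpha_level``.
    """
    for stage in (stage_a, stage_b):
        if stage not in set(matrix.groups):
            raise ValueError(f"stage {stage!r} absent from count matrix")
    if factors is None:
        factors = size_factors(matrix)
    normalized = normalize_counts(matrix, factors)
    cols_a = matrix.samples_of(stage_a)
    cols_b = matrix.samples_of(stage_b)
    n_a, n_b = len(cols_a), len(cols_b)
    if min(n_a, n_b) < 2:
        raise ValueError("both stages need at least 2 replicates for testing")
    alpha = estimate_dispersion(normalized, matrix.groups, (stage_a, stage_b))
    m_a = normalized[cols_a].mean(axis=1)
    m_b = normalized[cols_b].mean(axis=1)
    c = pseudocount
    log2fc = np.log2((m_b + c) / (m_a + c))
    # delta method on log means: Var(log m) ~ (1/mu + alpha) / n
    se = np.sqrt((1.0 / (m_a + c) + alpha) / n_a + (1.0 / (m_b + c) + alpha) / n_b)
    wald = (np.log(m_b + c) - np.log(m_a + c)) / se
    pvalue = 2.0 * stats.t.sf(np.abs(wald), df=n_a + n_b - 2)
    out = pd.DataFrame(
        {
            "basemean": pd.concat([normalized[cols_a], normalized[cols_b]], axis=1).mean(
                axis=1
            ),
            "log2fc": log2fc,
            "pvalue": pvalue,
            "dispersion": alpha,
        },
        index=matrix.counts.index,
    )
    out["significant"] = out["pvalue"] < alpha_level
    out.insert(0, "contrast", f"{stage_b}/{stage_a}")
    return out


def pairwise_contrasts(
    matrix: CountMatrix, alpha_level: float = 0.05, pseudocount: float = 1.0
) -> dict[str, pd.DataFrame]:
    """All six stage contrasts, keyed by their conventional letters A-F.

    Requires all four stages.  Contrast ``C`` (Bo/Li) is the one gating
    trend-associated RNA calls.
    """
    missing = [s for s in STAGE_ORDER if s not in set(matrix.groups)]
    if missing:
        raise ValueError(f"missing stages for the six pairwise contrasts: {missing}")
    factors = size_factors(matrix)
    return {
        label: de_test(
            matrix, a, b, alpha_level=alpha_level, pseudocount=pseudocount, factors=factors
        )
        for label, (a, b) in CONTRAST_LABELS
    }


@dataclass(frozen=True)
class TranscriptStructure:
    """Assembled transcript skeleton used by the lncRNA candidate filter."""

    transcript_id: str
    length_nt: int
    exon_count: int

    def __post_init__(self) -> None:
        if self.length_nt <= 0 or self.exon_count < 1:
            raise ValueError(
                f"invalid structure for {self.transcript_id}: "
                f"length={self.length_nt}, exons={self.exon_count}"
            )


def filter_lncrna_candidates(
    structures: Iterable[TranscriptStructure],
    min_length: int = 200,
    min_exons: int = 2,
) -> list[TranscriptStructure]:
    """Structural lncRNA candidate filter.

    Retains transcripts at least ``min_length`` nt long with at least
    ``min_exons`` exons; both boundaries inclusive (a 200 nt, 2-exon
    transcript is kept).
    """
    return [
        s
        for s in structures
        if s.length_nt >= min_length and s.exon_count >= min_exons
    ]


def presence_sets(
    matrix: CountMatrix, min_count: int = 1, min_samples: int = 1
) -> dict[str, object]:
    """Per-stage expressed RNA sets, their intersections and exclusive counts.

    An RNA counts as expressed in a stage when at least ``min_samples`` of
    that stage's replicates have counts >= ``min_count``.

    Returns a dict with keys ``expressed`` (stage -> set of RNA ids),
    ``exclusive`` (stage -> count expressed in that stage only) and
    ``intersections`` (frozenset of stages -> count of RNAs expressed in
    exactly those stages).
    """
    expressed: dict[str, set[str]] = {}
    for stage in matrix.stages:
        cols = matrix.samples_of(stage)
        hits = (matrix.counts[cols] >= min_count).sum(axis=1) >= min_samples
        expressed[stage] = set(matrix.counts.index[hits])
    membership: dict[frozenset, int] = {}
    for rna in matrix.counts.index:
        key = frozenset(s for s, ids in expressed.items() if rna in ids)
        if key:
            membership[key] = membership.get(key, 0) + 1
    exclusive = {
        stage: membership.get(frozenset({stage}), 0) for stage in matrix.stages
    }
    return {"expressed": expressed, "exclusive": exclusive, "intersections": membership}
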