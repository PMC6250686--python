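"""Synthetic ground-truth data for the heterophylly analysis pipeline.

Emulates the study design the pipeline targets — four ordered leaf stages
(Li, La, Ov, Bo) with three biological replicates each — and plants known
signal at every level so downstream stages can be scored against truth:

* **morphometry** — per-leaf length/width pairs whose leaf index is
  lognormal with stage-specific parameters, centred inside each stage's
  classification interval, with stage means decreasing Li -> Bo;
* **counts** — negative-binomial counts (Var = mu + alpha * mu^2) for the
  four RNA classes.  A fraction of RNAs is planted as CLI (expected stage
  means ``mu * 2**(-delta * k)`` for stage index k = 0..3) or OLI (the
  mirror image, increasing to ``mu``); the rest are flat.  Sample library
  sizes are drawn log-uniformly and recorded, so median-of-ratios size
  factors are exercised non-trivially;
* **sequences** — 21-nt small RNAs and 200-1500 nt transcripts over the
  RNA alphabet, with reverse-complement target sites planted for sponge
  triads (decoy + mRNA sharing one miRNA, labels chosen to satisfy the
  calling rules) and extra silencing pairs;
* **annotations** — random term -> gene maps over the mRNA universe with
  one term deliberately enriched among the planted-trend mRNAs.

All generators are deterministic functions of ``(seed, config)``; each
draws from its own child stream of the seed, so adding one generator never
shifts another's output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import CountMatrix, RNA_CLASSES
from .morphometrics import STAGE_ORDER
from .targeting import reverse_complement

_RNA_BASES = np.array(list("ACGU"))

#: Default per-leaf leaf-index lognormal parameters (log-mean, log-sd) per
#: stage, centred well inside each classification interval.
DEFAULT_LI_PARAMS: dict[str, tuple[float, float]] = {
    "Li": (math.log(7.0), 0.12),
    "La": (math.log(3.2), 0.15),
    "Ov": (math.log(1.5), 0.12),
    "Bo": (math.log(0.74), 0.10),
}

#: Typical mean leaf length (cm) per stage, used to split LI into (L, W).
_STAGE_LENGTH_CM = {"Li": 2.8, "La": 2.4, "Ov": 2.3, "Bo": 1.3}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the reference design: 4 stages x 3 replicates,
    two-fold expression change per stage step for planted RNAs
    (``per_stage_log2fc = 1``), NB dispersion 0.05, base mean 100, and 10%
    of RNAs planted in each trend direction.
    """

    seed: int = 0
    n_rna_per_class: dict = field(
        default_factory=lambda: {"mRNA": 2000, "miRNA": 120, "lncRNA": 300, "circRNA": 80}
    )
    n_replicates: int = 3
    groups: tuple = STAGE_ORDER
    frac_cli: float = 0.10
    frac_oli: float = 0.10
    per_stage_log2fc: float = 1.0
    base_mean: float = 100.0
    dispersion: float | dict = 0.05
    library_size_range: tuple = (500_000, 2_000_000)
    li_group_params: dict = field(default_factory=lambda: dict(DEFAULT_LI_PARAMS))
    leaves_per_bud_range: tuple = (7, 13)
    # interactome
    mirna_length: int = 21
    transcript_length_range: tuple = (200, 1500)
    n_sponge_triads: int = 15
    n_extra_silencing: int = 20
    # annotations
    n_terms: int = 50
    term_size_range: tuple = (10, 100)
    planted_term_coverage: float = 0.8
    plant_enriched_term: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.n_replicates, int) or self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        if self.frac_cli < 0 or self.frac_oli < 0 or self.frac_cli + self.frac_oli > 1:
            raise ValueError("need frac_cli, frac_oli >= 0 with sum <= 1")
        if len(set(self.groups)) < 2:
            raise ValueError("need at least 2 distinct stages")
        lo, hi = self.library_size_range
        if lo <= 0 or lo > hi:
            raise ValueError("library_size_range must satisfy 0 < min <= max")
        for alpha in self._dispersions().values():
            if alpha < 0:
                raise ValueError("dispersion must be non-negative")
        missing = [g for g in self.groups if g not in self.li_group_params]
        if missing:
            raise ValueError(f"li_group_params missing stages: {missing}")
        unknown = set(self.n_rna_per_class) - set(RNA_CLASSES)
        if unknown:
            raise ValueError(f"unknown RNA classes: {sorted(unknown)}")

    def _dispersions(self) -> dict[str, float]:
        if isinstance(self.dispersion, Mapping):
            return {c: float(self.dispersion.get(c, 0.05)) for c in self.n_rna_per_class}
        return {c: float(self.dispersion) for c in self.n_rna_per_class}

    def _rng(self, stream: int) -> np.random.Generator:
        # independent child stream per generator
        return np.random.default_rng([self.seed, stream])

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}{r + 1}" for g in self.groups for r in range(self.n_replicates)]

    @property
    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": [g for g in self.groups for _ in range(self.n_replicates)],
                "replicate": [
                    r + 1 for _ in self.groups for r in range(self.n_replicates)
                ],
            }
        )


@dataclass
class TruthTable:
    """Ground truth of one synthetic dataset."""

    trend_truth: dict = field(default_factory=dict)  # rna_id -> CLI/OLI/none
    rna_ids: dict = field(default_factory=dict)  # class -> list of ids
    library_sizes: dict = field(default_factory=dict)  # sample -> library size
    size_factors: dict = field(default_factory=dict)  # sample -> relative factor
    planted_targets: list = field(default_factory=list)  # (mirna, tx, start, score)
    planted_sponge_triads: list = field(default_factory=list)  # (decoy, mirna, mrna)
    enriched_terms: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        d = json.loads(text)
        d["planted_targets"] = [tuple(t) for t in d.get("planted_targets", [])]
        d["planted_sponge_triads"] = [
            tuple(t) for t in d.get("planted_sponge_triads", [])
        ]
        return cls(**d)


def simulate_morphometry(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leaf-level measurements and the sample sheet.

    Per sample, the number of leaves is uniform in ``leaves_per_bud_range``;
    each leaf's index LI is lognormal with the stage's parameters, its
    length lognormal around the stage-typical length, and width = L / LI.

    Returns ``(leaf_table, sample_sheet)``; the leaf table has one row per
    leaf with columns ``sample_id``, ``leaf_no``, ``length_cm``,
    ``width_cm``.
    """
    rng = config._rng(0)
    lo, hi = config.leaves_per_bud_range
    if lo < 1 or lo > hi:
        raise ValueError("leaves_per_bud_range must satisfy 1 <= min <= max")
    rows = []
    for g in config.groups:
        mu, sd = config.li_group_params[g]
        for r in range(config.n_replicates):
            sid = f"{g}{r + 1}"
            n_leaves = int(rng.integers(lo, hi + 1))
            li = rng.lognormal(mu, sd, size=n_leaves)
            length = rng.lognormal(math.log(_STAGE_LENGTH_CM.get(g, 2.0)), 0.15, n_leaves)
            width = length / li
            for i in range(n_leaves):
                rows.append((sid, i + 1, float(length[i]), float(width[i])))
    leaf_table = pd.DataFrame(
        rows, columns=["sample_id", "leaf_no", "length_cm", "width_cm"]
    )
    return leaf_table, config.sample_sheet


def _planted_stage_means(config: SimulationConfig, label: str) -> np.ndarray:
    """Expected stage means of a planted RNA across the ordered stages."""
    k = np.arange(len(config.groups), dtype=float)
    delta = config.per_stage_log2fc
    if label == "CLI":  # decreasing, like the leaf index
        return config.base_mean * 2.0 ** (-delta * k)
    if label == "OLI":  # mirror image: increasing up to the base mean
        return config.base_mean * 2.0 ** (-delta * (k[::-1]))
    return np.full_like(k, config.base_mean)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, Var = mean + alpha mean^2) counts; Poisson when alpha = 0."""
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def simulate_counts(
    config: SimulationConfig,
) -> tuple[dict[str, CountMatrix], TruthTable]:
    """Count matrices for all RNA classes plus the truth table.

    Counts are NB with mean ``s_j * q(g, stage)`` where the relative sample
    factor ``s_j`` comes from a log-uniform library size (normalized to
    geometric mean 1) and ``q`` encodes the planted trend.
    """
    rng = config._rng(1)
    samples = config.sample_ids
    lo, hi = config.library_size_range
    libs = np.exp(rng.uniform(math.log(lo), math.log(hi), size=len(samples)))
    s = libs / np.exp(np.mean(np.log(libs)))
    truth = TruthTable(
        library_sizes={sid: float(v) for sid, v in zip(samples, libs)},
        size_factors={sid: float(v) for sid, v in zip(samples, s)},
    )
    stage_of = {sid: g for sid, g in zip(samples, config.sample_sheet["group"])}
    stage_index = {g: i for i, g in enumerate(config.groups)}
    dispersions = config._dispersions()
    matrices: dict[str, CountMatrix] = {}
    for cls, n_rna in config.n_rna_per_class.items():
        ids = [f"{cls}-{i + 1:04d}" for i in range(n_rna)]
        n_cli = round(config.frac_cli * n_rna)
        n_oli = round(config.frac_oli * n_rna)
        labels = np.array(["CLI"] * n_cli + ["OLI"] * n_oli + ["none"] * (n_rna - n_cli - n_oli))
        rng.shuffle(labels)
        means = np.empty((n_rna, len(samples)))
        for lab in ("CLI", "OLI", "none"):
            mask = labels == lab
            profile = _planted_stage_means(config, lab)
            per_sample = np.array([profile[stage_index[stage_of[sid]]] for sid in samples])
            means[mask] = per_sample[None, :]
        counts = _nb_draw(rng, means * s[None, :], dispersions[cls])
        matrices[cls] = CountMatrix(
            counts=pd.DataFrame(counts, index=ids, columns=samples),
            groups=pd.Series(stage_of),
            rna_class=cls,
        )
        truth.rna_ids[cls] = ids
        truth.trend_truth.update({i: l for i, l in zip(ids, labels)})
    return matrices, truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RNA_BASES, size=length))


def simulate_interactome(
    config: SimulationConfig, truth: TruthTable
) -> tuple[dict[str, str], dict[str, str]]:
    """Small-RNA and transcript sequences with planted target sites.

    Plants ``n_sponge_triads`` sponge triads — a decoy (lncRNA or circRNA,
    alternating) and an mRNA that both carry a perfect site for one shared
    miRNA, with the miRNA's planted trend opposite the pair's — plus
    ``n_extra_silencing`` plain miRNA -> mRNA pairs with opposite trends.
    Updates ``truth.planted_targets`` / ``truth.planted_sponge_triads`` in
    place and returns ``(small_rna_seqs, transcript_seqs)``.
    """
    if not truth.rna_ids:
        raise ValueError("truth table has no RNA ids; run simulate_counts first")
    rng = config._rng(2)
    lo, hi = config.transcript_length_range
    if lo < config.mirna_length:
        raise ValueError("transcripts must be at least one small-RNA length long")

    small = {
        mid: _random_seq(rng, config.mirna_length)
        for mid in truth.rna_ids.get("miRNA", [])
    }
    transcripts = {
        tid: _random_seq(rng, int(rng.integers(lo, hi + 1)))
        for cls in ("mRNA", "lncRNA", "circRNA")
        for tid in truth.rna_ids.get(cls, [])
    }

    def pool(cls: str, label: str) -> list[str]:
        return [i for i in truth.rna_ids.get(cls, []) if truth.trend_truth[i] == label]

    planted_pairs: set[tuple[str, str]] = set()

    def plant(mirna_id: str, tx_id: str) -> None:
        if (mirna_id, tx_id) in planted_pairs:
            return
        site = reverse_complement(small[mirna_id])
        seq = transcripts[tx_id]
        start = int(rng.integers(0, len(seq) - len(site) + 1))
        transcripts[tx_id] = seq[:start] + site + seq[start + len(site):]
        truth.planted_targets.append((mirna_id, tx_id, start, 0.0))
        planted_pairs.add((mirna_id, tx_id))

    mir_pools = {"CLI": pool("miRNA", "CLI"), "OLI": pool("miRNA", "OLI")}
    mrna_pools = {"CLI": pool("mRNA", "CLI"), "OLI": pool("mRNA", "OLI")}
    decoy_pools = {
        cls: {"CLI": pool(cls, "CLI"), "OLI": pool(cls, "OLI")}
        for cls in ("lncRNA", "circRNA")
    }
    for lab in ("CLI", "OLI"):
        rng.shuffle(mir_pools[lab])
        rng.shuffle(mrna_pools[lab])
        for cls in decoy_pools:
            rng.shuffle(decoy_pools[cls][lab])

    decoy_classes = ("lncRNA", "circRNA")
    for t in range(config.n_sponge_triads):
        mir_lab = "CLI" if t % 2 == 0 else "OLI"
        pair_lab = "OLI" if mir_lab == "CLI" else "CLI"
        cls = decoy_classes[(t // 2) % 2]
        if not (mir_pools[mir_lab] and mrna_pools[pair_lab] and decoy_pools[cls][pair_lab]):
            raise ValueError(
                "not enough planted-trend RNAs to build the requested sponge "
                "triads; raise frac_cli/frac_oli or the class sizes"
            )
        mirna = mir_pools[mir_lab].pop()
        mrna = mrna_pools[pair_lab].pop()
        decoy = decoy_pools[cls][pair_lab].pop()
        plant(mirna, decoy)
        plant(mirna, mrna)
        truth.planted_sponge_triads.append((decoy, mirna, mrna))

    for t in range(config.n_extra_silencing):
        mir_lab = "CLI" if t % 2 == 0 else "OLI"
        tgt_lab = "OLI" if mir_lab == "CLI" else "CLI"
        if not (mir_pools[mir_lab] and mrna_pools[tgt_lab]):
            break
        plant(mir_pools[mir_lab].pop(), mrna_pools[tgt_lab].pop())

    return small, transcripts


def simulate_annotations(config: SimulationConfig, truth: TruthTable):
    """Random term -> gene annotation over the mRNA universe.

    When ``plant_enriched_term`` is set, one term ("term-planted") covers
    ``planted_term_coverage`` of the planted-trend (CLI or OLI) mRNAs and
    is recorded in ``truth.enriched_terms``; the remaining ``n_terms``
    terms draw genes uniformly from the universe.
    """
    from .enrichment import AnnotationMap

    rng = config._rng(3)
    universe = list(truth.rna_ids.get("mRNA", []))
    if not universe:
        raise ValueError("truth table has no mRNA ids; run simulate_counts first")
    lo, hi = config.term_size_range
    if config.n_terms and hi > len(universe):
        raise ValueError("term size range exceeds the mRNA universe")
    terms: dict[str, set] = {}
    if config.plant_enriched_term:
        trended = [g for g in universe if truth.trend_truth[g] != "none"]
        n_pick = round(config.planted_term_coverage * len(trended))
        picked = rng.choice(trended, size=n_pick, replace=False) if n_pick else []
        terms["term-planted"] = set(map(str, picked))
        truth.enriched_terms = ["term-planted"]
    for i in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        terms[f"term-{i + 1:03d}"] = set(
            map(str, rng.choice(universe, size=size, replace=False))
        )
    return AnnotationMap(terms=terms, universe=set(universe))


@dataclass
class SyntheticDataset:
    """Everything one synthetic study produces, bundled."""

    config: SimulationConfig
    leaf_table: pd.DataFrame
    sample_sheet: pd.DataFrame
    counts: dict
    truth: TruthTable
    small_rna_seqs: dict
    transcript_seqs: dict
    annotations: object


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run all four generators under one config."""
    config = config or SimulationConfig()
    leaf_table, sample_sheet = simulate_morphometry(config)
    counts, truth = simulate_counts(config)
    small, transcripts = simulate_interactome(config, truth)
    annotations = simulate_annotations(config, truth)
    return SyntheticDataset(
        config=config,
        leaf_table=leaf_table,
        sample_sheet=sample_sheet,
        counts=counts,
        truth=truth,
        small_rna_seqs=small,
        transcript_seqs=transcripts,
        annotations=annotations,
    )
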