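"""End-to-end orchestration: morphometrics -> DE -> trends -> network.

``run_all`` chains the analysis stages over an in-memory :class:`Bundle`
(either loaded from files via :func:`load_dataset` or taken from the
synthetic generator), optionally writing every result table plus a JSON
run manifest to an output directory.  The run is deterministic: every
stage is a pure function of the inputs and thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from . import cerna, enrichment, expression, io, morphometrics, phma, targeting
from .simulate import SyntheticDataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Thresholds and mode flags of one analysis run."""

    alpha: float = 0.05  # significance gate, raw p
    trend_tolerance: float = 0.0  # relative tolerance for monotone steps
    target_cutoff: float = 5.0  # max duplex expectation reported
    presence_min_count: int = 1
    presence_min_samples: int = 1
    strict_cerna: bool = False
    use_bh: bool = False  # gate PHMA on BH-adjusted q instead of raw p
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.trend_tolerance < 0 or self.target_cutoff < 0:
            raise ValueError("tolerances and cutoffs must be non-negative")


@dataclass
class PipelineConfig:
    """File locations plus parameters; the CLI's view of a run."""

    counts: dict = field(default_factory=dict)  # rna_class -> path
    sample_sheet: str = ""
    leaf_table: str = ""
    small_rnas: str = ""
    transcripts: str = ""
    annotations: str = ""
    outdir: str = "results"
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)


@dataclass
class Bundle:
    """Validated in-memory dataset the pipeline runs on."""

    counts: dict  # rna_class -> CountMatrix
    sample_sheet: pd.DataFrame
    leaf_table: pd.DataFrame | None = None
    small_rna_seqs: dict = field(default_factory=dict)
    transcript_seqs: dict = field(default_factory=dict)
    annotations: object | None = None

    @classmethod
    def from_synthetic(cls, dataset: SyntheticDataset) -> "Bundle":
        return cls(
            counts=dataset.counts,
            sample_sheet=dataset.sample_sheet,
            leaf_table=dataset.leaf_table,
            small_rna_seqs=dataset.small_rna_seqs,
            transcript_seqs=dataset.transcript_seqs,
            annotations=dataset.annotations,
        )


def load_dataset(config: PipelineConfig) -> Bundle:
    """Load and cross-validate all input files of a configured run."""
    sheet = io.read_sample_sheet(config.sample_sheet)
    counts = {
        rna_class: io.read_counts(path, sheet, rna_class)
        for rna_class, path in config.counts.items()
    }
    for rna_class, matrix in counts.items():
        logger.info(
            "loaded %s: %d RNAs x %d samples", rna_class, *matrix.counts.shape
        )
    leaf_table = io.read_leaf_table(config.leaf_table) if config.leaf_table else None
    small = io.read_fasta(config.small_rnas) if config.small_rnas else {}
    transcripts = io.read_fasta(config.transcripts) if config.transcripts else {}
    annotations = (
        io.read_annotation_map(config.annotations) if config.annotations else None
    )
    return Bundle(
        counts=counts,
        sample_sheet=sheet,
        leaf_table=leaf_table,
        small_rna_seqs=small,
        transcript_seqs=transcripts,
        annotations=annotations,
    )


@dataclass
class PipelineResult:
    """Everything one run produces."""

    morphometry: pd.DataFrame | None
    stage_means: dict  # rna_class -> DataFrame
    de: dict  # rna_class -> {contrast letter -> DataFrame}
    phma_records: pd.DataFrame
    phma_counts: pd.DataFrame
    target_pairs: list
    silencing_edges: list
    cerna_candidates: list
    cerna_edges: list
    network: nx.MultiDiGraph
    network_summary: dict
    enrichment: pd.DataFrame | None
    manifest: dict


def run_all(
    bundle: Bundle,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every analysis stage over a dataset bundle.

    Asserts the core invariant that the trend-associated (PHMA) set of
    every RNA class is a subset of the significant Bo/Li set.
    """
    params = params or PipelineParams()

    morpho = None
    if bundle.leaf_table is not None and len(bundle.leaf_table):
        morpho = morphometrics.summarize_samples(bundle.leaf_table, bundle.sample_sheet)
        morphometrics.assign_groups(morpho)

    classes = {}
    labels = {}
    stage_mean_tables = {}
    de_tables: dict[str, dict[str, pd.DataFrame]] = {}
    records = []
    for rna_class, matrix in bundle.counts.items():
        factors = expression.size_factors(matrix)
        normalized = expression.normalize_counts(matrix, factors)
        means = expression.stage_means(normalized, matrix.groups)
        stage_mean_tables[rna_class] = means
        de_tables[rna_class] = expression.pairwise_contrasts(
            matrix, alpha_level=params.alpha
        )
        trends = phma.trend_labels(means, rel_tolerance=params.trend_tolerance)
        li_bo = de_tables[rna_class]["C"]
        pvals = li_bo["pvalue"]
        if params.use_bh:
            from statsmodels.stats.multitest import multipletests

            pvals = pd.Series(
                multipletests(pvals, method="fdr_bh")[1], index=pvals.index
            )
        rec = phma.phma_classify(trends, pvals, rna_class=rna_class, alpha=params.alpha)
        phma_set = set(rec.index[rec["is_phma"]])
        significant = set(li_bo.index[pvals < params.alpha])
        assert phma_set <= significant, (
            f"{rna_class}: PHMA set escapes the significant Bo/Li set"
        )
        records.append(rec)
        labels.update(trends.to_dict())
        classes.update({rna_id: rna_class for rna_id in matrix.counts.index})
    phma_records = pd.concat(records) if records else pd.DataFrame()
    phma_counts = phma.phma_summary(phma_records)

    pairs: list = []
    silencing: list = []
    candidates: list = []
    edges: list = []
    network, summary = nx.MultiDiGraph(), {}
    if bundle.small_rna_seqs and bundle.transcript_seqs:
        pairs = targeting.predict_targets(
            bundle.small_rna_seqs, bundle.transcript_seqs, cutoff=params.target_cutoff
        )
        silencing = targeting.mirna_mrna_edges(
            [p for p in pairs if classes.get(p.transcript_id) == "mRNA"], labels
        )
        decoy_silencing = targeting.mirna_mrna_edges(
            [p for p in pairs if classes.get(p.transcript_id) in cerna.DECOY_CLASSES],
            labels,
        )
        candidates = cerna.shared_mirna_pairs(pairs, classes)
        edges = cerna.cerna_edges(candidates, labels, strict=params.strict_cerna)
        network, summary = cerna.assemble_network(
            silencing + decoy_silencing, edges, labels, classes
        )

    enrich = None
    if bundle.annotations is not None and "mRNA" in bundle.counts:
        phma_mrnas = set(
            phma_records.index[
                (phma_records["rna_class"] == "mRNA") & phma_records["is_phma"]
            ]
        )
        selection = phma_mrnas & bundle.annotations.universe
        dropped = len(phma_mrnas) - len(selection)
        if dropped:
            logger.info("%d PHMA mRNAs outside the annotation universe", dropped)
        enrich = enrichment.hypergeom_enrich(selection, bundle.annotations)

    manifest = _manifest(bundle, params, phma_counts, summary)
    result = PipelineResult(
        morphometry=morpho,
        stage_means=stage_mean_tables,
        de=de_tables,
        phma_records=phma_records,
        phma_counts=phma_counts,
        target_pairs=pairs,
        silencing_edges=silencing,
        cerna_candidates=candidates,
        cerna_edges=edges,
        network=network,
        network_summary=summary,
        enrichment=enrich,
        manifest=manifest,
    )
    if outdir is not None:
        write_results(result, outdir)
    return result


def _manifest(bundle: Bundle, params: PipelineParams, phma_counts, summary) -> dict:
    import numpy
    import scipy

    param_dict = dataclasses.asdict(params)
    return {
        "package_version": __version__,
        "versions": {
            "numpy": numpy.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "networkx": nx.__version__,
        },
        "params": param_dict,
        "config_hash": hashlib.sha256(
            json.dumps(param_dict, sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": params.seed,
        "n_samples": int(len(bundle.sample_sheet)),
        "n_rna": {c: int(m.counts.shape[0]) for c, m in bundle.counts.items()},
        "phma_counts": {
            str(k): {kk: int(vv) for kk, vv in row.items()}
            for k, row in phma_counts.to_dict("index").items()
        },
        "network": summary,
    }


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    """Write every result table; file names are stable across runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result.morphometry is not None:
        io.write_table(result.morphometry, outdir / "morphometry.tsv")
    for rna_class, tables in result.de.items():
        for label, df in tables.items():
            io.write_table(
                df.rename_axis("rna_id"), outdir / f"de_{rna_class}_{label}.tsv"
            )
    io.write_table(result.phma_records, outdir / "phma.tsv")
    io.write_table(result.phma_counts.rename_axis("rna_class"), outdir / "phma_summary.tsv")
    io.write_target_pairs(result.target_pairs, outdir / "target_pairs.tsv")
    io.write_target_pairs(result.silencing_edges, outdir / "silencing_edges.tsv")
    pd.DataFrame(
        [
            {
                "decoy_id": e.decoy_id,
                "mrna_id": e.mrna_id,
                "shared_mirnas": ",".join(sorted(e.shared_mirna_ids)),
                "decoy_label": e.decoy_label,
                "mrna_label": e.mrna_label,
            }
            for e in result.cerna_edges
        ],
        columns=["decoy_id", "mrna_id", "shared_mirnas", "decoy_label", "mrna_label"],
    ).to_csv(outdir / "cerna_edges.tsv", sep="\t", index=False)
    if result.network.number_of_nodes():
        nx.write_graphml(result.network, outdir / "network.graphml")
    if result.enrichment is not None:
        io.write_table(result.enrichment, outdir / "enrichment.tsv", index=False)
    io.write_json(result.manifest, outdir / "manifest.json")
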