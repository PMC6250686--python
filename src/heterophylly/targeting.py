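"""Plant small-RNA target-site scoring and target prediction.

Plant miRNAs recognise near-perfectly complementary sites on their targets,
so target prediction reduces to scanning each transcript for windows whose
duplex with the miRNA carries a low penalty ("expectation") score.  The
scheme here is the classical plant rule set:

* per aligned position (1-indexed from the miRNA 5' end): Watson-Crick
  match 0, G:U wobble 0.5, mismatch 1;
* penalties are doubled inside the core region, positions 2-13, which
  covers the seed and the cleavage site;
* no gaps; the duplex is an ungapped antiparallel alignment of the miRNA
  against the transcript window.

Lower scores are better; 0 is perfect complementarity.  Pairs at or below
the reporting cutoff (default 5.0) are called targets.  The second step of
interaction calling keeps only miRNA-target pairs whose expression trends
are opposite (one CLI, one OLI), since effective silencing should depress
the target whenever the miRNA rises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

CORE_START, CORE_END = 2, 13  # 1-indexed, inclusive
DEFAULT_CUTOFF = 5.0

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_VALID = set("ACGU")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; validate the alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    s = normalize_rna(seq)
    return "".join(_COMPLEMENT[b] for b in reversed(s))


@dataclass(frozen=True)
class TargetPair:
    """Best-scoring predicted site of a small RNA on a transcript.

    ``site_start`` is the 0-based offset of the site window on the
    transcript (half-open: the site is ``transcript[start : start + len]``).
    """

    small_rna_id: str
    transcript_id: str
    expectation: float
    site_start: int
    site_seq: str = ""


def score_duplex(mirna_seq: str, site_seq: str) -> float:
    """Penalty expectation of an ungapped miRNA:site duplex.

    ``site_seq`` is the target window in its transcript (5'->3') sense; a
    perfect site is the reverse complement of the miRNA.  Positions are
    counted from the miRNA 5' end; the miRNA's i-th base is paired with the
    site's (L - i + 1)-th base.
    """
    mir = normalize_rna(mirna_seq)
    site = normalize_rna(site_seq)
    if len(mir) != len(site):
        raise ValueError(
            f"duplex strands differ in length: {len(mir)} vs {len(site)}"
        )
    total = 0.0
    L = len(mir)
    for i, base in enumerate(mir):  # i = 0 is miRNA position 1
        partner = site[L - 1 - i]
        if _COMPLEMENT[base] == partner:
            penalty = 0.0
        elif {base, partner} == {"G", "U"}:
            penalty = 0.5
        else:
            penalty = 1.0
        if CORE_START <= i + 1 <= CORE_END:
            penalty *= 2.0
        total += penalty
    return total


_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_CODE_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->U, C<->G as codes


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode().translate(bytes.maketrans(b"ACGU", bytes(range(4)))), dtype=np.uint8
    )


def _penalty_table(mir_codes: np.ndarray) -> np.ndarray:
    """Per (miRNA position, partner base code) penalty, core doubling applied."""
    L = len(mir_codes)
    table = np.ones((L, 4))
    table[np.arange(L), _CODE_COMPLEMENT[mir_codes]] = 0.0
    # G:U wobble: miRNA G with site U, miRNA U with site G
    table[mir_codes == _CODE["G"], _CODE["U"]] = 0.5
    table[mir_codes == _CODE["U"], _CODE["G"]] = 0.5
    core = (np.arange(1, L + 1) >= CORE_START) & (np.arange(1, L + 1) <= CORE_END)
    table[core] *= 2.0
    return table


def window_scores(mirna_seq: str, transcript_seq: str) -> np.ndarray:
    """Expectation of every ungapped window, indexed by 0-based offset.

    Equivalent to ``[score_duplex(m, t[o:o+L]) for o in ...]`` but computed
    with per-position penalty lookups over the whole transcript at once.
    """
    mir = normalize_rna(mirna_seq)
    tx = normalize_rna(transcript_seq)
    L = len(mir)
    if len(tx) < L:
        raise ValueError("transcript shorter than the small RNA")
    mir_codes = _encode(mir)
    tx_codes = _encode(tx)
    table = _penalty_table(mir_codes)
    n_windows = len(tx) - L + 1
    scores = np.zeros(n_windows)
    for i in range(L):
        j = L - 1 - i  # site offset (within window) paired with miRNA pos i+1
        scores += table[i][tx_codes[j : j + n_windows]]
    return scores


def best_site(mirna_seq: str, transcript_seq: str) -> tuple[float, int]:
    """Minimum expectation over all ungapped windows, with its 0-based offset.

    Ties go to the leftmost window.  Raises if the transcript is shorter
    than the small RNA.
    """
    scores = window_scores(mirna_seq, transcript_seq)
    off = int(np.argmin(scores))
    return float(scores[off]), off


def predict_targets(
    small_rnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[TargetPair]:
    """Call target pairs for every (small RNA, transcript) combination.

    Scans each transcript with each small RNA, keeps the best window and
    reports pairs with expectation <= ``cutoff``.  Transcripts shorter than
    a small RNA are skipped for that small RNA with a warning.
    """
    if not small_rnas or not transcripts:
        raise ValueError("need at least one small RNA and one transcript")
    mirs = {k: normalize_rna(v) for k, v in small_rnas.items()}
    txs = {k: normalize_rna(v) for k, v in transcripts.items()}

    # One concatenated scan per small RNA: transcripts are joined with a
    # sentinel code whose per-position penalty dwarfs the cutoff, so any
    # window crossing a boundary can never be reported.
    max_len = max(len(s) for s in mirs.values())
    sep = max_len - 1
    order = list(txs)
    starts, chunks, pos = {}, [], 0
    for tid in order:
        starts[tid] = pos
        chunks.append(_encode(txs[tid]))
        chunks.append(np.full(sep, 4, dtype=np.uint8))
        pos += len(txs[tid]) + sep
    concat = np.concatenate(chunks)

    pairs: list[TargetPair] = []
    for mid, mseq in mirs.items():
        L = len(mseq)
        table = np.concatenate(
            [_penalty_table(_encode(mseq)), np.full((L, 1), 1e9)], axis=1
        )
        n_windows = len(concat) - L + 1
        if n_windows <= 0:
            logger.warning("all transcripts shorter than small RNA %s; skipped", mid)
            continue
        scores = np.zeros(n_windows)
        for i in range(L):
            j = L - 1 - i
            scores += table[i][concat[j : j + n_windows]]
        for tid in order:
            tseq = txs[tid]
            if len(tseq) < L:
                logger.warning(
                    "transcript %s (%d nt) shorter than small RNA %s (%d nt); skipped",
                    tid, len(tseq), mid, L,
                )
                continue
            window = scores[starts[tid] : starts[tid] + len(tseq) - L + 1]
            off = int(np.argmin(window))
            score = float(window[off])
            if score <= cutoff:
                pairs.append(TargetPair(mid, tid, score, off, tseq[off : off + L]))
    return pairs


def mirna_mrna_edges(
    pairs: Iterable[TargetPair], labels: Mapping[str, str]
) -> list[TargetPair]:
    """Silencing interactions: target pairs whose trend labels are opposite.

    A pair survives only when one endpoint is CLI and the other OLI.  Pairs
    with an unlabeled endpoint are dropped with a warning.
    """
    edges = []
    for pair in pairs:
        lm = labels.get(pair.small_rna_id)
        lt = labels.get(pair.transcript_id)
        if lm is None or lt is None:
            logger.warning(
                "dropping pair (%s, %s): missing trend label",
                pair.small_rna_id, pair.transcript_id,
            )
            continue
        if {lm, lt} == {"CLI", "OLI"}:
            edges.append(pair)
    return edges
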