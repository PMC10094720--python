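"""Adapter trimming and the mature-first one-mismatch alignment cascade.

Trimmed reads are placed on the mature tRNA references first; only reads with
no mature placement are tried against the precursors. At most one substitution
(Hamming) mismatch is tolerated — the allowance absorbs reverse-transcription
misincorporation at modified bases (m1A, m3C) rather than sequencing error.
Indels are not modelled: tsRNA reads are short and substitution-only distance
is the appropriate metric at this scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

#: smallest subtype window lower bound; reads shorter than this are rejected
MIN_FRAGMENT_LEN = 14

DEFAULT_MIN_OVERLAP = 3

REF_MATURE = "mature"
REF_PRECURSOR = "precursor"


@dataclass(frozen=True)
class Read:
    """A collapsed read: one unique sequence with its multiplicity."""

    read_id: str
    seq: str
    count: int = 1

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError("empty read sequence")
        if self.count < 1:
            raise ValueError("read count must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    """Placement of a fragment on a reference sequence."""

    read_id: str
    gene_id: str
    ref_kind: str  # mature | precursor
    start: int
    end: int
    mismatches: int


def load_read_counts(path) -> dict[str, int]:
    """Read a FASTQ/FASTA file (gzip allowed) into ``{sequence: multiplicity}``.

    Pre-collapsed FASTA with a ``;count=N`` name suffix is honoured; quality
    values are ignored (only sequences matter after the pass-filter step).
    """
    counts: dict[str, int] = {}
    with pysam.FastxFile(str(path)) as handle:
        for entry in handle:
            seq = entry.sequence.upper()
            mult = 1
            if ";count=" in entry.name:
                mult = int(entry.name.rsplit(";count=", 1)[1])
            counts[seq] = counts.get(seq, 0) + mult
    return counts


def trim_adapter(
    raw_seq: str,
    adapter3: Optional[str] = None,
    adapter5: Optional[str] = None,
    min_len: int = MIN_FRAGMENT_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> Optional[str]:
    """Remove literal adapter sequence; return the insert or ``None`` if too short.

    The 3' adapter is matched as an exact prefix-overlap at the read 3' end
    (leftmost occurrence wins, >= ``min_overlap`` nt); the 5' adapter as an
    exact suffix-overlap at the read 5' end. Rejection (``None``) is a normal,
    counted outcome, not an error.
    """
    seq = raw_seq.upper()
    if adapter5:
        jmax = min(len(adapter5), len(seq))
        for j in range(jmax, min_overlap - 1, -1):
            if seq[:j] == adapter5[-j:]:
                seq = seq[j:]
                break
    if adapter3:
        la = len(adapter3)
        for i in range(0, len(seq) - min_overlap + 1):
            tail = seq[i : i + la]
            if tail == adapter3[: len(tail)]:
                seq = seq[:i]
                break
    return seq if len(seq) >= min_len else None


def align_one(
    seq: str, reference_seq: str, max_mismatches: int = 1
) -> list[tuple[int, int]]:
    """All minimal-mismatch placements of ``seq`` on ``reference_seq``.

    Scans every offset, keeps offsets whose Hamming distance is within
    ``max_mismatches``, then retains only the minimal-distance placements.
    Returns ``[(start, mismatches), ...]`` in ascending start order.
    """
    m, n = len(seq), len(reference_seq)
    if m == 0 or m > n:
        return []
    query = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ref = np.frombuffer(reference_seq.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(ref, m)
    mismatches = (windows != query).sum(axis=1)
    ok = np.flatnonzero(mismatches <= max_mismatches)
    if ok.size == 0:
        return []
    best = int(mismatches[ok].min())
    keep = ok[mismatches[ok] == best]
    return [(int(s), best) for s in keep]


def _best_across(
    seq: str, models: Sequence, max_mismatches: int
) -> list[tuple[str, int, int]]:
    """Equally-best placements of ``seq`` over a set of reference models.

    A 0-mismatch placement anywhere suppresses 1-mismatch placements on every
    other gene: only globally minimal-mismatch hits survive.
    """
    found: list[tuple[str, int, int]] = []
    for model in models:
        for start, mm in align_one(seq, model.seq, max_mismatches):
            found.append((model.gene_id, start, mm))
    if not found:
        return []
    best = min(f[2] for f in found)
    return [f for f in found if f[2] == best]


def align_cascade(
    reads: Iterable[Read],
    matures: Sequence,
    precursors: Sequence,
    max_mismatches: int = 1,
) -> tuple[list[AlignmentHit], dict[str, int]]:
    """Mature-first cascade: reads unplaced on any mature go to the precursors.

    Returns the hit list plus multiplicity-weighted tallies for the partition
    ``aligned_mature + aligned_precursor + unaligned`` (adapter rejections are
    tallied upstream, before reads reach the cascade).
    """
    hits: list[AlignmentHit] = []
    stats = {REF_MATURE: 0, REF_PRECURSOR: 0, "unaligned": 0}
    for read in reads:
        placements = _best_across(read.seq, matures, max_mismatches)
        kind = REF_MATURE
        if not placements:
            placements = _best_across(read.seq, precursors, max_mismatches)
            kind = REF_PRECURSOR
        if not placements:
            stats["unaligned"] += read.count
            continue
        stats[kind] += read.count
        end_offset = len(read.seq)
        for gene_id, start, mm in placements:
            hits.append(
                AlignmentHit(read.read_id, gene_id, kind, start, start + end_offset, mm)
            )
    logger.info(
        "cascade: %d reads on matures, %d on precursors, %d unaligned",
        stats[REF_MATURE],
        stats[REF_PRECURSOR],
        stats["unaligned"],
    )
    return hits, stats
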