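"""tRNA reference models.

A tRNA locus is described by its genomic body (introns included), an optional
5' leader and 3' trailer, and the anticodon position. From a gene two alignable
references are derived:

* the **mature** tRNA — intron removed, non-templated ``CCA`` appended — with an
  annotated cloverleaf anatomy (acceptor stem, D-arm, anticodon stem/loop,
  T-arm, CCA tail), and
* the **precursor** — leader + body + trailer — carrying the RNase Z cut site
  (the body/trailer junction) and the RNA polymerase III terminator (the first
  run of >= 4 consecutive T in the trailer).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

#: minimum number of consecutive T recognised as a pol III termination signal
TERMINATOR_MIN_T = 4

#: width of the anticodon loop: the 7-nt single-stranded loop centred on the
#: anticodon triplet (canonical positions 32-38)
DEFAULT_LOOP_WIDTH = 7

#: paired nucleotides on each side of the anticodon stem
ANTICODON_STEM_WIDTH = 5

ANATOMY_COLUMNS = [
    "gene_id",
    "amino_acid",
    "anticodon",
    "anticodon_start",
    "intron_start",
    "intron_end",
    "leader_seq",
    "trailer_seq",
]


class ReferenceError(ValueError):
    """Raised when reference inputs violate the tRNA gene contracts."""


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TRNAGene:
    """One tRNA locus.

    ``body_seq`` is the genomic tRNA body on the + strand (minus-strand genes
    must be reverse-complemented upstream). ``anticodon_start`` indexes the
    first anticodon base on the *intron-removed* body.
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    body_seq: str
    anticodon_start: int
    chromosome: str = "."
    strand: str = "+"
    intron_span: Optional[Interval] = None
    leader_seq: str = ""
    trailer_seq: str = ""

    @property
    def mature_body(self) -> str:
        """Body sequence with the annotated intron removed."""
        if self.intron_span is None:
            return self.body_seq
        return (
            self.body_seq[: self.intron_span.start]
            + self.body_seq[self.intron_span.end :]
        )

    @property
    def family(self) -> tuple[str, str]:
        """Isodecoder family key: (amino acid, anticodon)."""
        return (self.amino_acid, self.anticodon)

    def validate(self) -> None:
        """Raise :class:`ReferenceError` listing every violated invariant."""
        problems: list[str] = []
        for label, seq in (
            ("body_seq", self.body_seq),
            ("leader_seq", self.leader_seq),
            ("trailer_seq", self.trailer_seq),
            ("anticodon", self.anticodon),
        ):
            bad = set(seq) - DNA_ALPHABET
            if bad:
                problems.append(f"non-DNA characters {sorted(bad)} in {label}")
        if len(self.anticodon) != 3:
            problems.append(f"anticodon {self.anticodon!r} is not 3 nt")
        if self.strand not in {"+", "-"}:
            problems.append(f"invalid strand {self.strand!r}")
        if self.intron_span is not None and not (
            0 < self.intron_span.start
            and self.intron_span.end < len(self.body_seq)
            and self.intron_span.width > 0
        ):
            problems.append(
                f"intron {self.intron_span} not strictly inside "
                f"{len(self.body_seq)}-nt body"
            )
        if not problems:
            mb = self.mature_body
            a = self.anticodon_start
            if not 0 <= a <= len(mb) - 3:
                problems.append(f"anticodon_start {a} outside intron-removed body")
            elif mb[a : a + 3] != self.anticodon:
                problems.append(
                    f"anticodon {self.anticodon} != body[{a}:{a + 3}] ({mb[a:a + 3]})"
                )
        if problems:
            raise ReferenceError(f"{self.gene_id}: " + "; ".join(problems))


@dataclass(frozen=True)
class Anatomy:
    """Cloverleaf intervals on the mature coordinate system.

    Intervals are non-overlapping and ordered 5'->3'; ``cca`` is the final
    three positions. ``anticodon_stem`` is the 5' strand of the stem; the 3'
    strand is taken to mirror its width immediately after the loop (see
    :attr:`anticodon_stemloop_region`).
    """

    acceptor_stem: Interval
    d_arm: Interval
    anticodon_stem: Interval
    anticodon_loop: Interval
    t_arm: Interval
    cca: Interval

    @property
    def anticodon_stemloop_region(self) -> Interval:
        """Region spanned by the anticodon stem-loop: 5' stem through the
        mirror-width 3' stem strand. Anchors the tRF-2 containment rule."""
        return Interval(
            self.anticodon_stem.start,
            self.anticodon_loop.end + self.anticodon_stem.width,
        )

    def ordered(self) -> Sequence[Interval]:
        return (
            self.acceptor_stem,
            self.d_arm,
            self.anticodon_stem,
            self.anticodon_loop,
            self.t_arm,
            self.cca,
        )

    def validate(self, seq_len: int, anticodon_start: Optional[int] = None) -> None:
        parts = self.ordered()
        for prev, nxt in zip(parts, parts[1:]):
            if prev.end > nxt.start:
                raise ReferenceError(f"anatomy intervals out of order: {prev} > {nxt}")
        if parts[-1].end > seq_len:
            raise ReferenceError("anatomy exceeds sequence bounds")
        if self.cca != Interval(seq_len - 3, seq_len):
            raise ReferenceError("cca must be the final 3 positions")
        if anticodon_start is not None:
            triplet = Interval(anticodon_start, anticodon_start + 3)
            if not (
                self.anticodon_loop.start <= triplet.start
                and triplet.end <= self.anticodon_loop.end
            ):
                raise ReferenceError("anticodon triplet outside the anticodon loop")


def default_anatomy(
    seq_len: int, anticodon_start: int, loop_width: int = DEFAULT_LOOP_WIDTH
) -> Anatomy:
    """Canonical anatomy for a mature tRNA of ``seq_len`` nt.

    The anticodon loop is the ``loop_width``-nt window centred on the anticodon
    triplet; remaining arms use canonical coordinates clipped to fit short or
    unusual bodies.
    """
    half = (loop_width - 3) // 2  # bases 5' of the anticodon triplet inside the loop
    loop_start = anticodon_start - half
    if loop_start < 0 or loop_start + loop_width > seq_len - 3:
        raise ReferenceError(
            f"anticodon at {anticodon_start} too close to an end for a "
            f"{loop_width}-nt loop on a {seq_len}-nt mature sequence"
        )
    loop = Interval(loop_start, loop_start + loop_width)
    stem_start = max(0, loop.start - ANTICODON_STEM_WIDTH)
    anticodon_stem = Interval(stem_start, loop.start)
    acceptor_stem = Interval(0, min(7, stem_start))
    d_arm = Interval(min(9, stem_start), min(25, stem_start))
    t_arm_start = min(loop.end + anticodon_stem.width + 2, seq_len - 3)
    t_arm = Interval(t_arm_start, seq_len - 3)
    cca = Interval(seq_len - 3, seq_len)
    anatomy = Anatomy(acceptor_stem, d_arm, anticodon_stem, loop, t_arm, cca)
    anatomy.validate(seq_len, anticodon_start)
    return anatomy


@dataclass(frozen=True)
class MatureModel:
    """Alignable mature tRNA: intron-removed body + ``CCA``, with anatomy."""

    gene_id: str
    seq: str
    anatomy: Anatomy


@dataclass(frozen=True)
class PrecursorModel:
    """Alignable precursor tRNA: leader + body (introns retained) + trailer.

    ``rnasez_cut`` is the index of the first trailer base; ``terminator`` is
    the pol III poly-T tract inside the trailer, or ``None`` when the trailer
    has no run of >= 4 T (tRF-1 calling is then disabled for this gene).
    """

    gene_id: str
    seq: str
    rnasez_cut: int
    terminator: Optional[Interval]


def build_mature(gene: TRNAGene, loop_width: int = DEFAULT_LOOP_WIDTH) -> MatureModel:
    """Construct the mature reference: remove the intron, append ``CCA``."""
    seq = gene.mature_body + "CCA"
    anatomy = default_anatomy(len(seq), gene.anticodon_start, loop_width)
    return MatureModel(gene.gene_id, seq, anatomy)


def build_precursor(gene: TRNAGene) -> PrecursorModel:
    """Construct the precursor reference with RNase Z cut and terminator."""
    if not gene.trailer_seq:
        raise ReferenceError(f"{gene.gene_id}: precursor requires a non-empty trailer")
    seq = gene.leader_seq + gene.body_seq + gene.trailer_seq
    cut = len(gene.leader_seq) + len(gene.body_seq)
    match = re.search("T{%d,}" % TERMINATOR_MIN_T, gene.trailer_seq)
    if match is None:
        logger.warning(
            "%s: trailer has no run of >=%d T; terminator absent, tRF-1 calling disabled",
            gene.gene_id,
            TERMINATOR_MIN_T,
        )
        terminator = None
    else:
        terminator = Interval(cut + match.start(), cut + match.end())
    return PrecursorModel(gene.gene_id, seq, cut, terminator)


def _parse_optional_int(value: str) -> Optional[int]:
    value = value.strip()
    return int(value) if value else None


def parse_reference(fasta_path, anatomy_table_path) -> list[TRNAGene]:
    """Read a tRNA gene set from a FASTA file plus an anatomy table.

    The FASTA holds genomic bodies keyed by gene_id (``chrom=``/``strand=``
    tokens in the description are honoured); the TSV supplies amino acid,
    anticodon, anticodon_start, optional intron span and leader/trailer
    sequences. Records violating the gene invariants are collected and raised
    together — never silently dropped.
    """
    table = pd.read_csv(anatomy_table_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANATOMY_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ReferenceError(f"anatomy table lacks columns: {missing_cols}")
    if table["gene_id"].duplicated().any():
        dups = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ReferenceError(f"duplicate anatomy rows for: {dups}")
    rows = table.set_index("gene_id")

    genes: list[TRNAGene] = []
    problems: list[str] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        gene_id = record.id
        seen.add(gene_id)
        if gene_id not in rows.index:
            problems.append(f"{gene_id}: no anatomy row for this FASTA record")
            continue
        row = rows.loc[gene_id]
        intron_start = _parse_optional_int(row["intron_start"])
        intron_end = _parse_optional_int(row["intron_end"])
        intron = (
            Interval(intron_start, intron_end)
            if intron_start is not None and intron_end is not None
            else None
        )
        meta = dict(
            token.split("=", 1)
            for token in record.description.split()[1:]
            if "=" in token
        )
        gene = TRNAGene(
            gene_id=gene_id,
            amino_acid=row["amino_acid"],
            anticodon=row["anticodon"].upper(),
            body_seq=str(record.seq).upper(),
            anticodon_start=int(row["anticodon_start"]),
            chromosome=meta.get("chrom", "."),
            strand=meta.get("strand", "+"),
            intron_span=intron,
            leader_seq=row["leader_seq"].upper(),
            trailer_seq=row["trailer_seq"].upper(),
        )
        try:
            gene.validate()
        except ReferenceError as exc:
            problems.append(str(exc))
            continue
        genes.append(gene)
    orphan_rows = set(rows.index) - seen
    if orphan_rows:
        logger.warning("anatomy rows without FASTA record: %s", sorted(orphan_rows))
    if problems:
        raise ReferenceError("invalid reference input: " + " | ".join(problems))
    logger.info("parsed %d tRNA genes from %s", len(genes), fasta_path)
    return genes


def write_reference(genes: Sequence[TRNAGene], fasta_path, anatomy_table_path) -> None:
    """Write genes as FASTA + anatomy TSV, the inverse of :func:`parse_reference`."""
    records = [
        SeqRecord(
            Seq(g.body_seq),
            id=g.gene_id,
            description=f"chrom={g.chromosome} strand={g.strand}",
        )
        for g in genes
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "gene_id": g.gene_id,
            "amino_acid": g.amino_acid,
            "anticodon": g.anticodon,
            "anticodon_start": g.anticodon_start,
            "intron_start": "" if g.intron_span is None else g.intron_span.start,
            "intron_end": "" if g.intron_span is None else g.intron_span.end,
            "leader_seq": g.leader_seq,
            "trailer_seq": g.trailer_seq,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=ANATOMY_COLUMNS).to_csv(
        anatomy_table_path, sep="\t", index=False
    )


def build_models(
    genes: Sequence[TRNAGene], loop_width: int = DEFAULT_LOOP_WIDTH
) -> tuple[list[MatureModel], list[PrecursorModel]]:
    """Build mature and precursor references for every gene.

    Genes without a trailer get no precursor entry (they cannot source tRF-1).
    """
    matures = [build_mature(g, loop_width) for g in genes]
    precursors = [build_precursor(g) for g in genes if g.trailer_seq]
    return matures, precursors
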