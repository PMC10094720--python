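"""tsRNA subtype classification, canonical naming, and known/novel flagging.

A fragment's subtype is decided by where its termini anchor on the tRNA
anatomy and by its length:

* **tiRNA-5 / tiRNA-3** (31-40 nt): halves from anticodon-loop cleavage — the
  5' half runs from the mature 5' end into the loop, the 3' half from the loop
  to the mature 3' end.
* **tRF-5a/5b/5c** (14-16 / 22-24 / 28-32 nt): anchored at the mature 5' end.
* **tRF-3a/3b** (17-18 / 19-22 nt): anchored at the mature 3' end (CCA tail).
* **tRF-2**: contained in the anticodon stem-loop, touching neither end.
* **tRF-1** (14-33 nt): precursor fragments starting at the RNase Z cut site
  and ending no later than the pol III poly-T terminator.

The tiRNA rules run first: a 5'-anchored 31-32 nt fragment ending inside the
loop is a half, not a tRF-5c — loop cleavage is the stronger positional claim.
Lengths falling in window gaps stay ``unclassified``; no category is forced.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .align import AlignmentHit, REF_MATURE
from .reference import MatureModel, PrecursorModel

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

SUBTYPES = (
    "tRF-1",
    "tRF-2",
    "tRF-3a",
    "tRF-3b",
    "tRF-5a",
    "tRF-5b",
    "tRF-5c",
    "tiRNA-5",
    "tiRNA-3",
    UNCLASSIFIED,
)

DEFAULT_WINDOWS: dict[str, tuple[int, int]] = {
    "tRF-1": (14, 33),
    "tRF-3a": (17, 18),
    "tRF-3b": (19, 22),
    "tRF-5a": (14, 16),
    "tRF-5b": (22, 24),
    "tRF-5c": (28, 32),
    "tiRNA": (31, 40),
}

#: decision-tree order; lower value = evaluated earlier = wins conflicts
RULE_PRIORITY: dict[str, int] = {
    "tiRNA-5": 0,
    "tiRNA-3": 1,
    "tRF-5a": 2,
    "tRF-5b": 2,
    "tRF-5c": 2,
    "tRF-3a": 3,
    "tRF-3b": 3,
    "tRF-2": 4,
    "tRF-1": 5,
    UNCLASSIFIED: 9,
}


@dataclass(frozen=True)
class ClassificationScheme:
    """Length windows (inclusive) and terminus tolerance for classification.

    ``end_slack`` is the nt tolerance for terminus anchoring (0 = exact;
    raise it to tolerate non-templated additions). ``trf2_min_len`` keeps
    tRF-2 calls at or above the global read minimum.
    """

    windows: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    end_slack: int = 0
    trf2_min_len: int = 14

    def __post_init__(self) -> None:
        for key, (lo, hi) in self.windows.items():
            if lo > hi:
                raise ValueError(f"empty window for {key}: [{lo}, {hi}]")
        for group in (("tRF-3a", "tRF-3b"), ("tRF-5a", "tRF-5b", "tRF-5c")):
            spans = [self.windows[k] for k in group if k in self.windows]
            spans.sort()
            for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise ValueError(f"overlapping windows within {group}")

    def in_window(self, key: str, length: int) -> bool:
        lo, hi = self.windows[key]
        return lo <= length <= hi


DEFAULT_SCHEME = ClassificationScheme()


def classify(
    hit: AlignmentHit,
    model: Union[MatureModel, PrecursorModel],
    scheme: ClassificationScheme = DEFAULT_SCHEME,
) -> str:
    """Assign one placement to a subtype (first matching rule wins)."""
    length = hit.end - hit.start
    if hit.ref_kind == REF_MATURE:
        anatomy = model.anatomy
        total = len(model.seq)
        loop = anatomy.anticodon_loop
        at5 = hit.start <= scheme.end_slack
        at3 = hit.end >= total - scheme.end_slack
        if at5 and loop.contains(hit.end - 1) and scheme.in_window("tiRNA", length):
            return "tiRNA-5"
        if at3 and loop.contains(hit.start) and scheme.in_window("tiRNA", length):
            return "tiRNA-3"
        if at5:
            for sub in ("tRF-5a", "tRF-5b", "tRF-5c"):
                if scheme.in_window(sub, length):
                    return sub
        if at3:
            for sub in ("tRF-3a", "tRF-3b"):
                if scheme.in_window(sub, length):
                    return sub
        region = anatomy.anticodon_stemloop_region
        if (
            hit.start > 0
            and hit.end < total
            and hit.start >= region.start
            and hit.end <= min(region.end, total)
            and length >= scheme.trf2_min_len
        ):
            return "tRF-2"
        return UNCLASSIFIED
    # precursor
    if model.terminator is None:
        logger.warning(
            "%s: precursor hit but terminator absent; cannot call tRF-1", model.gene_id
        )
        return UNCLASSIFIED
    if (
        abs(hit.start - model.rnasez_cut) <= scheme.end_slack
        and hit.end <= model.terminator.end
        and scheme.in_window("tRF-1", length)
    ):
        return "tRF-1"
    return UNCLASSIFIED


@dataclass(frozen=True)
class TsRNARecord:
    """A unique fragment sequence with its subtype, name and provenance."""

    fragment_seq: str
    subtype: str
    name: Optional[str]
    source_families: frozenset
    known: bool = False


class NameRegistry:
    """Deterministic canonical names: ``tRF-<AA>-<Anticodon>-<serial>``.

    Serials are assigned per isodecoder family in lexicographic order of the
    fragment sequences, so the assignment is invariant under input permutation
    and re-registering a fragment is idempotent. A fragment hitting several
    families is named by the lexicographically smallest one. Serials are
    repository-local (external catalogues number fragments differently).
    """

    def __init__(self) -> None:
        self._entries: dict[str, tuple[str, tuple[str, str]]] = {}

    def register(
        self, fragment_seq: str, subtype: str, families: Iterable[tuple[str, str]]
    ) -> None:
        families = set(families)
        if subtype == UNCLASSIFIED or not families:
            raise ValueError("only classified fragments with a source family get names")
        prefix = "tiRNA" if subtype.startswith("tiRNA") else "tRF"
        family = min(families)
        prior = self._entries.get(fragment_seq)
        if prior is not None and prior[0] != prefix:
            raise ValueError(
                f"fragment re-registered under conflicting kinds: {prior[0]} vs {prefix}"
            )
        if prior is not None:
            family = min(family, prior[1])
        self._entries[fragment_seq] = (prefix, family)

    def names(self) -> dict[str, str]:
        """Current ``{fragment_seq: name}`` mapping over everything registered."""
        grouped: dict[tuple[str, tuple[str, str]], list[str]] = defaultdict(list)
        for seq, key in self._entries.items():
            grouped[key].append(seq)
        out: dict[str, str] = {}
        for (prefix, (aa, anticodon)), seqs in grouped.items():
            for serial, seq in enumerate(sorted(seqs), start=1):
                out[seq] = f"{prefix}-{aa}-{anticodon}-{serial:03d}"
        return out


def name_tsrna(
    fragment_seq: str,
    subtype: str,
    families: Iterable[tuple[str, str]],
    registry: NameRegistry,
) -> str:
    """Register a classified fragment and return its canonical name."""
    registry.register(fragment_seq, subtype, families)
    return registry.names()[fragment_seq]


def load_catalog(path) -> frozenset:
    """Load a known-tsRNA catalogue: plain text, one fragment sequence per line."""
    with open(path) as handle:
        return frozenset(
            line.strip().upper() for line in handle if line.strip()
        )


def flag_known(fragment_seq: str, catalog: Optional[frozenset] = None) -> bool:
    """Known iff the exact sequence is in the catalogue; no catalogue => novel."""
    return catalog is not None and fragment_seq in catalog


def annotate_fragments(
    fragment_hits: Mapping[str, Sequence[AlignmentHit]],
    matures: Mapping[str, MatureModel],
    precursors: Mapping[str, PrecursorModel],
    families: Mapping[str, tuple[str, str]],
    scheme: ClassificationScheme = DEFAULT_SCHEME,
    catalog: Optional[frozenset] = None,
) -> dict[str, TsRNARecord]:
    """Classify and name every fragment from its placements.

    Each placement is classified independently; the fragment takes the label
    of highest rule priority among its placements (alternatives are logged),
    and its source families are those of the winning placements. Fragments are
    keyed by sequence, so a multi-gene fragment is counted once.
    """
    registry = NameRegistry()
    interim: list[tuple[str, str, frozenset]] = []
    for seq in sorted(fragment_hits):
        hits = fragment_hits[seq]
        labelled: list[tuple[str, AlignmentHit]] = []
        for hit in hits:
            model = (
                matures[hit.gene_id]
                if hit.ref_kind == REF_MATURE
                else precursors[hit.gene_id]
            )
            labelled.append((classify(hit, model, scheme), hit))
        subtype = min(
            (lab for lab, _ in labelled), key=RULE_PRIORITY.__getitem__, default=UNCLASSIFIED
        )
        winners = [hit for lab, hit in labelled if lab == subtype]
        losers = {lab for lab, _ in labelled} - {subtype}
        if losers and subtype != UNCLASSIFIED:
            logger.debug(
                "fragment %s...: kept %s, alternatives %s", seq[:12], subtype, sorted(losers)
            )
        fams = frozenset(families[h.gene_id] for h in winners)
        if subtype != UNCLASSIFIED:
            registry.register(seq, subtype, fams)
        interim.append((seq, subtype, fams))
    names = registry.names()
    return {
        seq: TsRNARecord(
            fragment_seq=seq,
            subtype=subtype,
            name=names.get(seq),
            source_families=fams,
            known=flag_known(seq, catalog),
        )
        for seq, subtype, fams in interim
    }
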