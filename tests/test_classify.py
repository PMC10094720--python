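"""Subtype decision tree, canonical naming, and known/novel flagging.

The exhaustive sweeps compare the classifier against an oracle re-derived
rule by rule from the subtype definitions (anchoring + length windows),
written independently of the package's decision-tree code.
"""

import random

import pytest

from tsrnakit.align import AlignmentHit
from tsrnakit.classify import (
    ClassificationScheme,
    NameRegistry,
    SUBTYPES,
    annotate_fragments,
    classify,
    flag_known,
    load_catalog,
    name_tsrna,
)
from tsrnakit.reference import build_mature, build_precursor, default_anatomy, MatureModel

from conftest import toy_gene


def mature_hit(start, end):
    return AlignmentHit("r", "g", "mature", start, end, 0)


def precursor_hit(start, end):
    return AlignmentHit("r", "g", "precursor", start, end, 0)


def oracle_subtype(start, end, ref_kind, total, loop, stemloop, rz_cut, term_end):
    """Independent rule-by-rule re-derivation of the subtype definitions."""
    n = end - start
    if ref_kind == "mature":
        if start == 0 and loop[0] <= end - 1 < loop[1] and 31 <= n <= 40:
            return "tiRNA-5"
        if end == total and loop[0] <= start < loop[1] and 31 <= n <= 40:
            return "tiRNA-3"
        if start == 0:
            if 14 <= n <= 16:
                return "tRF-5a"
            if 22 <= n <= 24:
                return "tRF-5b"
            if 28 <= n <= 32:
                return "tRF-5c"
        if end == total:
            if 17 <= n <= 18:
                return "tRF-3a"
            if 19 <= n <= 22:
                return "tRF-3b"
        if 0 < start and end < total and stemloop[0] <= start and end <= stemloop[1] and n >= 14:
            return "tRF-2"
        return "unclassified"
    if start == rz_cut and end <= term_end and 14 <= n <= 33:
        return "tRF-1"
    return "unclassified"


class TestDecisionTree:
    @pytest.mark.parametrize(
        ("start", "length", "expected"),
        [
            (0, 15, "tRF-5a"),
            (0, 23, "tRF-5b"),
            (0, 30, "tRF-5c"),  # ends at 29, outside the 31-38 loop
            (0, 32, "tiRNA-5"),  # ends at 31, inside the loop: the half wins
            (0, 35, "tiRNA-5"),
            (0, 18, "unclassified"),  # window gap 17-21
            (5, 20, "unclassified"),  # internal, not in the stem-loop
            (27, 16, "tRF-2"),  # inside the anticodon stem-loop
        ],
    )
    def test_five_prime_and_internal_rules(self, mature, start, length, expected):
        assert classify(mature_hit(start, start + length), mature) == expected

    @pytest.mark.parametrize(
        ("length", "expected"),
        [(17, "tRF-3a"), (18, "tRF-3a"), (19, "tRF-3b"), (22, "tRF-3b"),
         (25, "unclassified"), (39, "tiRNA-3"), (40, "tiRNA-3")],
    )
    def test_three_prime_rules(self, mature, length, expected):
        total = len(mature.seq)
        assert classify(mature_hit(total - length, total), mature) == expected

    def test_trf1_requires_cut_anchor_and_terminator(self, precursor):
        cut = precursor.rnasez_cut
        term_end = precursor.terminator.end
        assert classify(precursor_hit(cut, cut + 14), precursor) == "tRF-1"
        assert classify(precursor_hit(cut + 1, cut + 15), precursor) == "unclassified"
        assert (
            classify(precursor_hit(cut, term_end + 1), precursor) == "unclassified"
        )

    def test_absent_terminator_disables_trf1(self):
        pre = build_precursor(toy_gene(trailer="ACGACGACGACGACGACG"))
        cut = pre.rnasez_cut
        assert classify(precursor_hit(cut, cut + 20), pre) == "unclassified"

    def test_end_slack_tolerates_offset_termini(self, mature):
        slack = ClassificationScheme(end_slack=1)
        assert classify(mature_hit(1, 16), mature, slack) == "tRF-5a"
        assert classify(mature_hit(1, 16), mature) == "unclassified"

    def test_exhaustive_sweep_matches_oracle(self, mature, precursor):
        total = len(mature.seq)
        loop = mature.anatomy.anticodon_loop
        region = mature.anatomy.anticodon_stemloop_region
        for start in range(total):
            for end in range(start + 1, total + 1):
                expected = oracle_subtype(
                    start, end, "mature", total, (loop.start, loop.end),
                    (region.start, region.end), None, None,
                )
                assert classify(mature_hit(start, end), mature) == expected
        cut, term_end = precursor.rnasez_cut, precursor.terminator.end
        for start in range(cut - 5, len(precursor.seq)):
            for end in range(start + 1, len(precursor.seq) + 1):
                expected = oracle_subtype(
                    start, end, "precursor", None, None, None, cut, term_end
                )
                assert classify(precursor_hit(start, end), precursor) == expected

    def test_every_hit_gets_exactly_one_subtype(self, mature):
        total = len(mature.seq)
        for start in range(0, total, 3):
            for end in range(start + 1, total + 1, 3):
                assert classify(mature_hit(start, end), mature) in SUBTYPES


@pytest.fixture(scope="module")
def wide_mature():
    """A 90-nt mature tRNA whose loop (40-47) sits clear of the tRF windows."""
    random.seed(4)
    seq = "".join(random.choice("ACGT") for _ in range(87)) + "CCA"
    return MatureModel("toy", seq, default_anatomy(90, 42))


class TestWindowFaithfulness:
    """On a tRNA whose loop sits clear of the windows, the labelled length
    sets equal the defining windows exactly."""

    def test_five_prime_windows(self, wide_mature):
        labels = {}
        for length in range(10, 40):
            labels.setdefault(
                classify(mature_hit(0, length), wide_mature), set()
            ).add(length)
        assert labels["tRF-5a"] == set(range(14, 17))
        assert labels["tRF-5b"] == set(range(22, 25))
        assert labels["tRF-5c"] == set(range(28, 33))

    def test_three_prime_windows(self, wide_mature):
        total = len(wide_mature.seq)
        labels = {}
        for length in range(10, 31):
            labels.setdefault(
                classify(mature_hit(total - length, total), wide_mature), set()
            ).add(length)
        assert labels["tRF-3a"] == set(range(17, 19))
        assert labels["tRF-3b"] == set(range(19, 23))

    def test_half_takes_precedence_over_trf5c(self, mature):
        # 5'-anchored, 32 nt, ends inside the loop: tiRNA-5, never tRF-5c
        assert classify(mature_hit(0, 32), mature) == "tiRNA-5"


class TestNaming:
    def test_first_registration_seeds_serial_one(self):
        registry = NameRegistry()
        name = name_tsrna("ACGT" * 4, "tRF-3a", {("Trp", "CCA")}, registry)
        assert name == "tRF-Trp-CCA-001"

    def test_reregistration_is_idempotent(self):
        registry = NameRegistry()
        first = name_tsrna("ACGT" * 4, "tRF-3a", {("Trp", "CCA")}, registry)
        again = name_tsrna("ACGT" * 4, "tRF-3a", {("Trp", "CCA")}, registry)
        assert first == again

    def test_names_invariant_under_registration_order(self):
        frags = [f"{base}CGTACGTACGTACG" for base in ("T", "G", "A", "C")]
        orders = [frags, frags[::-1], [frags[2], frags[0], frags[3], frags[1]]]
        results = []
        for order in orders:
            registry = NameRegistry()
            for seq in order:
                registry.register(seq, "tRF-5a", {("Asp", "GTC")})
            results.append(registry.names())
        assert results[0] == results[1] == results[2]
        assert sorted(results[0].values())[0] == "tRF-Asp-GTC-001"

    def test_multi_family_fragment_named_by_smallest_family(self):
        registry = NameRegistry()
        name = name_tsrna(
            "A" * 16, "tiRNA-5", {("Val", "CAC"), ("Ala", "TGC")}, registry
        )
        assert name == "tiRNA-Ala-TGC-001"

    def test_unclassified_fragment_gets_no_name(self):
        registry = NameRegistry()
        with pytest.raises(ValueError):
            registry.register("A" * 16, "unclassified", {("Trp", "CCA")})


class TestKnownFlag:
    def test_catalog_membership(self, tmp_path):
        catalog_path = tmp_path / "known.txt"
        catalog_path.write_text("ACGTACGTACGTACGT\n\nTTTTCCCCAAAAGGGG\n")
        catalog = load_catalog(catalog_path)
        assert flag_known("ACGTACGTACGTACGT", catalog)
        assert not flag_known("GGGGGGGGGGGGGGGG", catalog)

    def test_no_catalog_means_all_novel(self):
        assert not flag_known("ACGTACGTACGTACGT", None)

    def test_empty_catalog_means_all_novel(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        assert not flag_known("ACGT" * 4, load_catalog(path))


class TestAnnotateFragments:
    def test_classified_counts_partition_fragments(self, gene, mature, precursor):
        frag5 = mature.seq[:15]
        frag1 = precursor.seq[precursor.rnasez_cut : precursor.rnasez_cut + 16]
        internal = mature.seq[5:25]
        hits = {
            frag5: [AlignmentHit(frag5, gene.gene_id, "mature", 0, 15, 0)],
            frag1: [
                AlignmentHit(
                    frag1, gene.gene_id, "precursor",
                    precursor.rnasez_cut, precursor.rnasez_cut + 16, 0,
                )
            ],
            internal: [AlignmentHit(internal, gene.gene_id, "mature", 5, 25, 0)],
        }
        records = annotate_fragments(
            hits,
            {gene.gene_id: mature},
            {gene.gene_id: precursor},
            {gene.gene_id: gene.family},
        )
        assert len(records) == 3
        subtypes = {rec.subtype for rec in records.values()}
        assert subtypes == {"tRF-5a", "tRF-1", "unclassified"}
        named = [rec for rec in records.values() if rec.name]
        assert {rec.name for rec in named} == {"tRF-Trp-CCA-001", "tRF-Trp-CCA-002"}
        assert records[internal].name is None
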