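"""Synthetic genes, fragments and libraries: determinism and self-consistency."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from tsrnakit.align import AlignmentHit
from tsrnakit.classify import DEFAULT_SCHEME, classify
from tsrnakit.reference import build_mature, build_precursor
from tsrnakit.simulate import (
    DEFAULT_SUBTYPE_MIX,
    SimConfig,
    make_counts,
    make_fragments,
    make_genes,
    make_libraries,
    simulate_dataset,
)


def single_subtype_config(subtype, **kwargs):
    return SimConfig(
        n_genes=6,
        n_fragments=15,
        subtype_mix={subtype: 1.0},
        seed=3,
        **kwargs,
    )


class TestMakeGenes:
    def test_deterministic_for_fixed_seed(self, tmp_path):
        cfg = SimConfig(n_genes=4, seed=9)
        a = make_genes(cfg)
        b = make_genes(cfg)
        assert a == b

    def test_generated_genes_satisfy_invariants(self):
        for gene in make_genes(SimConfig(n_genes=20, seed=1)):
            gene.validate()  # raises on violation
            assert len(build_mature(gene).seq) == 76
            pre = build_precursor(gene)
            assert pre.terminator is not None
            # exactly the planted tract: first >=4-T run starts at polyt_start
            assert pre.terminator.start == pre.rnasez_cut + 18
            assert pre.terminator.width == 6

    def test_family_labels_cycle_with_copy_numbers(self):
        genes = make_genes(SimConfig(n_genes=18, seed=2))
        ids = [g.gene_id for g in genes]
        assert ids[0] == "tRNA-Trp-CCA-1-1"
        assert ids[16] == "tRNA-Trp-CCA-2-1"  # 16 families, then second copies


class TestMakeFragments:
    def test_pure_trf5a_mix_anchors_at_five_prime(self):
        cfg = single_subtype_config("tRF-5a")
        truth = make_fragments(make_genes(cfg), cfg)
        assert (truth["start"] == 0).all()
        assert truth["fragment_seq"].str.len().between(14, 16).all()

    def test_pure_trf1_mix_anchors_at_rnasez_cut(self):
        cfg = single_subtype_config("tRF-1")
        genes = make_genes(cfg)
        truth = make_fragments(genes, cfg)
        cuts = {g.gene_id: build_precursor(g).rnasez_cut for g in genes}
        assert all(row.start == cuts[row.gene_id] for row in truth.itertuples())
        assert (truth["ref_kind"] == "precursor").all()

    def test_fragments_unique_and_lengths_inside_windows(self, small_genes, small_truth):
        assert small_truth["fragment_seq"].is_unique
        windows = dict(DEFAULT_SCHEME.windows)
        for row in small_truth.itertuples():
            length = row.end - row.start
            if row.subtype in ("tiRNA-5", "tiRNA-3"):
                lo, hi = windows["tiRNA"]
            elif row.subtype == "tRF-2":
                lo, hi = DEFAULT_SCHEME.trf2_min_len, 40
            else:
                lo, hi = windows[row.subtype]
            assert lo <= length <= hi

    def test_truth_anchors_reproduce_their_own_labels(self, small_genes, small_truth):
        matures = {g.gene_id: build_mature(g) for g in small_genes}
        precursors = {g.gene_id: build_precursor(g) for g in small_genes}
        for row in small_truth.itertuples():
            model = (
                matures[row.gene_id]
                if row.ref_kind == "mature"
                else precursors[row.gene_id]
            )
            hit = AlignmentHit("t", row.gene_id, row.ref_kind, row.start, row.end, 0)
            assert classify(hit, model) == row.subtype

    def test_de_fraction_and_fold_changes(self):
        cfg = SimConfig(n_genes=12, n_fragments=200, seed=5)
        truth = make_fragments(make_genes(cfg), cfg)
        assert truth["is_de"].sum() == 20
        de = truth[truth["is_de"]]
        assert set(np.round(de["true_fc"], 6)) <= {4.0, 0.25}
        assert (truth.loc[~truth["is_de"], "true_fc"] == 1.0).all()
        assert np.allclose(
            truth["mean_day42"], truth["mean_day7"] * truth["true_fc"]
        )


class TestMakeCounts:
    def test_zero_dispersion_limit_matches_means_within_poisson_error(self):
        cfg = SimConfig(
            n_genes=8, n_fragments=100, nb_dispersion=0.0, nb_sigma=0.0,
            nb_mean=200.0, seed=13,
        )
        truth = make_fragments(make_genes(cfg), cfg)
        counts, samples = make_counts(truth, cfg)
        day7 = samples.loc[samples["condition"] == "day7", "sample_id"]
        observed = counts[day7].to_numpy().ravel()
        mu = np.repeat(truth["mean_day7"].to_numpy(), len(day7))
        z = (observed - mu) / np.sqrt(mu)
        # standardised residuals ~ N(0,1): mean near 0, variance near 1
        assert abs(z.mean()) < 3 / np.sqrt(len(z))
        assert 0.8 < z.var() < 1.2

    def test_sample_sheet_layout(self, small_truth, small_config):
        counts, samples = make_counts(small_truth, small_config)
        assert list(samples["condition"].unique()) == ["day7", "day42"]
        assert counts.shape == (len(small_truth), 2 * small_config.replicates)


class TestMakeLibraries:
    def test_fixed_seed_reproduces_byte_identical_files(self, tmp_path):
        cfg = SimConfig(n_genes=5, n_fragments=30, replicates=2, nb_mean=5.0, seed=17)
        digests = []
        for sub in ("a", "b"):
            manifest = simulate_dataset(cfg, tmp_path / sub)
            digests.append(manifest["files"])
        assert digests[0] == digests[1]

    def test_noise_free_reads_are_fragment_plus_adapter(self, tmp_path, small_config,
                                                        small_genes, small_truth):
        make_libraries(small_genes, small_truth, small_config, tmp_path)
        samples = pd.read_csv(tmp_path / "samples.tsv", sep="\t")
        fragments = set(small_truth["fragment_seq"])
        lines = (tmp_path / samples.loc[0, "fastq"].split("/")[-1]).read_text().splitlines()
        seqs = lines[1::4]
        assert seqs, "first sample should contain reads"
        adapter = small_config.adapter3
        assert all(s.endswith(adapter) and s[: -len(adapter)] in fragments for s in seqs)

    def test_manifest_records_checksums(self, tmp_path):
        cfg = SimConfig(n_genes=4, n_fragments=10, replicates=2, nb_mean=3.0, seed=23)
        manifest = simulate_dataset(cfg, tmp_path)
        for name, digest in manifest["files"].items():
            path = tmp_path / name
            assert path.exists()
            assert hashlib.sha256(path.read_bytes()).hexdigest() == digest


class TestConfigValidation:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums"):
            SimConfig(subtype_mix={"tRF-1": 0.5})

    def test_polyt_must_fit_trailer(self):
        with pytest.raises(ValueError, match="poly-T"):
            SimConfig(polyt_start=38, polyt_len=6, trailer_len=40)

    def test_default_mix_is_normalised(self):
        assert sum(DEFAULT_SUBTYPE_MIX.values()) == pytest.approx(1.0)
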