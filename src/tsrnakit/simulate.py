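"""Synthetic tRNA genes, subtype-anchored fragments, and replicate libraries.

The generator emulates the structure of a two-condition small RNA-seq aging
experiment: a set of tRNA genes with canonical cloverleaf coordinates, 5'
leaders and 3' trailers ending in a poly-T pol III terminator; fragments
anchored per subtype rule with lengths drawn inside the subtype windows; and
per-sample counts drawn negative-binomially (5 biological replicates per
condition) with designated fold changes on a subset of fragments. Reads carry
the 3' sequencing adapter and iid substitution noise mimicking
modification-induced misincorporation.

Every truth row is self-consistent by construction: its anchor coordinates
satisfy the classification rule of its labelled subtype exactly, so at zero
noise the pipeline must reproduce the truth table verbatim.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentHit, REF_MATURE, REF_PRECURSOR
from .classify import ClassificationScheme, DEFAULT_SCHEME, classify
from .reference import (
    Interval,
    MatureModel,
    PrecursorModel,
    TRNAGene,
    build_mature,
    build_precursor,
    write_reference,
)

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

#: isodecoder families to cycle through; the head of the list carries the
#: families observed as most fragment-rich in fly libraries
AA_ANTICODONS: list[tuple[str, str]] = [
    ("Trp", "CCA"),
    ("Asp", "GTC"),
    ("Glu", "CTC"),
    ("Gln", "CTG"),
    ("Val", "CAC"),
    ("Ala", "TGC"),
    ("Gly", "GCC"),
    ("Lys", "CTT"),
    ("His", "GTG"),
    ("Pro", "CGG"),
    ("Ser", "GCT"),
    ("Leu", "CAA"),
    ("Arg", "TCT"),
    ("Ile", "GAT"),
    ("Thr", "TGT"),
    ("Cys", "GCA"),
]

#: fragment mix echoing the observed subtype spectrum: tRF-1 dominates,
#: then 5'-fragments, then 3'-fragments, with minor tRF-2 and halves
DEFAULT_SUBTYPE_MIX: dict[str, float] = {
    "tRF-1": 0.28,
    "tRF-5a": 0.12,
    "tRF-5b": 0.10,
    "tRF-5c": 0.10,
    "tRF-3a": 0.07,
    "tRF-3b": 0.10,
    "tRF-2": 0.05,
    "tiRNA-5": 0.12,
    "tiRNA-3": 0.06,
}

TRUTH_COLUMNS = [
    "fragment_seq",
    "gene_id",
    "subtype",
    "ref_kind",
    "start",
    "end",
    "base_mean",
    "is_de",
    "true_fc",
]


@dataclass
class SimConfig:
    """Parameters of the simulated experiment (all lengths in nt)."""

    n_genes: int = 30
    seed: int = 0
    body_len: int = 73
    anticodon_start: int = 33
    leader_len: int = 10
    trailer_len: int = 40
    polyt_len: int = 6
    polyt_start: int = 18
    subtype_mix: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_MIX))
    n_fragments: int = 500
    conditions: tuple = ("day7", "day42")
    replicates: int = 5
    nb_mean: float = 50.0
    nb_sigma: float = 0.8  # lognormal spread of per-fragment base abundance
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    true_fc: float = 4.0
    noise_rate: float = 0.005
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"

    def __post_init__(self) -> None:
        total = sum(self.subtype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_mix sums to {total}, expected 1")
        if min(self.subtype_mix.values()) < 0:
            raise ValueError("negative subtype proportion")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are modelled")
        if self.true_fc < 1:
            raise ValueError("true_fc must be >= 1")
        if not 0 <= self.noise_rate <= 1 or not 0 <= self.de_fraction <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.polyt_start + self.polyt_len > self.trailer_len:
            raise ValueError("poly-T tract exceeds the trailer")
        for count in (self.n_genes, self.n_fragments, self.replicates):
            if count < 0:
                raise ValueError("counts must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_r{rep + 1}"
            for cond in self.conditions
            for rep in range(self.replicates)
        ]


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)].copy()


def _cap_t_runs(arr: np.ndarray, rng: np.random.Generator, max_run: int = 3) -> None:
    """Break any run of T longer than ``max_run`` in place."""
    t_code = ord("T")
    run = 0
    for i, code in enumerate(arr):
        if code == t_code:
            run += 1
            if run > max_run:
                arr[i] = BASES[rng.integers(0, 3)]  # A/C/G
                run = 0
        else:
            run = 0


def make_genes(config: SimConfig, rng: Optional[np.random.Generator] = None) -> list[TRNAGene]:
    """Generate intronless tRNA genes with planted anticodons and terminators.

    The trailer carries exactly one >= 4-T run — the planted poly-T tract at
    ``polyt_start`` — so the precursor terminator lands at a known position.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t_code, c_code = ord("T"), ord("C")
    genes: list[TRNAGene] = []
    copies: dict[tuple[str, str], int] = {}
    for i in range(config.n_genes):
        aa, anticodon = AA_ANTICODONS[i % len(AA_ANTICODONS)]
        copies[(aa, anticodon)] = copies.get((aa, anticodon), 0) + 1
        gene_id = f"tRNA-{aa}-{anticodon}-{copies[(aa, anticodon)]}-1"
        body = _random_dna(rng, config.body_len)
        body[config.anticodon_start : config.anticodon_start + 3] = np.frombuffer(
            anticodon.encode("ascii"), dtype=np.uint8
        )
        leader = _random_dna(rng, config.leader_len)
        trailer = _random_dna(rng, config.trailer_len)
        _cap_t_runs(trailer, rng)
        ps, pl = config.polyt_start, config.polyt_len
        trailer[ps : ps + pl] = t_code
        if ps > 0 and trailer[ps - 1] == t_code:
            trailer[ps - 1] = c_code
        if ps + pl < len(trailer) and trailer[ps + pl] == t_code:
            trailer[ps + pl] = c_code
        genes.append(
            TRNAGene(
                gene_id=gene_id,
                amino_acid=aa,
                anticodon=anticodon,
                body_seq=body.tobytes().decode("ascii"),
                anticodon_start=config.anticodon_start,
                chromosome="2R",
                strand="+",
                leader_seq=leader.tobytes().decode("ascii"),
                trailer_seq=trailer.tobytes().decode("ascii"),
            )
        )
    for gene in genes:
        gene.validate()
    return genes


def _feasible_anchors(
    subtype: str,
    mature: MatureModel,
    precursor: PrecursorModel,
    scheme: ClassificationScheme,
) -> list[tuple[str, int, int]]:
    """All (ref_kind, start, end) placements that classify as ``subtype``."""
    total = len(mature.seq)
    loop = mature.anatomy.anticodon_loop
    windows = scheme.windows
    out: list[tuple[str, int, int]] = []

    def mature_ok(start: int, end: int) -> bool:
        hit = AlignmentHit("x", mature.gene_id, REF_MATURE, start, end, 0)
        return classify(hit, mature, scheme) == subtype

    if subtype in ("tRF-5a", "tRF-5b", "tRF-5c"):
        lo, hi = windows[subtype]
        out = [(REF_MATURE, 0, L) for L in range(lo, hi + 1) if mature_ok(0, L)]
    elif subtype in ("tRF-3a", "tRF-3b"):
        lo, hi = windows[subtype]
        out = [
            (REF_MATURE, total - L, total)
            for L in range(lo, hi + 1)
            if mature_ok(total - L, total)
        ]
    elif subtype == "tiRNA-5":
        lo, hi = windows["tiRNA"]
        out = [
            (REF_MATURE, 0, L)
            for L in range(max(lo, loop.start + 1), min(hi, loop.end) + 1)
            if mature_ok(0, L)
        ]
    elif subtype == "tiRNA-3":
        lo, hi = windows["tiRNA"]
        out = [
            (REF_MATURE, s, total)
            for s in range(loop.start, loop.end)
            if lo <= total - s <= hi and mature_ok(s, total)
        ]
    elif subtype == "tRF-2":
        region = mature.anatomy.anticodon_stemloop_region
        for length in range(scheme.trf2_min_len, region.width + 1):
            for s in range(max(1, region.start), region.end - length + 1):
                if s + length < total and mature_ok(s, s + length):
                    out.append((REF_MATURE, s, s + length))
    elif subtype == "tRF-1":
        if precursor.terminator is not None:
            lo, hi = windows["tRF-1"]
            cut = precursor.rnasez_cut
            hi = min(hi, precursor.terminator.end - cut)
            for L in range(lo, hi + 1):
                hit = AlignmentHit("x", precursor.gene_id, REF_PRECURSOR, cut, cut + L, 0)
                if classify(hit, precursor, scheme) == subtype:
                    out.append((REF_PRECURSOR, cut, cut + L))
    else:
        raise ValueError(f"cannot anchor subtype {subtype}")
    return out


def make_fragments(
    genes: Sequence[TRNAGene],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    scheme: ClassificationScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Draw the truth table: unique fragments anchored per subtype rule.

    Each requested fragment picks a subtype from ``subtype_mix`` and a random
    gene, then a feasible placement for that subtype; infeasible or duplicate
    draws are resampled (and logged). Base abundances are lognormal around
    ``nb_mean``; a ``de_fraction`` of fragments get the designated fold change,
    up or down with equal probability, in the second condition.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    matures = {g.gene_id: build_mature(g) for g in genes}
    precursors = {g.gene_id: build_precursor(g) for g in genes}
    subtypes = sorted(config.subtype_mix)
    probs = np.array([config.subtype_mix[s] for s in subtypes])
    probs = probs / probs.sum()

    rows: list[dict] = []
    seen: set[str] = set()
    n_resampled = 0
    for _ in range(config.n_fragments):
        for attempt in range(200):
            subtype = subtypes[rng.choice(len(subtypes), p=probs)]
            gene = genes[rng.integers(0, len(genes))]
            anchors = _feasible_anchors(
                subtype, matures[gene.gene_id], precursors[gene.gene_id], scheme
            )
            if not anchors:
                n_resampled += 1
                continue
            ref_kind, start, end = anchors[rng.integers(0, len(anchors))]
            model = matures[gene.gene_id] if ref_kind == REF_MATURE else precursors[gene.gene_id]
            seq = model.seq[start:end]
            if seq in seen:
                n_resampled += 1
                continue
            seen.add(seq)
            rows.append(
                {
                    "fragment_seq": seq,
                    "gene_id": gene.gene_id,
                    "subtype": subtype,
                    "ref_kind": ref_kind,
                    "start": start,
                    "end": end,
                }
            )
            break
        else:
            raise RuntimeError(
                "could not place a unique fragment after 200 attempts; "
                "increase n_genes or lower n_fragments"
            )
    if n_resampled:
        logger.info("make_fragments: %d draws resampled (duplicate/infeasible)", n_resampled)

    truth = pd.DataFrame(rows)
    n = len(truth)
    truth["base_mean"] = rng.lognormal(np.log(config.nb_mean), config.nb_sigma, size=n)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    truth["is_de"] = False
    truth.loc[de_idx, "is_de"] = True
    fc = np.ones(n)
    up = rng.random(n_de) < 0.5
    fc[de_idx] = np.where(up, config.true_fc, 1.0 / config.true_fc)
    truth["true_fc"] = fc
    cond_a, cond_b = config.conditions
    truth[f"mean_{cond_a}"] = truth["base_mean"]
    truth[f"mean_{cond_b}"] = truth["base_mean"] * truth["true_fc"]
    return truth


def make_counts(
    truth: pd.DataFrame,
    config: SimConfig,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial fragment x sample counts from the truth means.

    Variance is ``mu + dispersion * mu**2`` (common dispersion, the standard
    small-RNA count model); at dispersion 0 counts are Poisson. Returns the
    counts (indexed by fragment_seq) and the sample sheet.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    blocks = []
    sample_rows = []
    for cond in config.conditions:
        mu = truth[f"mean_{cond}"].to_numpy()[:, None]
        shape = (len(truth), config.replicates)
        if config.nb_dispersion <= 0:
            block = rng.poisson(mu, size=shape)
        else:
            size_param = 1.0 / config.nb_dispersion
            p = size_param / (size_param + mu)
            block = rng.negative_binomial(size_param, p, size=shape)
        blocks.append(block)
        sample_rows += [
            {"sample_id": f"{cond}_r{rep + 1}", "condition": cond}
            for rep in range(config.replicates)
        ]
    counts = pd.DataFrame(
        np.hstack(blocks),
        index=truth["fragment_seq"].to_numpy(),
        columns=[row["sample_id"] for row in sample_rows],
    )
    counts.index.name = "fragment_seq"
    return counts, pd.DataFrame(sample_rows)


def _mutate_reads(
    full_seq: str, n_reads: int, noise_rate: float, rng: np.random.Generator
) -> list[str]:
    """``n_reads`` copies of ``full_seq`` with iid substitutions at ``noise_rate``."""
    if noise_rate <= 0 or n_reads == 0:
        return [full_seq] * n_reads
    idx = np.array([BASE_INDEX[c] for c in full_seq], dtype=np.int8)
    mask = rng.random((n_reads, len(full_seq))) < noise_rate
    reads = []
    letters = "ACGT"
    for j in range(n_reads):
        row = mask[j]
        if not row.any():
            reads.append(full_seq)
            continue
        arr = idx.copy()
        shifts = rng.integers(1, 4, size=int(row.sum()))
        arr[row] = (arr[row] + shifts) % 4
        reads.append("".join(letters[k] for k in arr))
    return reads


def make_libraries(
    genes: Sequence[TRNAGene],
    truth: pd.DataFrame,
    config: SimConfig,
    outdir,
) -> dict:
    """Emit the full synthetic dataset and return its manifest.

    Writes reference FASTA + anatomy TSV, one FASTQ per sample (each read =
    fragment + 3' adapter with substitution noise), the sample sheet, the
    truth table, the true count matrix, and a JSON manifest recording the
    seed, parameters and file checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / "reference.fasta"
    anatomy_path = outdir / "anatomy.tsv"
    write_reference(genes, fasta_path, anatomy_path)

    counts, samples = make_counts(truth, config)
    rng = np.random.default_rng(config.seed + 2)
    fragment_seqs = truth["fragment_seq"].tolist()
    fastq_paths = []
    for sample_id in counts.columns:
        fastq_path = outdir / f"{sample_id}.fastq"
        fastq_paths.append(fastq_path)
        col = counts[sample_id].to_numpy()
        with open(fastq_path, "w") as handle:
            for row_idx, frag in enumerate(fragment_seqs):
                n_reads = int(col[row_idx])
                if n_reads == 0:
                    continue
                full = frag + config.adapter3
                for j, read_seq in enumerate(
                    _mutate_reads(full, n_reads, config.noise_rate, rng)
                ):
                    handle.write(
                        f"@{sample_id}.f{row_idx}.{j}\n{read_seq}\n+\n{'I' * len(read_seq)}\n"
                    )

    samples = samples.copy()
    samples["fastq"] = [p.name for p in fastq_paths]  # relative to the sheet
    samples_path = outdir / "samples.tsv"
    samples.to_csv(samples_path, sep="\t", index=False)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    counts_path = outdir / "true_counts.tsv"
    counts.to_csv(counts_path, sep="\t")

    files = [fasta_path, anatomy_path, samples_path, truth_path, counts_path] + fastq_paths
    manifest = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in files
        },
    }
    manifest_path = outdir / "sim_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("simulated dataset written to %s (%d samples)", outdir, len(samples))
    return manifest


def simulate_dataset(config: SimConfig, outdir) -> dict:
    """Convenience wrapper: genes -> fragments -> libraries in one call."""
    rng = np.random.default_rng(config.seed)
    genes = make_genes(config, rng)
    truth = make_fragments(genes, config, rng)
    return make_libraries(genes, truth, config, outdir)
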