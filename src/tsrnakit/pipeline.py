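"""End-to-end orchestration: trim -> align -> classify -> quantify -> report.

Fragments are keyed by their unique trimmed sequence and unified across
samples: the alignment cascade runs once over the union of fragment sequences,
then per-sample counts are joined back. Every stage logs the read-partition
tallies (rejected / mature / precursor / unaligned) so the bookkeeping is
auditable from logs alone, and a manifest records seeds, thresholds and
checksums of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .align import (
    AlignmentHit,
    Read,
    align_cascade,
    load_read_counts,
    trim_adapter,
)
from .classify import (
    ClassificationScheme,
    TsRNARecord,
    UNCLASSIFIED,
    annotate_fragments,
    load_catalog,
)
from .quantify import cpm, differential, expressed_set
from .reference import build_models, parse_reference

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the CLI exit path."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run."""

    reference_fasta: Path
    anatomy_table: Path
    sample_sheet: Path
    output_dir: Path
    known_catalog: Optional[Path] = None
    adapter3: Optional[str] = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: Optional[str] = None
    min_len: int = 14
    max_mismatches: int = 1
    loop_width: int = 7
    end_slack: int = 0
    windows: Optional[dict] = None
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    adjust: bool = False
    min_cpm: float = 1.0
    min_replicates: Optional[int] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "p_threshold", "min_cpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scheme(self) -> ClassificationScheme:
        kwargs = {"end_slack": self.end_slack}
        if self.windows:
            kwargs["windows"] = {
                k: tuple(v) for k, v in self.windows.items()
            }
        return ClassificationScheme(**kwargs)


@dataclass
class RunResult:
    """In-memory bundle of everything a run computed and wrote."""

    annotation: pd.DataFrame
    fragment_counts: pd.DataFrame
    sample_stats: pd.DataFrame
    counts: pd.DataFrame
    cpm: pd.DataFrame
    de: pd.DataFrame
    composition: pd.DataFrame
    length_distribution: pd.DataFrame
    venn: tuple[int, int, int]
    manifest: dict
    output_dir: Path


def read_sample_sheet(path) -> pd.DataFrame:
    """Load the sample sheet; relative FASTQ paths resolve against the sheet."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "fastq"}
    missing = required - set(sheet.columns)
    if missing:
        raise StageError("config", f"sample sheet lacks columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise StageError("config", "duplicate sample ids in sample sheet")
    base = Path(path).parent
    sheet["fastq"] = [
        str(p if p.is_absolute() else base / p) for p in map(Path, sheet["fastq"])
    ]
    return sheet


def collect_fragments(
    sheet: pd.DataFrame,
    adapter3: Optional[str],
    adapter5: Optional[str],
    min_len: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trim and collapse each sample; return the fragment table and stats.

    The fragment table has one row per unique trimmed sequence (``fragment_id``
    index, ``fragment_seq`` column, one count column per sample); stats carry
    the raw/rejected tallies per sample.
    """
    per_sample: dict[str, dict[str, int]] = {}
    stat_rows = []
    for row in sheet.itertuples():
        raw = load_read_counts(row.fastq)
        trimmed: dict[str, int] = defaultdict(int)
        n_raw = sum(raw.values())
        n_rejected = 0
        for seq, mult in raw.items():
            insert = trim_adapter(seq, adapter3, adapter5, min_len)
            if insert is None:
                n_rejected += mult
            else:
                trimmed[insert] += mult
        per_sample[row.sample_id] = dict(trimmed)
        stat_rows.append(
            {"sample_id": row.sample_id, "n_raw": n_raw, "n_rejected": n_rejected}
        )
        logger.info(
            "trim[%s]: %d raw, %d rejected, %d unique fragments",
            row.sample_id,
            n_raw,
            n_rejected,
            len(trimmed),
        )
    union = sorted(set().union(*per_sample.values()) if per_sample else set())
    table = pd.DataFrame(
        {
            "fragment_seq": union,
            **{
                sample: [per_sample[sample].get(seq, 0) for seq in union]
                for sample in per_sample
            },
        },
        index=pd.Index([f"u{i:06d}" for i in range(len(union))], name="fragment_id"),
    )
    return table, pd.DataFrame(stat_rows)


def align_stage(
    fragment_table: pd.DataFrame,
    matures: Sequence,
    precursors: Sequence,
    max_mismatches: int = 1,
) -> tuple[list[AlignmentHit], pd.DataFrame]:
    """Run the cascade over the fragment union; return hits + hits table."""
    reads = [
        Read(fid, seq)
        for fid, seq in fragment_table["fragment_seq"].items()
    ]
    hits, _ = align_cascade(reads, matures, precursors, max_mismatches)
    hits_df = pd.DataFrame(
        [
            {
                "read_id": h.read_id,
                "gene_id": h.gene_id,
                "ref_kind": h.ref_kind,
                "start": h.start,
                "end": h.end,
                "mismatches": h.mismatches,
            }
            for h in hits
        ],
        columns=["read_id", "gene_id", "ref_kind", "start", "end", "mismatches"],
    )
    return hits, hits_df


def sample_partition(
    fragment_table: pd.DataFrame,
    hits: Sequence[AlignmentHit],
    stats: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample read partition: mature / precursor / unaligned / rejected."""
    kind_by_fragment = {h.read_id: h.ref_kind for h in hits}
    sample_cols = [c for c in fragment_table.columns if c != "fragment_seq"]
    stats = stats.set_index("sample_id")
    kinds = pd.Index(
        [kind_by_fragment.get(fid, "unaligned") for fid in fragment_table.index]
    )
    sums = fragment_table[sample_cols].groupby(kinds).sum()
    for kind in ("mature", "precursor", "unaligned"):
        if kind in sums.index:
            stats[f"n_{kind}"] = sums.loc[kind].reindex(stats.index).fillna(0).astype(int)
        else:
            stats[f"n_{kind}"] = 0
    stats["n_aligned_total"] = stats["n_mature"] + stats["n_precursor"]
    return stats.reset_index()


def length_distribution(annotation: pd.DataFrame) -> pd.DataFrame:
    """Complete subtype x length grid of classified fragment counts, zero-filled."""
    classified = annotation[annotation["subtype"] != UNCLASSIFIED]
    if classified.empty:
        return pd.DataFrame()
    lengths = classified["fragment_seq"].str.len()
    grid = (
        pd.crosstab(classified["subtype"], lengths)
        .reindex(columns=range(int(lengths.min()), int(lengths.max()) + 1), fill_value=0)
    )
    grid.columns.name = "length"
    return grid


def venn_counts(expressed_a: set, expressed_b: set) -> tuple[int, int, int]:
    """(unique to A, unique to B, shared) membership counts."""
    return (
        len(expressed_a - expressed_b),
        len(expressed_b - expressed_a),
        len(expressed_a & expressed_b),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and write the report bundle to ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        genes = parse_reference(config.reference_fasta, config.anatomy_table)
        matures, precursors = build_models(genes, config.loop_width)
        sheet = read_sample_sheet(config.sample_sheet)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("reference", str(exc)) from exc

    try:
        fragment_table, trim_stats = collect_fragments(
            sheet, config.adapter3, config.adapter5, config.min_len
        )
        hits, hits_df = align_stage(
            fragment_table, matures, precursors, config.max_mismatches
        )
        stats = sample_partition(fragment_table, hits, trim_stats)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("align", str(exc)) from exc

    try:
        scheme = config.scheme()
        catalog = (
            load_catalog(config.known_catalog) if config.known_catalog else None
        )
        seq_of = fragment_table["fragment_seq"].to_dict()
        fragment_hits: dict[str, list[AlignmentHit]] = defaultdict(list)
        for hit in hits:
            fragment_hits[seq_of[hit.read_id]].append(hit)
        records = annotate_fragments(
            fragment_hits,
            {m.gene_id: m for m in matures},
            {p.gene_id: p for p in precursors},
            {g.gene_id: g.family for g in genes},
            scheme,
            catalog,
        )
        id_of = {seq: fid for fid, seq in seq_of.items()}
        annotation = pd.DataFrame(
            [
                {
                    "fragment_id": id_of[rec.fragment_seq],
                    "fragment_seq": rec.fragment_seq,
                    "length": len(rec.fragment_seq),
                    "subtype": rec.subtype,
                    "name": rec.name or "",
                    "families": ";".join(
                        f"{aa}-{ac}" for aa, ac in sorted(rec.source_families)
                    ),
                    "known": rec.known,
                }
                for rec in records.values()
            ]
        ).sort_values("fragment_id").reset_index(drop=True)
        n_classified = int((annotation["subtype"] != UNCLASSIFIED).sum())
        logger.info(
            "classify: %d fragments, %d classified, %d known",
            len(annotation),
            n_classified,
            int(annotation["known"].sum()),
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc

    try:
        named = annotation[annotation["name"] != ""]
        sample_ids = list(sheet["sample_id"])
        counts = (
            fragment_table.loc[named["fragment_id"], sample_ids]
            .set_axis(named["name"], axis=0)
        )
        counts.index.name = "name"
        aligned_totals = (
            stats.set_index("sample_id")["n_aligned_total"].reindex(sample_ids)
        )
        cpm_df = cpm(counts, aligned_totals)
        conditions = sheet.set_index("sample_id")["condition"]
        cond_names = list(dict.fromkeys(conditions))
        if len(cond_names) != 2:
            raise StageError(
                "quantify", f"expected 2 conditions, found {cond_names}"
            )
        cond_a, cond_b = cond_names
        de = differential(
            cpm_df,
            conditions.to_dict(),
            cond_a,
            cond_b,
            config.fc_threshold,
            config.p_threshold,
            adjust=config.adjust,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc

    try:
        samples_by_cond = {
            cond: list(sheet.loc[sheet["condition"] == cond, "sample_id"])
            for cond in cond_names
        }
        expressed = {
            cond: expressed_set(
                cpm_df, samples, config.min_cpm, config.min_replicates
            )
            for cond, samples in samples_by_cond.items()
        }
        venn = venn_counts(expressed[cond_a], expressed[cond_b])

        subtype_of = named.set_index("name")["subtype"]
        composition = pd.DataFrame(
            {
                "all_classified": annotation[annotation["subtype"] != UNCLASSIFIED][
                    "subtype"
                ].value_counts(),
                **{
                    cond: subtype_of.loc[sorted(expressed[cond])].value_counts()
                    for cond in cond_names
                },
            }
        ).fillna(0).astype(int)
        composition.index.name = "subtype"

        lengths = length_distribution(annotation)
        significant = de[de["significant"]]
        heat = np.log2(cpm_df.loc[significant.index] + 1)

        paths = {
            "annotation": out / "annotation.tsv",
            "fragment_counts": out / "fragment_counts.tsv",
            "hits": out / "hits.tsv",
            "sample_stats": out / "sample_stats.tsv",
            "counts": out / "counts.tsv",
            "cpm": out / "cpm.tsv",
            "de_results": out / "de_results.tsv",
            "composition": out / "composition.tsv",
            "length_distribution": out / "length_distribution.tsv",
            "overlap": out / "overlap.tsv",
            "significant_log2cpm": out / "significant_log2cpm.tsv",
        }
        annotation.to_csv(paths["annotation"], sep="\t", index=False)
        fragment_table.to_csv(paths["fragment_counts"], sep="\t")
        hits_df.to_csv(paths["hits"], sep="\t", index=False)
        stats.to_csv(paths["sample_stats"], sep="\t", index=False)
        counts.to_csv(paths["counts"], sep="\t")
        cpm_df.to_csv(paths["cpm"], sep="\t")
        de.to_csv(paths["de_results"], sep="\t")
        composition.to_csv(paths["composition"], sep="\t")
        lengths.to_csv(paths["length_distribution"], sep="\t")
        pd.DataFrame(
            [
                {
                    f"only_{cond_a}": venn[0],
                    f"only_{cond_b}": venn[1],
                    "shared": venn[2],
                    f"expressed_{cond_a}": len(expressed[cond_a]),
                    f"expressed_{cond_b}": len(expressed[cond_b]),
                }
            ]
        ).to_csv(paths["overlap"], sep="\t", index=False)
        heat.to_csv(paths["significant_log2cpm"], sep="\t")

        manifest = {
            "tool": "tsrnakit",
            "version": __version__,
            "seed": config.seed,
            "thresholds": {
                "fc": config.fc_threshold,
                "p": config.p_threshold,
                "min_cpm": config.min_cpm,
                "min_replicates": config.min_replicates,
                "max_mismatches": config.max_mismatches,
                "min_len": config.min_len,
                "end_slack": config.end_slack,
            },
            "samples": stats.to_dict(orient="records"),
            "n_fragments": int(len(annotation)),
            "n_classified": n_classified,
            "n_significant": int(de["significant"].sum()),
            "files": {name: _sha256(p) for name, p in paths.items()},
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("report", str(exc)) from exc

    return RunResult(
        annotation=annotation,
        fragment_counts=fragment_table,
        sample_stats=stats,
        counts=counts,
        cpm=cpm_df,
        de=de,
        composition=composition,
        length_distribution=lengths,
        venn=venn,
        manifest=manifest,
        output_dir=out,
    )
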