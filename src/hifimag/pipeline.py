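"""End-to-end orchestration: read QC -> graph triage -> genome quality ->
dereplication -> novelty -> depth abundance -> read-level 16S profile.

Every stage writes plain files (FASTA/FASTQ/TSV/JSON) into the output
directory and is runnable standalone on prior outputs, so any surrogate
stage can be swapped for the corresponding external tool's table. Identical
config + seed reproduces byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import abundance as ab
from . import derep as dr
from . import genome_quality as gq
from . import graph_triage as gt
from . import novelty as nv
from . import ssu as su
from .io import iter_fastq, mean_accuracy, read_fasta, write_fasta, write_fastq
from .taxonomy import RANKS

log = logging.getLogger(__name__)

EXIT_VALIDATION = 2
EXIT_STAGE_FAILURE = 3


@dataclass
class PipelineConfig:
    """All stage thresholds (defaults are the published protocol values)
    plus input paths and the seed."""

    reads: str = "reads.fastq"
    gfa: str = "assembly.gfa"
    annotations_gff: str | None = None
    taxonomy_tsv: str | None = None
    ref_ssu_fasta: str | None = None
    ref_ssu_taxonomy: str | None = None
    copy_numbers_tsv: str | None = None
    catalog_fasta: str | None = None
    outdir: str = "hifimag_out"

    read_min_bp: int = 1000
    read_min_accuracy: float = 0.99
    min_contig_bp: int = 2000
    min_circular_bp: int = 1_000_000
    mash_d_max: float = 0.05
    ani_min: float = 95.0
    cov_min: float = 50.0
    catalog_ani_min: float = 95.0
    ssu_min_bp: int = 1200
    ssu_max_bp: int = 1700
    ssu_min_accuracy: float = 0.99
    genus_identity_thr: float = 95.0
    species_identity_thr: float = 97.0
    n_bootstrap: int = 100
    conf_min: float = 0.8
    seed: int = 1

    _RANGES = {
        "read_min_bp": (1, 10**9),
        "read_min_accuracy": (0.0, 1.0),
        "min_contig_bp": (0, 10**9),
        "min_circular_bp": (0, 10**9),
        "mash_d_max": (0.0, 1.0),
        "ani_min": (0.0, 100.0),
        "cov_min": (0.0, 100.0),
        "catalog_ani_min": (0.0, 100.0),
        "ssu_min_bp": (1, 10**6),
        "ssu_max_bp": (1, 10**6),
        "ssu_min_accuracy": (0.0, 1.0),
        "genus_identity_thr": (0.0, 100.0),
        "species_identity_thr": (0.0, 100.0),
        "n_bootstrap": (1, 10**6),
        "conf_min": (0.0, 1.0),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(
                    f"config field {name}={v} outside [{lo}, {hi}]"
                )
        if self.ssu_min_bp > self.ssu_max_bp:
            raise ValueError("ssu_min_bp exceeds ssu_max_bp")

    def semantic_dict(self) -> dict:
        d = asdict(self)
        d.pop("outdir")
        return d

    def config_hash(self) -> str:
        text = json.dumps(self.semantic_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# standalone stage helpers


def qc_reads(
    reads,
    min_bp: int = 1000,
    min_accuracy: float = 0.99,
):
    """Filter (id, seq, qual) records by length and Phred-implied accuracy.

    Returns (kept records, n_removed).
    """
    kept, removed = [], 0
    for i, rec in enumerate(reads):
        try:
            name, seq, qual = rec
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed FASTQ record at index {i}") from exc
        if len(seq) >= min_bp and mean_accuracy(qual) >= min_accuracy:
            kept.append((name, seq, qual))
        else:
            removed += 1
    return kept, removed


def read_stats(lengths) -> dict:
    """n, total, min, max and N50..N90 of a set of sequence lengths.

    Nxx is the length L such that sequences >= L cover >= xx% of total
    bases (largest-first cumulative).
    """
    ls = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if ls.size == 0:
        raise ValueError("read_stats of an empty set")
    total = int(ls.sum())
    cum = np.cumsum(ls)
    out = {
        "n": int(ls.size),
        "total_bp": total,
        "max_bp": int(ls[0]),
        "min_bp": int(ls[-1]),
    }
    for xx in (50, 60, 70, 80, 90):
        idx = int(np.searchsorted(cum, total * xx / 100.0))
        out[f"N{xx}"] = int(ls[min(idx, ls.size - 1)])
    return out


def _read_tsv_map(path: str, key: str, value: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ki, vi = header.index(key), header.index(value)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out[f[ki]] = f[vi]
    return out


# ---------------------------------------------------------------------------
# run_all


@dataclass
class RunReport:
    config_hash: str
    seed: int
    counts: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "counts": self.counts,
                "stats": self.stats,
            },
            sort_keys=True,
            indent=1,
        )


def run_all(config: PipelineConfig) -> RunReport:
    config.validate()
    for path in (config.reads, config.gfa):
        if not Path(path).exists():
            raise FileNotFoundError(path)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config.config_hash(), config.seed)
    stage = "qc_reads"
    try:
        # 1. read QC
        kept, removed = qc_reads(
            iter_fastq(config.reads), config.read_min_bp,
            config.read_min_accuracy,
        )
        (out / "qc").mkdir(exist_ok=True)
        write_fastq(out / "qc" / "filtered.fastq", kept)
        report.counts["reads_in"] = len(kept) + removed
        report.counts["reads_kept"] = len(kept)
        report.counts["reads_removed"] = removed
        report.stats["reads"] = read_stats(len(s) for _, s, _ in kept)

        # 2. graph triage
        stage = "graph_triage"
        graph = gt.parse_gfa(config.gfa)
        calls = gt.classify_components(graph)
        (out / "triage").mkdir(exist_ok=True)
        (out / "triage" / "components.tsv").write_text(
            gt.component_table(calls)
        )
        circular = gt.extract_circular(graph, calls, 0)
        write_fasta(out / "triage" / "circular.fasta", circular)
        linear = gt.prebinning_filter(graph, calls, config.min_contig_bp)
        write_fasta(out / "triage" / "prebinning.fasta", linear)
        by_topo = {t: 0 for t in gt.TOPOLOGIES}
        for c in calls:
            by_topo[c.topology] += 1
        report.counts["components"] = by_topo
        report.counts["circular_contigs"] = len(circular)
        report.counts["prebinning_contigs"] = len(linear)

        # candidate genomes: circular contigs above the completeness split
        genomes = {
            name: seq for name, seq in circular
            if len(seq) >= config.min_circular_bp
        }
        report.counts["candidate_genomes"] = len(genomes)

        # 3. genome quality
        stage = "genome_quality"
        annotations = (
            gq.read_gff_annotations(config.annotations_gff)
            if config.annotations_gff
            else {}
        )
        quality: dict[str, gq.QualityEstimate] = {}
        qlines = [
            "genome_id\tcp\tct\trank\tscore\tn_rrn_operons\t"
            "n_partial_operons\tn_trna_types"
        ]
        for gid in sorted(genomes):
            est = gq.assess(gq.find_marker_hits(gid, genomes[gid]))
            quality[gid] = est
            ann = annotations.get(gid, [])
            n_op, n_part = gq.count_rrna_operons(ann)
            n_trna = gq.count_trna_types(ann)
            qlines.append(
                f"{gid}\t{est.cp:.2f}\t{est.ct:.2f}\t{est.rank}\t"
                f"{est.score:.2f}\t{n_op}\t{n_part}\t{n_trna}"
            )
        (out / "quality.tsv").write_text("\n".join(qlines) + "\n")
        report.counts["genomes_by_rank"] = {
            r: sum(1 for q in quality.values() if q.rank == r)
            for r in gq.RANKS
        }
        passing = {
            g: s for g, s in genomes.items() if quality[g].rank != "fail"
        }

        # 4. dereplication
        stage = "derep"
        if passing:
            res = dr.dereplicate(
                passing,
                {g: quality[g].score for g in passing},
                {g: quality[g].cp for g in passing},
                d_max=config.mash_d_max,
                ani_min=config.ani_min,
                cov_min=config.cov_min,
            )
            reps = {g: passing[g] for g in res.representatives}
            (out / "derep").mkdir(exist_ok=True)
            with open(out / "derep" / "membership.tsv", "w") as fh:
                fh.write("genome_id\trepresentative\n")
                for g in sorted(res.membership):
                    fh.write(f"{g}\t{res.membership[g]}\n")
            write_fasta(out / "derep" / "representatives.fasta",
                        sorted(reps.items()))
        else:
            res = None
            reps = {}
        report.counts["clusters"] = len(res.clusters) if res else 0
        report.counts["representatives"] = len(reps)
        report.counts["absorbed"] = len(passing) - len(reps)

        # 5. novelty vs catalog (optional)
        stage = "novelty"
        if config.catalog_fasta and reps:
            catalog = read_fasta(config.catalog_fasta)
            ssu_refs = (
                read_fasta(config.ref_ssu_fasta)
                if config.ref_ssu_fasta
                else None
            )
            genome_ssu = {
                gid: [
                    g.sequence
                    for g in su.detect_ssu(gid, seq, "I" * len(seq))
                    if config.ssu_min_bp <= g.length_bp <= config.ssu_max_bp
                ]
                for gid, seq in reps.items()
            }
            calls_nv = nv.match_catalog(
                reps, catalog, config.catalog_ani_min,
                ssu_genes=genome_ssu, ssu_references=ssu_refs,
            )
            (out / "novelty.tsv").write_text(nv.novelty_table(calls_nv))
            report.counts["novel_genomes"] = sum(
                1 for c in calls_nv if c.status == "novel"
            )
            report.counts["matched_genomes"] = sum(
                1 for c in calls_nv if c.status == "matched"
            )

        # 6. depth-based abundance
        stage = "abundance"
        taxonomy = (
            _read_tsv_map(config.taxonomy_tsv, "replicon", "taxon_path")
            if config.taxonomy_tsv
            else {}
        )
        (out / "abundance").mkdir(exist_ok=True)
        if reps:
            idx = ab.index_genomes(reps)
            assignments = ab.assign_reads(
                [(n, s) for n, s, _ in kept], idx
            )
            depths = ab.mean_depth(assignments, idx.lengths, len(kept))
            (out / "abundance" / "depth.tsv").write_text(
                ab.depth_table(depths)
            )
            for rank in ("domain", "phylum", "genus"):
                prof = ab.rank_profile(depths, taxonomy, rank)
                _write_profile(out / "abundance" / f"profile_{rank}.tsv",
                               prof)
            report.counts["reads_assigned"] = len(assignments)
            report.stats["depth_profile_genus"] = _round_profile(
                ab.rank_profile(depths, taxonomy, "genus")
            )

        # 7. read-level 16S profile
        stage = "ssu_profile"
        (out / "ssu").mkdir(exist_ok=True)
        candidates = su.detect_ssu_in_reads(kept)
        genes = su.filter_ssu(
            candidates, config.ssu_min_bp, config.ssu_max_bp,
            config.ssu_min_accuracy,
        )
        report.counts["ssu_candidates"] = len(candidates)
        report.counts["ssu_genes_kept"] = len(genes)
        write_fasta(
            out / "ssu" / "genes.fasta",
            [(f"{g.read_id}:{g.start}-{g.end}{g.strand}", g.sequence)
             for g in genes],
        )
        if config.ref_ssu_fasta and config.ref_ssu_taxonomy and genes:
            refs = read_fasta(config.ref_ssu_fasta)
            ref_tax = _read_tsv_map(
                config.ref_ssu_taxonomy, "sequence_id", "taxon_path"
            )
            model = su.train_classifier(
                [(n, ref_tax[n], s) for n, s in refs.items()]
            )
            classified = su.classify_all(
                genes, model, config.n_bootstrap, config.conf_min,
                config.seed,
            )
            copies = su.CopyNumberTable(
                {
                    t: float(c)
                    for t, c in _read_tsv_map(
                        config.copy_numbers_tsv, "taxon", "copies"
                    ).items()
                }
                if config.copy_numbers_tsv
                else {}
            )
            for rank in ("domain", "phylum", "genus"):
                prof = su.copy_adjusted_profile(
                    classified, copies, rank, config.conf_min
                )
                _write_profile(out / "ssu" / f"profile_{rank}.tsv", prof)
            report.counts["ssu_genes_classified"] = sum(
                1 for c in classified if c.assigned_rank is not None
            )
            report.stats["ssu_profile_genus"] = _round_profile(
                su.copy_adjusted_profile(
                    classified, copies, "genus", config.conf_min
                )
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(report.to_json() + "\n")
    return report


def _write_profile(path: Path, profile: dict[str, float]) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\trelative_abundance\n")
        for taxon, v in sorted(profile.items()):
            fh.write(f"{taxon}\t{v:.6f}\n")


def _round_profile(profile: dict[str, float]) -> dict[str, float]:
    return {t: round(v, 6) for t, v in sorted(profile.items())}
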