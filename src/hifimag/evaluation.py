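"""Truth-recovery evaluation harness for the synthetic benchmark.

Bundles the end-to-end exercise used by the benchmark suite: simulate the
default community, run the full pipeline, and compare the recovered
depth-based and copy-number-adjusted 16S profiles against the generator's
cell proportions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pipeline import PipelineConfig, run_all
from .synthio import write_fixture


@dataclass
class RecoveryTrial:
    seed: int
    truth: dict[str, dict[str, float]]  # rank -> taxon -> cell fraction
    depth: dict[str, dict[str, float]]  # recovered, depth-based
    ssu: dict[str, dict[str, float]]  # recovered, copy-adjusted 16S
    n_reads: int
    n_ssu_genes: int


def _read_profile(path: Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            taxon, v = line.rstrip("\n").split("\t")
            out[taxon] = float(v)
    return out


def community_recovery_trial(
    seed: int,
    workdir: str | os.PathLike,
    depth_target: float = 6.0,
) -> RecoveryTrial:
    """One end-to-end run of the default synthetic community."""
    work = Path(workdir)
    fix = work / f"fixture_s{seed}"
    truth = write_fixture(fix, seed=seed, depth_target=depth_target)
    out = work / f"run_s{seed}"
    cfg = PipelineConfig(
        reads=str(fix / "reads.fastq"),
        gfa=str(fix / "assembly.gfa"),
        annotations_gff=str(fix / "truth_features.gff3"),
        taxonomy_tsv=str(fix / "truth_replicons.tsv"),
        ref_ssu_fasta=str(fix / "ref_16s.fasta"),
        ref_ssu_taxonomy=str(fix / "ref_16s_taxonomy.tsv"),
        copy_numbers_tsv=str(fix / "copy_numbers.tsv"),
        outdir=str(out),
        seed=seed,
    )
    report = run_all(cfg)
    ranks = ("phylum", "genus")
    return RecoveryTrial(
        seed=seed,
        truth={r: truth.cell_proportions(r) for r in ranks},
        depth={
            r: _read_profile(out / "abundance" / f"profile_{r}.tsv")
            for r in ranks
        },
        ssu={
            r: _read_profile(out / "ssu" / f"profile_{r}.tsv")
            for r in ranks
        },
        n_reads=report.counts["reads_kept"],
        n_ssu_genes=report.counts["ssu_genes_kept"],
    )


def mean_profile(
    profiles: list[dict[str, float]]
) -> dict[str, float]:
    taxa = sorted({t for p in profiles for t in p})
    return {
        t: float(np.mean([p.get(t, 0.0) for p in profiles])) for t in taxa
    }


def profile_errors(
    estimate: dict[str, float], truth: dict[str, float]
) -> dict[str, float]:
    """Per-taxon absolute error in percentage points (truth taxa only;
    an "unclassified" bucket in the estimate is ignored)."""
    taxa = sorted(set(truth) | (set(estimate) - {"unclassified"}))
    return {
        t: 100.0 * abs(estimate.get(t, 0.0) - truth.get(t, 0.0))
        for t in taxa
    }


def pooled_pearson(
    pairs: list[tuple[dict[str, float], dict[str, float]]]
) -> float:
    """Pearson r between estimated and true abundances pooled over trials."""
    xs, ys = [], []
    for est, truth in pairs:
        for t in sorted(set(truth) | (set(est) - {"unclassified"})):
            xs.append(est.get(t, 0.0))
            ys.append(truth.get(t, 0.0))
    return float(np.corrcoef(xs, ys)[0, 1])
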