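"""Novelty assessment of representative genomes.

Two complementary calls: (1) catalog matching — a genome matches a
reference MAG catalog when its best ANI against any catalog genome is
>= 95% (sketch prefilter at Mash d <= 0.1, then fragment ANI); (2)
16S-based taxon novelty — best full-length 16S identity < 95% marks a
novel genus and < 97% a novel species, the conventional prokaryotic
demarcation thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib

from .derep import ani_pair, mash_distance, sketch

log = logging.getLogger(__name__)

SSU_MIN_BP = 1200
SSU_MAX_BP = 1700


@dataclass(frozen=True)
class NoveltyCall:
    genome_id: str
    catalog_match: tuple[str, float] | None  # (catalog id, ani)
    status: str  # matched | novel
    ssu_best: tuple[str, float] | None  # (reference id, identity pct)
    taxon_novelty: str  # known | novel_species | novel_genus | unassessed


def ssu_identity(a: str, b: str) -> float:
    """Percent identity of two full-length 16S genes.

    Semi-global alignment (end gaps free on the longer sequence) with unit
    scoring; identity = matches / alignment columns spanning the shorter
    sequence x 100. Both sequences must be 1,200-1,700 bp.
    """
    for seq in (a, b):
        if not SSU_MIN_BP <= len(seq) <= SSU_MAX_BP:
            raise ValueError(
                f"16S sequence length {len(seq)} outside "
                f"{SSU_MIN_BP}-{SSU_MAX_BP} bp"
            )
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(query, target, mode="HW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    columns = len(nice["matched_aligned"])
    matches = nice["matched_aligned"].count("|")
    return 100.0 * matches / columns


def taxon_novelty(
    best_identity: float | None,
    genus_thr: float = 95.0,
    species_thr: float = 97.0,
) -> str:
    """Novelty band from the best 16S identity against a reference set."""
    if best_identity is None:
        return "unassessed"
    if best_identity < genus_thr:
        return "novel_genus"
    if best_identity < species_thr:
        return "novel_species"
    return "known"


def best_ssu_identity(
    genes: list[str], references: dict[str, str]
) -> tuple[str, float] | None:
    """Maximum identity over all (gene copy, reference) pairs.

    Using the maximum over a genome's 16S copies is the conservative
    choice against false novelty calls.
    """
    best: tuple[str, float] | None = None
    for gene in genes:
        for rid, ref in references.items():
            ident = ssu_identity(gene, ref)
            if best is None or ident > best[1]:
                best = (rid, ident)
    return best


def match_catalog(
    representatives: dict[str, str],
    catalog: dict[str, str],
    ani_min: float = 95.0,
    prefilter_d: float = 0.1,
    ssu_genes: dict[str, list[str]] | None = None,
    ssu_references: dict[str, str] | None = None,
) -> list[NoveltyCall]:
    """Call each representative matched/novel against a MAG catalog.

    Candidate catalog genomes are prefiltered by Mash distance <=
    ``prefilter_d`` and confirmed by fragment ANI; matched iff the best
    ANI >= ``ani_min``. When per-genome 16S genes and a 16S reference
    collection are supplied, the genus/species novelty bands are also
    called (genomes without a 16S gene stay unassessed).
    """
    if not catalog:
        log.warning("empty catalog: all representatives called novel")
    cat_sketches = {g: sketch(s, g) for g, s in catalog.items()}
    calls: list[NoveltyCall] = []
    for gid in sorted(representatives):
        gseq = representatives[gid]
        gsk = sketch(gseq, gid)
        best: tuple[str, float] | None = None
        for cid in sorted(catalog):
            if mash_distance(gsk, cat_sketches[cid]) > prefilter_d:
                continue
            res = ani_pair(gseq, catalog[cid], gid, cid)
            if res.ani_pct is not None and (
                best is None or res.ani_pct > best[1]
            ):
                best = (cid, res.ani_pct)
        matched = best is not None and best[1] >= ani_min
        ssu_best = None
        if ssu_genes is not None and ssu_references:
            ssu_best = best_ssu_identity(ssu_genes.get(gid, []),
                                         ssu_references)
        calls.append(
            NoveltyCall(
                gid,
                best if matched else None,
                "matched" if matched else "novel",
                ssu_best,
                taxon_novelty(ssu_best[1] if ssu_best else None),
            )
        )
    return calls


def novelty_table(calls: list[NoveltyCall]) -> str:
    lines = [
        "genome_id\tstatus\tcatalog_id\tcatalog_ani\tssu_ref\t"
        "ssu_identity\ttaxon_novelty"
    ]
    for c in calls:
        cat_id, cat_ani = c.catalog_match or ("NA", float("nan"))
        ssu_id, ssu_pct = c.ssu_best or ("NA", float("nan"))
        lines.append(
            f"{c.genome_id}\t{c.status}\t{cat_id}\t{cat_ani:.2f}\t"
            f"{ssu_id}\t{ssu_pct:.2f}\t{c.taxon_novelty}"
        )
    return "\n".join(lines) + "\n"
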