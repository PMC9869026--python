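"""Rank-labelled lineages for synthetic taxa and rank arithmetic."""

from __future__ import annotations

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: 12 synthetic taxa: 10 bacteria (sharing some phyla, so rank aggregation
#: is non-trivial) and 2 archaea, mirroring a digester-like community with
#: one strongly dominant lineage.
_DEFAULT_LINEAGES: tuple[tuple[str, ...], ...] = tuple(
    tuple(path.split(";"))
    for path in (
        "Bacteria;PhylumA;ClassA1;OrderA1;FamilyA1;Genus01",
        "Bacteria;PhylumB;ClassB1;OrderB1;FamilyB1;Genus02",
        "Bacteria;PhylumB;ClassB1;OrderB2;FamilyB2;Genus03",
        "Bacteria;PhylumC;ClassC1;OrderC1;FamilyC1;Genus04",
        "Bacteria;PhylumC;ClassC2;OrderC2;FamilyC2;Genus05",
        "Bacteria;PhylumD;ClassD1;OrderD1;FamilyD1;Genus06",
        "Bacteria;PhylumE;ClassE1;OrderE1;FamilyE1;Genus07",
        "Bacteria;PhylumE;ClassE1;OrderE1;FamilyE2;Genus08",
        "Bacteria;PhylumF;ClassF1;OrderF1;FamilyF1;Genus09",
        "Bacteria;PhylumG;ClassG1;OrderG1;FamilyG1;Genus10",
        "Archaea;PhylumH;ClassH1;OrderH1;FamilyH1;Genus11",
        "Archaea;PhylumH;ClassH2;OrderH2;FamilyH2;Genus12",
    )
)


def default_taxon_path(index: int) -> str:
    """Semicolon-joined lineage for synthetic taxon ``index`` (cycled)."""
    return ";".join(_DEFAULT_LINEAGES[index % len(_DEFAULT_LINEAGES)])


def split_path(path: str) -> dict[str, str]:
    parts = path.split(";")
    if len(parts) > len(RANKS):
        raise ValueError(f"lineage has more than {len(RANKS)} ranks: {path}")
    return dict(zip(RANKS, parts))


def taxon_at_rank(path: str, rank: str) -> str:
    labels = split_path(path)
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    return labels.get(rank, "unclassified")


def n_default_taxa() -> int:
    return len(_DEFAULT_LINEAGES)
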