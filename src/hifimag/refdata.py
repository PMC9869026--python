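"""Synthetic reference sequences packaged with the pipeline.

Everything here is generated deterministically at import time from fixed
internal seeds — no data files ship with the package.  The objects stand in
for the external references a production run would use:

* a 16S rRNA scaffold (1,542 bp) with ten conserved regions at roughly the
  canonical positions, from which genus-level variants diverge only in the
  variable regions — the source of both the read-level 16S detector's anchor
  k-mers and the classifier's training sequences;
* 23S (2,904 bp) and 5S (119 bp) rRNA scaffolds used to plant complete
  16S-23S-5S operons;
* a universal single-copy marker panel (40 genes x 120 bp) planted once per
  chromosome, giving the completeness/contamination surrogate an exact
  ground truth;
* one 76 bp gene per standard tRNA isotype.

All sequences are synthetic stand-ins: they share the *architecture* of the
real molecules (conserved/variable structure, lengths, copy numbers), not
their composition.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ._kmers import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SSU_LEN = 1542
LSU_LEN = 2904
S5_LEN = 119
MARKER_COUNT = 40
MARKER_LEN = 120
TRNA_LEN = 76

#: conserved-region intervals on the 16S scaffold (start, end), 0-based
#: half-open; positions approximate the canonical conserved blocks that
#: universal 16S primers target, with the outermost blocks near the ends so
#: anchor-based boundary extension is tight.
SSU_CONSERVED: tuple[tuple[int, int], ...] = (
    (5, 30),
    (100, 125),
    (330, 355),
    (505, 530),
    (775, 800),
    (925, 950),
    (1090, 1115),
    (1215, 1240),
    (1385, 1410),
    (1512, 1537),
)

STANDARD_TRNA_ISOTYPES: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

_MASTER_SEED = 160_493


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode("ascii")


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            protected: tuple[tuple[int, int], ...] = ()) -> str:
    """Substitute bases at the given rate, never touching protected spans."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    ok = np.ones(arr.size, dtype=bool)
    for s, e in protected:
        ok[s:e] = False
    hit = (rng.random(arr.size) < rate) & ok
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


@lru_cache(maxsize=1)
def ssu_master() -> str:
    rng = np.random.default_rng(_MASTER_SEED)
    return _random_seq(rng, SSU_LEN)


@lru_cache(maxsize=1)
def lsu_master() -> str:
    rng = np.random.default_rng(_MASTER_SEED + 1)
    return _random_seq(rng, LSU_LEN)


@lru_cache(maxsize=1)
def s5_master() -> str:
    rng = np.random.default_rng(_MASTER_SEED + 2)
    return _random_seq(rng, S5_LEN)


def genus_ssu(genus_index: int, divergence: float = 0.08) -> str:
    """Genus-level 16S variant: variable regions mutated, conserved kept.

    Independent mutation of two genera at rate m gives ~1.5*2m pairwise
    divergence over variable positions; the default yields roughly 10%
    variable-region (about 8-9% overall) inter-genus distance.
    """
    rng = np.random.default_rng(_MASTER_SEED + 1000 + genus_index)
    return _mutate(ssu_master(), divergence, rng, protected=SSU_CONSERVED)


def genus_lsu(genus_index: int, divergence: float = 0.08) -> str:
    rng = np.random.default_rng(_MASTER_SEED + 2000 + genus_index)
    return _mutate(lsu_master(), divergence, rng)


def genus_s5(genus_index: int, divergence: float = 0.08) -> str:
    rng = np.random.default_rng(_MASTER_SEED + 3000 + genus_index)
    return _mutate(s5_master(), divergence, rng)


@lru_cache(maxsize=1)
def marker_panel() -> dict[str, str]:
    """Universal single-copy marker genes: marker id -> sequence."""
    rng = np.random.default_rng(_MASTER_SEED + 7)
    return {
        f"SCM{i:03d}": _random_seq(rng, MARKER_LEN)
        for i in range(1, MARKER_COUNT + 1)
    }


@lru_cache(maxsize=1)
def trna_genes() -> dict[str, str]:
    """One 76 bp gene per standard tRNA isotype."""
    rng = np.random.default_rng(_MASTER_SEED + 8)
    return {iso: _random_seq(rng, TRNA_LEN) for iso in STANDARD_TRNA_ISOTYPES}


def reference_ssu_set(
    n_genera: int,
    variants_per_genus: int = 3,
    intra_divergence: float = 0.01,
) -> list[tuple[str, str, str]]:
    """Training collection for the 16S classifier.

    Returns (sequence id, taxon path, sequence) triples: per genus the genus
    template plus ``variants_per_genus - 1`` strain-level variants at
    ``intra_divergence`` substitution rate.
    """
    from .taxonomy import default_taxon_path

    out = []
    for g in range(n_genera):
        base = genus_ssu(g)
        path = default_taxon_path(g)
        out.append((f"ref_g{g:02d}_v0", path, base))
        for v in range(1, variants_per_genus):
            rng = np.random.default_rng(_MASTER_SEED + 5000 + 100 * g + v)
            out.append(
                (f"ref_g{g:02d}_v{v}", path,
                 _mutate(base, intra_divergence, rng,
                         protected=SSU_CONSERVED))
            )
    return out


def ssu_anchor_kmers(anchor_len: int = 15) -> list[tuple[int, str]]:
    """(reference offset, k-mer) anchors from the conserved 16S regions."""
    master = ssu_master()
    anchors = []
    for s, e in SSU_CONSERVED:
        for off in range(s, e - anchor_len + 1, 5):
            anchors.append((off, master[off : off + anchor_len]))
    return anchors


def anchor_variants_1mm(anchor: str) -> list[str]:
    """The anchor plus every single-substitution neighbour."""
    out = [anchor]
    for i, b in enumerate(anchor):
        for alt in "ACGT":
            if alt != b:
                out.append(anchor[:i] + alt + anchor[i + 1 :])
    return out


__all__ = [
    "SSU_LEN", "LSU_LEN", "S5_LEN", "SSU_CONSERVED",
    "STANDARD_TRNA_ISOTYPES", "MARKER_COUNT", "MARKER_LEN",
    "ssu_master", "lsu_master", "s5_master",
    "genus_ssu", "genus_lsu", "genus_s5",
    "marker_panel", "trna_genes", "reference_ssu_set",
    "ssu_anchor_kmers", "anchor_variants_1mm", "revcomp",
]
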