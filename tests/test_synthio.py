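"""Synthetic community generator: planted truth, read model, graphs."""

import numpy as np
import pytest

from hifimag import refdata, synthio
from hifimag._kmers import revcomp
from hifimag.io import mean_accuracy
from hifimag.pipeline import read_stats
from hifimag.taxonomy import default_taxon_path


def _chrom(copies=2, trna=refdata.STANDARD_TRNA_ISOTYPES, length=1_000_000,
           gc=0.45):
    return synthio.RepliconSpec(
        "chrT", length, "circular", "chromosome", gc, copies, tuple(trna),
        default_taxon_path(0),
    )


class TestGenerateReplicon:
    def test_planted_feature_counts(self):
        seq, feats = synthio.generate_replicon(_chrom(copies=2), 7)
        assert len(seq) == 1_000_000
        n16 = sum(1 for f in feats if f.kind == "rRNA_16S")
        n_trna = sum(1 for f in feats if f.kind == "tRNA")
        assert n16 == 2
        assert n_trna >= 20

    def test_zero_operon_copies_means_no_ssu(self):
        seq, feats = synthio.generate_replicon(_chrom(copies=0), 7)
        assert not any(f.kind.startswith("rRNA") for f in feats)

    def test_deterministic_for_fixed_seed(self):
        a, fa = synthio.generate_replicon(_chrom(), 9)
        b, fb = synthio.generate_replicon(_chrom(), 9)
        assert a == b and fa == fb

    def test_gc_within_two_percent(self):
        seq, _ = synthio.generate_replicon(_chrom(gc=0.60), 3)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.60) < 0.02

    def test_features_round_trip_onto_sequence(self):
        """Every truth interval maps back exactly onto the sequence."""
        seq, feats = synthio.generate_replicon(_chrom(copies=1), 5)
        gidx = synthio.genus_index_for(default_taxon_path(0))
        expected = {
            "rRNA_16S": refdata.genus_ssu(gidx),
            "rRNA_23S": refdata.genus_lsu(gidx),
            "rRNA_5S": refdata.genus_s5(gidx),
        }
        for f in feats:
            sub = seq[f.start : f.end]
            if f.strand == "-":
                sub = revcomp(sub)
            if f.kind in expected:
                assert sub == expected[f.kind]
            elif f.kind == "tRNA":
                assert sub == refdata.trna_genes()[f.isotype]
            elif f.kind == "marker":
                assert sub in refdata.marker_panel().values()

    def test_oversized_feature_load_raises(self):
        spec = synthio.RepliconSpec(
            "plsT", 5_000, "circular", "plasmid", 0.5, 2, (),
            default_taxon_path(1),
        )
        with pytest.raises(ValueError, match="exceed"):
            synthio.generate_replicon(spec, 1)


class TestSimulateReads:
    def test_coverage_matches_lander_waterman(self):
        spec = _chrom(copies=0, trna=())
        comm = synthio.CommunitySpec((spec,), (1.0,), seed=2)
        reads, _ = synthio.simulate_hifi_reads(
            comm, synthio.ReadModel(), 50.0, 2
        )
        total = sum(len(s) for _, s, _ in reads)
        assert 48.0 <= total / 1e6 <= 52.0

    def test_no_read_below_minimum_length(self, single_replicon_reads):
        reads, _ = single_replicon_reads
        assert min(len(s) for _, s, _ in reads) >= 1000

    def test_empirical_accuracy_matches_model(self, single_replicon_reads):
        """Planted substitutions vs read bases, over >= 10 Mb."""
        reads, truth = single_replicon_reads
        total = sum(len(s) for _, s, _ in reads)
        assert total >= 10_000_000
        n_sub = sum(rt.n_sub for rt in truth.reads.values())
        emp_accuracy = 1.0 - n_sub / total
        assert emp_accuracy == pytest.approx(0.9994, abs=0.0005)

    def test_phred_implied_accuracy_is_unbiased(self, single_replicon_reads):
        reads, truth = single_replicon_reads
        total = sum(len(s) for _, s, _ in reads)
        phred_acc = (
            sum(mean_accuracy(q) * len(s) for _, s, q in reads) / total
        )
        emp_acc = 1.0 - sum(r.n_sub for r in truth.reads.values()) / total
        assert phred_acc == pytest.approx(emp_acc, abs=0.0003)

    def test_n50_within_ten_percent_of_target(self, single_replicon_reads):
        reads, _ = single_replicon_reads
        stats = read_stats(len(s) for _, s, _ in reads)
        assert abs(stats["N50"] - 14_254) / 14_254 < 0.10

    def test_truth_intervals_recover_planted_genes(
        self, single_replicon_reads
    ):
        """Read-coordinate 16S intervals match the planted gene sequence
        up to simulated base errors."""
        reads, truth = single_replicon_reads
        gidx = synthio.genus_index_for(default_taxon_path(0))
        gene = refdata.genus_ssu(gidx)
        checked = 0
        by_id = {r[0]: r[1] for r in reads}
        for rt in truth.reads.values():
            for s, e, strand, _ in rt.ssu:
                sub = by_id[rt.read_id][s:e]
                if strand == "-":
                    sub = revcomp(sub)
                assert len(sub) == len(gene)
                ident = sum(a == b for a, b in zip(sub, gene)) / len(gene)
                assert ident > 0.995
                checked += 1
        assert checked >= 10

    def test_reproducible_byte_identical(self):
        spec = synthio.RepliconSpec(
            "plsA", 100_000, "circular", "plasmid", 0.5, 0, (),
            default_taxon_path(1),
        )
        comm = synthio.CommunitySpec((spec,), (1.0,), seed=6)
        r1, _ = synthio.simulate_hifi_reads(comm, synthio.ReadModel(), 20, 6)
        r2, _ = synthio.simulate_hifi_reads(comm, synthio.ReadModel(), 20, 6)
        assert r1 == r2


class TestBuildGfa:
    def test_requested_structure(self):
        rng = np.random.default_rng(0)
        seq = lambda n: "".join(rng.choice(list("ACGT"), n))  # noqa: E731
        comps = (
            [synthio.GfaComponent(((f"c{i}", seq(3000)),), "circular")
             for i in range(3)]
            + [
                synthio.GfaComponent(
                    tuple((f"t{i}s{j}", seq(1500)) for j in range(4)),
                    "tangled_circular",
                )
                for i in range(2)
            ]
            + [synthio.GfaComponent(((f"l{i}", seq(2500)),), "linear")
               for i in range(5)]
        )
        gfa, labels = synthio.build_gfa(comps, 0)
        assert sum(1 for line in gfa.splitlines() if line.startswith("S")) \
            == 3 + 8 + 5
        topo = {row["segment"]: row["topology"] for row in labels}
        assert sum(1 for t in topo.values() if t == "circular") == 3
        assert sum(1 for t in topo.values() if t == "linear") == 5

    def test_empty_request_is_header_only(self):
        gfa, labels = synthio.build_gfa([], 0)
        assert gfa.startswith("H\t") and labels == []

    def test_contradictory_request_raises(self):
        with pytest.raises(ValueError):
            synthio.build_gfa(
                [synthio.GfaComponent((("a", "ACGT"), ("b", "ACGT")),
                                      "circular")],
                0,
            )

    def test_tangle_members_stay_near_identical_to_base(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACGT"), 30_000))
        comp = synthio.tangle_from_variants("x", base, 3, 0.02, 3, 4)
        # each piece aligns to its base slice with >= 80% identity
        pieces0 = [s for n, s in comp.segments if n.startswith("x_v0")]
        offset = 0
        slices = []
        for p in pieces0:
            slices.append((offset, offset + len(p)))
            offset += len(p)
        for vi in range(3):
            pieces = [s for n, s in comp.segments
                      if n.startswith(f"x_v{vi}")]
            for (s, e), piece in zip(slices, pieces):
                ref = base[s:e]
                ident = sum(a == b for a, b in zip(ref, piece)) / len(ref)
                assert ident >= 0.80


def test_default_community_is_skewed_and_valid():
    comm = synthio.default_community(3)
    comm.validate()
    assert max(comm.abundances) >= 0.6
    classes = {r.replicon_class for r in comm.replicons}
    assert classes == {"chromosome", "plasmid", "virus"}
    domains = {r.taxon_path.split(";")[0] for r in comm.replicons}
    assert domains == {"Bacteria", "Archaea"}
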