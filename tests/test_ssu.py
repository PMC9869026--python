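"""Read-level 16S detection, filtering, classification, profiles."""

import numpy as np
import pytest

from hifimag import refdata, ssu, synthio
from hifimag._kmers import revcomp
from hifimag.io import phred_to_qual


def _seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _q(n, q=33):
    return phred_to_qual(np.full(n, q))


@pytest.fixture(scope="module")
def model():
    return ssu.train_classifier(refdata.reference_ssu_set(12))


class TestDetect:
    def test_planted_gene_with_flanks(self):
        rng = np.random.default_rng(0)
        gene = refdata.genus_ssu(2)
        read = _seq(rng, 2000) + gene + _seq(rng, 2000)
        (cand,) = ssu.detect_ssu("r", read, _q(len(read)))
        assert abs(cand.start - 2000) <= 25
        assert abs(cand.end - (2000 + len(gene))) <= 25
        assert cand.strand == "+"

    def test_reverse_strand_recovered_with_reversed_quality(self):
        rng = np.random.default_rng(1)
        gene = refdata.genus_ssu(2)
        read = _seq(rng, 1500) + gene + _seq(rng, 1500)
        qual = phred_to_qual(
            np.asarray(rng.integers(25, 40, size=len(read)))
        )
        (fwd,) = ssu.detect_ssu("r", read, qual)
        (rev,) = ssu.detect_ssu("r", revcomp(read), qual[::-1])
        assert rev.strand == "-"
        assert rev.sequence == fwd.sequence
        assert rev.quality == fwd.quality

    def test_random_read_yields_nothing(self):
        rng = np.random.default_rng(2)
        assert ssu.detect_ssu("r", _seq(rng, 6000), _q(6000)) == []

    def test_read_spanning_two_operons(self):
        rng = np.random.default_rng(3)
        gene = refdata.genus_ssu(5)
        read = (
            _seq(rng, 500) + gene + _seq(rng, 3000) + gene + _seq(rng, 500)
        )
        cands = ssu.detect_ssu("r", read, _q(len(read)))
        assert len(cands) == 2

    def test_gene_survives_read_errors(self):
        rng = np.random.default_rng(4)
        gene = refdata.genus_ssu(7)
        noisy = synthio._mutate_str(gene, 0.002, rng)  # HiFi-scale errors
        read = _seq(rng, 1000) + noisy + _seq(rng, 1000)
        assert len(ssu.detect_ssu("r", read, _q(len(read)))) == 1


class TestFilter:
    def _gene(self, n, q):
        return ssu.SsuGene("r", 0, n, "+", "A" * n, _q(n, q), False)

    @pytest.mark.parametrize(
        "length,q,kept",
        [
            (1512, 30, True),   # Q30 accuracy 99.9% >= 99%
            (1100, 40, False),  # below 1,200 bp
            (1750, 40, False),  # above 1,700 bp
            (1200, 30, True),   # inclusive lower bound
            (1700, 30, True),   # inclusive upper bound
            (1512, 13, False),  # error 0.0501 > 0.01
            (1512, 20, True),   # exactly Q20 boundary
        ],
    )
    def test_length_and_accuracy_bounds(self, length, q, kept):
        out = ssu.filter_ssu([self._gene(length, q)])
        assert (len(out) == 1) is kept

    def test_matches_brute_force_rescan(self):
        rng = np.random.default_rng(5)
        cands = [
            self._gene(int(n), int(q))
            for n, q in zip(
                rng.integers(1000, 1900, 50), rng.integers(10, 45, 50)
            )
        ]
        got = ssu.filter_ssu(cands)
        brute = [
            g
            for g in cands
            if 1200 <= g.length_bp <= 1700 and g.mean_accuracy >= 0.99
        ]
        assert got == brute


class TestClassifier:
    def test_training_sequences_classify_to_own_genus(self, model):
        refs = refdata.reference_ssu_set(12)
        for name, path, seq in refs[::5]:
            gene = ssu.SsuGene("r", 0, len(seq), "+", seq, _q(len(seq)),
                               False)
            c = ssu.classify_ssu(gene, model, seed=1)
            assert c.genus == path.split(";")[-1]
            assert c.confidence == 1.0

    def test_single_genus_training_raises(self):
        refs = [r for r in refdata.reference_ssu_set(1)]
        with pytest.raises(ValueError, match="2 genera"):
            ssu.train_classifier(refs)

    def test_duplicate_ids_raise(self):
        refs = refdata.reference_ssu_set(2)
        with pytest.raises(ValueError, match="duplicate"):
            ssu.train_classifier(refs + [refs[0]])

    def test_serialization_round_trips_bit_identically(self, model):
        clone = ssu.SsuClassifier.from_json(model.to_json())
        assert clone.to_json() == model.to_json()
        assert np.array_equal(clone.logp, model.logp)

    def test_deterministic_for_fixed_seed(self, model):
        gene_seq = refdata.genus_ssu(4)
        gene = ssu.SsuGene("r", 0, len(gene_seq), "+", gene_seq,
                           _q(len(gene_seq)), False)
        a = ssu.classify_ssu(gene, model, seed=9)
        b = ssu.classify_ssu(gene, model, seed=9)
        assert a.calls == b.calls

    def test_random_queries_stay_unclassified(self, model):
        rng = np.random.default_rng(6)
        n_unclassified = 0
        for i in range(20):
            q = _seq(rng, 1500)
            gene = ssu.SsuGene("r", 0, 1500, "+", q, _q(1500), False)
            c = ssu.classify_ssu(gene, model, seed=i)
            if c.taxon_at("genus") == "unclassified":
                n_unclassified += 1
        assert n_unclassified == 20

    def test_confidence_declines_with_divergence(self, model):
        """Median genus confidence is non-increasing along a divergence
        ladder (0%, 2%, 5%, 10%) from a training genus."""
        gene_seq = refdata.genus_ssu(3)
        med = []
        for rate in (0.0, 0.02, 0.05, 0.10):
            confs = []
            for s in range(5):
                rng = np.random.default_rng(100 + s)
                q = (
                    gene_seq
                    if rate == 0
                    else synthio._mutate_str(gene_seq, rate, rng)
                )
                gene = ssu.SsuGene("r", 0, len(q), "+", q, _q(len(q)),
                                   False)
                confs.append(
                    ssu.classify_ssu(gene, model, seed=s).confidence
                )
            med.append(float(np.median(confs)))
        assert all(a >= b - 0.05 for a, b in zip(med, med[1:]))
        assert med[0] == 1.0


class TestCopyAdjustedProfile:
    def _cls(self, genus, n):
        path = {"domain": "Bacteria", "phylum": "P", "class": "C",
                "order": "O", "family": "F", "genus": genus}
        gene = ssu.SsuGene("r", 0, 1500, "+", "A" * 1500, _q(1500), False)
        calls = {r: (t, 1.0) for r, t in path.items()}
        return [
            ssu.Classification(gene, calls, "genus", genus, 1.0)
        ] * n

    def test_copy_adjustment_examples(self):
        copies = ssu.CopyNumberTable({"A": 4.0, "B": 1.0})
        prof = ssu.copy_adjusted_profile(
            self._cls("A", 40) + self._cls("B", 10), copies
        )
        assert prof == {"A": 0.5, "B": 0.5}

    def test_unit_copies_is_raw_proportion(self):
        copies = ssu.CopyNumberTable({"A": 1.0, "B": 1.0})
        prof = ssu.copy_adjusted_profile(
            self._cls("A", 30) + self._cls("B", 10), copies
        )
        assert prof == {"A": 0.75, "B": 0.25}

    def test_two_thirds_example(self):
        copies = ssu.CopyNumberTable({"A": 3.0, "B": 2.0})
        prof = ssu.copy_adjusted_profile(
            self._cls("A", 30) + self._cls("B", 10), copies
        )
        assert prof["A"] == pytest.approx(2 / 3)
        assert prof["B"] == pytest.approx(1 / 3)

    def test_non_positive_copies_raise(self):
        with pytest.raises(ValueError):
            ssu.copy_adjusted_profile(
                self._cls("A", 1), ssu.CopyNumberTable({"A": 0.0})
            )

    def test_default_copy_number_for_unlisted_taxa(self):
        copies = ssu.CopyNumberTable({"A": 4.0}, default=2.0)
        prof = ssu.copy_adjusted_profile(
            self._cls("A", 40) + self._cls("B", 20), copies
        )
        # 40/4 = 10 vs 20/2 = 10
        assert prof == {"A": 0.5, "B": 0.5}


def test_strand_invariance_of_profile(model):
    """Reverse-complementing every read leaves the profile unchanged."""
    rng = np.random.default_rng(7)
    reads = []
    for i, gidx in enumerate([0, 0, 1, 2, 5, 8]):
        gene = refdata.genus_ssu(gidx)
        seq = _seq(rng, 800) + gene + _seq(rng, 800)
        reads.append((f"r{i}", seq, _q(len(seq))))
    rc_reads = [(n, revcomp(s), q[::-1]) for n, s, q in reads]
    copies = ssu.CopyNumberTable({})

    def profile(rs):
        genes = ssu.filter_ssu(ssu.detect_ssu_in_reads(rs))
        cls = ssu.classify_all(genes, model, seed=3)
        return ssu.copy_adjusted_profile(cls, copies)

    assert profile(reads) == profile(rc_reads)
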