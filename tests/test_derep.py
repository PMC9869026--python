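"""MinHash sketching, Mash distance, fragment ANI, dereplication."""

import math

import numpy as np
import pytest

from hifimag import derep as dr
from hifimag import synthio
from hifimag._kmers import revcomp


def _seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def exact_canonical_jaccard(a: str, b: str, k: int = 21) -> float:
    """Independent oracle: exhaustive canonical k-mer sets as strings."""

    def kmers(s):
        out = set()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            out.add(min(km, revcomp(km)))
        return out

    ka, kb = kmers(a), kmers(b)
    return len(ka & kb) / len(ka | kb)


class TestSketch:
    def test_identical_genomes_identical_sketches(self):
        rng = np.random.default_rng(0)
        g = _seq(rng, 50_000)
        assert np.array_equal(dr.sketch(g, "a").hashes,
                              dr.sketch(g, "b").hashes)

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(1)
        g = _seq(rng, 50_000)
        assert np.array_equal(dr.sketch(g, "a").hashes,
                              dr.sketch(revcomp(g), "a").hashes)

    def test_multi_contig_pooling(self):
        rng = np.random.default_rng(2)
        g = _seq(rng, 40_000)
        pooled = dr.sketch({"c1": g[:20_000], "c2": g[20_000:]}, "a")
        # pooling loses only the k-mers spanning the split point
        whole = dr.sketch(g, "a")
        shared = np.intersect1d(pooled.hashes, whole.hashes).size
        assert shared >= 995

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError):
            dr.sketch("ACGT", "a")

    def test_jaccard_estimate_close_to_exact(self):
        rng = np.random.default_rng(3)
        a = _seq(rng, 10_000)
        b = synthio._mutate_str(a, 0.02, rng)
        sa, sb = dr.sketch(a, "a"), dr.sketch(b, "b")
        merged = np.unique(np.concatenate([sa.hashes, sb.hashes]))[: sa.s]
        est = np.intersect1d(
            merged, np.intersect1d(sa.hashes, sb.hashes)
        ).size / merged.size
        assert abs(est - exact_canonical_jaccard(a, b)) <= 0.05


class TestMashDistance:
    def test_identical_is_zero(self):
        rng = np.random.default_rng(4)
        s = dr.sketch(_seq(rng, 20_000), "a")
        assert dr.mash_distance(s, s) == 0.0

    def test_disjoint_capped_at_one(self):
        rng = np.random.default_rng(5)
        a = dr.sketch(_seq(rng, 20_000), "a")
        b = dr.sketch(_seq(rng, 20_000), "b")
        assert dr.mash_distance(a, b) == 1.0

    def test_mismatched_parameters_raise(self):
        rng = np.random.default_rng(6)
        a = dr.sketch(_seq(rng, 20_000), "a", k=21)
        b = dr.sketch(_seq(rng, 20_000), "b", k=17)
        with pytest.raises(ValueError):
            dr.mash_distance(a, b)

    def test_distance_tracks_divergence_closed_form(self):
        """d at 1% substitution agrees with the closed-form Mash distance
        computed from the exact Jaccard of the two k-mer sets."""
        rng = np.random.default_rng(7)
        a = _seq(rng, 50_000)
        b = synthio._mutate_str(a, 0.01, rng)
        d = dr.mash_distance(dr.sketch(a, "a"), dr.sketch(b, "b"))
        j = exact_canonical_jaccard(a, b)
        d_exact = -math.log(2 * j / (1 + j)) / 21
        assert 0.005 <= d <= 0.02
        assert abs(d - d_exact) <= 0.004

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        a = _seq(rng, 30_000)
        b = synthio._mutate_str(a, 0.03, rng)
        sa, sb = dr.sketch(a, "a"), dr.sketch(b, "b")
        assert dr.mash_distance(sa, sb) == dr.mash_distance(sb, sa)


class TestClustering:
    def test_copies_form_one_cluster(self):
        rng = np.random.default_rng(9)
        g = _seq(rng, 30_000)
        sketches = [dr.sketch(g, f"g{i}") for i in range(3)]
        assert dr.cluster_sketches(sketches) == [["g0", "g1", "g2"]]

    def test_unrelated_genomes_stay_apart(self):
        rng = np.random.default_rng(10)
        sketches = [dr.sketch(_seq(rng, 30_000), f"g{i}") for i in range(2)]
        assert dr.cluster_sketches(sketches) == [["g0"], ["g1"]]

    def test_single_linkage_chain(self):
        """A~B and B~C below d_max chain A,B,C together even when A-C is
        above d_max (oracle: brute-force connected components)."""
        rng = np.random.default_rng(11)
        a = _seq(rng, 50_000)
        b = synthio._mutate_str(a, 0.035, rng)
        c = synthio._mutate_str(b, 0.035, rng)
        sk = [dr.sketch(x, n) for x, n in ((a, "A"), (b, "B"), (c, "C"))]
        dab = dr.mash_distance(sk[0], sk[1])
        dbc = dr.mash_distance(sk[1], sk[2])
        dac = dr.mash_distance(sk[0], sk[2])
        assert dab <= 0.05 and dbc <= 0.05 and dac > 0.05
        assert dr.cluster_sketches(sk, 0.05) == [["A", "B", "C"]]


class TestFragmentAni:
    def test_self_ani_is_one_hundred(self):
        rng = np.random.default_rng(12)
        g = _seq(rng, 120_000)
        res = dr.ani_pair(g, g, "g", "g")
        assert res.ani_pct == pytest.approx(100.0, abs=0.01)
        assert res.query_cov_pct >= 99 and res.ref_cov_pct >= 99

    def test_two_percent_divergence(self):
        rng = np.random.default_rng(13)
        a = _seq(rng, 200_000)
        b = synthio._mutate_str(a, 0.02, rng)
        res = dr.ani_pair(a, b, "a", "b")
        assert 97.5 <= res.ani_pct <= 98.5

    def test_unrelated_genomes_undefined(self):
        rng = np.random.default_rng(14)
        a, b = _seq(rng, 100_000), _seq(rng, 100_000)
        res = dr.ani_pair(a, b, "a", "b")
        assert res.ani_pct is None
        assert res.query_cov_pct < 5 and res.ref_cov_pct < 5

    @pytest.mark.parametrize("rate", [0.005, 0.02, 0.04])
    def test_ani_recovers_substitution_rate(self, rate):
        """|ANI - 100(1-r)| <= 0.5 for substitution-only divergence
        (oracle: the planted rate itself)."""
        rng = np.random.default_rng(int(rate * 1000))
        a = _seq(rng, 300_000)
        b = synthio._mutate_str(a, rate, rng)
        res = dr.ani_pair(a, b, "a", "b")
        assert abs(res.ani_pct - 100.0 * (1 - rate)) <= 0.5


class TestSameSpecies:
    @pytest.mark.parametrize(
        "ani,cq,cr,expected",
        [
            (96, 60, 55, True),
            (96, 60, 40, False),  # coverage must hold for both
            (94.9, 100, 100, False),
            (95.0, 50.0, 50.0, True),  # inclusive boundaries
        ],
    )
    def test_rule(self, ani, cq, cr, expected):
        res = dr.AniResult("a", "b", ani, cq, cr, 10)
        assert dr.same_species(res) is expected

    def test_undefined_ani_is_not_same_species(self):
        assert not dr.same_species(dr.AniResult("a", "b", None, 0, 0, 0))


class TestDereplicate:
    def test_best_score_becomes_representative(self):
        rng = np.random.default_rng(15)
        base = _seq(rng, 100_000)
        genomes = {
            "A": base,
            "B": synthio._mutate_str(base, 0.01, rng),
            "C": _seq(rng, 100_000),
        }
        res = dr.dereplicate(genomes, {"A": 85.0, "B": 80.0, "C": 70.0})
        assert res.representatives == ["A", "C"]
        assert res.membership == {"A": "A", "B": "A", "C": "C"}

    def test_distinct_genomes_all_representatives(self):
        rng = np.random.default_rng(16)
        genomes = {f"g{i}": _seq(rng, 60_000) for i in range(4)}
        res = dr.dereplicate(genomes, {g: 90.0 for g in genomes})
        assert res.representatives == sorted(genomes)

    def test_variant_set_collapses_to_species(self):
        genomes, species = synthio.make_variant_genomes(4, 3, 60_000, 0.01,
                                                        seed=17)
        scores = {g: 80.0 + (2 if g.endswith("v1") else 0) for g in genomes}
        res = dr.dereplicate(genomes, scores)
        assert len(res.representatives) == 4
        # each representative is the max-score variant of its species
        assert all(r.endswith("v1") for r in res.representatives)
        for g, rep in res.membership.items():
            assert species[g] == species[rep]

    def test_idempotence(self):
        genomes, _ = synthio.make_variant_genomes(3, 2, 60_000, 0.01,
                                                  seed=18)
        scores = {g: 75.0 + int(g[-1]) for g in genomes}
        res = dr.dereplicate(genomes, scores)
        reps = {g: genomes[g] for g in res.representatives}
        res2 = dr.dereplicate(reps, {g: scores[g] for g in reps})
        assert res2.representatives == res.representatives

    def test_missing_score_raises(self):
        with pytest.raises(ValueError):
            dr.dereplicate({"a": "ACGT" * 10_000}, {})
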