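#!/usr/bin/env python
"""Score the recovered circular genomes: marker completeness and
contamination, quality ranks, rRNA operon and tRNA-type counts.

Writes results/03_quality.tsv.
"""

from common import FIXTURE, RESULTS, ensure_fixture


def main():
    ensure_fixture()
    from hifimag import genome_quality as gq
    from hifimag import graph_triage as gt

    graph = gt.parse_gfa(FIXTURE / "assembly.gfa")
    calls = gt.classify_components(graph)
    genomes = dict(gt.extract_circular(graph, calls, 1_000_000))
    ann = gq.read_gff_annotations(FIXTURE / "truth_features.gff3")

    lines = ["genome_id\tcp\tct\trank\tscore\tn_operons\tn_trna_types"]
    n_with_operon = n_full_trna = 0
    for gid in sorted(genomes):
        est = gq.assess(gq.find_marker_hits(gid, genomes[gid]))
        n_op, _ = gq.count_rrna_operons(ann.get(gid, []))
        n_trna = gq.count_trna_types(ann.get(gid, []))
        n_with_operon += n_op >= 1
        n_full_trna += n_trna >= 18
        lines.append(
            f"{gid}\t{est.cp:.1f}\t{est.ct:.1f}\t{est.rank}\t"
            f"{est.score:.1f}\t{n_op}\t{n_trna}"
        )
    (RESULTS / "03_quality.tsv").write_text("\n".join(lines) + "\n")
    print(f"scored {len(genomes)} circular genomes; "
          f"{n_with_operon} carry >= 1 complete rRNA operon, "
          f"{n_full_trna} have >= 18 tRNA isotypes")


if __name__ == "__main__":
    main()
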