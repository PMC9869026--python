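#!/usr/bin/env python
"""Triage the synthetic assembly graph into the three contig topologies.

Writes results/02_components.tsv; reports how many components of each
type were found and whether the generator's labels were recovered.
"""

from common import FIXTURE, RESULTS, ensure_fixture


def main():
    ensure_fixture()
    from hifimag import graph_triage as gt

    graph = gt.parse_gfa(FIXTURE / "assembly.gfa")
    calls = gt.classify_components(graph)
    (RESULTS / "02_components.tsv").write_text(gt.component_table(calls))

    labels = {}
    with open(FIXTURE / "gfa_labels.tsv") as fh:
        fh.readline()
        for line in fh:
            seg, comp, topo, _ = line.split("\t")
            labels[seg] = topo
    got = {m: c.topology for c in calls for m in c.members}
    n_ok = sum(1 for s in labels if got[s] == labels[s])
    by_topo = {t: sum(1 for c in calls if c.topology == t)
               for t in gt.TOPOLOGIES}
    circ = gt.extract_circular(graph, calls, 1_000_000)
    print(f"components: {by_topo}")
    print(f"segment labels recovered: {n_ok}/{len(labels)}")
    print(f"circular contigs >= 1 Mb (candidate genomes): {len(circ)}")
    print(
        "linear contigs >= 2 kb for binning: "
        f"{len(gt.prebinning_filter(graph, calls))}"
    )


if __name__ == "__main__":
    main()
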