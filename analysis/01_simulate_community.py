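#!/usr/bin/env python
"""Simulate the default 12-taxon digester-like community and summarise
the read set.

Writes results/01_read_stats.tsv and results/01_truth_abundances.tsv.
"""

from common import FIXTURE, RESULTS, ensure_fixture


def main():
    ensure_fixture()
    import pysam

    from hifimag.pipeline import read_stats

    with pysam.FastxFile(str(FIXTURE / "reads.fastq")) as fh:
        lengths = [len(r.sequence) for r in fh]
    stats = read_stats(lengths)
    with open(RESULTS / "01_read_stats.tsv", "w") as out:
        out.write("metric\tvalue\n")
        for k, v in stats.items():
            out.write(f"{k}\t{v}\n")
    (RESULTS / "01_truth_abundances.tsv").write_text(
        (FIXTURE / "truth_replicons.tsv").read_text()
    )
    print(
        f"simulated {stats['n']} HiFi-like reads, "
        f"{stats['total_bp'] / 1e6:.1f} Mb total, N50 {stats['N50']} bp "
        f"(model target 14,254 bp), N90 {stats['N90']} bp"
    )
    print("truth abundances copied to results/01_truth_abundances.tsv")


if __name__ == "__main__":
    main()
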