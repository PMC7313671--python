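#!/usr/bin/env python
"""Call insertion sites from split short reads and spanning long reads,
cluster them across lines, and compute sharing statistics.

Short-read calls use clipped reads whose clipped portion matches a terminal
element window; long-read calls require genomic anchors on both sides of the
element segment and also type each copy's exon structure. Sites are merged
across lines by single-linkage clustering (50-bp window) into the
unique/shared table, and the haplotype-sites-per-copy statistic is computed
for the panel alongside the published worked example.
"""

import sys
from pathlib import Path

import pandas as pd

from dysgene import experiments, insertions, tequant
from dysgene.formats import write_bed

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

lib, panel = experiments.simulate_line_panel(SEED)
ann = lib.annotation

per_line_sites = {}
site_rows = []
supports = []
for line, short, long_ in panel:
    sites = insertions.call_insertions_short(
        short.truth, "PE", ann.length, line_id=line.line_id
    )
    per_line_sites[line.line_id] = sites
    supports += [s.support for s in sites]
    long_calls, diag = insertions.call_insertions_long(long_.truth, ann, line_id=line.line_id)
    merged = insertions.merge_long_read_calls(long_calls)
    structures = {s.position: st for s, st in merged}
    truth_pos = [i.position for i in line.truth.insertions]
    for s in sites:
        nearest_truth = min((abs(s.position - t) for t in truth_pos), default=None)
        long_structure = next(
            (st for p, st in structures.items() if abs(p - s.position) <= 50), None
        )
        site_rows.append(
            {
                "line_id": s.line_id,
                "contig": s.contig,
                "position": s.position,
                "precision": s.precision,
                "support": s.support,
                "truth_distance_bp": nearest_truth,
                "long_read_structure": (
                    "complete" if long_structure == "complete"
                    else "exons" + "".join(map(str, sorted(long_structure)))
                    if long_structure else "none"
                ),
            }
        )

df = pd.DataFrame(site_rows)
df.to_csv(OUT / "insertion_sites.tsv", sep="\t", index=False)
write_bed([s for sites in per_line_sites.values() for s in sites], OUT / "insertion_sites.bed")
print(df.to_string(index=False))

mean_support = sum(supports) / len(supports)
print(f"\nmean read-pair support per site: {mean_support:.1f}")

table = insertions.cluster_sites_across_lines(per_line_sites, window=50)
print(f"clusters: {len(table.clusters)} ({table.n_unique} unique to a line, "
      f"{table.n_shared} shared); by-line histogram: {table.histogram()}")

cn = pd.read_csv(OUT / "copy_number.tsv", sep="\t") if (OUT / "copy_number.tsv").exists() else None
n_sites = len(df)
n_lines = sum(1 for s in per_line_sites.values() if s)
mean_cn = cn[cn.copy_number >= 0.5].copy_number.mean() if cn is not None else None
if mean_cn:
    spc = insertions.haplotype_sites_per_copy(n_sites, n_lines, 2, mean_cn)
    print(f"panel haplotype-sites per copy ({n_sites}/{n_lines} lines/2 haplotypes/"
          f"{mean_cn:.2f} copies): {spc}")
print("published worked example (1311 sites / 6 lines / 40 haplotypes / 6.6 copies):",
      insertions.haplotype_sites_per_copy(1311, 6, 40, 6.6))
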