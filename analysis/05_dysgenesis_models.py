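#!/usr/bin/env python
"""Fit the dysgenesis phenotype models on a simulated diallel cross.

Simulates the 2M x 2P diallel at 23 and 29 C (50 females per cross and
temperature), then: multinomial ovary-count models per temperature with
type-III term tests, pairwise Fisher-Pitman comparisons at the
Bonferroni-adjusted 0.008 threshold, the Poisson ovariole model with the
full mother x element x hobo term structure, and the reproductive-senescence
ANCOVA comparing age slopes between crosses.
"""

import sys
from itertools import combinations
from pathlib import Path

import pandas as pd

from dysgene import hdstats, presets, synth
from dysgene.formats import phenotypes_to_frame, write_phenotypes

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# diallel: two M lines (0 copies) and two P lines near the population mean
LINES = {"M1": 0.0, "M2": 0.0, "P1": 6.6, "P2": 8.0}
design = [
    synth.DesignCell(
        "M" if LINES[mom] == 0 else "P", dad, LINES[dad], 16.0, temp, 50
    )
    for mom in LINES
    for dad in LINES
    for temp in (23.0, 29.0)
]
records = synth.simulate_phenotypes(design, presets.DEFAULT_COEFFS, seed=SEED)
write_phenotypes(records, OUT / "diallel_phenotypes.csv")
df = phenotypes_to_frame(records)
print(hdstats.hd_summary(df).to_string(index=False))

# ovary number ~ mother x father genotype, per temperature
rows = []
for temp in (23.0, 29.0):
    sub = df[df.temperature == temp]
    table = hdstats.type3_terms(
        sub, [(), ("mother_genotype",), ("father_type",), ("mother_genotype", "father_type")],
        family="multinomial",
    )
    for term, res in table.items():
        rows.append({"model": f"ovary_{temp:g}C", "term": ":".join(term),
                     "chi2": res.chi2, "df": res.df, "p": res.p})
    print(f"\novary model at {temp:g} C: "
          + "; ".join(f"{':'.join(t)} LRT={r.chi2:.2f} p={r.p:.3g}" for t, r in table.items()))

# pairwise cross comparisons on ovary count (Fisher-Pitman, alpha = 0.008)
print(f"\npairwise Fisher-Pitman on ovary count at 29 C (alpha={presets.BONFERRONI_ALPHA:.3f}):")
sub = df[df.temperature == 29.0]
for a, b in combinations(sorted(sub["cross"].unique()), 2):
    res = hdstats.fisher_pitman(
        sub[sub.cross == a]["ovary_count"], sub[sub.cross == b]["ovary_count"],
        n_permutations=10000, seed=SEED,
    )
    flag = "*" if res.p < presets.BONFERRONI_ALPHA else " "
    print(f"  {a} vs {b}: Z={res.statistic:+.2f} p={res.p:.4f} {flag}")
    rows.append({"model": "fisher_pitman_29C", "term": f"{a}~{b}",
                 "chi2": res.statistic, "df": 0, "p": res.p})

# ovariole number: Poisson with the full term structure, per temperature
terms = [
    (), ("mother_M",), ("father_pe_cn",), ("father_hobo_cn",),
    ("mother_M", "father_pe_cn"), ("mother_M", "father_hobo_cn"),
    ("father_pe_cn", "father_hobo_cn"),
    ("mother_M", "father_pe_cn", "father_hobo_cn"),
]
for temp in (23.0, 29.0):
    sub = hdstats.poisson_response(df[df.temperature == temp])
    table = hdstats.type3_terms(sub, terms, family="poisson")
    print(f"\novariole Poisson model at {temp:g} C (deletable terms):")
    for term, res in table.items():
        print(f"  {':'.join(term)}: LRT={res.chi2:.3f} p={res.p:.3g}")
        rows.append({"model": f"ovariole_{temp:g}C", "term": ":".join(term),
                     "chi2": res.chi2, "df": res.df, "p": res.p})

# reproductive senescence: 6 ages x 4 cross types at 29 C, 960 females
# (the study's per-temperature observation count)
sen_design = [
    synth.DesignCell(mg, dad, pe, 16.0, 29.0, 40, ages=(age,))
    for (mg, dad, pe) in [("M", "Mf", 0.0), ("M", "Pf", 6.6), ("P", "Mf", 0.0), ("P", "Pf", 6.6)]
    for age in (4.0, 9.0, 14.0, 19.0, 24.0, 29.0)
]
sen = phenotypes_to_frame(
    synth.simulate_phenotypes(sen_design, presets.SENESCENCE_COEFFS, seed=SEED + 1)
)
full, reduced, res, contrasts = hdstats.senescence_compare(sen)
print(f"\nsenescence age x cross interaction: LRT chi2={res.chi2:.2f} df={res.df} p={res.p:.3g}")
print(contrasts.to_string(index=False))
rows.append({"model": "senescence_29C", "term": "age:cross", "chi2": res.chi2,
             "df": res.df, "p": res.p})

pd.DataFrame(rows).to_csv(OUT / "hd_model_tests.tsv", sep="\t", index=False)
print(f"\nwrote {OUT / 'hd_model_tests.tsv'}")
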