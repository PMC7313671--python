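"""Default study conditions for the synthetic pipeline.

The element geometries mirror the canonical Drosophila elements: a
P-element-like consensus of 2,907 bp with 31-bp terminal inverted repeats
and four exons (0-3), and a hobo-like consensus of 2,959 bp with 12-bp TIRs.
Exon intervals tile the TIR-free interior; their exact boundaries are
synthetic stand-ins for the real gene structure (only lengths and order
matter to the pipeline).

Phenotype coefficient presets reproduce the qualitative dysgenesis pattern —
atrophy and ovariole loss only in M-mother x P-father progeny, only above
25 C, increasing with paternal element copy number — with synthetic effect
magnitudes (the study reports test statistics, not usable effect sizes).
"""

from __future__ import annotations

import math

from .synth import make_te_library

__all__ = [
    "PE_LENGTH",
    "PE_TIR",
    "HOBO_LENGTH",
    "HOBO_TIR",
    "default_pe_library",
    "default_hobo_library",
    "DEFAULT_COEFFS",
    "SENESCENCE_COEFFS",
    "NULL_COEFFS",
    "BONFERRONI_ALPHA",
]

PE_LENGTH = 2907
PE_TIR = 31
HOBO_LENGTH = 2959
HOBO_TIR = 12

#: pairwise-comparison significance threshold, 0.05 Bonferroni-corrected for
#: the six pairwise cross comparisons
BONFERRONI_ALPHA = 0.05 / 6


def _tiling_exons(length: int, tir: int, n: int = 4) -> tuple[tuple[int, int], ...]:
    edges = [tir + round(i * (length - 2 * tir) / n) for i in range(n + 1)]
    return tuple((edges[i], edges[i + 1]) for i in range(n))


def default_pe_library(seed: int = 7):
    """P-element-like library with a {0,3}-truncated variant (the common
    internally-deleted form in which only the terminal exons survive)."""
    return make_te_library(
        PE_LENGTH,
        _tiling_exons(PE_LENGTH, PE_TIR),
        PE_TIR,
        seed,
        name="PE",
        truncated_structures=(frozenset({0, 3}),),
    )


def default_hobo_library(seed: int = 11):
    return make_te_library(
        HOBO_LENGTH,
        _tiling_exons(HOBO_LENGTH, HOBO_TIR),
        HOBO_TIR,
        seed,
        name="hobo",
        truncated_structures=(frozenset({0, 3}),),
    )


# Dysgenesis preset: baseline atrophy ~2%, rising steeply with paternal
# copy number for M mothers at activated temperatures (temp_act = 0 at
# <=25 C, 1 at 29 C). Healthy ovarioles average ~20 per ovary with a mild
# age decline; dysgenic combinations lose ovarioles multiplicatively.
DEFAULT_COEFFS = {
    "ovary0": {
        ("1",): -4.0,
        ("mother_M", "temp_act", "pe_cn"): 0.45,
    },
    "ovary1": {
        ("1",): -4.0,
        ("mother_M", "temp_act", "pe_cn"): 0.30,
    },
    "ovarioles": {
        ("1",): math.log(20.0),
        ("age",): -0.004,
        ("mother_M", "temp_act", "pe_cn"): -0.02,
    },
}

# Senescence preset: adds an accelerated age decline specific to dysgenic
# crosses, on top of the baseline decline shared by all genotypes. The
# four-way magnitude is set so that at the mean paternal copy number of a
# P line (~6.6) the dysgenic-cross age-slope contrast is about -6.2e-3 per
# day on the log scale, the size of contrast the assay is meant to resolve.
SENESCENCE_COEFFS = {
    "ovary0": DEFAULT_COEFFS["ovary0"],
    "ovary1": DEFAULT_COEFFS["ovary1"],
    "ovarioles": {
        ("1",): math.log(20.0),
        ("age",): -0.004,
        ("mother_M", "temp_act", "pe_cn"): -0.015,
        ("mother_M", "temp_act", "pe_cn", "age"): -0.00094,
    },
}

# No-effect preset for null simulations.
NULL_COEFFS = {
    "ovary0": {("1",): -4.0},
    "ovary1": {("1",): -4.0},
    "ovarioles": {("1",): math.log(20.0)},
}
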