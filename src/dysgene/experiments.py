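"""End-to-end validation experiments over the synthetic study conditions.

Each function runs one slice of the pipeline at the study's stated scale —
100-kb line genomes, ~30x paired-end coverage, 100-150 bp reads, diallel
phenotype designs — and returns plainly-named summary numbers. The analysis
drivers, the test suite, and the acceptance script all call these, so the
same computation backs every reported figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hdstats, insertions, presets, synth, tequant
from .formats import phenotypes_to_frame

__all__ = [
    "worked_example_sites_per_copy",
    "copy_number_recovery",
    "insertion_recovery",
    "truncation_fold",
    "long_read_structures",
    "fisher_pitman_agreement",
    "lrt_type1_error",
    "coefficient_recovery",
    "ci_coverage",
    "qualitative_pattern",
    "temperature_interaction",
]

GENOME_LENGTH = 100_000
COVERAGE = 30.0
READ_LENGTH = 150

#: the simulated isofemale-line panel: (line_id, n_full, n_truncated)
#: copy counts span the realistic 0-20 range, with one element-free (M)
#: line and one line dominated by internally-deleted copies
PANEL = (
    ("lineM", 0, 0),
    ("line02", 2, 0),
    ("line05", 5, 0),
    ("line08", 2, 6),
    ("line12", 12, 0),
    ("line20", 20, 0),
)


def simulate_line_panel(
    seed: int,
    genome_length: int = GENOME_LENGTH,
    coverage: float = COVERAGE,
    long_coverage: float = 20.0,
):
    """Simulate the standard line panel: genomes, short reads, long reads.

    Returns a list of (LineGenome, short ReadSim, long ReadSim); all stages
    of the pipeline downstream of alignment run from these truth alignments.
    """
    lib = presets.default_pe_library()
    seeds = _child_seeds(seed, 2 * len(PANEL))
    panel = []
    for i, (line_id, n_full, n_trunc) in enumerate(PANEL):
        g = synth.random_genome(genome_length, seeds[2 * i])
        line = synth.make_line_genome(
            g, lib, n_full=n_full, n_truncated=n_trunc, seed=seeds[2 * i + 1], line_id=line_id
        )
        short = synth.simulate_short_reads(
            line, coverage=coverage, read_length=READ_LENGTH,
            seed=seeds[2 * i + 1], with_sequences=False,
        )
        long = synth.simulate_long_reads(
            line, coverage=long_coverage, seed=seeds[2 * i + 1], with_sequences=False
        )
        panel.append((line, short, long))
    return lib, panel


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def worked_example_sites_per_copy() -> float:
    """The in-study worked example: 1,311 sites over 6 lines of 40 pooled
    haplotypes at 6.6 mean copies -> haplotype-sites per copy."""
    return insertions.haplotype_sites_per_copy(1311, 6, 40, 6.6)


# ---------------------------------------------------------------------------
# copy number


def copy_number_recovery(
    seed: int,
    ks: tuple[int, ...] = (0, 1, 2, 5, 10, 20),
    n_seeds: int = 20,
    genome_length: int = GENOME_LENGTH,
    coverage: float = COVERAGE,
) -> pd.DataFrame:
    """Depth-ratio copy-number estimates for k homozygous full copies.

    For each k, ``n_seeds`` independent lines are simulated at the study
    coverage and the estimate and P/M call recorded. Returns one row per
    (k, replicate)."""
    lib = presets.default_pe_library()
    rows = []
    seeds = _child_seeds(seed, n_seeds * len(ks) * 2)
    i = 0
    for k in ks:
        for rep in range(n_seeds):
            g = synth.random_genome(genome_length, seeds[i])
            line = synth.make_line_genome(
                g, lib, n_full=k, n_truncated=0, seed=seeds[i + 1], line_id=f"k{k}r{rep}"
            )
            sim = synth.simulate_short_reads(
                line, coverage=coverage, read_length=READ_LENGTH,
                seed=seeds[i + 1], with_sequences=False,
            )
            i += 2
            d_te = tequant.mean_depth(sim.truth_for("PE"), lib.annotation.length)
            d_g = tequant.mean_depth(sim.truth_for(line.contig), genome_length)
            cn = tequant.estimate_copy_number(d_te, d_g)
            rows.append(
                {
                    "k": k,
                    "rep": rep,
                    "copy_number": cn,
                    "status": tequant.classify_infection(cn),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# insertion calling


@dataclass
class InsertionRecovery:
    n_truth: int
    n_recovered: int  # truth positions matched within the tolerance
    n_called: int
    n_false_on_te_free: int
    tolerance_bp: int

    @property
    def recovery_fraction(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else float("nan")


def insertion_recovery(
    seed: int,
    n_insertions: int = 10,
    tolerance_bp: int = 5,
    min_support: int = 3,
    genome_length: int = GENOME_LENGTH,
    coverage: float = COVERAGE,
) -> InsertionRecovery:
    """Short-read split-read recovery of simulated homozygous insertions,
    plus the false-call count on a TE-free genome."""
    lib = presets.default_pe_library()
    s1, s2, s3 = _child_seeds(seed, 3)
    g = synth.random_genome(genome_length, s1)
    line = synth.make_line_genome(g, lib, n_full=n_insertions, n_truncated=0, seed=s2, line_id="ins")
    sim = synth.simulate_short_reads(
        line, coverage=coverage, read_length=READ_LENGTH, seed=s2, with_sequences=False
    )
    sites = insertions.call_insertions_short(
        sim.truth, "PE", lib.annotation.length, min_support=min_support, line_id="ins"
    )
    truth_pos = [ins.position for ins in line.truth.insertions]
    recovered = sum(
        any(abs(s.position - t) <= tolerance_bp for s in sites) for t in truth_pos
    )

    free = synth._bare_line(synth.random_genome(genome_length, s3), "free", "chr2L")
    fsim = synth.simulate_short_reads(
        free, coverage=coverage, read_length=READ_LENGTH, seed=s3, with_sequences=False
    )
    false_calls = insertions.call_insertions_short(
        fsim.truth, "PE", lib.annotation.length, min_support=min_support, line_id="free"
    )
    return InsertionRecovery(
        n_truth=len(truth_pos),
        n_recovered=recovered,
        n_called=len(sites),
        n_false_on_te_free=len(false_calls),
        tolerance_bp=tolerance_bp,
    )


# ---------------------------------------------------------------------------
# truncation profiling


def truncation_fold(
    seed: int,
    n_full: int = 2,
    n_truncated: int = 6,
    genome_length: int = GENOME_LENGTH,
    coverage: float = COVERAGE,
):
    """Exon-depth fold when {0,3}-truncated copies outnumber complete copies
    3:1; the expected terminal/internal depth ratio is (3+1)/1 = 4."""
    lib = presets.default_pe_library()
    s1, s2 = _child_seeds(seed, 2)
    g = synth.random_genome(genome_length, s1)
    line = synth.make_line_genome(g, lib, n_full=n_full, n_truncated=n_truncated, seed=s2)
    sim = synth.simulate_short_reads(
        line, coverage=coverage, read_length=READ_LENGTH, seed=s2, with_sequences=False
    )
    profile = tequant.coverage_profile(sim.truth_for("PE"), lib.annotation)
    return tequant.exon_summary(profile, lib.annotation)


def long_read_structures(
    seed: int,
    n_full: int = 2,
    n_truncated: int = 6,
    genome_length: int = GENOME_LENGTH,
    coverage: float = 25.0,
    length_mean: float = 15_000.0,
):
    """Spanning-long-read copy-structure calls on a mixed full/truncated
    line: per-site majority structures after merging per-read calls."""
    lib = presets.default_pe_library()
    s1, s2 = _child_seeds(seed, 2)
    g = synth.random_genome(genome_length, s1)
    line = synth.make_line_genome(g, lib, n_full=n_full, n_truncated=n_truncated, seed=s2)
    sim = synth.simulate_long_reads(
        line, coverage=coverage, length_mean=length_mean, seed=s2, with_sequences=False
    )
    calls, diag = insertions.call_insertions_long(sim.truth, lib.annotation, line_id=line.line_id)
    merged = insertions.merge_long_read_calls(calls)
    return merged, diag, line.truth


# ---------------------------------------------------------------------------
# statistical engine checks


def fisher_pitman_agreement(seed: int, n_mc: int = 100_000) -> float:
    """|Monte-Carlo - exact| permutation p on an n=8 two-sample instance."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 4)
    y = rng.normal(1, 1, 4)
    exact = hdstats.fisher_pitman(x, y, seed=seed)  # n<=10: enumerated
    mc = hdstats.fisher_pitman(x, y, n_permutations=n_mc, seed=seed, exact_max_n=0)
    return abs(exact.p - mc.p)


def lrt_type1_error(seed: int, n_sims: int = 1000, n_per_sim: int = 150, alpha: float = 0.05) -> float:
    """Type-I error of the Poisson LRT when the tested copy-number effect is
    truly absent.

    Responses are drawn Poisson under the reduced (intercept-only) truth, so
    the simulation checks the test's calibration at the model's own
    assumptions. (Per-female *mean* ovarioles over two ovaries is mildly
    under-dispersed relative to Poisson, which makes the applied test
    conservative; that pipeline property is documented, not tested here.)
    """
    rng = np.random.default_rng(seed)
    pe = np.tile(np.array([0.0, 3.0, 6.0, 9.0, 12.0]), n_per_sim // 5 + 1)[:n_per_sim]
    rejections = 0
    for _ in range(n_sims):
        df = pd.DataFrame(
            {"father_pe_cn": pe, "ovarioles_int": rng.poisson(20.0, n_per_sim)}
        )
        full = hdstats.fit_poisson(df, [(), ("father_pe_cn",)])
        reduced = hdstats.fit_poisson(df, [()])
        if hdstats.lrt(full, reduced).p < alpha:
            rejections += 1
    return rejections / n_sims


#: generating coefficients used by the recovery and coverage experiments
_RECOVERY_COEFFS = {
    "ovary0": {("1",): -3.0, ("pe_cn",): 0.25},
    "ovary1": {("1",): -3.0, ("pe_cn",): 0.15},
    "ovarioles": {("1",): math.log(20.0), ("pe_cn",): -0.07},
}


def _recovery_design(n_females: int) -> list[synth.DesignCell]:
    pes = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    per = max(1, n_females // len(pes))
    return [
        synth.DesignCell("M", f"F{pe:g}", pe, 16.0, 29.0, per) for pe in pes
    ]


def _per_ovary_frame(recs) -> pd.DataFrame:
    """One row per female with at least one ovary, with a single per-ovary
    ovariole count as response.

    The generator draws each ovary's count Poisson given the covariates, so
    this response meets the Poisson model's assumptions exactly; the applied
    per-female *mean* over two ovaries is mildly under-dispersed and makes
    the applied models conservative.
    """
    df = phenotypes_to_frame(recs)
    df["ovarioles_int"] = [r.ovarioles[0] if r.ovarioles else np.nan for r in recs]
    return df[df["ovarioles_int"].notna()].copy()


def coefficient_recovery(
    seed: int, n_multinomial: int = 2000, n_poisson: int = 1000, n_reps: int = 5
) -> dict:
    """Fit models to data drawn from known coefficients; report the mean
    absolute estimation error in SE units for the copy-number effect over
    ``n_reps`` replicates (a calibrated estimator averages ~0.8)."""
    seeds = _child_seeds(seed, 2 * n_reps)
    z_mn, z_po = [], []
    for r in range(n_reps):
        recs = synth.simulate_phenotypes(
            _recovery_design(n_multinomial), _RECOVERY_COEFFS, seed=seeds[2 * r]
        )
        df = phenotypes_to_frame(recs)
        mfit = hdstats.fit_multinomial(df, [(), ("father_pe_cn",)])
        z_mn.append(
            abs(
                (mfit.coefficients.loc["father_pe_cn", "logit0"] - 0.25)
                / mfit.bse.loc["father_pe_cn", "logit0"]
            )
        )
        recs = synth.simulate_phenotypes(
            _recovery_design(n_poisson), _RECOVERY_COEFFS, seed=seeds[2 * r + 1]
        )
        dfp = _per_ovary_frame(recs)
        pfit = hdstats.fit_poisson(dfp, [(), ("father_pe_cn",)])
        z_po.append(
            abs(
                (pfit.coefficients.loc["father_pe_cn", "coef"] - (-0.07))
                / pfit.bse.loc["father_pe_cn", "coef"]
            )
        )
    return {
        "multinomial_z_error": float(np.mean(z_mn)),
        "poisson_z_error": float(np.mean(z_po)),
    }


def ci_coverage(seed: int, n_sims: int = 500, n_per_sim: int = 420) -> dict:
    """95% Wald CI coverage for the copy-number coefficient in the closed
    generator -> fitter loop, for both model families."""
    seeds = _child_seeds(seed, n_sims)
    design = _recovery_design(n_per_sim)
    hit_mn = hit_po = n_mn = n_po = 0
    for s in seeds:
        recs = synth.simulate_phenotypes(design, _RECOVERY_COEFFS, seed=s)
        df = phenotypes_to_frame(recs)
        mfit = hdstats.fit_multinomial(df, [(), ("father_pe_cn",)])
        if not mfit.separation and mfit.converged:
            est = mfit.coefficients.loc["father_pe_cn", "logit0"]
            se = mfit.bse.loc["father_pe_cn", "logit0"]
            n_mn += 1
            hit_mn += abs(est - 0.25) <= 1.96 * se
        dfp = _per_ovary_frame(recs)
        pfit = hdstats.fit_poisson(dfp, [(), ("father_pe_cn",)])
        est = pfit.coefficients.loc["father_pe_cn", "coef"]
        se = pfit.bse.loc["father_pe_cn", "coef"]
        n_po += 1
        hit_po += abs(est - (-0.07)) <= 1.96 * se
    return {
        "multinomial_coverage": hit_mn / max(n_mn, 1),
        "poisson_coverage": hit_po / n_po,
        "n_multinomial": n_mn,
        "n_poisson": n_po,
    }


# ---------------------------------------------------------------------------
# qualitative dysgenesis pattern


def qualitative_pattern(seed: int, n_per_cell: int = 150) -> dict:
    """Diallel phenotypes under the shipped preset: dysgenic fraction and
    ovariole means per cross/temperature, plus monotonicity of dysgenesis in
    paternal copy number for M mothers at 29 C."""
    pe_grid = (0.0, 4.0, 8.0, 12.0)
    design = []
    for mg in ("M", "P"):
        for pe in pe_grid:
            for temp in (23.0, 29.0):
                design.append(
                    synth.DesignCell(mg, f"F{pe:g}", pe, 16.0, temp, n_per_cell)
                )
    recs = synth.simulate_phenotypes(design, presets.DEFAULT_COEFFS, seed=seed)
    df = phenotypes_to_frame(recs)
    summary = hdstats.hd_summary(df)

    mxp29 = summary.query("cross == 'MxP' and temperature == 29.0")
    others = summary.query("not (cross == 'MxP' and temperature == 29.0)")
    dys_mxp29 = float(mxp29["dysgenic_fraction"].max())
    dys_other_max = float(others["dysgenic_fraction"].max())

    m29 = df.query("mother_M == 1 and temperature == 29.0")
    frac_by_pe = m29.groupby("father_pe_cn")["dysgenic"].mean()
    ov_by_pe = m29.groupby("father_pe_cn")["mean_ovarioles"].mean()
    monotone_dys = bool(frac_by_pe.is_monotonic_increasing)
    monotone_ov = bool(ov_by_pe.is_monotonic_decreasing)

    p23 = df.query("mother_M == 1 and temperature == 23.0")
    return {
        "summary": summary,
        "dysgenic_fraction_MxP_29C": float(
            m29[m29.father_pe_cn == max(pe_grid)]["dysgenic"].mean()
        ),
        "dysgenic_fraction_other_max": dys_other_max,
        "dysgenic_fraction_MxP_23C": float(
            p23[p23.father_pe_cn == max(pe_grid)]["dysgenic"].mean()
        ),
        "monotone_dysgenesis": monotone_dys,
        "monotone_ovariole_deficit": monotone_ov,
        "dysgenic_by_pe_cn": frac_by_pe,
        "ovarioles_by_pe_cn": ov_by_pe,
    }


def temperature_interaction(
    seed: int,
    n_per_cell: int = 40,
    n_boot: int = 300,
) -> dict:
    """Temperature-range experiment: fit the mother x copy-number x
    temperature ovariole model on two synthetic 'species' differing in
    interaction strength, report D-squared for each and the bootstrap
    permutation comparison of the two distributions."""
    temps = (17.0, 19.0, 21.0, 23.0, 25.0, 27.0, 29.0)
    pe_grid = (0.0, 3.0, 6.0, 9.0, 12.0)

    def _species(coeff_scale: float, s: int) -> pd.DataFrame:
        coeffs = {
            "ovary0": presets.DEFAULT_COEFFS["ovary0"],
            "ovary1": presets.DEFAULT_COEFFS["ovary1"],
            "ovarioles": {
                ("1",): math.log(20.0),
                ("mother_M", "temp_act", "pe_cn"): -0.02 * coeff_scale,
            },
        }
        design = [
            synth.DesignCell(mg, f"F{pe:g}", pe, 16.0, t, n_per_cell)
            for mg in ("M", "P")
            for pe in pe_grid
            for t in temps
        ]
        recs = synth.simulate_phenotypes(design, coeffs, seed=s)
        return hdstats.poisson_response(phenotypes_to_frame(recs), rounding="up")

    s1, s2, s3 = _child_seeds(seed, 3)
    terms = [(), ("mother_M", "father_pe_cn", "temperature")]
    df_a = _species(1.0, s1)
    df_b = _species(2.0, s2)
    fit_a = hdstats.fit_poisson(df_a, terms)
    fit_b = hdstats.fit_poisson(df_b, terms)
    result, d2_a, d2_b = hdstats.bootstrap_r2_compare(
        df_a, terms, df_b, terms, n_boot=n_boot, seed=s3
    )
    return {
        "dsquared_a": hdstats.dsquared(fit_a),
        "dsquared_b": hdstats.dsquared(fit_b),
        "compare": result,
        "boot_a": d2_a,
        "boot_b": d2_b,
    }
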