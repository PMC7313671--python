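"""Synthetic data: everything the downstream pipeline consumes.

The module emulates the study system — isofemale *Drosophila* lines whose
genomes carry 0–25 full or internally-deleted transposable-element copies,
paired-end short reads (100–150 bp, ~30x target coverage), long reads
spanning whole insertions, and diallel-cross ovary/ovariole phenotype tables.

Reads come with *truth alignments*: the alignment records an ideal mapper
would produce, split across TE/genome junctions with clip fields set. Tests
and analyses therefore need no external aligner.

Randomness: every operation takes a seed and spawns per-purpose generators
from one ``numpy.random.SeedSequence``, so a fixed seed gives byte-identical
output and partial re-runs are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .formats import AlignmentRecord, PhenotypeRecord, TEAnnotation

__all__ = [
    "TELibrary",
    "SimTruth",
    "Insertion",
    "LineGenome",
    "ReadSim",
    "DesignCell",
    "make_te_library",
    "random_genome",
    "make_line_genome",
    "simulate_short_reads",
    "simulate_long_reads",
    "simulate_phenotypes",
    "revcomp",
]

_COMP = str.maketrans("ACGTacgtN", "TGCAtgcaN")

#: length of the target-site duplication created on insertion (characteristic
#: of the element family; not a fitted quantity)
DEFAULT_TSD = 8


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _rand_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class PlacementError(RuntimeError):
    """Could not place insertions without overlap."""


# ---------------------------------------------------------------------------
# TE library


@dataclass(frozen=True)
class TELibrary:
    """A TE consensus plus its internally-deleted variants.

    Each variant is a tuple of consensus intervals, concatenated in order to
    form the variant sequence; the full element is the single interval
    ``(0, length)``, a truncated copy keeps both terminal inverted repeats
    plus the retained exons.
    """

    annotation: TEAnnotation
    consensus: str
    variants: dict[frozenset, tuple[tuple[int, int], ...]]

    def variant_intervals(self, structure) -> tuple[tuple[int, int], ...]:
        if structure == "complete":
            return ((0, self.annotation.length),)
        return self.variants[frozenset(structure)]

    def variant_seq(self, structure) -> str:
        return "".join(self.consensus[a:b] for a, b in self.variant_intervals(structure))


def make_te_library(
    te_length: int,
    exon_boundaries: Sequence[tuple[int, int]],
    tir_length: int,
    seed: int,
    name: str = "TE",
    truncated_structures: Iterable[frozenset] = (frozenset({0, 3}),),
) -> TELibrary:
    """Build a random TE consensus with reverse-complementary terminal
    inverted repeats and a set of internally-deleted variants.

    Exon intervals must tile within the TIR-free interior ``[tir, L - tir)``;
    a truncated variant concatenates both TIRs around the retained exons.
    """
    if 2 * tir_length > te_length:
        raise ValueError(f"2*tir_length ({2 * tir_length}) exceeds te_length ({te_length})")
    ann = TEAnnotation(name=name, length=te_length, exons=tuple(exon_boundaries), tir_length=tir_length)
    for a, b in ann.exons:
        if a < tir_length or b > te_length - tir_length:
            raise ValueError(f"exon ({a},{b}) overlaps a terminal repeat")
    rng = np.random.default_rng(seed)
    body = _rand_seq(te_length - tir_length, rng)
    head = body[:tir_length]
    consensus = body + revcomp(head)  # last tir bases = revcomp of first tir
    variants: dict[frozenset, tuple[tuple[int, int], ...]] = {}
    for structure in truncated_structures:
        structure = frozenset(structure)
        if any(i >= ann.n_exons for i in structure):
            raise ValueError(f"variant {set(structure)} references missing exons")
        ivals: list[tuple[int, int]] = []
        if tir_length:
            ivals.append((0, tir_length))
        ivals.extend(ann.exons[i] for i in sorted(structure))
        if tir_length:
            ivals.append((te_length - tir_length, te_length))
        variants[structure] = tuple(ivals)
    return TELibrary(annotation=ann, consensus=consensus, variants=variants)


# ---------------------------------------------------------------------------
# line genomes


@dataclass(frozen=True)
class Insertion:
    contig: str
    position: int  # 0-based breakpoint on the base genome (TSD midpoint)
    structure: object  # "complete" or frozenset of retained exon indices


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated line."""

    line_id: str
    insertions: tuple[Insertion, ...]
    zygosity: float  # fraction of pool haplotypes carrying the insertions

    def __post_init__(self) -> None:
        if not (0 < self.zygosity <= 1):
            raise ValueError("zygosity must be in (0, 1]")


@dataclass(frozen=True)
class _Piece:
    """One contiguous stretch of a haplotype mapped to one target interval."""

    h_start: int
    h_end: int
    target_id: str
    t_start: int


@dataclass
class LineGenome:
    """A simulated line: weighted haplotypes with per-base target maps.

    ``haplotypes`` holds ``(sequence, pieces, weight)``; weights are the
    fraction of the sequenced pool each haplotype class represents (e.g.
    0.5/0.5 for an insertion at 50% frequency in the pool).
    """

    line_id: str
    contig: str
    base_length: int
    te_name: str
    haplotypes: list[tuple[str, tuple[_Piece, ...], float]]
    truth: SimTruth

    @property
    def mean_length(self) -> float:
        return sum(len(s) * w for s, _, w in self.haplotypes)


def random_genome(length: int, seed: int) -> str:
    return _rand_seq(length, np.random.default_rng(seed))


def make_line_genome(
    base_genome: str,
    library: TELibrary,
    n_full: int,
    n_truncated: int,
    seed: int,
    truncated_structure: frozenset = frozenset({0, 3}),
    zygosity: float = 1.0,
    line_id: str = "line",
    contig: str = "chr2L",
    tsd_length: int = DEFAULT_TSD,
    min_separation: int = 2000,
    max_tries: int = 200,
) -> LineGenome:
    """Insert TE copies into a base genome at uniform non-overlapping sites.

    Each insertion duplicates the ``tsd_length`` bases at the target site.
    The recorded truth position is the midpoint of the duplication, since the
    breakpoint is intrinsically ambiguous within it. ``zygosity`` < 1 yields
    a two-class haplotype pool (carrier/non-carrier) with the given carrier
    fraction.
    """
    n_total = n_full + n_truncated
    base_len = len(base_genome)
    te_len = library.annotation.length
    if n_total * (te_len + min_separation) > base_len:
        raise PlacementError("genome too small for requested insertion count")
    rng = np.random.default_rng(seed)
    margin = 5000 if base_len > 20000 else 200
    # uniform placement with a minimum gap: draw in the gap-collapsed
    # interval, sort, then re-inflate by i*min_separation
    span = (base_len - 2 * margin) - (n_total - 1) * min_separation if n_total else 0
    if n_total and span <= 0:
        raise PlacementError("genome too small for requested insertion count")
    positions = (
        sorted(rng.integers(0, span, n_total).tolist()) if n_total else []
    )
    positions = [margin + p + i * min_separation for i, p in enumerate(positions)]
    structures = ["complete"] * n_full + [frozenset(truncated_structure)] * n_truncated
    rng.shuffle(structures)

    pieces: list[_Piece] = []
    seq_parts: list[str] = []
    h = 0
    prev = 0

    def _emit(target_id: str, t_start: int, t_end: int, part: str) -> None:
        nonlocal h
        if t_end <= t_start:
            return
        pieces.append(_Piece(h, h + (t_end - t_start), target_id, t_start))
        seq_parts.append(part)
        h += t_end - t_start

    for pos, structure in zip(positions, structures):
        _emit(contig, prev, pos + tsd_length, base_genome[prev : pos + tsd_length])
        for a, b in library.variant_intervals(structure):
            _emit(library.annotation.name, a, b, library.consensus[a:b])
        prev = pos  # re-emit the TSD on the right side
    _emit(contig, prev, base_len, base_genome[prev:])
    carrier_seq = "".join(seq_parts)
    carrier = (carrier_seq, tuple(pieces), zygosity)

    haplotypes = [carrier]
    if zygosity < 1.0:
        base_pieces = (_Piece(0, base_len, contig, 0),)
        haplotypes.append((base_genome, base_pieces, 1.0 - zygosity))

    truth = SimTruth(
        line_id=line_id,
        insertions=tuple(
            Insertion(contig, pos + tsd_length // 2, s) for pos, s in zip(positions, structures)
        ),
        zygosity=zygosity if n_total else 1.0,
    )
    return LineGenome(
        line_id=line_id,
        contig=contig,
        base_length=base_len,
        te_name=library.annotation.name,
        haplotypes=haplotypes,
        truth=truth,
    )


def _bare_line(base_genome: str, line_id: str, contig: str) -> LineGenome:
    pieces = (_Piece(0, len(base_genome), contig, 0),)
    return LineGenome(
        line_id=line_id,
        contig=contig,
        base_length=len(base_genome),
        te_name="TE",
        haplotypes=[(base_genome, pieces, 1.0)],
        truth=SimTruth(line_id=line_id, insertions=(), zygosity=1.0),
    )


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadSim:
    """Simulated reads plus their truth alignments."""

    reads: list  # (read_id, seq) or (read_id, seq1, seq2) tuples
    truth: list  # AlignmentRecord

    def truth_for(self, target_id: str) -> list:
        return [r for r in self.truth if r.target_id == target_id]


#: truth blocks shorter than this are treated as unmappable and dropped,
#: mirroring a mapper's minimum seed/chain length
MIN_TRUTH_BLOCK = 15


def _map_interval(
    pieces: Sequence[_Piece],
    starts: np.ndarray,
    s: int,
    e: int,
    read_id: str,
    mate: int,
    strand: str,
    mapq: int = 60,
) -> list[AlignmentRecord]:
    """Truth alignments for haplotype interval [s, e): one record per
    overlapped piece, with clips in reference orientation."""
    out: list[AlignmentRecord] = []
    i = int(np.searchsorted(starts, s, side="right")) - 1
    i = max(i, 0)
    while i < len(pieces) and pieces[i].h_start < e:
        p = pieces[i]
        lo, hi = max(s, p.h_start), min(e, p.h_end)
        if hi - lo >= MIN_TRUTH_BLOCK:
            out.append(
                AlignmentRecord(
                    read_id=read_id,
                    mate=mate,
                    target_id=p.target_id,
                    target_start=p.t_start + (lo - p.h_start),
                    target_end=p.t_start + (hi - p.h_start),
                    read_start=lo - s,
                    read_end=hi - s,
                    strand=strand,
                    mapq=mapq,
                    clip_head=lo - s,
                    clip_tail=e - hi,
                )
            )
        i += 1
    return out


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    subs = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, n_err)]
    arr[pos] = np.where(arr[pos] == subs, subs ^ 6, subs)  # force a change
    return arr.tobytes().decode()


def simulate_short_reads(
    genome: LineGenome,
    coverage: float,
    read_length: int = 150,
    insert_mean: float = 400.0,
    insert_sd: float = 40.0,
    error_rate: float = 0.001,
    seed: int = 0,
    with_sequences: bool = True,
    fastq_prefix: str | Path | None = None,
) -> ReadSim:
    """Paired-end reads at the requested mean coverage with truth alignments.

    Pair count = round(coverage * mean genome length / (2 * read length)).
    Read 2 is the reverse complement of the fragment tail. Sequencing error
    is uniform substitution.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_length >= insert_mean:
        raise ValueError("read_length must be < insert_mean")
    n_pairs = int(round(coverage * genome.mean_length / (2 * read_length)))
    ss = np.random.SeedSequence(seed)
    rng_geom, rng_err = (np.random.default_rng(s) for s in ss.spawn(2))

    weights = np.array([w for _, _, w in genome.haplotypes])
    weights = weights / weights.sum()
    hap_idx = rng_geom.choice(len(genome.haplotypes), size=n_pairs, p=weights)
    frag_lens = np.maximum(
        rng_geom.normal(insert_mean, insert_sd, n_pairs).round().astype(int),
        read_length + 1,
    )
    u = rng_geom.random(n_pairs)

    starts_cache = [np.array([p.h_start for p in pieces]) for _, pieces, _ in genome.haplotypes]
    reads = []
    truth: list[AlignmentRecord] = []
    for k in range(n_pairs):
        seq, pieces, _ = genome.haplotypes[hap_idx[k]]
        starts = starts_cache[hap_idx[k]]
        f = min(int(frag_lens[k]), len(seq))
        s = int(u[k] * (len(seq) - f + 1))
        rid = f"{genome.line_id}_r{k}"
        truth.extend(_map_interval(pieces, starts, s, s + read_length, rid, 1, "+"))
        truth.extend(_map_interval(pieces, starts, s + f - read_length, s + f, rid, 2, "-"))
        if with_sequences:
            r1 = _apply_errors(seq[s : s + read_length], error_rate, rng_err)
            r2 = _apply_errors(revcomp(seq[s + f - read_length : s + f]), error_rate, rng_err)
            reads.append((rid, r1, r2))
    sim = ReadSim(reads=reads, truth=truth)
    if fastq_prefix is not None:
        _write_fastq_pairs(reads, Path(fastq_prefix))
    return sim


def simulate_long_reads(
    genome: LineGenome,
    coverage: float,
    length_mean: float = 15000.0,
    error_rate: float = 0.05,
    seed: int = 0,
    with_sequences: bool = True,
    fastq_path: str | Path | None = None,
) -> ReadSim:
    """Single-molecule long reads (gamma-distributed lengths, shape 4) with
    truth alignments reporting the TE-internal segments actually present,
    so internal deletions are visible downstream."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    n_reads = int(round(coverage * genome.mean_length / length_mean))
    ss = np.random.SeedSequence(seed)
    rng_geom, rng_err = (np.random.default_rng(s) for s in ss.spawn(2))

    weights = np.array([w for _, _, w in genome.haplotypes])
    weights = weights / weights.sum()
    hap_idx = rng_geom.choice(len(genome.haplotypes), size=n_reads, p=weights)
    lens = np.maximum(rng_geom.gamma(4.0, length_mean / 4.0, n_reads).astype(int), 200)
    u = rng_geom.random(n_reads)
    starts_cache = [np.array([p.h_start for p in pieces]) for _, pieces, _ in genome.haplotypes]

    reads = []
    truth: list[AlignmentRecord] = []
    for k in range(n_reads):
        seq, pieces, _ = genome.haplotypes[hap_idx[k]]
        starts = starts_cache[hap_idx[k]]
        L = min(int(lens[k]), len(seq))
        s = int(u[k] * (len(seq) - L + 1))
        rid = f"{genome.line_id}_lr{k}"
        truth.extend(_map_interval(pieces, starts, s, s + L, rid, 0, "+", mapq=60))
        if with_sequences:
            reads.append((rid, _apply_errors(seq[s : s + L], error_rate, rng_err)))
    sim = ReadSim(reads=reads, truth=truth)
    if fastq_path is not None:
        _write_fastq(reads, Path(fastq_path))
    return sim


def _write_fastq_pairs(reads, prefix: Path) -> None:
    with open(f"{prefix}_1.fastq", "w") as f1, open(f"{prefix}_2.fastq", "w") as f2:
        for rid, r1, r2 in reads:
            f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def _write_fastq(reads, path: Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_genome_fasta(genome: LineGenome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for i, (seq, _, _) in enumerate(genome.haplotypes):
            fh.write(f">{genome.line_id}_hap{i}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


# ---------------------------------------------------------------------------
# phenotypes

#: model variables available to coefficient terms; ``temp_act`` is the
#: activated-temperature scale (0 below 25 C, 1 at 29 C) capturing that
#: dysgenesis manifests only above 25 C
VARIABLES = ("1", "mother_M", "pe_cn", "hobo_cn", "temp", "temp_act", "age")


@dataclass(frozen=True)
class DesignCell:
    """One cell of a cross design: a cross at one temperature."""

    mother_genotype: str
    father_line: str
    father_pe_cn: float
    father_hobo_cn: float
    temperature: float
    n_females: int
    ages: tuple[float, ...] = (4.0,)


class CoefficientError(KeyError):
    """A coefficient term references an unknown model variable."""


def _term_value(term: tuple, values: dict) -> float:
    prod = 1.0
    for v in term:
        if v not in values:
            raise CoefficientError(f"unknown model variable {v!r} (have {sorted(values)})")
        prod *= values[v]
    return prod


def _linpred(coeffs: dict, values: dict) -> float:
    return sum(c * _term_value(term, values) for term, c in coeffs.items())


def simulate_phenotypes(
    design: Sequence[DesignCell],
    coefficients: dict,
    seed: int = 0,
) -> list[PhenotypeRecord]:
    """Draw per-female ovary counts and ovariole counts under the pipeline's
    phenotype models.

    ``coefficients`` must have keys ``ovary0`` and ``ovary1`` (logits of the
    0- and 1-ovary categories against the 2-ovary reference) and
    ``ovarioles`` (log mean ovarioles per functional ovary); each maps term
    tuples over :data:`VARIABLES` to coefficients. Ovary category is drawn
    from the multinomial logit, per-ovary ovariole counts are Poisson.
    """
    for key in ("ovary0", "ovary1", "ovarioles"):
        if key not in coefficients:
            raise CoefficientError(f"missing coefficient block {key!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    records: list[PhenotypeRecord] = []
    fid = 0
    for cell in design:
        for k in range(cell.n_females):
            age = cell.ages[k % len(cell.ages)]
            values = {
                "1": 1.0,
                "mother_M": 1.0 if cell.mother_genotype == "M" else 0.0,
                "pe_cn": cell.father_pe_cn,
                "hobo_cn": cell.father_hobo_cn,
                "temp": cell.temperature,
                "temp_act": max(0.0, (cell.temperature - 25.0) / 4.0),
                "age": age,
            }
            l0 = _linpred(coefficients["ovary0"], values)
            l1 = _linpred(coefficients["ovary1"], values)
            logits = np.array([l0, l1, 0.0])
            logits -= logits.max()
            probs = np.exp(logits)
            probs /= probs.sum()
            ovary_count = int(rng.choice(3, p=probs))
            mu = math.exp(_linpred(coefficients["ovarioles"], values))
            ovarioles = tuple(int(v) for v in rng.poisson(mu, ovary_count))
            records.append(
                PhenotypeRecord(
                    female_id=f"f{fid}",
                    mother_genotype=cell.mother_genotype,
                    father_line=cell.father_line,
                    temperature=cell.temperature,
                    age=age,
                    ovary_count=ovary_count,
                    ovarioles=ovarioles,
                    father_pe_cn=cell.father_pe_cn,
                    father_hobo_cn=cell.father_hobo_cn,
                )
            )
            fid += 1
    return records
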