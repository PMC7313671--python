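"""TE copy number from depth ratios, cytotype classification, and per-base
coverage profiling along the element.

Copy number is mean read depth over the element consensus divided by mean
read depth over the host genome; a line with fewer than 0.5 copies (less
than a single heterozygous copy) is classified M (element-free cytotype),
0.5 or more is P.

Internally-deleted copies depress coverage over the deleted interior, so the
per-exon depth summary (terminal exons 0 and 3 vs internal exons 1 and 2)
exposes the abundance of truncated copies; spanning long reads classify each
copy's retained-exon structure directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats import AlignmentRecord, TEAnnotation

__all__ = [
    "CoverageProfile",
    "CopyNumberEstimate",
    "DepthFilters",
    "M_THRESHOLD",
    "mean_depth",
    "estimate_copy_number",
    "classify_infection",
    "coverage_profile",
    "exon_summary",
    "ExonSummary",
    "classify_copy_structure",
]

#: lines with fewer than this many estimated copies are element-negative (M)
M_THRESHOLD = 0.5

#: fraction of an exon's bases that must be covered by a spanning read's
#: element-aligned segments for the exon to count as retained
EXON_RETENTION = 0.8


class UndefinedEstimateError(ZeroDivisionError):
    """Genome depth is zero; the copy-number ratio is undefined."""


@dataclass(frozen=True)
class DepthFilters:
    """Alignment filters applied before depth accumulation.

    Secondary/supplementary records and records below ``min_mapq`` are
    excluded from depth by default (they are retained elsewhere for
    split-read evidence, which legitimately maps poorly).
    """

    min_mapq: int = 20
    include_secondary: bool = False
    include_supplementary: bool = False

    def keep(self, rec: AlignmentRecord) -> bool:
        if rec.mapq < self.min_mapq:
            return False
        if rec.secondary and not self.include_secondary:
            return False
        if rec.supplementary and not self.include_supplementary:
            return False
        return True


@dataclass(frozen=True)
class CoverageProfile:
    target_id: str
    depth: np.ndarray  # per-base read counts, length = target length

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0


@dataclass(frozen=True)
class CopyNumberEstimate:
    line_id: str
    te_name: str
    te_mean_depth: float
    genome_mean_depth: float

    @property
    def copy_number(self) -> float:
        return estimate_copy_number(self.te_mean_depth, self.genome_mean_depth)

    @property
    def status(self) -> str:
        return classify_infection(self.copy_number)

    def as_row(self) -> dict:
        return {
            "line_id": self.line_id,
            "te_name": self.te_name,
            "te_depth": round(self.te_mean_depth, 2),
            "genome_depth": round(self.genome_mean_depth, 2),
            "copy_number": round(self.copy_number, 2),
            "status": self.status,
        }


def _accumulate(
    alignments: Iterable[AlignmentRecord],
    target_length: int,
    filters: DepthFilters | None,
    clip_warn: list | None = None,
) -> np.ndarray:
    """Per-base depth via a difference array over [0, target_length)."""
    diff = np.zeros(target_length + 1, dtype=np.int64)
    for rec in alignments:
        if filters is not None and not filters.keep(rec):
            continue
        a, b = rec.target_start, rec.target_end
        if a < 0 or b > target_length:
            if clip_warn is not None:
                clip_warn.append(rec)
            a, b = max(a, 0), min(b, target_length)
            if a >= b:
                continue
        diff[a] += 1
        diff[b] -= 1
    return np.cumsum(diff[:-1])


def mean_depth(
    alignments: Iterable[AlignmentRecord],
    target_length: int,
    filters: DepthFilters | None = None,
) -> float:
    """Mean per-base depth over the full target, zero-depth positions
    included in the denominator."""
    if target_length <= 0:
        raise ValueError("target_length must be > 0")
    if filters is None:
        filters = DepthFilters()
    depth = _accumulate(alignments, target_length, filters)
    return float(depth.sum() / target_length)


def estimate_copy_number(te_depth: float, genome_depth: float) -> float:
    """Copies per genome = mean element depth / mean genome depth."""
    if genome_depth <= 0:
        raise UndefinedEstimateError(
            "genome mean depth is zero; copy number is undefined"
        )
    return te_depth / genome_depth


def classify_infection(copy_number: float, threshold: float = M_THRESHOLD) -> str:
    """M below the threshold (strictly fewer than 0.5 copies), P at or above."""
    if copy_number < 0:
        raise ValueError("copy_number must be >= 0")
    return "M" if copy_number < threshold else "P"


def coverage_profile(
    alignments: Iterable[AlignmentRecord],
    annotation: TEAnnotation,
    filters: DepthFilters | None = None,
) -> CoverageProfile:
    """Per-base read counts along the element consensus (half-open
    accumulation); out-of-bounds blocks are clipped with a warning."""
    import logging

    if filters is None:
        filters = DepthFilters()
    clipped: list = []
    depth = _accumulate(alignments, annotation.length, filters, clip_warn=clipped)
    if clipped:
        logging.getLogger(__name__).warning(
            "%d alignments exceeded consensus bounds and were clipped", len(clipped)
        )
    return CoverageProfile(target_id=annotation.name, depth=depth)


@dataclass(frozen=True)
class ExonSummary:
    exon_means: tuple[float, ...]
    terminal_internal_fold: float  # mean depth exons {0,3} / exons {1,2}
    fold_defined: bool


def exon_summary(profile: CoverageProfile, annotation: TEAnnotation) -> ExonSummary:
    """Per-exon mean depth and the terminal/internal fold ratio.

    The fold compares the terminal exons (0 and 3, retained by the common
    truncated form) to the internal ones (1 and 2); a flat profile gives 1,
    truncated copies three times as numerous as complete copies give ~4.
    """
    if not annotation.exons:
        raise ValueError("annotation has no exons")
    means = tuple(float(profile.depth[a:b].mean()) for a, b in annotation.exons)
    terminal = [means[i] for i in (0, annotation.n_exons - 1)]
    internal = [means[i] for i in range(1, annotation.n_exons - 1)]
    t, i = float(np.mean(terminal)), float(np.mean(internal)) if internal else 0.0
    if i > 0:
        return ExonSummary(means, t / i, True)
    return ExonSummary(means, float("inf") if t > 0 else float("nan"), False)


def classify_copy_structure(
    read_te_alignments: Sequence[AlignmentRecord],
    annotation: TEAnnotation,
    retention: float = EXON_RETENTION,
):
    """Classify one spanning read's copy as complete or a retained-exon set.

    ``read_te_alignments`` are the element-targeted blocks of a single long
    read that fully spans the insertion. An exon is retained when at least
    ``retention`` of its bases are covered by those blocks; the copy is
    complete iff every exon is retained.
    """
    cov = np.zeros(annotation.length, dtype=bool)
    for rec in read_te_alignments:
        cov[max(rec.target_start, 0) : min(rec.target_end, annotation.length)] = True
    retained = frozenset(
        i
        for i, (a, b) in enumerate(annotation.exons)
        if cov[a:b].mean() >= retention
    )
    if len(retained) == annotation.n_exons:
        return "complete"
    return retained
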