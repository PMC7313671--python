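"""TE insertion-site calling and cross-line sharing statistics.

Short-read calls come from split reads: a read clipped on the host genome
whose clipped portion aligns to a terminal window of the element marks a
breakpoint; breakpoints are grouped per contig and groups with enough
support emit a site. Long-read calls require a single read with genomic
anchors on both sides of its element-aligned segments, which also yields the
copy's retained-exon structure.

Sites from many lines are merged by single-linkage clustering within a
window, giving the shared-vs-unique site table, and the closed-form
haplotype-sites-per-copy statistic summarizes how private insertions are
within a sequenced pool.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .formats import AlignmentRecord, TEAnnotation
from .tequant import classify_copy_structure

logger = logging.getLogger(__name__)

__all__ = [
    "InsertionSite",
    "SharedSiteTable",
    "LongReadDiagnostics",
    "call_insertions_short",
    "call_insertions_long",
    "cluster_sites_across_lines",
    "haplotype_sites_per_copy",
]


@dataclass(frozen=True)
class InsertionSite:
    """One TE insertion breakpoint in one line."""

    line_id: str
    contig: str
    position: int  # 0-based breakpoint
    precision: str  # "exact" or "approximate"
    support: int  # supporting read (pairs) or long reads
    te_orientation: str = "unknown"  # "+", "-" or "unknown"


@dataclass
class SiteCluster:
    cluster_id: int
    members: tuple[InsertionSite, ...]  # at most one per line

    @property
    def n_lines(self) -> int:
        return len({s.line_id for s in self.members})

    @property
    def position(self) -> float:
        return float(np.median([s.position for s in self.members]))


@dataclass
class SharedSiteTable:
    clusters: list[SiteCluster]

    @property
    def n_unique(self) -> int:
        return sum(1 for c in self.clusters if c.n_lines == 1)

    @property
    def n_shared(self) -> int:
        return sum(1 for c in self.clusters if c.n_lines > 1)

    def histogram(self) -> dict[int, int]:
        """Count of clusters by the number of lines sharing them."""
        out: dict[int, int] = defaultdict(int)
        for c in self.clusters:
            out[c.n_lines] += 1
        return dict(sorted(out.items()))

    @property
    def total_member_sites(self) -> int:
        return sum(len(c.members) for c in self.clusters)


def _terminal_hit(
    rec: AlignmentRecord, te_length: int, tir_window: int
) -> str | None:
    """Which element end a TE-side alignment touches, if any."""
    if rec.target_start < tir_window:
        return "head"
    if rec.target_end > te_length - tir_window:
        return "tail"
    return None


def call_insertions_short(
    alignments: Iterable[AlignmentRecord],
    te_name: str,
    te_length: int,
    min_clip: int = 20,
    min_support: int = 3,
    group_window: int = 10,
    tir_window: int = 200,
    min_mapq_te: int = 1,
    line_id: str = "",
) -> list[InsertionSite]:
    """Call insertion sites for one line from split short reads.

    A genome-targeted record clipped by at least ``min_clip`` whose read also
    aligns to a terminal (``tir_window``-proximal) portion of the element
    contributes one breakpoint: at ``target_start`` when the head is clipped
    (element on the reference-left) or ``target_end`` when the tail is.
    Breakpoints within ``group_window`` on one contig are single-linkage
    grouped; groups with ``min_support`` or more reads emit a site. Precision
    is exact when the modal breakpoint carries a strict majority of support,
    else approximate; the reported position is the mode (exact) or the
    support-weighted median (approximate).
    """
    te_records: dict[tuple[str, int], list[AlignmentRecord]] = defaultdict(list)
    genome_records: list[AlignmentRecord] = []
    for rec in alignments:
        if rec.target_id == te_name:
            if rec.mapq >= min_mapq_te:
                te_records[(rec.read_id, rec.mate)].append(rec)
        else:
            genome_records.append(rec)
        if not line_id and "_r" in rec.read_id:
            line_id = rec.read_id.rsplit("_r", 1)[0]

    if not te_records:
        logger.warning("no element-targeted alignments: likely an M line")
        return []

    # breakpoint evidence: (contig, position, te_strand)
    evidence: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for rec in genome_records:
        mates = te_records.get((rec.read_id, rec.mate))
        if not mates:
            continue
        terminal = [m for m in mates if _terminal_hit(m, te_length, tir_window)]
        if not terminal:
            continue
        strand = terminal[0].strand
        if rec.clip_head >= min_clip:
            evidence[rec.target_id].append((rec.target_start, strand))
        elif rec.clip_tail >= min_clip:
            evidence[rec.target_id].append((rec.target_end, strand))

    sites: list[InsertionSite] = []
    for contig, points in evidence.items():
        points.sort()
        group: list[tuple[int, str]] = []
        for pt in points + [(None, "")]:
            if group and (pt[0] is None or pt[0] - group[-1][0] > group_window):
                site = _emit_site(line_id, contig, group, min_support)
                if site is not None:
                    sites.append(site)
                group = []
            if pt[0] is not None:
                group.append(pt)
    sites.sort(key=lambda s: (s.contig, s.position))
    return sites


def _emit_site(
    line_id: str, contig: str, group: list[tuple[int, str]], min_support: int
) -> InsertionSite | None:
    support = len(group)
    if support < min_support:
        return None
    positions = np.array([p for p, _ in group])
    strands = {s for _, s in group}
    vals, counts = np.unique(positions, return_counts=True)
    modal_idx = int(counts.argmax())
    if counts[modal_idx] * 2 > support:
        precision, position = "exact", int(vals[modal_idx])
    else:
        precision, position = "approximate", int(np.median(positions))
    return InsertionSite(
        line_id=line_id,
        contig=contig,
        position=position,
        precision=precision,
        support=support,
        te_orientation=strands.pop() if len(strands) == 1 else "unknown",
    )


@dataclass
class LongReadDiagnostics:
    n_spanning: int = 0
    n_one_sided: int = 0  # anchor on only one side: excluded


def call_insertions_long(
    alignments: Iterable[AlignmentRecord],
    annotation: TEAnnotation,
    anchor_min: int = 200,
    line_id: str = "",
) -> tuple[list[tuple[InsertionSite, object]], LongReadDiagnostics]:
    """Call sites from long reads that fully span an insertion.

    A site is emitted only when one read carries genomic anchors of at least
    ``anchor_min`` aligned bases on both sides (in read coordinates) of its
    element-aligned segments; the copy structure comes from
    :func:`classify_copy_structure` on those segments. One-sided reads are
    excluded and tallied.
    """
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in alignments:
        by_read[rec.read_id].append(rec)

    calls: list[tuple[InsertionSite, object]] = []
    diag = LongReadDiagnostics()
    for read_id, recs in by_read.items():
        ordered = sorted(recs, key=lambda r: r.read_start)
        if not any(r.target_id == annotation.name for r in ordered):
            continue
        # segment the read into alternating genome / element runs so one
        # read spanning several insertions yields one call per element run
        runs: list[tuple[bool, list[AlignmentRecord]]] = []
        for r in ordered:
            is_te = r.target_id == annotation.name
            if runs and runs[-1][0] == is_te:
                runs[-1][1].append(r)
            else:
                runs.append((is_te, [r]))
        for i, (is_te, blocks) in enumerate(runs):
            if not is_te:
                continue
            left = runs[i - 1][1] if i > 0 and not runs[i - 1][0] else []
            right = runs[i + 1][1] if i + 1 < len(runs) and not runs[i + 1][0] else []
            left_anchor = sum(r.read_end - r.read_start for r in left)
            right_anchor = sum(r.read_end - r.read_start for r in right)
            if left_anchor >= anchor_min and right_anchor >= anchor_min:
                diag.n_spanning += 1
                anchor = max(left, key=lambda r: r.read_end)
                structure = classify_copy_structure(blocks, annotation)
                calls.append(
                    (
                        InsertionSite(
                            line_id=line_id or read_id.rsplit("_lr", 1)[0],
                            contig=anchor.target_id,
                            position=anchor.target_end,
                            precision="exact",
                            support=1,
                            te_orientation=blocks[0].strand,
                        ),
                        structure,
                    )
                )
            else:
                diag.n_one_sided += 1
    calls.sort(key=lambda cs: (cs[0].contig, cs[0].position))
    return calls, diag


def merge_long_read_calls(
    calls: Sequence[tuple[InsertionSite, object]], window: int = 50
) -> list[tuple[InsertionSite, object]]:
    """Collapse per-read long-read calls at one locus into per-site calls,
    keeping the majority copy structure and summing support."""
    merged: list[tuple[InsertionSite, object]] = []
    group: list[tuple[InsertionSite, object]] = []

    def _flush() -> None:
        if not group:
            return
        sites = [s for s, _ in group]
        structures = [st for _, st in group]
        pos = int(np.median([s.position for s in sites]))
        best = max(set(structures), key=structures.count)
        merged.append(
            (
                InsertionSite(
                    line_id=sites[0].line_id,
                    contig=sites[0].contig,
                    position=pos,
                    precision="exact" if len({s.position for s in sites}) == 1 else "approximate",
                    support=len(sites),
                    te_orientation=sites[0].te_orientation,
                ),
                best,
            )
        )

    prev: InsertionSite | None = None
    for site, structure in sorted(calls, key=lambda cs: (cs[0].contig, cs[0].position)):
        if prev is not None and (
            site.contig != prev.contig or site.position - prev.position > window
        ):
            _flush()
            group = []
        group.append((site, structure))
        prev = site
    _flush()
    return merged


def cluster_sites_across_lines(
    sites_per_line: dict[str, Sequence[InsertionSite]],
    window: int = 50,
) -> SharedSiteTable:
    """Single-linkage clustering of sites across lines.

    Sites on one contig within ``window`` of each other chain into one
    cluster; a cluster keeps at most one site per line (the one nearest the
    cluster median; the rest split into their own clusters).
    """
    all_sites = [s for sites in sites_per_line.values() for s in sites]
    all_sites.sort(key=lambda s: (s.contig, s.position))
    raw: list[list[InsertionSite]] = []
    for s in all_sites:
        if raw and raw[-1][-1].contig == s.contig and s.position - raw[-1][-1].position <= window:
            raw[-1].append(s)
        else:
            raw.append([s])

    clusters: list[SiteCluster] = []
    cid = 0
    for members in raw:
        med = float(np.median([s.position for s in members]))
        keep: dict[str, InsertionSite] = {}
        spill: list[InsertionSite] = []
        for s in members:
            cur = keep.get(s.line_id)
            if cur is None:
                keep[s.line_id] = s
            elif abs(s.position - med) < abs(cur.position - med):
                spill.append(cur)
                keep[s.line_id] = s
            else:
                spill.append(s)
        clusters.append(SiteCluster(cid, tuple(keep.values())))
        cid += 1
        for s in spill:  # duplicates within a line become singleton clusters
            clusters.append(SiteCluster(cid, (s,)))
            cid += 1
    return SharedSiteTable(clusters)


def haplotype_sites_per_copy(
    n_sites: int,
    n_lines: int,
    haplotypes_per_line: int,
    mean_copy_number: float,
) -> float:
    """Average insertion-site frequency per sequenced haplotype per copy.

    sites / (lines * haplotypes per line * mean copies). A value near 1
    means almost every site is carried by a single haplotype within each
    sequenced pool. Reported truncated to 3 decimals.
    """
    denom = n_lines * haplotypes_per_line * mean_copy_number
    if n_sites <= 0 or denom <= 0:
        raise ValueError("all inputs must be > 0")
    return math.floor(n_sites / denom * 1000) / 1000
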