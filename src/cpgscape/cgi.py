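"""CpG-island calling, functional classification, shores and signed distances.

Islands are called with the Gardiner-Garden criteria: GC fraction >= 0.5,
length > 200 bp, and observed/expected CpG ratio > 0.6 where the expected
count in a segment of length L with c cytosines and g guanines is c*g/L.
Qualifying sliding windows are merged and the merged segment is re-scored;
only merged segments that themselves satisfy all three criteria survive
(the ``recheck=False`` mode keeps the raw merged unions for comparison).

Functional classes follow the five-type scheme plus MISC:

* ``TSS_CODING`` / ``TSS_NONCODING`` — island intersects the +/-100 bp
  window around a gene's strand-aware TSS;
* ``INTRAGENIC_CODING`` / ``INTRAGENIC_NONCODING`` — island intersects the
  transcript body but no TSS window;
* ``INTERGENIC`` — island intersects no gene;
* ``MISC`` — island collects more than one distinct candidate label from
  different genes (a TSS hit outranks a body hit from the *same* gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genes import GeneModel
from .genome import GenomeSequence

log = logging.getLogger(__name__)

__all__ = [
    "CpGIsland",
    "Shore",
    "CGI_CLASSES",
    "call_cgis",
    "load_cgis_bed",
    "write_cgis_bed",
    "classify_cgis",
    "derive_shores",
    "signed_distances",
    "gardiner_garden_stats",
]

CGI_CLASSES = (
    "TSS_CODING",
    "TSS_NONCODING",
    "INTRAGENIC_CODING",
    "INTRAGENIC_NONCODING",
    "INTERGENIC",
    "MISC",
)


@dataclass
class CpGIsland:
    chrom: str
    start: int
    end: int
    gc_fraction: float = float("nan")
    obs_exp_ratio: float = float("nan")
    cgi_class: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Shore:
    """Up-to-2-kb flank of an island, clipped at chromosome ends and neighbours."""

    parent: CpGIsland
    side: str  # "left" | "right"
    start: int
    end: int


def gardiner_garden_stats(seq: str) -> tuple[float, float]:
    """(GC fraction, observed/expected CpG ratio) of a sequence segment."""
    L = len(seq)
    c = seq.count("C")
    g = seq.count("G")
    cpg = seq.count("CG")
    gc = (c + g) / L if L else 0.0
    oe = (cpg * L) / (c * g) if c and g else 0.0
    return gc, oe


def _passes(seq: str, min_gc: float = 0.5, min_oe: float = 0.6) -> bool:
    gc, oe = gardiner_garden_stats(seq)
    return gc >= min_gc and oe > min_oe


def call_cgis(
    genome: GenomeSequence,
    window: int = 200,
    step: int = 1,
    min_length: int = 200,
    recheck: bool = True,
    chroms: list[str] | None = None,
) -> list[CpGIsland]:
    """Call islands by sliding-window screening and merge-and-recheck.

    Windows of ``window`` bp slid by ``step`` that pass GC >= 0.5 and
    obs/exp > 0.6 are unioned; each union is re-scored as a whole and kept
    only if it passes both composition criteria and is longer than
    ``min_length`` bp (strictly).
    """
    islands: list[CpGIsland] = []
    for chrom in chroms if chroms is not None else genome.chrom_names:
        L = genome.length(chrom)
        if window > L:
            log.warning("chromosome %s shorter than window (%d bp); skipped", chrom, window)
            continue
        seq = genome.chrom_seq(chrom)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = (arr == ord("C")).astype(np.int64)
        is_g = (arr == ord("G")).astype(np.int64)
        is_cpg = np.zeros(len(arr), dtype=np.int64)
        is_cpg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        cum_c = np.concatenate([[0], np.cumsum(is_c)])
        cum_g = np.concatenate([[0], np.cumsum(is_g)])
        cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])

        starts = np.arange(0, L - window + 1, step, dtype=np.int64)
        ends = starts + window
        c = cum_c[ends] - cum_c[starts]
        g = cum_g[ends] - cum_g[starts]
        # CpG anchors fully inside the window: anchor in [start, end-2]
        cpg = cum_cpg[ends - 1] - cum_cpg[starts]
        gc_ok = (c + g) >= np.ceil(0.5 * window)
        oe_ok = cpg * window > 0.6 * c * g
        ok = gc_ok & oe_ok
        if not ok.any():
            continue

        # merge overlapping/adjacent qualifying windows
        ok_starts = starts[ok]
        ok_ends = ends[ok]
        merged: list[list[int]] = []
        for s, e in zip(ok_starts, ok_ends):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], int(e))
            else:
                merged.append([int(s), int(e)])

        for s, e in merged:
            seg = seq[s:e]
            gc, oe = gardiner_garden_stats(seg)
            if recheck and not (
                gc >= 0.5 and oe > 0.6 and (e - s) > min_length
            ):
                continue
            islands.append(CpGIsland(chrom, s, e, gc, oe))
    return islands


def load_cgis_bed(path: str, genome: GenomeSequence | None = None) -> list[CpGIsland]:
    """Read islands from a BED3+ file; sort and merge overlapping records.

    Gardiner-Garden invariants are *not* enforced on ingested records.
    Records on chromosomes absent from ``genome`` (when given) are dropped
    with a warning.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            if genome is not None and chrom not in genome:
                log.warning("%s:%d: chromosome %s not in genome; record dropped", path, lineno, chrom)
                continue
            raw.setdefault(chrom, []).append((start, end))

    islands: list[CpGIsland] = []
    for chrom in raw:
        merged: list[list[int]] = []
        for s, e in sorted(raw[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            isl = CpGIsland(chrom, s, e)
            if genome is not None:
                isl.gc_fraction, isl.obs_exp_ratio = gardiner_garden_stats(
                    genome.fetch(chrom, s, e)
                )
            islands.append(isl)
    islands.sort(key=lambda i: (i.chrom, i.start))
    return islands


def write_cgis_bed(islands: list[CpGIsland], path: str) -> None:
    """BED4 output; the name column carries the functional class (or '.')."""
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\t{isl.cgi_class or '.'}\n")


def _intersects(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def classify_cgis(
    cgis: list[CpGIsland],
    genes: list[GeneModel],
    tss_window: int = 100,
) -> list[CpGIsland]:
    """Assign a functional class to every island (in place; also returned).

    Per gene a single candidate label is produced (TSS hit outranks body hit
    for the same gene); islands accumulating >1 distinct label across genes
    become MISC, islands touching no gene become INTERGENIC.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    for isl in cgis:
        labels: set[str] = set()
        for g in by_chrom.get(isl.chrom, []):
            tss = g.tss
            # closed +/- tss_window bp around the TSS, as half-open interval
            if _intersects(isl.start, isl.end, tss - tss_window, tss + tss_window + 1):
                labels.add("TSS_CODING" if g.is_coding else "TSS_NONCODING")
            elif _intersects(isl.start, isl.end, g.tx_start, g.tx_end):
                labels.add("INTRAGENIC_CODING" if g.is_coding else "INTRAGENIC_NONCODING")
        if not labels:
            isl.cgi_class = "INTERGENIC"
        elif len(labels) == 1:
            isl.cgi_class = labels.pop()
        else:
            isl.cgi_class = "MISC"
    return cgis


def derive_shores(
    cgis: list[CpGIsland],
    chrom_lengths: dict[str, int],
    width: int = 2000,
) -> list[Shore]:
    """The up-to-``width``-bp flanks of each island.

    Shores are clipped at chromosome ends and at neighbouring islands so no
    base is simultaneously shore and island.
    """
    shores: list[Shore] = []
    by_chrom: dict[str, list[CpGIsland]] = {}
    for isl in sorted(cgis, key=lambda i: (i.chrom, i.start)):
        by_chrom.setdefault(isl.chrom, []).append(isl)
    for chrom, isls in by_chrom.items():
        L = chrom_lengths[chrom]
        for i, isl in enumerate(isls):
            lo = max(0, isl.start - width)
            if i > 0:
                lo = max(lo, isls[i - 1].end)
            if lo < isl.start:
                shores.append(Shore(isl, "left", lo, isl.start))
            hi = min(L, isl.end + width)
            if i + 1 < len(isls):
                hi = min(hi, isls[i + 1].start)
            if isl.end < hi:
                shores.append(Shore(isl, "right", isl.end, hi))
    return shores


def signed_distances(
    positions: np.ndarray,
    cgis: list[CpGIsland],
) -> tuple[np.ndarray, np.ndarray]:
    """Signed distance of each position to the nearest island border.

    Islands must all be on the position's chromosome, sorted and
    non-overlapping.  Convention: a site inside an island gets distance NaN
    (use the index array to see which island); otherwise the distance is
    ``pos - start`` (negative) for a site left of its nearest island and
    ``pos - end`` (non-negative) for a site right of it; equidistant ties go
    to the lower-coordinate island.

    Returns ``(distance, island_index)`` where ``island_index`` is the index
    into ``cgis`` of the nearest (or containing) island, and -1 where no
    island exists.
    """
    positions = np.asarray(positions, dtype=np.int64)
    n = len(positions)
    dist = np.full(n, np.nan)
    idx = np.full(n, -1, dtype=np.int64)
    if not cgis:
        return dist, idx
    starts = np.array([i.start for i in cgis], dtype=np.int64)
    ends = np.array([i.end for i in cgis], dtype=np.int64)

    prev = np.searchsorted(starts, positions, side="right") - 1  # island at or before pos
    inside = (prev >= 0) & (positions < ends[np.clip(prev, 0, None)])
    idx[inside] = prev[inside]

    out = ~inside
    # candidate distances to previous island's right border and next island's left border
    d_right = np.where(prev >= 0, positions - ends[np.clip(prev, 0, None)], np.iinfo(np.int64).max)
    nxt = prev + 1
    has_next = nxt < len(starts)
    d_left = np.where(has_next, positions - starts[np.clip(nxt, None, len(starts) - 1)], np.iinfo(np.int64).min)
    abs_right = np.where(prev >= 0, np.abs(d_right), np.iinfo(np.int64).max)
    abs_left = np.where(has_next, np.abs(d_left), np.iinfo(np.int64).max)
    # tie -> lower-coordinate island, i.e. the previous one (positive distance)
    use_right = abs_right <= abs_left
    sel = out & use_right
    dist[sel] = d_right[sel]
    idx[sel] = prev[sel]
    sel = out & ~use_right
    dist[sel] = d_left[sel]
    idx[sel] = nxt[sel]
    return dist, idx
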