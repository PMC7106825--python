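"""Consequence-primed coding CpG sites and their observed C:G>T:A spectrum.

Every CDS base that is the C or the G of a plus-strand CpG dinucleotide is a
*primed site*: deamination would substitute it (C>T on the C, G>A on the G),
and the genetic-code context determines whether the resulting codon change
is silent, missense or nonsense — before any variant is observed.  Crossing
primed sites with an exome-scale catalogue then measures, per consequence
class, what fraction of the primable changes the population actually
carries, and how their allele counts distribute.  Depletion of observed
nonsense-primed changes relative to silent ones is the footprint of negative
selection.

Conventions: a change preserving a stop codon is SILENT; stop-loss is
counted as MISSENSE (and flagged).  A site covered by several transcripts
receives each transcript's consequence in the long table; headline tables
resolve conflicts by severity (NONSENSE > MISSENSE > SILENT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cgi import CpGIsland
from .genes import FrameError, GeneModel, cds_intervals, spliced_cds
from .genome import GenomeSequence

log = logging.getLogger(__name__)

__all__ = [
    "GENETIC_CODE",
    "translate_codon",
    "classify_codon_change",
    "enumerate_primed_sites",
    "cross_with_observed",
    "ac_spectrum",
    "AC_BIN_EDGES",
    "ac_bin_label",
    "SEVERITY",
]

# standard genetic code (NCBI table 1), '*' = stop
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
GENETIC_CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

SEVERITY = {"SILENT": 0, "MISSENSE": 1, "NONSENSE": 2}

#: default allele-count bins: singleton, AC=2, 3-5, >5
AC_BIN_EDGES = ((1, 1), (2, 2), (3, 5), (6, None))


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon.upper()]


def classify_codon_change(codon_before: str, codon_after: str) -> tuple[str, bool]:
    """(consequence, is_stop_loss) for a single-base codon change."""
    aa0 = translate_codon(codon_before)
    aa1 = translate_codon(codon_after)
    if aa0 == aa1:
        return "SILENT", False
    if aa1 == "*":
        return "NONSENSE", False
    if aa0 == "*":
        return "MISSENSE", True  # stop-loss, pooled with missense but flagged
    return "MISSENSE", False


def _region_class(cgi_class: str | None, in_cgi: bool) -> str:
    if not in_cgi:
        return "NON_CGI"
    if cgi_class in ("TSS_CODING", "TSS_NONCODING"):
        return "TSS_CGI"
    if cgi_class in ("INTRAGENIC_CODING", "INTRAGENIC_NONCODING"):
        return "INTRAGENIC_CGI"
    return "OTHER_CGI"


def enumerate_primed_sites(
    genome: GenomeSequence,
    genes: list[GeneModel],
    cgis: list[CpGIsland] | None = None,
    site_beta: pd.DataFrame | None = None,
    beta_min: float | None = 0.67,
    collapse: bool = True,
) -> pd.DataFrame:
    """All CDS CpG bases with the consequence their deamination would cause.

    For each coding gene the spliced CDS is built once; every CDS position
    that is the C of a plus-strand CpG (substitution C>T) or its G
    (substitution G>A) is projected into transcript orientation, the codon
    mutated and both codons translated.  With ``beta_min`` set, only sites
    whose per-CpG beta (from ``site_beta``: chrom,pos,beta of the dinucleotide
    anchor) meets the threshold are retained — the hyper-methylated subset
    where deamination is actually primed.

    Returns one row per (site x transcript), or per site after severity-max
    collapsing when ``collapse`` is true, with columns ``chrom, pos, ref,
    alt, gene, strand, region_class, codon_before, codon_after, offset,
    consequence, stop_loss, beta, cpg_pos``.
    """
    beta_lookup: dict[tuple[str, int], float] = {}
    if site_beta is not None:
        beta_lookup = {
            (c, int(p)): float(b)
            for c, p, b in zip(site_beta["chrom"], site_beta["pos"], site_beta["beta"])
        }

    cgi_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
    if cgis:
        tmp: dict[str, list[CpGIsland]] = {}
        for isl in cgis:
            tmp.setdefault(isl.chrom, []).append(isl)
        for c, lst in tmp.items():
            lst.sort(key=lambda i: i.start)
            cgi_by_chrom[c] = (
                np.array([i.start for i in lst]),
                np.array([i.end for i in lst]),
                lst,
            )

    def island_of(chrom: str, pos: int) -> CpGIsland | None:
        entry = cgi_by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, lst = entry
        j = np.searchsorted(starts, pos, side="right") - 1
        if j >= 0 and pos < ends[j]:
            return lst[j]
        return None

    rows = []
    for gene in genes:
        if not gene.is_coding:
            continue
        try:
            cds = spliced_cds(genome, gene)
            if len(cds) % 3 != 0:
                raise FrameError(f"{gene.name}: CDS length {len(cds)} not divisible by 3")
        except FrameError as exc:
            log.warning("%s; gene skipped", exc)
            continue
        seq = genome.chrom_seq(gene.chrom)
        ivs = cds_intervals(gene)
        total = len(cds)
        offset = 0
        for s, e in ivs:
            for p in range(s, e):
                base = seq[p]
                if base == "C":
                    if seq[p : p + 2] != "CG":
                        continue
                    ref, alt, cpg_pos = "C", "T", p
                elif base == "G":
                    if p < 1 or seq[p - 1 : p + 1] != "CG":
                        continue
                    ref, alt, cpg_pos = "G", "A", p - 1
                else:
                    continue
                plus_index = offset + (p - s)
                i = plus_index if gene.strand == "+" else total - 1 - plus_index
                codon_start = 3 * (i // 3)
                codon_before = cds[codon_start : codon_start + 3]
                # genomic C>T / G>A is always a transcript-strand C>T or G>A
                t_ref = cds[i]
                t_alt = {"C": "T", "G": "A"}[t_ref]
                codon_after = (
                    codon_before[: i % 3] + t_alt + codon_before[i % 3 + 1 :]
                )
                consequence, stop_loss = classify_codon_change(codon_before, codon_after)
                beta = beta_lookup.get((gene.chrom, cpg_pos), np.nan)
                if beta_min is not None and not (beta >= beta_min):
                    continue
                isl = island_of(gene.chrom, p)
                rows.append(
                    {
                        "chrom": gene.chrom,
                        "pos": p,
                        "ref": ref,
                        "alt": alt,
                        "gene": gene.name,
                        "strand": gene.strand,
                        "region_class": _region_class(
                            isl.cgi_class if isl else None, isl is not None
                        ),
                        "codon_before": codon_before,
                        "codon_after": codon_after,
                        "offset": i % 3,
                        "consequence": consequence,
                        "stop_loss": stop_loss,
                        "beta": beta,
                        "cpg_pos": cpg_pos,
                    }
                )
            offset += e - s

    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "strand", "region_class",
            "codon_before", "codon_after", "offset", "consequence",
            "stop_loss", "beta", "cpg_pos",
        ],
    )
    if collapse and len(df):
        df["_sev"] = df["consequence"].map(SEVERITY)
        keep = df.groupby(["chrom", "pos"])["_sev"].idxmax()
        df = df.loc[keep].drop(columns="_sev").sort_values(["chrom", "pos"])
    return df.reset_index(drop=True)


def cross_with_observed(primed: pd.DataFrame, events) -> pd.DataFrame:
    """Mark primed sites observed in a variant catalogue, carrying AC.

    A primed site is observed iff an event exists at exactly its genomic
    position with the matching ref>alt substitution; events at primed
    positions with a different alt are ignored (counted).
    """
    index: dict[tuple[str, int, str, str], tuple[float, float]] = {}
    for ev in events:
        key = (ev.chrom, ev.pos, ev.ref, ev.alt)
        ac = float(ev.ac) if ev.ac is not None else np.nan
        af = float(ev.af) if ev.af is not None else np.nan
        index[key] = (ac, af)
    out = primed.copy()
    observed = np.zeros(len(out), dtype=bool)
    acs = np.full(len(out), np.nan)
    afs = np.full(len(out), np.nan)
    n_mismatch = 0
    positions = {(ev.chrom, ev.pos) for ev in events}
    for i, (chrom, pos, ref, alt) in enumerate(
        zip(out["chrom"], out["pos"], out["ref"], out["alt"])
    ):
        hit = index.get((chrom, int(pos), ref, alt))
        if hit is not None:
            observed[i] = True
            acs[i], afs[i] = hit
        elif (chrom, int(pos)) in positions:
            n_mismatch += 1
    if n_mismatch:
        log.info("%d events at primed positions with mismatching alt ignored", n_mismatch)
    out["observed"] = observed
    out["ac"] = acs
    out["af"] = afs
    return out


def ac_bin_label(ac: int, edges=AC_BIN_EDGES) -> str:
    for lo, hi in edges:
        if ac >= lo and (hi is None or ac <= hi):
            if lo == hi:
                return f"AC={lo}"
            if hi is None:
                return f"AC>{lo - 1}"
            return f"{lo}<=AC<={hi}"
    raise ValueError(f"allele count {ac} fits no bin")


def ac_spectrum(primed_observed: pd.DataFrame, edges=AC_BIN_EDGES) -> pd.DataFrame:
    """Allele-count bin proportions within each consequence class.

    Only observed sites (AC >= 1) contribute; within a consequence class the
    bin proportions sum to 1.
    """
    obs = primed_observed[primed_observed["observed"] & primed_observed["ac"].notna()]
    labels = [ac_bin_label(int(a), edges) for a in obs["ac"]]
    order = []
    for lo, hi in edges:
        order.append(
            f"AC={lo}" if lo == hi else (f"AC>{lo - 1}" if hi is None else f"{lo}<=AC<={hi}")
        )
    work = obs.assign(ac_bin=pd.Categorical(labels, categories=order))
    counts = (
        work.groupby(["consequence", "ac_bin"], observed=False)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = work.groupby("consequence", observed=False).size().rename("total").reset_index()
    out = counts.merge(totals, on="consequence")
    out["proportion"] = np.where(out["total"] > 0, out["count"] / out["total"], np.nan)
    return out
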