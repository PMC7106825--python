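"""Variant-catalogue ingestion: C:G>T:A filtering, CpG attachment, allele frequencies.

Variants are read from VCF (plain or bgzipped) at site level — genotypes are
never required.  Multiallelic records are split into allele-level events.
The allele frequency comes from the ``AF`` INFO field, falling back to
``AC/AN``; events with neither are kept with a missing frequency and
counted.

The ``Af = 0`` bin of the six-bin allele-frequency partition is the
complement: CpG sites with *no* reported variant (every reported variant has
AC >= 1, so a literal zero-frequency class would be empty).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSequence

log = logging.getLogger(__name__)

__all__ = [
    "VariantEvent",
    "AfBin",
    "DEFAULT_AF_BINS",
    "load_snvs",
    "load_ct_variants",
    "attach_to_cpg",
    "merge_catalogues",
    "rare_filter",
    "af_bin_label",
    "normalize_chrom",
]

_CT_PAIRS = {("C", "T"), ("G", "A")}


@dataclass
class VariantEvent:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    af: float | None = None
    ac: int | None = None
    an: int | None = None
    source: str = ""
    cpg_pos: int | None = None  # anchor of the linked CpG site, or None

    @property
    def is_ct(self) -> bool:
        return (self.ref, self.alt) in _CT_PAIRS


@dataclass(frozen=True)
class AfBin:
    label: str
    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool

    def contains(self, af: float) -> bool:
        if self.lower == self.upper:
            return af == self.lower
        lo_ok = af >= self.lower if self.lower_closed else af > self.lower
        hi_ok = af <= self.upper if self.upper_closed else af < self.upper
        return lo_ok and hi_ok


#: Af = 0 (unmutated complement), then (0, 0.06), [0.06, 0.12), [0.12, 0.18),
#: [0.18, 0.24), [0.24, 1].
DEFAULT_AF_BINS = (
    AfBin("Af=0", 0.0, 0.0, True, True),
    AfBin("0<Af<0.06", 0.0, 0.06, False, False),
    AfBin("0.06<=Af<0.12", 0.06, 0.12, True, False),
    AfBin("0.12<=Af<0.18", 0.12, 0.18, True, False),
    AfBin("0.18<=Af<0.24", 0.18, 0.24, True, False),
    AfBin("Af>=0.24", 0.24, 1.0, True, True),
)


def af_bin_label(af: float | None, bins: tuple[AfBin, ...] = DEFAULT_AF_BINS) -> str:
    """Bin label of an allele frequency; missing/zero maps to the Af=0 bin."""
    if af is None or (isinstance(af, float) and math.isnan(af)) or af == 0.0:
        return bins[0].label
    for b in bins[1:]:
        if b.contains(af):
            return b.label
    raise ValueError(f"allele frequency {af} outside [0, 1]")


_ALIAS_STYLES = {"chr": lambda c: c if c.startswith("chr") else f"chr{c}",
                 "plain": lambda c: c[3:] if c.startswith("chr") else c}


def normalize_chrom(chrom: str, style: str = "chr") -> str:
    """Map between 'chr1' and '1' naming styles."""
    try:
        return _ALIAS_STYLES[style](chrom)
    except KeyError:
        raise ValueError(f"unknown chromosome naming style {style!r}")


def _info_float(variant, key: str, alt_index: int) -> float | None:
    val = variant.INFO.get(key)
    if val is None:
        return None
    if isinstance(val, (tuple, list, np.ndarray)):
        val = val[alt_index] if alt_index < len(val) else None
    return float(val) if val is not None else None


def load_snvs(
    vcf_path: str,
    source: str = "",
    ct_only: bool = False,
    chrom_style: str | None = None,
) -> list[VariantEvent]:
    """Site-level SNV events from a VCF; multiallelic records are split.

    Records with a populated FILTER other than PASS are dropped (an
    all-missing FILTER column bypasses the check, as consortium consensus
    files differ in FILTER discipline).  With ``ct_only`` only C>T / G>A
    events are emitted.
    """
    from cyvcf2 import VCF

    events: list[VariantEvent] = []
    n_filtered = n_no_af = 0
    vcf = VCF(vcf_path)
    for v in vcf:
        # cyvcf2 reports FILTER None for PASS and for '.', both acceptable
        if v.FILTER is not None:
            n_filtered += 1
            continue
        ref = v.REF.upper()
        if len(ref) != 1:
            continue
        an = int(v.INFO.get("AN")) if v.INFO.get("AN") is not None else None
        for k, alt in enumerate(v.ALT):
            alt = alt.upper()
            if len(alt) != 1 or alt not in "ACGT":
                continue
            if ct_only and (ref, alt) not in _CT_PAIRS:
                continue
            af = _info_float(v, "AF", k)
            ac_val = v.INFO.get("AC")
            if isinstance(ac_val, (tuple, list, np.ndarray)):
                ac_val = ac_val[k] if k < len(ac_val) else None
            ac = int(ac_val) if ac_val is not None else None
            if af is None and ac is not None and an:
                af = ac / an
            if af is None:
                n_no_af += 1
            chrom = v.CHROM
            if chrom_style is not None:
                chrom = normalize_chrom(chrom, chrom_style)
            events.append(VariantEvent(chrom, v.POS - 1, ref, alt, af, ac, an, source))
    if n_filtered:
        log.info("%s: %d records dropped by FILTER", vcf_path, n_filtered)
    if n_no_af:
        log.info("%s: %d events without AF or AC/AN", vcf_path, n_no_af)
    return events


def load_ct_variants(vcf_path: str, source: str = "", chrom_style: str | None = None) -> list[VariantEvent]:
    """C:G>T:A single-nucleotide events only (see :func:`load_snvs`)."""
    return load_snvs(vcf_path, source=source, ct_only=True, chrom_style=chrom_style)


def attach_to_cpg(events: list[VariantEvent], genome: GenomeSequence) -> list[VariantEvent]:
    """Link C:G>T:A events to the CpG dinucleotide they hit (in place).

    A C>T event at p belongs to the site anchored at p when the genome reads
    CG at [p, p+2); a G>A event at p belongs to the site anchored at p-1 when
    the genome reads CG at [p-1, p+1).  Everything else keeps ``cpg_pos``
    None and feeds the non-CpG control pool.
    """
    seqs = {c: genome.chrom_seq(c) for c in genome.chrom_names}
    for ev in events:
        ev.cpg_pos = None
        seq = seqs.get(ev.chrom)
        if seq is None:
            continue
        if ev.ref == "C" and ev.alt == "T":
            if seq[ev.pos : ev.pos + 2] == "CG":
                ev.cpg_pos = ev.pos
        elif ev.ref == "G" and ev.alt == "A":
            if ev.pos >= 1 and seq[ev.pos - 1 : ev.pos + 1] == "CG":
                ev.cpg_pos = ev.pos - 1
    return events


def merge_catalogues(
    catalogues: list[list[VariantEvent]],
    af_policy: str = "max",
) -> pd.DataFrame:
    """Collapse CpG-attached C:G>T:A events into one site-level mutation table.

    One row per mutated CpG dinucleotide with columns ``chrom, cpg_pos, af,
    ac, sources, strand_events``.  Both strand observations of one
    dinucleotide (its C>T and its G>A) collapse to a single row;
    ``strand_events`` (1 or 2) records how many orientations were seen, for
    the strand-base counting mode.  ``af_policy`` "max" keeps the largest
    frequency across events/catalogues; "per_source" keeps per-source maxima
    in a wide table instead.
    """
    rows: dict[tuple[str, int], dict] = {}
    for cat in catalogues:
        for ev in cat:
            if ev.cpg_pos is None or not ev.is_ct:
                continue
            key = (ev.chrom, ev.cpg_pos)
            rec = rows.setdefault(
                key,
                {"af": np.nan, "ac": np.nan, "sources": set(), "per_source": {},
                 "strands": set()},
            )
            rec["sources"].add(ev.source)
            rec["strands"].add((ev.ref, ev.alt))
            if ev.af is not None and not (isinstance(ev.af, float) and math.isnan(ev.af)):
                if math.isnan(rec["af"]) or ev.af > rec["af"]:
                    rec["af"] = ev.af
                    rec["ac"] = ev.ac if ev.ac is not None else np.nan
                prev = rec["per_source"].get(ev.source, np.nan)
                if math.isnan(prev) or ev.af > prev:
                    rec["per_source"][ev.source] = ev.af

    if not rows:
        return pd.DataFrame(
            columns=["chrom", "cpg_pos", "af", "ac", "sources", "strand_events"]
        )
    data = {
        "chrom": [k[0] for k in rows],
        "cpg_pos": [k[1] for k in rows],
        "af": [r["af"] for r in rows.values()],
        "ac": [r["ac"] for r in rows.values()],
        "sources": [",".join(sorted(r["sources"])) for r in rows.values()],
        "strand_events": [len(r["strands"]) for r in rows.values()],
    }
    df = pd.DataFrame(data)
    if af_policy == "per_source":
        for src in sorted({s for r in rows.values() for s in r["per_source"]}):
            df[f"af_{src}"] = [r["per_source"].get(src, np.nan) for r in rows.values()]
    elif af_policy != "max":
        raise ValueError(f"unknown af_policy {af_policy!r}")
    return df.sort_values(["chrom", "cpg_pos"]).reset_index(drop=True)


def rare_filter(events: list[VariantEvent], af_max: float = 0.01) -> list[VariantEvent]:
    """Events with allele frequency <= ``af_max`` (inclusive).

    Events with a missing frequency cannot be certified rare and are dropped
    (counted in the log).
    """
    kept: list[VariantEvent] = []
    n_missing = 0
    for ev in events:
        if ev.af is None or (isinstance(ev.af, float) and math.isnan(ev.af)):
            n_missing += 1
            continue
        if ev.af <= af_max:
            kept.append(ev)
    if n_missing:
        log.info("rare_filter: %d events with missing AF dropped", n_missing)
    return kept
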