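"""Synthetic genome bundles with known ground truth for closed-loop testing.

The generator emits a complete toy dataset in the standard formats the
pipeline consumes — FASTA genome, genePred gene models, island BED,
bedGraph methylation, VCF variant catalogues — together with truth tables
recording every CpG site's stratum, true mutation probability, drawn
mutation status, allele frequency, methylation beta and (for CDS CpGs) true
coding consequence.

What it emulates
----------------
* a multi-chromosome sequence: AT-rich, CpG-depleted background (so no
  spurious islands arise) with embedded CpG-dense islands whose composition
  satisfies the Gardiner-Garden criteria;
* gene models placed so that every functional island class — TSS-coding,
  TSS-noncoding, intragenic-coding (hyper- and hypo-methylated subgroups),
  intragenic-noncoding, intergenic, miscellaneous — is realized, on both
  strands, with multi-exon genes and junction-spanning codons;
* per-stratum C:G>T:A site-mutation probabilities whose defaults mirror the
  per-class rates the pipeline is meant to resolve, with a distinct shore
  band and a non-CpG control rate;
* a two-component allele-frequency distribution (mass near zero plus a
  uniform tail) so every frequency bin is populated;
* a methylation track with class-specific island betas, a linear shore ramp
  to the background level over 2 kb, and Gaussian noise;
* an exome-style catalogue over consequence-primed coding CpGs with
  consequence-dependent observation probabilities and allele-count
  distributions (emulating negative selection on nonsense changes).

Everything is reproducible from ``(config, seed)``: one integer RNG stream,
fixed iteration order, fixed number formatting.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .consequence import GENETIC_CODE
from .genes import GeneModel, cds_intervals, write_genepred

__all__ = ["SyntheticConfig", "Bundle", "generate", "truth_compare"]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

# slot plan cycled along each chromosome; IC = intragenic coding
_SLOT_CLASSES = (
    "TSS_CODING", "INTERGENIC", "IC_HYPER", "TSS_NONCODING",
    "IC_HYPO", "GENE_ONLY", "INTRAGENIC_NONCODING", "TSS_CODING",
    "MISC", "IC_HYPER", "INTERGENIC", "TSS_NONCODING",
    "IC_HYPO", "TSS_CODING", "INTRAGENIC_NONCODING", "GENE_ONLY",
)

_CLASS_OF_SLOT = {
    "TSS_CODING": "TSS_CODING",
    "TSS_NONCODING": "TSS_NONCODING",
    "INTERGENIC": "INTERGENIC",
    "IC_HYPER": "INTRAGENIC_CODING",
    "IC_HYPO": "INTRAGENIC_CODING",
    "INTRAGENIC_NONCODING": "INTRAGENIC_NONCODING",
    "MISC": "MISC",
}


@dataclass
class SyntheticConfig:
    """Study conditions of the demo dataset; all draws derive from ``seed``."""

    seed: int = 7
    n_chroms: int = 2
    chrom_length: int = 500_000
    slot_spacing: int = 31_250

    # sequence composition
    background_gc: float = 0.38
    background_cpg_retention: float = 0.35  # fraction of iid-expected CpGs kept
    island_gc: float = 0.70

    # true per-site C:G>T:A probabilities
    class_rates: dict = field(
        default_factory=lambda: {
            "TSS_CODING": 0.036,
            "TSS_NONCODING": 0.041,
            "INTERGENIC": 0.062,
            "INTRAGENIC_NONCODING": 0.060,
            "MISC": 0.050,
        }
    )
    ic_hyper_rate: float = 0.25
    ic_hypo_rate: float = 0.06
    # shore rates per class of the parent island (ordered like the island rates)
    shore_rates: dict = field(
        default_factory=lambda: {
            "TSS_CODING": 0.030,
            "TSS_NONCODING": 0.030,
            "INTERGENIC": 0.055,
            "INTRAGENIC_CODING": 0.100,
            "INTRAGENIC_NONCODING": 0.060,
            "MISC": 0.050,
        }
    )
    shore_width: int = 2000
    noncgi_rate: float = 0.276
    noncpg_ct_rate: float = 0.02
    other_sub_rate: float = 0.004

    # allele-frequency model (whole-genome catalogue)
    an_wgs: int = 8654
    af_rare_weight: float = 0.7
    af_rare_beta: tuple = (0.5, 25.0)

    # methylation regimes
    beta_island: dict = field(
        default_factory=lambda: {
            "TSS_CODING": 0.02,
            "TSS_NONCODING": 0.04,
            "INTERGENIC": 0.14,
            "INTRAGENIC_NONCODING": 0.15,
            "MISC": 0.10,
        }
    )
    beta_ic_hyper: float = 0.85
    beta_ic_hypo: float = 0.10
    beta_shore_border: float = 0.30
    beta_background: float = 0.80
    beta_noise_sd: float = 0.05

    # exome-style consequence catalogue
    hyper_beta_min: float = 0.67
    p_observed: dict = field(
        default_factory=lambda: {"SILENT": 0.8, "MISSENSE": 0.7, "NONSENSE": 0.5}
    )
    p_singleton: dict = field(
        default_factory=lambda: {"SILENT": 0.28, "MISSENSE": 0.42, "NONSENSE": 0.55}
    )
    an_exome: int = 121_412

    def validate(self) -> None:
        probs = [
            *self.class_rates.values(), self.ic_hyper_rate, self.ic_hypo_rate,
            *self.shore_rates.values(), self.noncgi_rate, self.noncpg_ct_rate,
            self.other_sub_rate, *self.p_observed.values(),
            *self.p_singleton.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.slot_spacing > self.chrom_length:
            raise ValueError("slot spacing exceeds chromosome length")
        if self.slot_spacing < 16_000:
            raise ValueError("slot spacing below 16 kb cannot host an island plus flanks")


@dataclass
class Bundle:
    config: SyntheticConfig
    out_dir: str
    paths: dict
    truth_islands: pd.DataFrame
    truth_sites: pd.DataFrame
    truth_primed: pd.DataFrame


# ---------------------------------------------------------------------------
# sequence construction


def _background_seq(rng: np.random.Generator, length: int, gc: float, retention: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=length, p=p)
    # deplete CpG dinucleotides: replace the G of most CG pairs by A or T
    mask = np.zeros(length, dtype=bool)
    mask[:-1] = (arr[:-1] == 1) & (arr[1:] == 2)
    hits = np.nonzero(mask)[0]
    kill = hits[rng.random(len(hits)) >= retention]
    arr[kill + 1] = np.where(rng.random(len(kill)) < 0.5, 0, 3)
    return arr


def _island_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for _ in range(10):
        arr = rng.choice(4, size=length, p=p)
        seq = arr_to_str(arr)
        c, g, cpg = seq.count("C"), seq.count("G"), seq.count("CG")
        gc_frac = (c + g) / length
        oe = cpg * length / (c * g) if c and g else 0.0
        if gc_frac >= 0.55 and oe > 0.75:  # margin over the calling thresholds
            return arr
    raise RuntimeError("could not draw an island satisfying composition targets")


def arr_to_str(arr: np.ndarray) -> str:
    return _ALPHABET[arr].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# gene construction


def _fix_frame(exons, strand, cds_lo, cds_hi):
    L = sum(max(0, min(e, cds_hi) - max(s, cds_lo)) for s, e in exons)
    rem = L % 3
    if rem:
        if strand == "+":
            cds_hi -= rem
        else:
            cds_lo += rem
    return cds_lo, cds_hi


def _make_gene(name, chrom, strand, tss, rng, coding=True) -> GeneModel:
    exon_lens = [int(rng.integers(300, 500)), int(rng.integers(400, 600)), int(rng.integers(700, 1000))]
    intron_lens = [int(rng.integers(500, 900)), int(rng.integers(500, 900))]
    span = sum(exon_lens) + sum(intron_lens)
    if strand == "+":
        tx_start, tx_end = tss, tss + span
    else:
        tx_end = tss + 1
        tx_start = tx_end - span
    exons = []
    cur = tx_start
    for i, el in enumerate(exon_lens):
        exons.append((cur, cur + el))
        cur += el + (intron_lens[i] if i < len(intron_lens) else 0)
    if not coding:
        return GeneModel(name, chrom, strand, tx_start, tx_end, tx_start, tx_start, exons)
    cds_lo = exons[0][0] + int(rng.integers(50, 150))
    cds_hi = exons[-1][1] - int(rng.integers(50, 150))
    cds_lo, cds_hi = _fix_frame(exons, strand, cds_lo, cds_hi)
    return GeneModel(name, chrom, strand, tx_start, tx_end, cds_lo, cds_hi, exons)


def _make_spanning_gene(name, chrom, strand, isl_start, isl_end, rng, coding=True) -> GeneModel:
    if coding:
        left, right = isl_start - 6000, isl_end + 1500
        exons = [
            (left, left + 300),
            (isl_start - 200, isl_end + 200),
            (right - 500, right),
        ]
        cds_lo, cds_hi = left + 100, right - 100
        cds_lo, cds_hi = _fix_frame(exons, strand, cds_lo, cds_hi)
        return GeneModel(name, chrom, strand, left, right, cds_lo, cds_hi, exons)
    left, right = isl_start - 2500, isl_end + 800
    return GeneModel(name, chrom, strand, left, right, left, left, [(left, right)])


# ---------------------------------------------------------------------------
# truth-side geometry (independent mirror of the distance convention)


def _truth_distance(pos: int, islands: list[tuple[int, int]]) -> tuple[float, int]:
    best_d, best_i = np.nan, -1
    for i, (s, e) in enumerate(islands):
        if s <= pos < e:
            return np.nan, i
        d = pos - s if pos < s else pos - e
        if best_i == -1 or abs(d) < abs(best_d):
            best_d, best_i = d, i
    return best_d, best_i


def _naive_consequence(cds: str, i: int, alt: str) -> str:
    """Full-protein translate-and-diff of a single transcript substitution."""
    mutated = cds[:i] + alt + cds[i + 1 :]

    def protein(s: str) -> str:
        return "".join(GENETIC_CODE[s[k : k + 3]] for k in range(0, len(s) - len(s) % 3, 3))

    p0, p1 = protein(cds), protein(mutated)
    if p0 == p1:
        return "SILENT"
    diffs = [(a, b) for a, b in zip(p0, p1) if a != b]
    if any(b == "*" for _, b in diffs):
        return "NONSENSE"
    return "MISSENSE"


# ---------------------------------------------------------------------------
# generator


def generate(config: SyntheticConfig, out_dir: str) -> Bundle:
    """Build the bundle and write every artefact under ``out_dir``.

    Returns a :class:`Bundle` with truth tables in memory and all file
    paths.  Identical ``(config, seed)`` produce byte-identical trees.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    os.makedirs(out_dir, exist_ok=True)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    island_rows = []
    islands_by_chrom: dict[str, list[tuple[int, int]]] = {}
    isl_meta_by_chrom: dict[str, list[dict]] = {}

    gene_counter = 0
    for chrom in chrom_names:
        arr = _background_seq(
            rng, config.chrom_length, config.background_gc, config.background_cpg_retention
        )
        n_slots = config.chrom_length // config.slot_spacing
        islands: list[tuple[int, int]] = []
        meta: list[dict] = []
        for slot in range(n_slots):
            kind = _SLOT_CLASSES[slot % len(_SLOT_CLASSES)]
            center = slot * config.slot_spacing + config.slot_spacing // 2
            center += int(rng.integers(-1000, 1001))
            strand = "+" if slot % 2 == 0 else "-"

            if kind == "GENE_ONLY":
                genes.append(_make_gene(f"gene{gene_counter}", chrom, strand, center, rng))
                gene_counter += 1
                continue

            if kind in ("IC_HYPER",):
                length = int(rng.integers(400, 520))
            elif kind == "IC_HYPO":
                length = int(rng.integers(1100, 1400))
            elif kind in ("TSS_CODING", "TSS_NONCODING"):
                length = int(rng.integers(800, 1400))
            else:
                length = int(rng.integers(600, 1000))
            if length >= config.chrom_length:
                raise ValueError("island longer than chromosome")
            start = center - length // 2
            end = start + length
            arr[start:end] = _island_seq(rng, length, config.island_gc)
            islands.append((start, end))

            if kind == "TSS_CODING":
                tss = start + length // 3
                genes.append(_make_gene(f"gene{gene_counter}", chrom, strand, tss, rng, coding=True))
                gene_counter += 1
            elif kind == "TSS_NONCODING":
                tss = start + length // 3
                genes.append(_make_gene(f"gene{gene_counter}", chrom, strand, tss, rng, coding=False))
                gene_counter += 1
            elif kind in ("IC_HYPER", "IC_HYPO"):
                genes.append(
                    _make_spanning_gene(f"gene{gene_counter}", chrom, strand, start, end, rng, coding=True)
                )
                gene_counter += 1
            elif kind == "INTRAGENIC_NONCODING":
                genes.append(
                    _make_spanning_gene(f"gene{gene_counter}", chrom, strand, start, end, rng, coding=False)
                )
                gene_counter += 1
            elif kind == "MISC":
                tss = start + length // 3
                genes.append(_make_gene(f"gene{gene_counter}", chrom, strand, tss, rng, coding=True))
                gene_counter += 1
                genes.append(
                    _make_spanning_gene(f"gene{gene_counter}", chrom, "+", start, end, rng, coding=False)
                )
                gene_counter += 1

            if kind == "IC_HYPER":
                rate, beta0, group = config.ic_hyper_rate, config.beta_ic_hyper, "A"
            elif kind == "IC_HYPO":
                rate, beta0, group = config.ic_hypo_rate, config.beta_ic_hypo, "B"
            else:
                rate = config.class_rates[kind]
                beta0 = config.beta_island[kind]
                group = ""
            meta.append(
                {
                    "chrom": chrom, "start": start, "end": end,
                    "cgi_class": _CLASS_OF_SLOT[kind], "group": group,
                    "rate": rate, "beta": beta0,
                }
            )
        sequences[chrom] = arr_to_str(arr)
        islands_by_chrom[chrom] = islands
        isl_meta_by_chrom[chrom] = meta
        island_rows.extend(meta)

    truth_islands = pd.DataFrame(island_rows)

    # --- per-CpG truth, mutation draws, methylation -----------------------
    site_rows = []
    vcf_records: list[tuple[str, int, str, str, float, int, int]] = []
    meth_rows = []
    for chrom in chrom_names:
        seq = sequences[chrom]
        islands = islands_by_chrom[chrom]
        meta = isl_meta_by_chrom[chrom]
        b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        cpg_pos = np.nonzero((b[:-1] == ord("C")) & (b[1:] == ord("G")))[0]
        for pos in cpg_pos:
            pos = int(pos)
            d, i = _truth_distance(pos, islands)
            if i >= 0 and np.isnan(d):
                m = meta[i]
                stratum = f"CGI:{m['cgi_class']}" + (f":{m['group']}" if m["group"] else "")
                p_true, beta_mean = m["rate"], m["beta"]
                cgi_class, group = m["cgi_class"], m["group"]
            elif i >= 0 and abs(d) <= config.shore_width:
                parent_class = meta[i]["cgi_class"]
                stratum = f"SHORE:{parent_class}"
                p_true = config.shore_rates[parent_class]
                frac = abs(d) / config.shore_width
                beta_mean = config.beta_shore_border + frac * (
                    config.beta_background - config.beta_shore_border
                )
                cgi_class, group = "NONE", ""
            else:
                stratum = "NONCGI"
                p_true = config.noncgi_rate
                beta_mean = config.beta_background
                cgi_class, group = "NONE", ""
            mutated = bool(rng.random() < p_true)
            af = np.nan
            ac = 0
            if mutated:
                if rng.random() < config.af_rare_weight:
                    af_raw = float(rng.beta(*config.af_rare_beta))
                else:
                    af_raw = float(rng.random())
                ac = max(1, int(round(af_raw * config.an_wgs)))
                ac = min(ac, config.an_wgs)
                af = ac / config.an_wgs
                u = rng.random()
                if u < 0.45:
                    vcf_records.append((chrom, pos, "C", "T", af, ac, config.an_wgs))
                elif u < 0.90:
                    vcf_records.append((chrom, pos + 1, "G", "A", af, ac, config.an_wgs))
                else:  # both strand observations of one dinucleotide
                    vcf_records.append((chrom, pos, "C", "T", af, ac, config.an_wgs))
                    ac2 = max(1, ac // 2)
                    vcf_records.append(
                        (chrom, pos + 1, "G", "A", ac2 / config.an_wgs, ac2, config.an_wgs)
                    )
            beta = float(np.clip(beta_mean + rng.normal(0, config.beta_noise_sd), 0.0, 1.0))
            meth_rows.append((chrom, pos, beta))
            site_rows.append(
                (chrom, pos, stratum, cgi_class, group,
                 d if not np.isnan(d) else np.nan, p_true, mutated, af, beta)
            )

        # non-CpG C>T control events and other substitution classes
        is_c = b == ord("C")
        is_g = b == ord("G")
        nxt_g = np.zeros(len(b), dtype=bool)
        nxt_g[:-1] = b[1:] == ord("G")
        prv_c = np.zeros(len(b), dtype=bool)
        prv_c[1:] = b[:-1] == ord("C")
        noncpg_c = np.nonzero(is_c & ~nxt_g)[0]
        noncpg_g = np.nonzero(is_g & ~prv_c)[0]
        for positions, ref, alt in ((noncpg_c, "C", "T"), (noncpg_g, "G", "A")):
            hit = positions[rng.random(len(positions)) < config.noncpg_ct_rate]
            for pos in hit:
                af_raw = float(rng.beta(0.5, 50.0))
                ac = min(max(1, int(round(af_raw * config.an_wgs))), config.an_wgs)
                vcf_records.append((chrom, int(pos), ref, alt, ac / config.an_wgs, ac, config.an_wgs))
        other = {"A": ("G", "C"), "T": ("C", "G"), "C": ("A", "G"), "G": ("T", "C")}
        for base, alts in other.items():
            positions = np.nonzero(b == ord(base))[0]
            hit = positions[rng.random(len(positions)) < config.other_sub_rate]
            for pos in hit:
                alt = alts[int(rng.integers(0, 2))]
                af_raw = float(rng.beta(0.5, 50.0))
                ac = min(max(1, int(round(af_raw * config.an_wgs))), config.an_wgs)
                vcf_records.append((chrom, int(pos), base, alt, ac / config.an_wgs, ac, config.an_wgs))

    truth_sites = pd.DataFrame(
        site_rows,
        columns=["chrom", "pos", "stratum", "cgi_class", "group",
                 "distance", "p_true", "mutated", "af", "beta"],
    )

    # --- consequence-primed coding CpGs and the exome catalogue -----------
    beta_lookup = {
        (c, int(p)): float(bv)
        for c, p, bv in zip(truth_sites["chrom"], truth_sites["pos"], truth_sites["beta"])
    }
    primed_rows = []
    exome_records: list[tuple[str, int, str, str, float, int, int]] = []
    for gene in genes:
        if not gene.is_coding:
            continue
        seq = sequences[gene.chrom]
        ivs = cds_intervals(gene)
        pieces = [seq[s:e] for s, e in ivs]
        plus_cds = "".join(pieces)
        if gene.strand == "-":
            comp = str.maketrans("ACGT", "TGCA")
            cds = plus_cds.translate(comp)[::-1]
        else:
            cds = plus_cds
        assert len(cds) % 3 == 0
        total = len(cds)
        offset = 0
        islands = islands_by_chrom[gene.chrom]
        meta = isl_meta_by_chrom[gene.chrom]
        for s, e in ivs:
            for p in range(s, e):
                base = seq[p]
                if base == "C" and seq[p : p + 2] == "CG":
                    ref, alt, anchor = "C", "T", p
                elif base == "G" and p >= 1 and seq[p - 1 : p + 1] == "CG":
                    ref, alt, anchor = "G", "A", p - 1
                else:
                    continue
                plus_index = offset + (p - s)
                i = plus_index if gene.strand == "+" else total - 1 - plus_index
                t_alt = {"C": "T", "G": "A"}[cds[i]]
                consequence = _naive_consequence(cds, i, t_alt)
                region = "NON_CGI"
                for j, (s2, e2) in enumerate(islands):
                    if s2 <= p < e2:
                        c2 = meta[j]["cgi_class"]
                        region = (
                            "TSS_CGI" if c2.startswith("TSS")
                            else "INTRAGENIC_CGI" if c2.startswith("INTRAGENIC")
                            else "OTHER_CGI"
                        )
                        break
                beta = beta_lookup.get((gene.chrom, anchor), np.nan)
                hyper = beta >= config.hyper_beta_min
                observed = False
                ac = 0
                if hyper and rng.random() < config.p_observed[consequence]:
                    observed = True
                    ac = int(rng.geometric(config.p_singleton[consequence]))
                    ac = min(ac, config.an_exome)
                    exome_records.append(
                        (gene.chrom, p, ref, alt, ac / config.an_exome, ac, config.an_exome)
                    )
                primed_rows.append(
                    (gene.chrom, p, ref, alt, gene.name, region, consequence,
                     anchor, beta, hyper, observed, ac if observed else np.nan)
                )
            offset += e - s
    truth_primed = pd.DataFrame(
        primed_rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "region_class", "consequence",
                 "cpg_pos", "beta", "hyper", "observed", "ac"],
    )

    # --- write the bundle --------------------------------------------------
    paths = {
        "fasta": os.path.join(out_dir, "genome.fa"),
        "genes": os.path.join(out_dir, "genes.genepred"),
        "cgi_bed": os.path.join(out_dir, "cgi_truth.bed"),
        "methylation": os.path.join(out_dir, "methylation.bedgraph"),
        "wgs_vcf": os.path.join(out_dir, "wgs.vcf"),
        "coding_vcf": os.path.join(out_dir, "coding.vcf"),
        "truth_islands": os.path.join(out_dir, "truth_islands.tsv"),
        "truth_sites": os.path.join(out_dir, "truth_sites.tsv"),
        "truth_primed": os.path.join(out_dir, "truth_primed.tsv"),
        "config": os.path.join(out_dir, "config.json"),
    }

    with open(paths["fasta"], "w") as fh:
        for chrom in chrom_names:
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")
    write_genepred(sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.name)), paths["genes"])
    with open(paths["cgi_bed"], "w") as fh:
        for r in island_rows:
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['cgi_class']}\n")
    with open(paths["methylation"], "w") as fh:
        for chrom, pos, beta in meth_rows:
            fh.write(f"{chrom}\t{pos}\t{pos + 2}\t{beta:.6f}\n")
    _write_vcf(paths["wgs_vcf"], vcf_records, chrom_names,
               {c: len(sequences[c]) for c in chrom_names})
    _write_vcf(paths["coding_vcf"], exome_records, chrom_names,
               {c: len(sequences[c]) for c in chrom_names})
    truth_islands.to_csv(paths["truth_islands"], sep="\t", index=False, float_format="%.8g")
    truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False, float_format="%.8g")
    truth_primed.to_csv(paths["truth_primed"], sep="\t", index=False, float_format="%.8g")
    with open(paths["config"], "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True, default=list)

    return Bundle(config, out_dir, paths, truth_islands, truth_sites, truth_primed)


def _write_vcf(path: str, records, chrom_names, chrom_lengths) -> None:
    records = sorted(records, key=lambda r: (chrom_names.index(r[0]), r[1], r[2], r[3]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chrom_names:
            fh.write(f"##contig=<ID={c},length={chrom_lengths[c]}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele Count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Total Alleles">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, af, ac, an in records:
            fh.write(
                f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t"
                f"AF={af:.8g};AC={ac};AN={an}\n"
            )


# ---------------------------------------------------------------------------
# closing the loop


def truth_compare(
    bundle: Bundle,
    site_table: pd.DataFrame,
    n_se: float = 3.0,
) -> pd.DataFrame:
    """Per-stratum comparison of pipeline rate estimates against truth.

    For every truth stratum the pipeline's estimated mutation rate (over the
    sites the generator placed in that stratum) is compared with the
    expected rate (mean of the per-site true probabilities); the tolerance
    is ``n_se`` binomial standard errors computed from the truth
    probabilities.  Site universes must match exactly.
    """
    truth = bundle.truth_sites
    merged = truth.merge(
        site_table[["chrom", "pos", "mutated"]],
        on=["chrom", "pos"],
        how="left",
        suffixes=("_true", "_est"),
        indicator=True,
    )
    missing = merged[merged["_merge"] != "both"]
    if len(missing):
        first = missing.iloc[0]
        raise ValueError(
            f"site universes diverge: truth site {first['chrom']}:{first['pos']} "
            "not found in the pipeline table"
        )
    rows = []
    for stratum, g in merged.groupby("stratum"):
        n = len(g)
        p = g["p_true"].to_numpy()
        expected = float(p.mean())
        est = float(g["mutated_est"].mean())
        se = float(np.sqrt((p * (1 - p)).sum()) / n)
        tol = n_se * se
        rows.append(
            {
                "stratum": stratum, "n": n, "expected": expected,
                "estimated": est, "abs_error": abs(est - expected),
                "tolerance": tol, "passed": abs(est - expected) <= tol,
            }
        )
    return pd.DataFrame(rows).sort_values("stratum").reset_index(drop=True)
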