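"""Mutation-rate statistics over CpG site tables.

All rate computations operate on a *site table*: a :class:`pandas.DataFrame`
with one row per CpG dinucleotide and (a subset of) the columns

``chrom, pos, in_cgi, cgi_class, distance, mutated, af, beta, coding``

The fundamental statistic is the per-site rate

    rate = (# C:G>T:A-mutated CpG units in stratum) / (# CpG units in stratum)

with its allele-frequency-weighted analogue replacing the numerator by the
sum of allele frequencies of the mutated units.  Binomial 95% confidence
intervals use the Wilson score (a normal-approximation mode exists for
comparison).  The spatial analogue resolves the same ratio at every signed
distance from the nearest island border within +/-5 kb.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

log = logging.getLogger(__name__)

__all__ = [
    "write_sites_bed",
    "mutation_rate",
    "af_weighted_rate",
    "af_binned_rates",
    "distance_profile",
    "smooth_profile",
    "region_split_rates",
    "build_site_table",
    "SMOOTH_WINDOWS",
]

#: Block widths (in distance positions) for per-class profile smoothing:
#: 20 positions for TSS-coding, intragenic-coding and intergenic islands,
#: 100 for the sparser noncoding classes.
SMOOTH_WINDOWS = {
    "TSS_CODING": 20,
    "INTRAGENIC_CODING": 20,
    "INTERGENIC": 20,
    "TSS_NONCODING": 100,
    "INTRAGENIC_NONCODING": 100,
    "MISC": 20,
    None: 20,
}


def _ci(numer: np.ndarray, denom: np.ndarray, method: str = "wilson") -> tuple[np.ndarray, np.ndarray]:
    lo = np.full(len(numer), np.nan)
    hi = np.full(len(numer), np.nan)
    ok = denom > 0
    if ok.any():
        lo_ok, hi_ok = proportion_confint(
            numer[ok], denom[ok], alpha=0.05,
            method="wilson" if method == "wilson" else "normal",
        )
        lo[ok], hi[ok] = lo_ok, hi_ok
    return lo, hi


def write_sites_bed(site_table: pd.DataFrame, path: str) -> None:
    """Export the CpG site catalogue as BED3+ (interval = the dinucleotide).

    Columns beyond chrom/start/end carry the annotations: island class,
    in-island flag, signed distance, CDS overlap, mutation flag, allele
    frequency and beta.
    """
    out = site_table.copy()
    out.insert(2, "end", out["pos"] + 2)
    cols = ["chrom", "pos", "end", "cgi_class", "in_cgi", "distance",
            "coding", "mutated", "af", "beta"]
    out[[c for c in cols if c in out.columns]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.6g"
    )


def mutation_rate(
    sites: pd.DataFrame,
    by: str | list[str] | None = None,
    ci_method: str = "wilson",
    count_unit: str = "dinucleotide",
) -> pd.DataFrame:
    """Per-stratum mutation rate with 95% confidence intervals.

    ``by`` names stratum column(s) of the site table; ``None`` gives the
    single overall row.  Empty strata (possible with categorical columns)
    get denominator 0 and a missing rate.

    ``count_unit`` selects what a "C or G at CpG context" is: the default
    ``"dinucleotide"`` counts each CpG unit once; ``"strand-base"`` counts
    the C and the G separately (denominator doubled, numerator from the
    per-site ``strand_events`` column when present).
    """
    if count_unit not in ("dinucleotide", "strand-base"):
        raise ValueError(f"unknown count unit {count_unit!r}")
    if by is None:
        grouped = [(("all",), sites)]
        keys = ["stratum"]
    else:
        keys = [by] if isinstance(by, str) else list(by)
        grouped = [
            (k if isinstance(k, tuple) else (k,), g)
            for k, g in sites.groupby(keys, dropna=False, observed=False)
        ]
    recs = []
    for key, g in grouped:
        if count_unit == "strand-base":
            n = 2 * len(g)
            if "strand_events" in g.columns:
                m = int(g["strand_events"].fillna(0).sum())
            else:
                m = int(g["mutated"].sum())
        else:
            n = len(g)
            m = int(g["mutated"].sum())
        recs.append((*key, m, n, m / n if n else np.nan))
    out = pd.DataFrame(recs, columns=[*keys, "numerator", "denominator", "rate"])
    out["ci_low"], out["ci_high"] = _ci(
        out["numerator"].to_numpy(), out["denominator"].to_numpy(), ci_method
    )
    return out


def af_weighted_rate(sites: pd.DataFrame, by: str | list[str] | None = None) -> pd.DataFrame:
    """Allele-frequency-weighted rate: sum of AFs of mutated units / all units.

    Mutated sites with a missing frequency are excluded from the numerator
    and reported in the ``n_missing_af`` column.
    """
    if by is None:
        grouped = [(("all",), sites)]
        keys = ["stratum"]
    else:
        keys = [by] if isinstance(by, str) else list(by)
        grouped = [
            (k if isinstance(k, tuple) else (k,), g)
            for k, g in sites.groupby(keys, dropna=False, observed=False)
        ]
    recs = []
    for key, g in grouped:
        n = len(g)
        mut = g[g["mutated"]]
        af_sum = float(mut["af"].sum(skipna=True))
        n_missing = int(mut["af"].isna().sum())
        recs.append((*key, af_sum, n, af_sum / n if n else np.nan, n_missing))
    return pd.DataFrame(
        recs, columns=[*keys, "numerator", "denominator", "rate", "n_missing_af"]
    )


def af_binned_rates(
    sites: pd.DataFrame,
    bins=None,
    by: str | list[str] | None = None,
) -> pd.DataFrame:
    """Fraction of sites per allele-frequency bin within each stratum.

    The Af=0 bin is the unmutated complement, so within a stratum the six
    bin fractions sum to 1.
    """
    from .variants import DEFAULT_AF_BINS, af_bin_label

    bins = tuple(bins) if bins is not None else DEFAULT_AF_BINS
    for i, a in enumerate(bins):
        for b in bins[i + 1 :]:
            if a.lower < b.upper and b.lower < a.upper and not (a.lower == a.upper or b.lower == b.upper):
                raise ValueError(f"overlapping AF bins {a.label} / {b.label}")
    af = sites["af"].where(sites["mutated"], 0.0)
    labels = [af_bin_label(v, bins) for v in af]
    work = sites.assign(af_bin=pd.Categorical(labels, categories=[b.label for b in bins]))
    keys = ["af_bin"] if by is None else ([by, "af_bin"] if isinstance(by, str) else [*by, "af_bin"])
    grp = work.groupby(keys, dropna=False, observed=False).size().rename("numerator").reset_index()
    if by is None:
        grp["denominator"] = len(sites)
    else:
        bykeys = [by] if isinstance(by, str) else list(by)
        totals = work.groupby(bykeys, dropna=False, observed=False).size().rename("denominator").reset_index()
        grp = grp.merge(totals, on=bykeys, how="left")
    grp["rate"] = np.where(grp["denominator"] > 0, grp["numerator"] / grp["denominator"], np.nan)
    return grp


def distance_profile(
    sites: pd.DataFrame,
    max_dist: int = 5000,
    by_class: bool = False,
    value: str = "mutated",
) -> pd.DataFrame:
    """Per-distance rate (or mean value) around island borders.

    Restricted to sites outside islands with ``|distance| <= max_dist``.
    For ``value="mutated"`` the per-distance mutation rate is reported; for
    ``value="beta"`` the mean methylation.  Distances with zero qualifying
    sites are simply absent (missing, not 0).  With ``by_class`` the profile
    is resolved per functional class of the nearest island.
    """
    work = sites[sites["distance"].notna() & (sites["distance"].abs() <= max_dist)]
    keys = (["cgi_class"] if by_class else []) + ["distance"]
    if value == "mutated":
        g = work.groupby(keys, observed=True)["mutated"].agg(["sum", "size"])
        g.columns = ["numerator", "denominator"]
        g["rate"] = g["numerator"] / g["denominator"]
    else:
        sub = work[work[value].notna()]
        g = sub.groupby(keys, observed=True)[value].agg(["sum", "size"])
        g.columns = ["numerator", "denominator"]
        g["rate"] = g["numerator"] / g["denominator"]
    return g.reset_index()


def smooth_profile(profile: pd.DataFrame, window: int | None = None, cgi_class: str | None = None) -> pd.DataFrame:
    """Average a raw distance profile over non-overlapping position blocks.

    Blocks run outward from the island border on each side; each block of
    ``window`` consecutive distance positions is replaced by the mean of the
    per-position rates present in it (a trailing partial block averages what
    is available).  The block label is its midpoint.  When ``window`` is not
    given it is taken from :data:`SMOOTH_WINDOWS` for ``cgi_class``.
    """
    if window is None:
        window = SMOOTH_WINDOWS.get(cgi_class, 20)
    d = profile["distance"].to_numpy(dtype=float)
    # block index counted outward from the border on each side
    side = np.sign(d)
    side[side == 0] = 1.0
    block = np.where(d >= 0, np.floor(d / window), -1 - np.floor((-d - 1) / window))
    work = profile.assign(_block=block)
    recs = []
    for b, g in work.groupby("_block", sort=True):
        b = float(b)
        if b >= 0:
            mid = b * window + (window - 1) / 2.0
        else:
            mid = -((-b - 1) * window + (window + 1) / 2.0)
        recs.append(
            {
                "distance": mid,
                "rate": float(g["rate"].mean()),
                "n_positions": int(len(g)),
                "numerator": float(g["numerator"].sum()),
                "denominator": float(g["denominator"].sum()),
            }
        )
    return pd.DataFrame(recs).sort_values("distance").reset_index(drop=True)


def region_split_rates(sites: pd.DataFrame) -> pd.DataFrame:
    """Rates crossed by region (TSS-coding CGI / intragenic-coding CGI / non-CGI)
    and by coding-exon membership of the C position."""
    def region(row_class, in_cgi):
        if not in_cgi:
            return "NON_CGI"
        return row_class
    work = sites.copy()
    work["region"] = [region(c, i) for c, i in zip(work["cgi_class"], work["in_cgi"])]
    work = work[work["region"].isin(["TSS_CODING", "INTRAGENIC_CODING", "NON_CGI"])]
    work["exon_class"] = np.where(work["coding"], "coding-exon", "noncoding")
    return mutation_rate(work, by=["region", "exon_class"])


def build_site_table(
    genome,
    cgis,
    genes=None,
    mutation_table: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
    chroms: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the central per-CpG site table.

    Enumerates every CpG dinucleotide, annotates island membership and
    functional class, signed distance to the nearest island border, CDS
    overlap, observed mutation status with allele frequency, and methylation
    beta.  ``mutation_table`` is the output of
    :func:`cpgscape.variants.merge_catalogues`; ``methylation`` a
    ``chrom,pos,beta`` frame.
    """
    from .cgi import signed_distances
    from .genes import cds_intervals
    from .genome import cpg_positions

    frames = []
    cgi_by_chrom: dict[str, list] = {}
    for isl in cgis:
        cgi_by_chrom.setdefault(isl.chrom, []).append(isl)
    for lst in cgi_by_chrom.values():
        lst.sort(key=lambda i: i.start)

    cds_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if genes is not None:
        for g in genes:
            if g.is_coding:
                cds_by_chrom.setdefault(g.chrom, []).extend(cds_intervals(g))

    for chrom in chroms if chroms is not None else genome.chrom_names:
        pos = cpg_positions(genome, chrom)
        df = pd.DataFrame({"chrom": chrom, "pos": pos})
        isls = cgi_by_chrom.get(chrom, [])
        dist, idx = signed_distances(pos, isls)
        df["distance"] = dist
        df["in_cgi"] = np.isnan(dist) & (idx >= 0)
        classes = np.array([i.cgi_class or "NONE" for i in isls] + ["NONE"], dtype=object)
        df["cgi_class"] = classes[np.where(idx >= 0, idx, len(isls))]
        df.loc[~df["in_cgi"] & df["distance"].isna(), "cgi_class"] = "NONE"

        coding = np.zeros(len(pos), dtype=bool)
        ivs = sorted(set(cds_by_chrom.get(chrom, [])))
        if ivs:
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged])
            ends = np.array([m[1] for m in merged])
            j = np.searchsorted(starts, pos, side="right") - 1
            coding = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        df["coding"] = coding
        frames.append(df)

    table = pd.concat(frames, ignore_index=True)
    table["mutated"] = False
    table["af"] = np.nan
    table["ac"] = np.nan
    table["strand_events"] = 0
    if mutation_table is not None and len(mutation_table):
        mt = mutation_table.rename(columns={"cpg_pos": "pos"})
        cols = ["chrom", "pos", "af"] + [
            c for c in ("ac", "strand_events") if c in mt.columns
        ]
        table = table.merge(
            mt[cols].rename(
                columns={"af": "_af_obs", "ac": "_ac_obs", "strand_events": "_se_obs"}
            ),
            on=["chrom", "pos"],
            how="left",
            indicator=True,
        )
        table["mutated"] = table["_merge"] == "both"
        table["af"] = table["_af_obs"]
        if "_ac_obs" in table.columns:
            table["ac"] = table["_ac_obs"]
        if "_se_obs" in table.columns:
            table["strand_events"] = table["_se_obs"].fillna(0).astype(int)
        table = table.drop(
            columns=[c for c in ("_af_obs", "_ac_obs", "_se_obs", "_merge") if c in table.columns]
        )
    table["beta"] = np.nan
    if methylation is not None and len(methylation):
        meth = methylation[["chrom", "pos", "beta"]].rename(columns={"beta": "_beta_obs"})
        table = table.merge(meth, on=["chrom", "pos"], how="left")
        table["beta"] = table["_beta_obs"]
        table = table.drop(columns=["_beta_obs"])
    return table
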