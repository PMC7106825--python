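"""Per-CpG methylation: track ingestion, per-island means, hyper/hypo split.

Methylation input is a bedGraph-like track (``chrom start end beta
[coverage]``) or a MethBase-style table (``chrom pos strand context beta
coverage``).  Beta values on a 0-100 scale are autodetected and rescaled to
[0, 1].  Strand-duplicated records for one dinucleotide (a C record and the
following G record) are averaged into a single site-level beta anchored at
the C.

Islands are grouped by mean beta: Group A (hyper-methylated) strictly above
0.67, Group B (hypo-methylated) strictly below 0.33, the rest intermediate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cgi import CpGIsland
from .genome import GenomeSequence

log = logging.getLogger(__name__)

__all__ = [
    "load_methylation",
    "collapse_to_sites",
    "mean_methylation_per_cgi",
    "methylation_distance_profile",
    "split_intragenic_coding",
]

HYPER_THRESHOLD = 0.67
HYPO_THRESHOLD = 0.33


def load_methylation(path: str, fmt: str = "bedgraph") -> pd.DataFrame:
    """Read a methylation track into a ``chrom,pos,beta,coverage`` frame.

    ``fmt="bedgraph"``: columns chrom, start, end, beta[, coverage]; the
    record anchor is ``start``.  ``fmt="methbase"``: chrom, pos, strand,
    context, beta, coverage; minus-strand records are re-anchored to the C of
    the dinucleotide (pos - 1).  Betas above 1 anywhere trigger 0-100 scale
    autodetection; values outside [0, 1] after normalization are an error.
    """
    if fmt == "bedgraph":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", engine="python")
        if df.shape[1] < 4:
            raise ValueError(f"{path}: bedGraph needs >=4 columns")
        df = df.iloc[:, :5] if df.shape[1] >= 5 else df
        df.columns = ["chrom", "pos", "end", "beta", "coverage"][: df.shape[1]]
        if "coverage" not in df.columns:
            df["coverage"] = 1
        df = df[["chrom", "pos", "beta", "coverage"]]
    elif fmt == "methbase":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "pos", "strand", "context", "beta", "coverage"],
            engine="python",
        )
        df.loc[df["strand"] == "-", "pos"] -= 1
        df = df[["chrom", "pos", "beta", "coverage"]]
    else:
        raise ValueError(f"unknown methylation format {fmt!r}")

    if (df["beta"] > 1).any():
        df["beta"] = df["beta"] / 100.0
    bad = df.index[(df["beta"] < 0) | (df["beta"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: beta outside [0,1] after normalization at line {bad[0] + 1}")
    df["coverage"] = df["coverage"].fillna(1).astype(int)
    return df


def collapse_to_sites(records: pd.DataFrame, genome: GenomeSequence) -> pd.DataFrame:
    """Average strand-duplicated records of one dinucleotide onto the C anchor.

    A record at position p+1 where the genome reads CG at [p, p+2) is a
    G-strand measurement of the site anchored at p; it is re-anchored and
    averaged with any C-strand record.  Records at positions that are not
    part of any CpG are kept as-is but counted as orphans.
    """
    recs = records.copy()
    anchor = np.empty(len(recs), dtype=np.int64)
    orphans = 0
    seqs = {c: genome.chrom_seq(c) for c in genome.chrom_names if c in genome}
    for i, (chrom, pos) in enumerate(zip(recs["chrom"], recs["pos"])):
        seq = seqs.get(chrom)
        p = int(pos)
        if seq is not None and seq[p : p + 2] == "CG":
            anchor[i] = p
        elif seq is not None and p >= 1 and seq[p - 1 : p + 1] == "CG":
            anchor[i] = p - 1
        else:
            anchor[i] = p
            orphans += 1
    if orphans:
        log.warning("%d methylation records do not map onto a CpG dinucleotide", orphans)
    recs["pos"] = anchor
    out = (
        recs.groupby(["chrom", "pos"], as_index=False)
        .agg(beta=("beta", "mean"), coverage=("coverage", "sum"))
    )
    return out


def mean_methylation_per_cgi(
    records: pd.DataFrame,
    cgis: list[CpGIsland],
    min_cpgs: int = 5,
) -> pd.DataFrame:
    """Mean beta over covered CpGs inside each island, with group labels.

    Returns one row per island: ``chrom, start, end, cgi_class, length,
    mean_beta, n_covered, group``.  The group (A / B / intermediate) is
    assigned only when at least ``min_cpgs`` CpGs are covered; islands with
    no covered CpG get a missing mean.
    """
    by_chrom: dict[str, pd.DataFrame] = {
        c: g.sort_values("pos") for c, g in records.groupby("chrom")
    }
    rows = []
    for isl in cgis:
        g = by_chrom.get(isl.chrom)
        if g is None:
            betas = np.empty(0)
        else:
            pos = g["pos"].to_numpy()
            lo, hi = np.searchsorted(pos, [isl.start, isl.end])
            betas = g["beta"].to_numpy()[lo:hi]
        n = len(betas)
        mean = float(np.mean(betas)) if n else np.nan
        if n >= min_cpgs:
            if mean > HYPER_THRESHOLD:
                group = "A"
            elif mean < HYPO_THRESHOLD:
                group = "B"
            else:
                group = "intermediate"
        else:
            group = None
        rows.append(
            {
                "chrom": isl.chrom,
                "start": isl.start,
                "end": isl.end,
                "cgi_class": isl.cgi_class,
                "length": isl.length,
                "mean_beta": mean,
                "n_covered": n,
                "group": group,
            }
        )
    return pd.DataFrame(rows)


def methylation_distance_profile(
    sites: pd.DataFrame,
    max_dist: int = 5000,
    by_class: bool = False,
) -> pd.DataFrame:
    """Mean beta per signed distance from the nearest island border.

    Operates on a site table carrying ``beta`` and ``distance`` columns;
    distances with no covered CpG are absent (missing, not 0).
    """
    from .rates import distance_profile

    return distance_profile(sites, max_dist=max_dist, by_class=by_class, value="beta")


def split_intragenic_coding(
    summaries: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition intragenic-coding islands into hyper (A) and hypo (B) groups.

    Returns ``(group_a, group_b, stats)`` where ``stats`` holds one row per
    grouped island with its length and group, ready for a rank-sum length
    comparison and per-group rate computation.
    """
    sub = summaries[summaries["cgi_class"] == "INTRAGENIC_CODING"]
    group_a = sub[sub["group"] == "A"].reset_index(drop=True)
    group_b = sub[sub["group"] == "B"].reset_index(drop=True)
    stats = sub[sub["group"].isin(["A", "B"])][
        ["chrom", "start", "end", "length", "mean_beta", "group"]
    ].reset_index(drop=True)
    return group_a, group_b, stats
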