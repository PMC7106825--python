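"""End-to-end orchestration: inputs -> site table -> rate/methylation/consequence
tables -> signature weights -> statistical battery -> TSV output tree.

Stage order is fixed by data dependencies: sites -> islands -> distances ->
rates & methylation -> consequences -> signatures.  Outputs are plain TSV
(UTF-8, '.' decimal) so reruns on identical inputs are byte-identical; a
manifest records per-stage row counts and a checksum for every emitted
file.  A missing methylation track degrades gracefully: methylation- and
consequence-dependent stages are marked SKIPPED and the rate stages still
run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cgi as cgi_mod
from . import methylation as meth_mod
from . import rates as rates_mod
from . import signatures as sig_mod
from . import stats as stats_mod
from . import variants as var_mod
from .consequence import ac_spectrum, cross_with_observed, enumerate_primed_sites
from .genes import collapse_by_name, read_genepred
from .genome import GenomeSequence

log = logging.getLogger(__name__)

__all__ = ["PipelineInputs", "PipelineResult", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineInputs:
    fasta: str
    genes: str
    vcfs: list = field(default_factory=list)  # [(path, source_label), ...]
    cgi_bed: str | None = None  # called from sequence when absent
    methylation: str | None = None
    coding_vcf: str | None = None
    exclude_chroms_af: tuple = ("chrY", "Y")  # chromosomes dropped from AF analyses


@dataclass
class PipelineResult:
    out_dir: str
    site_table: pd.DataFrame
    tables: dict
    tests: dict
    manifest: dict


def _write(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def run_pipeline(inputs: PipelineInputs, out_dir: str) -> PipelineResult:
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"stages": {}, "files": {}, "skipped": []}
    tables: dict = {}
    tests: dict = {}

    def stage(name: str, n: int) -> None:
        log.info("stage %s: %d rows", name, n)
        manifest["stages"][name] = n

    # 1. genome and CpG universe ------------------------------------------
    genome = GenomeSequence.from_fasta(inputs.fasta)
    genes = read_genepred(inputs.genes)
    genes_collapsed = collapse_by_name(genes)

    # 2. islands: ingest or call, then classify ---------------------------
    if inputs.cgi_bed:
        cgis = cgi_mod.load_cgis_bed(inputs.cgi_bed, genome)
    else:
        cgis = cgi_mod.call_cgis(genome)
    cgi_mod.classify_cgis(cgis, genes_collapsed)
    stage("cgi", len(cgis))

    # 3. variants ----------------------------------------------------------
    all_events = []
    catalogues = []
    for path, label in inputs.vcfs:
        ev = var_mod.load_snvs(path, source=label)
        var_mod.attach_to_cpg(ev, genome)
        all_events.extend(ev)
        catalogues.append([e for e in ev if e.is_ct])
    mutation_table = var_mod.merge_catalogues(catalogues)
    stage("variants", len(all_events))

    # 4. site table --------------------------------------------------------
    meth_records = None
    if inputs.methylation:
        meth_records = meth_mod.load_methylation(inputs.methylation)
        meth_records = meth_mod.collapse_to_sites(meth_records, genome)
    site_table = rates_mod.build_site_table(
        genome, cgis, genes_collapsed, mutation_table, meth_records
    )
    stage("sites", len(site_table))
    sites_bed = os.path.join(out_dir, "sites.bed")
    rates_mod.write_sites_bed(site_table, sites_bed)
    manifest["files"]["sites.bed"] = _checksum(sites_bed)

    af_sites = site_table[~site_table["chrom"].isin(inputs.exclude_chroms_af)]

    # 5. rates -------------------------------------------------------------
    overall = rates_mod.mutation_rate(af_sites)
    in_cgi = af_sites[af_sites["in_cgi"]]
    cgi_vs_non = rates_mod.mutation_rate(
        af_sites.assign(grp=np.where(af_sites["in_cgi"], "CGI", "non-CGI")), by="grp"
    )
    per_class = rates_mod.mutation_rate(in_cgi, by="cgi_class")
    af_weighted = rates_mod.af_weighted_rate(in_cgi, by="cgi_class")
    af_binned = rates_mod.af_binned_rates(in_cgi, by="cgi_class")
    region_split = rates_mod.region_split_rates(af_sites)
    tables.update(
        overall_rate=overall, cgi_vs_noncgi=cgi_vs_non, rate_per_class=per_class,
        af_weighted_per_class=af_weighted, af_binned_per_class=af_binned,
        region_split=region_split,
    )
    stage("rates", len(per_class))

    # 6. distance profiles -------------------------------------------------
    profile_cpg = rates_mod.distance_profile(af_sites, by_class=False)
    profile_by_class = rates_mod.distance_profile(af_sites, by_class=True)
    smoothed = []
    for cls, g in profile_by_class.groupby("cgi_class"):
        sm = rates_mod.smooth_profile(g, cgi_class=cls)
        sm.insert(0, "cgi_class", cls)
        smoothed.append(sm)
    profile_smoothed = (
        pd.concat(smoothed, ignore_index=True) if smoothed else pd.DataFrame()
    )
    tables.update(profile_cpg=profile_cpg, profile_by_class=profile_by_class,
                  profile_smoothed=profile_smoothed)
    stage("profiles", len(profile_cpg))

    # chi-squared: CGI vs non-CGI mutated counts
    r = cgi_vs_non.set_index("grp")
    if {"CGI", "non-CGI"} <= set(r.index):
        table = [
            [r.loc["CGI", "numerator"], r.loc["CGI", "denominator"] - r.loc["CGI", "numerator"]],
            [r.loc["non-CGI", "numerator"], r.loc["non-CGI", "denominator"] - r.loc["non-CGI", "numerator"]],
        ]
        tests["chi2_cgi_vs_noncgi"] = stats_mod.chi2_contingency(table)

    # 7. methylation -------------------------------------------------------
    if meth_records is not None:
        cgi_meth = meth_mod.mean_methylation_per_cgi(meth_records, cgis)
        meth_profile = meth_mod.methylation_distance_profile(af_sites, by_class=True)
        group_a, group_b, ab_stats = meth_mod.split_intragenic_coding(cgi_meth)
        tables.update(cgi_methylation=cgi_meth, methylation_profile=meth_profile,
                      intragenic_coding_groups=ab_stats)
        if len(group_a) and len(group_b):
            tests["wilcoxon_groupA_vs_B_length"] = stats_mod.wilcoxon_rank_sum(
                group_a["length"], group_b["length"]
            )
            # per-group mutation rates over the sites inside each group's islands
            rows = []
            for label, grp in (("A", group_a), ("B", group_b)):
                sel = np.zeros(len(af_sites), dtype=bool)
                for _, isl in grp.iterrows():
                    sel |= (
                        (af_sites["chrom"] == isl["chrom"]).to_numpy()
                        & (af_sites["pos"] >= isl["start"]).to_numpy()
                        & (af_sites["pos"] < isl["end"]).to_numpy()
                    )
                sub = af_sites[sel]
                rows.append({
                    "group": label,
                    "numerator": int(sub["mutated"].sum()),
                    "denominator": len(sub),
                    "rate": sub["mutated"].mean() if len(sub) else np.nan,
                })
            tables["group_rates"] = pd.DataFrame(rows)
        # paired t: intragenic-coding vs TSS-coding shore profiles
        pa = profile_by_class[profile_by_class["cgi_class"] == "INTRAGENIC_CODING"]
        pb = profile_by_class[profile_by_class["cgi_class"] == "TSS_CODING"]
        try:
            tests["paired_t_IC_vs_TSS_shores"] = stats_mod.paired_t_profiles(pa, pb)
        except ValueError as exc:
            log.warning("paired t skipped: %s", exc)
        stage("methylation", len(cgi_meth))
    else:
        manifest["skipped"].append("methylation")

    # 8. coding consequences ----------------------------------------------
    if inputs.coding_vcf and meth_records is not None:
        primed = enumerate_primed_sites(
            genome, genes, cgis, site_beta=meth_records, beta_min=0.67
        )
        coding_events = var_mod.load_ct_variants(inputs.coding_vcf, source="exome")
        primed = cross_with_observed(primed, coding_events)
        obs_prop = (
            primed.groupby(["region_class", "consequence"], observed=True)["observed"]
            .agg(["sum", "size", "mean"])
            .reset_index()
            .rename(columns={"sum": "observed", "size": "primed", "mean": "proportion"})
        )
        spectrum_ac = ac_spectrum(primed)
        tables.update(primed_sites=primed, observed_proportions=obs_prop,
                      ac_spectrum=spectrum_ac)
        # chi-squared: observed/unobserved by consequence (pooled regions)
        pooled = primed.groupby("consequence")["observed"].agg(["sum", "size"])
        if len(pooled) >= 2 and pooled["sum"].gt(0).any():
            tab = np.column_stack([pooled["sum"], pooled["size"] - pooled["sum"]])
            if (tab.sum(axis=1) > 0).all() and (tab.sum(axis=0) > 0).all():
                tests["chi2_consequence_observed"] = stats_mod.chi2_contingency(tab)
        stage("consequence", len(primed))
    else:
        manifest["skipped"].append("consequence")

    # 9. signatures --------------------------------------------------------
    rare = var_mod.rare_filter(all_events, af_max=0.01)
    if rare:
        spectrum = sig_mod.build_spectrum(rare, genome)
        sigmat = sig_mod.synthetic_signatures()
        decomp = sig_mod.decompose(spectrum, sigmat)
        tables["spectrum"] = spectrum.to_frame()
        tables["signature_weights"] = (
            decomp.weights.rename("weight").rename_axis("signature").reset_index()
        )
        manifest["stages"]["signatures"] = int(spectrum.total)
    else:
        manifest["skipped"].append("signatures")

    # island length comparison across classes (size distributions)
    lengths = {}
    for cls in cgi_mod.CGI_CLASSES:
        vals = [i.length for i in cgis if i.cgi_class == cls]
        if len(vals) >= 2:
            lengths[cls] = vals
    if len(lengths) >= 3:
        tests["kruskal_island_lengths"] = stats_mod.kruskal_wallis(*lengths.values())
        if tests["kruskal_island_lengths"].significant:
            tables["dunn_island_lengths"] = stats_mod.dunn_posthoc(lengths)

    # 10. emit -------------------------------------------------------------
    for name, df in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        _write(df, path)
        manifest["files"][f"{name}.tsv"] = _checksum(path)
    test_rows = [
        {"name": k, "test": t.test, "statistic": t.statistic, "p_value": t.p_value,
         "inputs": t.inputs}
        for k, t in tests.items()
    ]
    tests_path = os.path.join(out_dir, "tests.tsv")
    _write(pd.DataFrame(test_rows, columns=["name", "test", "statistic", "p_value", "inputs"]), tests_path)
    manifest["files"]["tests.tsv"] = _checksum(tests_path)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return PipelineResult(out_dir, site_table, tables, tests, manifest)
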