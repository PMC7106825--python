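"""Methylation track ingestion, per-island means and the hyper/hypo split."""

import numpy as np
import pandas as pd
import pytest

from cpgscape.cgi import CpGIsland
from cpgscape.methylation import (
    collapse_to_sites,
    load_methylation,
    mean_methylation_per_cgi,
    methylation_distance_profile,
    split_intragenic_coding,
)
from cpgscape.stats import wilcoxon_rank_sum

from .conftest import make_genome


def test_load_bedgraph_unit_scale(tmp_path):
    p = tmp_path / "m.bedgraph"
    p.write_text("chr1\t1000\t1002\t0.85\nchr1\t2000\t2002\t0.10\n")
    df = load_methylation(str(p))
    assert list(df.pos) == [1000, 2000]
    assert df.beta.tolist() == [0.85, 0.10]


def test_load_bedgraph_percent_autodetect(tmp_path):
    p = tmp_path / "m.bedgraph"
    p.write_text("chr1\t1000\t1002\t85\nchr1\t2000\t2002\t10\n")
    df = load_methylation(str(p))
    assert df.beta.tolist() == [0.85, 0.10]


def test_load_bedgraph_bad_beta(tmp_path):
    p = tmp_path / "m.bedgraph"
    p.write_text("chr1\t1000\t1002\t0.5\nchr1\t2000\t2002\t150\n")
    with pytest.raises(ValueError, match="beta outside"):
        load_methylation(str(p))


def test_load_methbase_reanchors_minus_strand(tmp_path):
    p = tmp_path / "m.meth"
    p.write_text("chr1\t1000\t+\tCpG\t0.8\t30\nchr1\t1001\t-\tCpG\t0.6\t20\n")
    df = load_methylation(str(p), fmt="methbase")
    assert list(df.pos) == [1000, 1000]


def test_collapse_averages_strand_duplicates():
    g = make_genome(chr1="ACGT")
    records = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "pos": [1, 2], "beta": [0.8, 0.6], "coverage": [10, 10]}
    )
    out = collapse_to_sites(records, g)
    assert len(out) == 1
    assert out.loc[0, "pos"] == 1
    assert out.loc[0, "beta"] == pytest.approx(0.7)
    assert out.loc[0, "coverage"] == 20


def _summaries(vals, cls="INTRAGENIC_CODING"):
    rows = []
    for i, (mean, length) in enumerate(vals):
        if mean is None:
            group = None
        elif mean > 0.67:
            group = "A"
        elif mean < 0.33:
            group = "B"
        else:
            group = "intermediate"
        rows.append(
            {"chrom": "chr1", "start": 1000 * i, "end": 1000 * i + length,
             "cgi_class": cls, "length": length, "mean_beta": mean,
             "n_covered": 10, "group": group}
        )
    cols = ["chrom", "start", "end", "cgi_class", "length", "mean_beta",
            "n_covered", "group"]
    return pd.DataFrame(rows, columns=cols)


def test_mean_methylation_groups():
    cgis = [CpGIsland("chr1", 0, 300), CpGIsland("chr1", 1000, 1300),
            CpGIsland("chr1", 2000, 2300), CpGIsland("chr2", 0, 300)]
    recs = pd.DataFrame(
        {
            "chrom": ["chr1"] * 11,
            "pos": [10, 20, 30, 40, 50, 1010, 1020, 1030, 1040, 1050, 2010],
            "beta": [0.9, 0.8, 0.7, 0.9, 0.8, 0.1, 0.2, 0.15, 0.1, 0.2, 0.5],
            "coverage": 10,
        }
    )
    out = mean_methylation_per_cgi(recs, cgis, min_cpgs=5)
    assert out.loc[0, "group"] == "A" and out.loc[0, "mean_beta"] == pytest.approx(0.82)
    assert out.loc[1, "group"] == "B"
    assert out.loc[2, "group"] is None  # only 1 covered CpG < min_cpgs
    assert np.isnan(out.loc[3, "mean_beta"])  # no coverage at all


def test_boundary_values_are_intermediate():
    cgis = [CpGIsland("chr1", 0, 100)]
    recs = pd.DataFrame(
        {"chrom": "chr1", "pos": [1, 2, 3, 4, 5], "beta": 0.5, "coverage": 1}
    )
    out = mean_methylation_per_cgi(recs, cgis)
    assert out.loc[0, "group"] == "intermediate"


def test_methylation_profile_flat_and_missing():
    sites = pd.DataFrame(
        {"distance": [10.0, 20.0, 10.0, -50.0], "beta": [0.5, 0.5, 0.5, np.nan],
         "mutated": False}
    )
    prof = methylation_distance_profile(sites)
    assert set(prof.distance) == {10.0, 20.0}  # uncovered distances are absent
    assert np.allclose(prof.rate, 0.5)


def test_split_intragenic_coding_partition():
    summaries = _summaries([(0.70, 400), (0.30, 1200), (0.50, 800), (None, 500)])
    a, b, stats = split_intragenic_coding(summaries)
    assert len(a) == 1 and a.loc[0, "mean_beta"] == pytest.approx(0.70)
    assert len(b) == 1 and b.loc[0, "mean_beta"] == pytest.approx(0.30)
    assert len(stats) == 2  # intermediate and ungrouped islands excluded
    other = split_intragenic_coding(_summaries([], cls="INTERGENIC"))
    assert len(other[0]) == 0 and len(other[1]) == 0


def test_demo_group_a_shorter_than_group_b(demo_bundle, demo_result):
    """Planted short/hyper-methylated vs long/hypo-methylated islands."""
    groups = demo_result.tables["intragenic_coding_groups"]
    a = groups[groups.group == "A"]["length"]
    b = groups[groups.group == "B"]["length"]
    assert a.mean() < b.mean()
    assert wilcoxon_rank_sum(a, b).p_value < 0.05


def test_demo_per_class_mean_beta_ordering(demo_bundle, demo_result):
    """Island mean betas follow the regimes the generator imposed."""
    meth = demo_result.tables["cgi_methylation"]
    by_cls = meth.groupby("cgi_class")["mean_beta"].mean()
    assert by_cls["TSS_CODING"] < 0.1
    assert by_cls["TSS_NONCODING"] < 0.15
    assert by_cls["INTRAGENIC_CODING"] > by_cls["INTERGENIC"]  # bimodal pulls the mean up
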