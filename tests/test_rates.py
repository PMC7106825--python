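"""Rate formulas against brute-force oracles; profiles and smoothing."""

import math

import numpy as np
import pandas as pd
import pytest

from cpgscape.rates import (
    af_binned_rates,
    af_weighted_rate,
    distance_profile,
    mutation_rate,
    region_split_rates,
    smooth_profile,
)


def _random_sites(rng, n=500, strata=("a", "b", "c")):
    mutated = rng.random(n) < 0.3
    af = np.where(mutated, rng.random(n), np.nan)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(n),
            "stratum": rng.choice(strata, size=n),
            "mutated": mutated,
            "af": af,
        }
    )


def test_mutation_rate_examples():
    df = pd.DataFrame({"mutated": [True] * 4 + [False] * 6, "af": np.nan})
    out = mutation_rate(df)
    assert out.loc[0, "rate"] == pytest.approx(0.4)
    zero = mutation_rate(pd.DataFrame({"mutated": [False] * 10, "af": np.nan}))
    assert zero.loc[0, "rate"] == 0.0
    assert zero.loc[0, "ci_low"] == 0.0


def test_wilson_interval_matches_closed_form():
    df = pd.DataFrame({"mutated": [True] * 260 + [False] * 740, "af": np.nan})
    out = mutation_rate(df)
    # closed-form Wilson score interval as independent oracle
    n, p, z = 1000, 0.26, 1.959963984540054
    center = (p + z**2 / (2 * n)) / (1 + z**2 / n)
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
    assert out.loc[0, "rate"] == pytest.approx(0.26)
    assert out.loc[0, "ci_low"] == pytest.approx(center - half, abs=1e-9)
    assert out.loc[0, "ci_high"] == pytest.approx(center + half, abs=1e-9)
    assert (out.loc[0, "ci_low"], out.loc[0, "ci_high"]) == pytest.approx(
        (0.2336, 0.2882), abs=5e-4
    )


def test_mutation_rate_equals_bruteforce_loop(rng):
    sites = _random_sites(rng)
    out = mutation_rate(sites, by="stratum").set_index("stratum")
    for s in ("a", "b", "c"):
        num = sum(1 for _, r in sites.iterrows() if r.stratum == s and r.mutated)
        den = sum(1 for _, r in sites.iterrows() if r.stratum == s)
        assert out.loc[s, "numerator"] == num
        assert out.loc[s, "denominator"] == den
        assert out.loc[s, "rate"] == num / den


def test_empty_stratum_row_has_missing_rate():
    df = pd.DataFrame(
        {"mutated": [True, False], "af": np.nan,
         "stratum": pd.Categorical(["a", "a"], categories=["a", "b"])}
    )
    out = mutation_rate(df, by="stratum").set_index("stratum")
    assert out.loc["b", "denominator"] == 0
    assert np.isnan(out.loc["b", "rate"])


def test_af_weighted_examples():
    df = pd.DataFrame(
        {"mutated": [True, True] + [False] * 8, "af": [0.1, 0.2] + [np.nan] * 8}
    )
    assert af_weighted_rate(df).loc[0, "rate"] == pytest.approx(0.03)
    none = pd.DataFrame({"mutated": [False] * 5, "af": np.nan})
    assert af_weighted_rate(none).loc[0, "rate"] == 0.0
    full = pd.DataFrame({"mutated": [True] * 10, "af": 1.0})
    assert af_weighted_rate(full).loc[0, "rate"] == 1.0


def test_af_weighted_missing_af_excluded_and_counted():
    df = pd.DataFrame({"mutated": [True, True], "af": [0.4, np.nan]})
    out = af_weighted_rate(df)
    assert out.loc[0, "numerator"] == pytest.approx(0.4)
    assert out.loc[0, "n_missing_af"] == 1


def test_af_weighted_dominated_by_plain_rate(rng):
    """Numerator-wise dominance: sum of afs <= count of mutated sites."""
    for _ in range(10):
        sites = _random_sites(rng, n=300)
        sites["af"] = sites["af"].fillna(0.5)  # every mutated site carries an af
        plain = mutation_rate(sites, by="stratum").set_index("stratum")["rate"]
        weighted = af_weighted_rate(sites, by="stratum").set_index("stratum")["rate"]
        assert (weighted <= plain + 1e-12).all()


def test_af_binned_partition_and_boundaries():
    df = pd.DataFrame(
        {
            "mutated": [True] * 5 + [False] * 95,
            "af": [0.03, 0.06, 0.13, 0.2, 0.9] + [np.nan] * 95,
        }
    )
    out = af_binned_rates(df).set_index("af_bin")
    assert out.loc["0<Af<0.06", "numerator"] == 1
    assert out.loc["0.06<=Af<0.12", "numerator"] == 1  # af exactly 0.06
    assert out.loc["Af=0", "numerator"] == 95
    assert out["rate"].sum() == pytest.approx(1.0)  # partition identity


def test_distance_profile_recovers_step(rng):
    n = 20000
    d = rng.integers(-5000, 5001, size=n)
    d = d[d != 0]
    p = np.where(np.abs(d) <= 2000, 0.05, 0.30)
    sites = pd.DataFrame(
        {"distance": d, "mutated": rng.random(len(d)) < p, "cgi_class": "x"}
    )
    prof = distance_profile(sites)
    near = prof[prof.distance.abs() <= 2000]
    far = prof[prof.distance.abs() > 2000]
    for band, p_true in ((near, 0.05), (far, 0.30)):
        est = band.numerator.sum() / band.denominator.sum()
        se = math.sqrt(p_true * (1 - p_true) / band.denominator.sum())
        assert abs(est - p_true) <= 3 * se


def test_distance_profile_missing_not_zero():
    sites = pd.DataFrame({"distance": [10.0, 10.0, 30.0], "mutated": [True, False, False]})
    prof = distance_profile(sites)
    assert set(prof.distance) == {10.0, 30.0}  # nothing at other distances


def test_smoothing_identity_and_windows():
    prof = pd.DataFrame(
        {"distance": np.arange(-100, 100, dtype=float),
         "rate": 0.4, "numerator": 1, "denominator": 2}
    )
    sm = smooth_profile(prof, window=20)
    assert np.allclose(sm["rate"], 0.4)
    # class-specific default windows
    sm100 = smooth_profile(prof, cgi_class="TSS_NONCODING")
    assert sm100["n_positions"].max() == 100
    sm20 = smooth_profile(prof, cgi_class="TSS_CODING")
    assert sm20["n_positions"].max() == 20


def test_smoothing_linear_ramp_gives_midpoint_means():
    d = np.arange(0, 200, dtype=float)
    prof = pd.DataFrame({"distance": d, "rate": 0.001 * d, "numerator": 0, "denominator": 1})
    sm = smooth_profile(prof, window=20)
    assert np.allclose(sm["rate"], 0.001 * sm["distance"])


def test_smoothing_partial_trailing_block():
    d = np.arange(0, 30, dtype=float)  # one full block of 20 + partial of 10
    prof = pd.DataFrame({"distance": d, "rate": 1.0, "numerator": 0, "denominator": 1})
    sm = smooth_profile(prof, window=20)
    assert list(sm["n_positions"]) == [20, 10]
    assert np.allclose(sm["rate"], 1.0)


def test_region_split_rates():
    sites = pd.DataFrame(
        {
            "cgi_class": ["TSS_CODING"] * 4 + ["NONE"] * 4,
            "in_cgi": [True] * 4 + [False] * 4,
            "coding": [True, True, False, False] * 2,
            "mutated": [True, False, False, False, True, True, False, False],
            "af": np.nan,
        }
    )
    out = region_split_rates(sites).set_index(["region", "exon_class"])
    assert out.loc[("TSS_CODING", "coding-exon"), "rate"] == pytest.approx(0.5)
    assert out.loc[("TSS_CODING", "noncoding"), "rate"] == 0.0
    assert out.loc[("NON_CGI", "coding-exon"), "denominator"] == 2


def test_strand_base_counting_mode():
    """Strand-base units double the denominator and count both orientations."""
    sites = pd.DataFrame(
        {"mutated": [True, True, False, False], "strand_events": [2, 1, 0, 0],
         "af": np.nan}
    )
    dinuc = mutation_rate(sites)
    strand = mutation_rate(sites, count_unit="strand-base")
    assert (dinuc.loc[0, "numerator"], dinuc.loc[0, "denominator"]) == (2, 4)
    assert (strand.loc[0, "numerator"], strand.loc[0, "denominator"]) == (3, 8)
    with pytest.raises(ValueError):
        mutation_rate(sites, count_unit="base-pair")


def test_write_sites_bed(tmp_path):
    from cpgscape.rates import write_sites_bed

    df = pd.DataFrame(
        {"chrom": ["chr1"], "pos": [10], "cgi_class": ["NONE"], "in_cgi": [False],
         "distance": [40.0], "coding": [False], "mutated": [True],
         "af": [0.25], "beta": [0.8]}
    )
    path = tmp_path / "sites.bed"
    write_sites_bed(df, str(path))
    fields = path.read_text().strip().split("\t")
    assert fields[:3] == ["chr1", "10", "12"]  # dinucleotide interval


def test_monotone_class_rate_recovery_at_scale():
    """With 1e5 sites per class the estimated ordering of the true class
    rates (intragenic-coding > intergenic > TSS-coding) is recovered."""
    truth = {"INTRAGENIC_CODING": 0.112, "INTERGENIC": 0.062, "TSS_CODING": 0.036}
    for seed in (1, 2, 3):
        g = np.random.default_rng(seed)
        frames = [
            pd.DataFrame({"stratum": cls, "mutated": g.random(100_000) < p,
                          "af": np.nan})
            for cls, p in truth.items()
        ]
        est = mutation_rate(pd.concat(frames), by="stratum").set_index("stratum")["rate"]
        assert est["INTRAGENIC_CODING"] > est["INTERGENIC"] > est["TSS_CODING"]


def test_profile_conservation_against_global_tallies(rng):
    """Summing per-distance tallies plus in-island sites returns the totals."""
    n = 5000
    dist = rng.integers(-4000, 4001, size=n).astype(float)
    in_cgi = rng.random(n) < 0.1
    dist[in_cgi] = np.nan
    sites = pd.DataFrame(
        {"distance": dist, "in_cgi": in_cgi, "mutated": rng.random(n) < 0.2}
    )
    prof = distance_profile(sites, max_dist=5000)
    assert prof.denominator.sum() + in_cgi.sum() == n
    assert prof.numerator.sum() + sites.loc[in_cgi, "mutated"].sum() == sites.mutated.sum()
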