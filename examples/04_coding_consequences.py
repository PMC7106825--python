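"""Negative selection on coding CpG changes: silent vs missense vs nonsense.

Enumerates every hyper-methylated (beta >= 0.67) CDS base whose deamination
is primed to cause a silent, missense or nonsense change, crosses the sites
with an exome-style catalogue, and prints the fraction observed and the
singleton (allele count = 1) fraction per consequence class.
"""

import tempfile

from cpgscape.pipeline import PipelineInputs, run_pipeline
from cpgscape.synthetic import SyntheticConfig, generate

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate(SyntheticConfig(seed=7), f"{tmp}/bundle")
    res = run_pipeline(
        PipelineInputs(
            fasta=bundle.paths["fasta"],
            genes=bundle.paths["genes"],
            vcfs=[(bundle.paths["wgs_vcf"], "wgs")],
            methylation=bundle.paths["methylation"],
            coding_vcf=bundle.paths["coding_vcf"],
        ),
        f"{tmp}/out",
    )

    primed = res.tables["primed_sites"]
    print("observed fraction per consequence (pooled regions):")
    print(primed.groupby("consequence")["observed"].agg(["size", "mean"]).to_string())
    print("\nallele-count spectrum (proportion per bin within consequence):")
    print(res.tables["ac_spectrum"].to_string(index=False))
    chi2 = res.tests.get("chi2_consequence_observed")
    if chi2:
        print(f"\nchi-squared (observed x consequence): "
              f"{chi2.statistic:.2f}, p = {chi2.p_value:.3g}")

# Silent-primed sites are observed most often and nonsense-primed least —
# the footprint of negative selection the generator emulates; nonsense
# variants that are observed skew toward singletons (lowest allele counts).
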