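"""Coverage-filter the acreage reports and compute bag-of-alleles
county-year allele frequencies.

County-years where fewer than 80% of grown varieties are genotyped are
dropped (inclusive threshold, count mode); the rest get the
acreage-weighted frequency vector c_j = sum_i A_i m_ij. Writes
allele_freqs.csv and coverage_report.csv under results/run/.
"""

from ricegxw.pipeline import run_aggregate

OUTDIR = "results/run"

if __name__ == "__main__":
    counts = run_aggregate(OUTDIR, threshold=0.8, mode="count")
    kept, total = counts["county_years_retained"], counts["county_years_in"]
    print(f"coverage filter: {kept}/{total} county-years retained ({kept / total:.0%})")
    print("wrote allele_freqs.csv and coverage_report.csv")
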