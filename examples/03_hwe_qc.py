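"""Hardy-Weinberg equilibrium QC on genotype counts.

Systematic deviation from the p^2 / 2pq / q^2 proportions flags calling
error.  The test is a 1-df chi-square with the allele frequency estimated
from the data.
"""

from augcall.evaluation import GenotypeCounts, hwe_chi_square, minor_allele_frequency

snps = {
    "in_equilibrium": GenotypeCounts(25, 50, 25),
    "het_deficit": GenotypeCounts(30, 40, 30),
    "monomorphic": GenotypeCounts(100, 0, 0),
    "severe_het_loss": GenotypeCounts(45, 10, 45),
}

for name, counts in snps.items():
    res = hwe_chi_square(counts)
    maf = minor_allele_frequency(counts)
    print(
        f"{name:>16}: MAF={maf:.3f}  chi2={res.chi_square:7.3f}  "
        f"p={res.p_value:.3g}"
    )
# A het deficit relative to 2pq inflates chi2; p below ~1e-4 is the usual
# QC exclusion threshold for a called SNP.
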