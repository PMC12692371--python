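"""Published contingency tables for the Greek late-onset FECD case-control
study (36 patients, 58 controls) at the two *TCF4* loci.

These printed counts are input data: they let the association module be run
against the study's reported tables without access to per-subject records
(which were never deposited).  Per-subject covariates (sex, age) are not
public, so odds ratios computed from these counts are unadjusted.
"""

from __future__ import annotations

from .stats import GenotypeCounts

__all__ = [
    "EXPANSION_COUNTS",
    "SNP_COUNTS",
    "COHORT_N_CASES",
    "COHORT_N_CONTROLS",
    "GEL_BAND_COUNTS",
]

COHORT_N_CASES = 36
COHORT_N_CONTROLS = 58

#: CTG18.1 expansion genotype counts (N/N, N/X, X/X) per status.
EXPANSION_COUNTS = GenotypeCounts(
    controls=(55, 3, 0),
    cases=(16, 17, 3),
    genotype_labels=("N/N", "N/X", "X/X"),
)

#: rs613872 SNP genotype counts (T/T, G/T, G/G) per status; G is the risk allele.
SNP_COUNTS = GenotypeCounts(
    controls=(38, 20, 0),
    cases=(14, 15, 7),
    genotype_labels=("T/T", "G/T", "G/G"),
)

#: STR-PCR gel band counts per status: {status: (two bands, one band, no band)}.
#: Two bands = both normal alleles amplified; one band = homozygote or
#: expanded-allele dropout; no band = biallelic dropout (X/X).
GEL_BAND_COUNTS = {
    "control": (55, 3, 0),
    "case": (16, 17, 3),
}
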