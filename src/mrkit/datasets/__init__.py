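"""Packaged instrument tables for the serum-mineral → heart-failure analysis.

The two TSVs transcribe the published instrument table: seven SNPs reaching
genome-wide significance for serum calcium (from a GWAS meta-analysis of
61,079 European-ancestry individuals, jointly explaining 0.9% of calcium
variance) and six for serum magnesium (23,829 individuals, 1.6% of variance),
each paired with its log-odds association with all-cause heart failure from
the UK Biobank GWAS (394,156 participants, 6,504 cases). Exposure and outcome
effects are pre-harmonized to the exposure effect allele, so the other-allele
column is empty. rs7965584's outcome association was read off the LD proxy
rs10858938 (r² = 0.95), recorded as metadata.
"""

from __future__ import annotations

from importlib import resources

from ..summary import ExclusionSet, ExposureSpec, InstrumentSet, read_instrument_table

#: Serum calcium: SD 0.5 mg/dl, instrument R² 0.9%.
CALCIUM = ExposureSpec(name="calcium", sd_value=0.5, sd_units="mg/dl", variance_explained=0.009)

#: Serum magnesium: SD constant 0.1 (source units as published), instrument R² 1.6%.
MAGNESIUM = ExposureSpec(name="magnesium", sd_value=0.1, sd_units="mmol/dl", variance_explained=0.016)

#: Outcome GWAS sample: UK Biobank all-cause heart failure.
HEART_FAILURE_N_TOTAL = 394_156
HEART_FAILURE_N_CASES = 6_504


def _load(filename: str, exposure: ExposureSpec) -> InstrumentSet:
    with resources.as_file(resources.files(__package__) / filename) as path:
        return read_instrument_table(path, exposure, label=exposure.name)


def calcium_instruments() -> InstrumentSet:
    """The 7-SNP serum-calcium instrument set with heart-failure outcome betas."""
    return _load("calcium_hf.tsv", CALCIUM)


def magnesium_instruments() -> InstrumentSet:
    """The 6-SNP serum-magnesium instrument set with heart-failure outcome betas."""
    return _load("magnesium_hf.tsv", MAGNESIUM)


def pleiotropy_exclusions() -> tuple[ExclusionSet, ...]:
    """Sensitivity exclusion sets from the phenome-wide pleiotropy screen.

    Three horizontal-pleiotropy sets are re-run without the named SNPs; the
    blood-pressure association of rs448378 is classified as vertical (mediated
    by magnesium itself) so that SNP is retained and its set is documentation
    only.
    """
    return (
        ExclusionSet(
            name="shroom3",
            rsids=("rs13146355",),
            rationale="SHROOM3 locus associated with kidney function; "
            "the only single SNP associated with heart failure",
            pleiotropy_class="horizontal",
        ),
        ExclusionSet(
            name="kidney_function",
            rsids=("rs3925584", "rs13146355"),
            rationale="DCDC5 and SHROOM3 loci associated with kidney function",
            pleiotropy_class="horizontal",
        ),
        ExclusionSet(
            name="metabolic_syndrome",
            rsids=("rs780094",),
            rationale="GCKR locus associated with the metabolic syndrome and its "
            "components (lipids, fasting glucose/insulin, type 2 diabetes)",
            pleiotropy_class="horizontal",
        ),
        ExclusionSet(
            name="blood_pressure",
            rsids=("rs448378",),
            rationale="MDS1 locus associated with blood pressure; magnesium lowers "
            "blood pressure in trials, so this is vertical pleiotropy and the SNP is retained",
            pleiotropy_class="vertical",
        ),
    )
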