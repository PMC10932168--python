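"""Published summary statistics of the reference case-control study.

The reference study profiled DNA double-strand-break (DSB) repair in
peripheral blood mononuclear cells from 45 rheumatoid-arthritis (RA)
patients and 45 healthy controls: a bleomycin-challenge comet assay scored
per-subject repair efficiency (RepEff), TaqMan assays genotyped a panel of
17 SNPs in homologous-recombination (HR), non-homologous end-joining (NHEJ)
and other DSB-response genes, and qPCR measured the expression of seven
DSB-repair genes relative to the RPLP1 reference gene.

Only arm-level summaries were published (no individual-level data), so the
constants below are the calibration targets for the synthetic-cohort
generator and the desk-scale inputs for the reproduction tests: per-arm
genotype counts for each SNP, the 2 x 4 repair-group distribution, the
repair-group bin edges, and per-arm median expression folds.
"""

from __future__ import annotations

ARMS = ("control", "case")

#: Ordinal repair-efficiency groups, 1 = best repair.
GROUP_LABELS = {
    1: "highly efficient DNA repair",
    2: "efficient DNA repair",
    3: "marginally efficient DNA repair",
    4: "no DNA repair",
}

#: Subjects per repair group (groups 1..4) in each study arm.
REPAIR_GROUP_COUNTS = {
    "control": (12, 11, 11, 11),
    "case": (1, 1, 5, 38),
}

#: Percent-repaired cut points separating groups 4|3, 3|2 and 2|1.
#: Midpoints of the published rounded group ranges (<65, 65.1-78.6,
#: 78.7-83.3, >83.4), which contain one-decimal rounding gaps.
REPAIR_BIN_EDGES = (65.05, 78.65, 83.35)

#: SNP panel with per-arm genotype counts.  Genotype order is as published,
#: first genotype = reference category for odds ratios.
SNP_TABLE = (
    {
        "snp_id": "rs3218536", "gene": "XRCC2", "pathway": "DSB",
        "alleles": ("C", "T"), "genotypes": ("C/C", "C/T", "T/T"),
        "control": (3, 41, 1), "case": (1, 43, 1),
    },
    {
        "snp_id": "rs1801320", "gene": "RAD51", "pathway": "HR",
        "alleles": ("G", "C"), "genotypes": ("G/G", "G/C", "C/C"),
        "control": (32, 2, 11), "case": (19, 8, 18),
    },
    {
        "snp_id": "rs7180135", "gene": "RAD51", "pathway": "HR",
        "alleles": ("A", "G"), "genotypes": ("G/G", "A/G", "A/A"),
        "control": (5, 22, 18), "case": (4, 31, 10),
    },
    {
        "snp_id": "rs45549040", "gene": "RAD51", "pathway": "HR",
        "alleles": ("A", "C"), "genotypes": ("A/A", "A/C", "C/C"),
        "control": (41, 3, 1), "case": (43, 0, 2),
    },
    {
        "snp_id": "rs1801321", "gene": "RAD51", "pathway": "HR",
        "alleles": ("G", "T"), "genotypes": ("G/G", "G/T", "T/T"),
        "control": (17, 9, 19), "case": (7, 11, 27),
    },
    {
        "snp_id": "rs2619681", "gene": "RAD51", "pathway": "HR",
        "alleles": ("C", "T"), "genotypes": ("C/C", "C/T", "T/T"),
        "control": (30, 13, 2), "case": (30, 13, 2),
    },
    {
        "snp_id": "rs963917", "gene": "RAD51B", "pathway": "HR",
        "alleles": ("A", "G"), "genotypes": ("G/G", "A/G", "A/A"),
        "control": (12, 23, 10), "case": (26, 17, 2),
    },
    {
        "snp_id": "rs963918", "gene": "RAD51B", "pathway": "HR",
        "alleles": ("C", "T"), "genotypes": ("C/C", "C/T", "T/T"),
        "control": (7, 17, 21), "case": (5, 26, 14),
    },
    {
        "snp_id": "rs3784099", "gene": "RAD51B", "pathway": "HR",
        "alleles": ("A", "G"), "genotypes": ("G/G", "A/G", "A/A"),
        "control": (30, 11, 4), "case": (20, 23, 2),
    },
    {
        "snp_id": "rs10483813", "gene": "RAD51B", "pathway": "HR",
        "alleles": ("A", "T"), "genotypes": ("T/T", "A/T", "A/A"),
        "control": (34, 8, 3), "case": (33, 11, 1),
    },
    {
        "snp_id": "rs1042522", "gene": "TP53", "pathway": "DSB",
        "alleles": ("C", "G"), "genotypes": ("C/C", "C/G", "G/G"),
        "control": (21, 11, 13), "case": (26, 14, 5),
    },
    {
        "snp_id": "rs1051669", "gene": "RAD52", "pathway": "DSB",
        "alleles": ("C", "T"), "genotypes": ("C/C", "C/T", "T/T"),
        "control": (31, 14, 0), "case": (25, 19, 1),
    },
    {
        "snp_id": "rs2155209", "gene": "MRE11A", "pathway": "DSB",
        "alleles": ("C", "T"), "genotypes": ("T/T", "C/T", "C/C"),
        "control": (15, 19, 11), "case": (15, 26, 4),
    },
    {
        "snp_id": "rs132774", "gene": "XRCC6", "pathway": "NHEJ",
        "alleles": ("C", "G"), "genotypes": ("G/G", "C/G", "C/C"),
        "control": (20, 13, 12), "case": (16, 18, 11),
    },
    {
        "snp_id": "rs207906", "gene": "XRCC5", "pathway": "NHEJ",
        "alleles": ("A", "G"), "genotypes": ("G/G", "A/G", "A/A"),
        "control": (33, 8, 4), "case": (29, 12, 4),
    },
    {
        "snp_id": "rs7003908", "gene": "PRKDC", "pathway": "NHEJ",
        "alleles": ("A", "C"), "genotypes": ("A/A", "A/C", "C/C"),
        "control": (14, 27, 4), "case": (10, 25, 10),
    },
    {
        "snp_id": "rs861539", "gene": "XRCC3", "pathway": "HR",
        "alleles": ("A", "G"), "genotypes": ("G/G", "A/G", "A/A"),
        "control": (33, 4, 8), "case": (39, 1, 5),
    },
)

SNP_IDS = tuple(row["snp_id"] for row in SNP_TABLE)

#: qPCR reference gene used for the delta-Ct normalisation.
REFERENCE_GENE = "RPLP1"

#: Published per-arm median expression folds (2^-dCt vs RPLP1).  RAD51B,
#: BRCA1 and BRCA2 were significantly elevated in RA; H2AFX showed a
#: non-significant downward trend; RAD51, ATM and PRKDC did not differ
#: (no medians were published for those three, so a single plausible
#: median is used for both arms).
EXPRESSION_MEDIANS = {
    "RAD51B": {"control": 0.00213, "case": 0.0069},
    "BRCA1": {"control": 0.004, "case": 0.008},
    "BRCA2": {"control": 0.00057, "case": 0.001},
    "RAD51": {"control": 0.01, "case": 0.01},
    "ATM": {"control": 0.02, "case": 0.02},
    "PRKDC": {"control": 0.005, "case": 0.005},
    "H2AFX": {"control": 0.046, "case": 0.037},
}

EXPRESSION_GENES = tuple(EXPRESSION_MEDIANS)


def snp_row(snp_id: str) -> dict:
    """Return the panel row for ``snp_id`` (KeyError if absent)."""
    for row in SNP_TABLE:
        if row["snp_id"] == snp_id:
            return row
    raise KeyError(snp_id)
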