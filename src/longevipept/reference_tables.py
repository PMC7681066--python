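"""Published reference values from the MrOS serum-proteomics longevity study.

The study compared 554 community-dwelling men who reached the 90th percentile
of expected age for their birth cohort ("long-lived") against 642 who died
earlier, using 3831 label-free LC-IMS-MS serum peptides mapping to 224
proteins.  Two published tables are reproduced here as plain data:

* the 25 "tier 1" longevity-associated proteins (signed meta-analyzed fold
  change and posterior sign-error probability, with the number of peptides
  quantified per protein), and
* the age-adjusted mortality hazard ratios (per SD of abundance) for the
  same 25 proteins in the full proteomics cohort (N = 2473).

These values serve two purposes in this package: they are the default
ground-truth effect sizes for the paper-scale synthetic cohort (the
generator plants exactly these fold changes on 25 signal proteins), and
they are the benchmark inputs for the selection-rule arithmetic checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Gene symbol, UniProt short name, number of quantified peptides,
# signed meta fold change, meta-p (posterior sign-error probability).
TIER1_ASSOCIATIONS: list[tuple[str, str, int, float, float]] = [
    ("C9", "CO9", 19, -1.217, 0.0002),
    ("S100A9", "S10A9", 3, -1.206, 0.0700),
    ("CD163", "C163A", 5, -1.179, 0.0179),
    ("CRP", "CRP", 6, -1.170, 0.0183),
    ("IGHM", "IGHM", 19, -1.157, 0.0002),
    ("C7", "CO7", 49, -1.150, 0.0001),
    ("FCGR3A", "FCG3A", 4, -1.148, 0.0984),
    ("LGALS3BP", "LG3BP", 14, -1.148, 0.0002),
    ("NRP1", "NRP1", 3, -1.140, 0.0966),
    ("ALCAM", "CD166", 4, -1.139, 0.0535),
    ("GPLD1", "PHLD", 7, -1.136, 0.0239),
    ("B2M", "B2MG", 7, -1.133, 0.0133),
    ("A2M", "A2MG", 21, -1.133, 0.0002),
    ("MMP2", "MMP2", 5, -1.132, 0.0286),
    ("VWF", "VWF", 58, -1.120, 0.0001),
    ("CSF1R", "CSF1R", 5, -1.119, 0.0390),
    ("HPR", "HPTR", 13, -1.117, 0.0003),
    ("CFD", "CFAD", 7, -1.111, 0.0078),
    ("CD5L", "CD5L", 6, -1.111, 0.0788),
    ("FCGBP", "FCGBP", 34, -1.108, 0.0001),
    ("IGHG3", "IGHG3", 13, -1.106, 0.0014),
    ("F2", "THRB", 53, -1.104, 0.0001),
    ("CST3", "CYTC", 7, -1.102, 0.0569),
    ("PTGDS", "PTGDS", 4, -1.101, 0.0826),
    ("MCAM", "MUC18", 7, -1.101, 0.0445),
]

# Gene symbol, age-adjusted mortality hazard ratio per SD, p-value upper
# bound as printed ("<0.0001" stored as 0.0001).
MORTALITY_HAZARD_RATIOS: list[tuple[str, float, float]] = [
    ("A2M", 1.18, 0.0001),
    ("B2M", 1.20, 0.0001),
    ("CD163", 1.03, 0.2891),
    ("ALCAM", 1.14, 0.0001),
    ("CD5L", 1.08, 0.0109),
    ("CFD", 1.16, 0.0001),
    ("C7", 1.32, 0.0001),
    ("C9", 1.22, 0.0001),
    ("CRP", 1.17, 0.0001),
    ("CSF1R", 1.15, 0.0001),
    ("CST3", 1.21, 0.0001),
    ("FCGR3A", 1.14, 0.0001),
    ("FCGBP", 1.14, 0.0001),
    ("HPR", 1.11, 0.0001),
    ("IGHG3", 1.10, 0.0001),
    ("LGALS3BP", 1.16, 0.0001),
    ("MMP2", 1.13, 0.0001),
    ("MCAM", 1.07, 0.0142),
    ("IGHM", 1.08, 0.0030),
    ("NRP1", 1.14, 0.0001),
    ("GPLD1", 1.15, 0.0001),
    ("PTGDS", 1.16, 0.0001),
    ("S100A9", 1.13, 0.0001),
    ("F2", 1.11, 0.0001),
    ("VWF", 1.15, 0.0001),
]


def tier1_table() -> pd.DataFrame:
    """Return the published tier-1 association table as a DataFrame."""
    return pd.DataFrame(
        TIER1_ASSOCIATIONS,
        columns=["gene", "uniprot", "n_peptides", "meta_fold", "meta_p"],
    )


def mortality_table() -> pd.DataFrame:
    """Return the published age-adjusted mortality hazard-ratio table."""
    return pd.DataFrame(
        MORTALITY_HAZARD_RATIOS, columns=["gene", "hazard_ratio", "p_value"]
    )


def tier1_log10_effects() -> np.ndarray:
    """Signed log10 group effects implied by the published fold changes.

    A signed fold f (|f| >= 1) maps back to sign(f) * log10(|f|); these are
    the default planted effects for the 25 signal proteins of the
    paper-scale synthetic cohort.
    """
    folds = np.array([row[3] for row in TIER1_ASSOCIATIONS])
    return np.sign(folds) * np.log10(np.abs(folds))


def tier1_peptide_counts() -> np.ndarray:
    """Published per-protein peptide counts for the 25 tier-1 proteins."""
    return np.array([row[2] for row in TIER1_ASSOCIATIONS], dtype=int)
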