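"""Shipped 26-SNP placeholder panel and its generative allele frequencies.

The published 26-variant susceptibility panel lives in an access-controlled
repository, so the package ships a *synthetic* stand-in: 26 biallelic SNPs
with odds ratios on the scale typical of genome-wide-significant complex-
disease hits (1.11-1.98) and moderate allele frequencies, chosen so the raw
weighted score of a random individual has mean ~5.9 and variance ~1.2 —
i.e. a score distribution on the same scale as the study's (case mean 6.3,
control mean 5.4, range roughly 3.5-9.8).

To analyse real data, substitute the published panel: write it as a weights
TSV (columns ``snp_id, chrom, pos, effect_allele, other_allele, or``) and
pass it wherever a panel path is accepted; nothing in the pipeline assumes
this placeholder.
"""

from __future__ import annotations

import numpy as np

from .io_formats import WeightEntry, WeightPanel

__all__ = ["default_panel", "default_allele_freqs"]

# (chrom, pos, effect, other, odds_ratio, allele_freq) — synthetic placeholders
_PANEL_ROWS = [
    ("1", 1_100_000, "A", "G", 1.98, 0.48),
    ("1", 2_300_000, "C", "T", 1.84, 0.23),
    ("2", 1_700_000, "G", "A", 1.70, 0.39),
    ("2", 4_800_000, "T", "C", 1.63, 0.22),
    ("3", 3_500_000, "A", "C", 1.57, 0.50),
    ("4", 2_900_000, "C", "G", 1.52, 0.41),
    ("5", 5_200_000, "T", "A", 1.48, 0.54),
    ("6", 1_400_000, "G", "T", 1.44, 0.16),
    ("6", 6_600_000, "A", "G", 1.40, 0.60),
    ("7", 2_100_000, "C", "T", 1.37, 0.52),
    ("7", 7_300_000, "G", "A", 1.34, 0.35),
    ("8", 3_800_000, "T", "C", 1.31, 0.31),
    ("8", 8_100_000, "A", "C", 1.29, 0.29),
    ("9", 1_900_000, "C", "G", 1.27, 0.18),
    ("10", 4_400_000, "T", "A", 1.25, 0.62),
    ("11", 2_600_000, "G", "T", 1.23, 0.42),
    ("11", 9_500_000, "A", "G", 1.21, 0.44),
    ("12", 3_200_000, "C", "T", 1.20, 0.27),
    ("13", 5_700_000, "G", "A", 1.18, 0.46),
    ("14", 1_600_000, "T", "C", 1.17, 0.25),
    ("15", 6_900_000, "A", "C", 1.16, 0.63),
    ("16", 2_400_000, "C", "G", 1.15, 0.58),
    ("17", 4_100_000, "T", "A", 1.14, 0.20),
    ("18", 3_000_000, "G", "T", 1.13, 0.56),
    ("19", 1_200_000, "A", "G", 1.12, 0.33),
    ("21", 2_800_000, "C", "T", 1.11, 0.37),
]


def default_panel() -> WeightPanel:
    """The shipped synthetic 26-SNP panel."""
    entries = tuple(
        WeightEntry(
            snp_id=f"snp{i + 1:02d}",
            chrom=chrom,
            pos=pos,
            effect_allele=eff,
            other_allele=oth,
            odds_ratio=orr,
        )
        for i, (chrom, pos, eff, oth, orr, _) in enumerate(_PANEL_ROWS)
    )
    return WeightPanel(entries)


def default_allele_freqs() -> np.ndarray:
    """Effect-allele frequencies matching :func:`default_panel`, in order."""
    return np.array([row[5] for row in _PANEL_ROWS], dtype=float)
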