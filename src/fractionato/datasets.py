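"""Published observational inputs bundled as data.

Two small tables from the maize fractionation study are carried as plain
data so the statistics built on them can be recomputed: the nine-region
deletion-count table (under/over-fractionated homeolog per sorghum region)
and the sixteen exon-internal deletions with their flanking direct repeats.
The numbers here are the study's *inputs* (counts, labels, sequences, gap
sizes as printed); every statistic derived from them — p-values, bias
ratios, footprint fractions, gap summaries — is computed by the package at
run time.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "NINE_REGION_DELETIONS",
    "EXON_DELETIONS",
    "WORKED_EXAMPLE_RAW_CODE",
    "nine_region_frame",
    "exon_deletion_frame",
]

#: The 13-gene worked-example stretch of region Sb2 (14 symbols as printed).
WORKED_EXAMPLE_RAW_CODE = "B021BB2DDDB10B"


@dataclass(frozen=True)
class RegionDeletionCounts:
    """Deletion bookkeeping for one of the nine control regions."""

    region_id: str
    under_chromosome: str
    over_chromosome: str
    tie: bool
    deletions_under: int
    deletions_over: int
    retained: int
    total_shared: int


#: Nine representative long sorghum regions: deletions per homeolog,
#: retained (B) genes and total shared genes.  For Sb8 the two homeologs
#: are tied, so the under/over designation is arbitrary.
NINE_REGION_DELETIONS: tuple[RegionDeletionCounts, ...] = (
    RegionDeletionCounts("Sb1", "Zm1", "Zm9", False, 17, 47, 105, 169),
    RegionDeletionCounts("Sb2", "Zm7", "Zm2", False, 26, 36, 29, 91),
    RegionDeletionCounts("Sb3", "Zm3", "Zm8", False, 19, 29, 45, 93),
    RegionDeletionCounts("Sb4", "Zm5", "Zm4", False, 7, 54, 45, 106),
    RegionDeletionCounts("Sb6", "Zm2", "Zm10", False, 34, 53, 81, 168),
    RegionDeletionCounts("Sb7", "Zm6", "Zm4", False, 14, 44, 38, 96),
    RegionDeletionCounts("Sb8", "Zm1", "Zm3", True, 11, 11, 4, 26),
    RegionDeletionCounts("Sb9", "Zm6", "Zm8", False, 28, 77, 93, 198),
    RegionDeletionCounts("Sb10", "Zm5", "Zm6", False, 25, 69, 86, 180),
)


@dataclass(frozen=True)
class ExonDeletionRecord:
    """One exon-internal deletion in a maize homeolog.

    ``repeat`` is the direct repeat found flanking the deletion in the
    intact homeolog ("" where none was found); ``gap_size`` is the deletion
    length in bp; the chromosome fields say where the gapped copy sits
    relative to the region's over-fractionated homeolog.
    """

    sorghum_gene: str
    ungapped_chromosome: int
    gapped_chromosome: int
    over_fractionated_chromosome: int
    repeat: str
    gap_size: int


#: Sixteen fully flanked exon-internal deletions across eight genes.
EXON_DELETIONS: tuple[ExonDeletionRecord, ...] = (
    ExonDeletionRecord("Sb01g039030", 1, 9, 9, "CGAT", 12),
    ExonDeletionRecord("Sb01g039030", 1, 9, 9, "GAAG", 12),
    ExonDeletionRecord("Sb01g039030", 1, 9, 9, "", 14),
    ExonDeletionRecord("Sb01g039030", 1, 9, 9, "AGG", 5),
    ExonDeletionRecord("Sb06g019130", 2, 10, 10, "", 8),
    ExonDeletionRecord("Sb06g019400", 2, 10, 10, "", 19),
    ExonDeletionRecord("Sb09g023600", 6, 8, 8, "CGCCGAGAAGGCCA", 55),
    ExonDeletionRecord("Sb09g023840", 6, 8, 8, "CCGCCT", 9),
    ExonDeletionRecord("Sb09g023840", 6, 8, 8, "", 8),
    ExonDeletionRecord("Sb09g023840", 6, 8, 8, "CCC", 9),
    ExonDeletionRecord("Sb09g023840", 6, 8, 8, "", 9),
    ExonDeletionRecord("Sb10g029310", 6, 5, 6, "CTTAAGAGCGATACCGTGCATCTG", 178),
    ExonDeletionRecord("Sb10g030110 (1)", 5, 6, 6, "CCCGT", 27),
    ExonDeletionRecord("Sb10g030110 (2)", 5, 6, 6, "", 12),
    ExonDeletionRecord("Sb10g030110 (2)", 5, 6, 6, "GGACT", 9),
    ExonDeletionRecord("Sb10g030776", 5, 6, 6, "GAAAC", 27),
)


def nine_region_frame() -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in NINE_REGION_DELETIONS])


def exon_deletion_frame() -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in EXON_DELETIONS])
    df["repeat_length"] = df["repeat"].str.len()
    df["gapped_on_over"] = df["gapped_chromosome"] == df["over_fractionated_chromosome"]
    return df
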