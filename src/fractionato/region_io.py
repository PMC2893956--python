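"""Reading, validating, condensing and reducing fractionation code strings.

After a whole-genome duplication, each gene of the outgroup (here sorghum)
maps to two homeologous positions in the duplicated genome (maize).  The
retention status of every outgroup gene is written as one symbol:

======  =====================================================
symbol  meaning
======  =====================================================
``B``   retained on both homeologs
``1``   retained only on homeolog 1 (deleted from homeolog 2)
``2``   retained only on homeolog 2 (deleted from homeolog 1)
``0``   found on neither homeolog
``D``   local (tandem) duplicate of a nearby mother gene
``N``   invalid / unusable annotation
======  =====================================================

A region's string of symbols is the raw input of the whole pipeline.  The
*reduced* form drops ``D``/``N``/``0`` (and optionally implausibly long runs
of ``1`` or ``2``, which are putative segmental translocations rather than
deletions) and trims the ends so the region begins and ends with a ``B``.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "CODE_ALPHABET",
    "GeneRecord",
    "RegionCode",
    "CodeTable",
    "CodeParseError",
    "UntrimmableRegionError",
    "parse_code_string",
    "condense_tandem_arrays",
    "reduce_region",
    "read_code_table",
    "write_code_table",
    "read_code_fasta",
    "regions_from_table",
]

logger = logging.getLogger("fractionato")
if not logger.handlers:  # default: structured discard log on stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.WARNING)

#: Valid retention symbols.
CODE_ALPHABET = frozenset("B120DN")

#: Default ceiling on plausible deletion runs; longer runs of 1s or 2s are
#: treated as segmental translocations and dropped ("strictly greater than").
DEFAULT_LONG_RUN_THRESHOLD = 9


class CodeParseError(ValueError):
    """A code string or table contained an invalid symbol."""


class UntrimmableRegionError(ValueError):
    """A region contains no retained (B) gene, so it cannot be trimmed."""


@dataclass(frozen=True)
class GeneRecord:
    """One outgroup gene with its retention code.

    Parameters
    ----------
    gene_id : str
        Identifier of the sorghum gene (or a synthesized placeholder).
    position : int
        0-based index in outgroup gene order.
    code : str
        One symbol of :data:`CODE_ALPHABET`.
    family_id : str, optional
        Tandem-array family label, where known.
    """

    gene_id: str
    position: int
    code: str
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.code not in CODE_ALPHABET:
            raise CodeParseError(
                f"invalid code {self.code!r} for gene {self.gene_id!r}"
            )


@dataclass(frozen=True)
class RegionCode:
    """An ordered run of :class:`GeneRecord` for one orthologous region."""

    region_id: str
    genes: tuple[GeneRecord, ...]
    homeolog_labels: tuple[str, str] = ("homeolog1", "homeolog2")
    reduced: bool = False

    def __post_init__(self) -> None:
        positions = [g.position for g in self.genes]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(
                f"region {self.region_id!r}: positions must be strictly increasing"
            )
        if self.reduced:
            codes = self.code_string
            if codes and (set(codes) - set("B12") or codes[0] != "B" or codes[-1] != "B"):
                raise ValueError(
                    f"region {self.region_id!r} marked reduced but code is {codes!r}"
                )

    @property
    def code_string(self) -> str:
        return "".join(g.code for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def count(self, symbol: str) -> int:
        return self.code_string.count(symbol)


@dataclass
class CodeTable:
    """Long-format rows of (region_id, gene_id, code) plus provenance."""

    rows: pd.DataFrame  # columns: region_id, gene_id, code, family_id
    source: Optional[str] = None
    parse_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"region_id", "gene_id", "code"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"code table missing columns: {sorted(missing)}")
        if "family_id" not in self.rows.columns:
            self.rows = self.rows.assign(family_id=pd.NA)
        bad = ~self.rows["code"].isin(sorted(CODE_ALPHABET))
        if bad.any():
            first = self.rows[bad].iloc[0]
            raise CodeParseError(
                f"invalid code {first['code']!r} for gene {first['gene_id']!r}"
            )
        dup = self.rows.duplicated(subset=["region_id", "gene_id"])
        if dup.any():
            first = self.rows[dup].iloc[0]
            raise ValueError(
                f"duplicate (region_id, gene_id): ({first['region_id']!r}, "
                f"{first['gene_id']!r})"
            )

    def region_ids(self) -> list[str]:
        return list(dict.fromkeys(self.rows["region_id"]))


def _canonical(symbol: str) -> str:
    # The Dataset S1 legend writes letter "O" for digit "0"; accept both.
    s = symbol.upper()
    return "0" if s == "O" else s


def parse_code_string(
    raw: str, region_id: str = "region", gene_ids: Optional[Sequence[str]] = None
) -> RegionCode:
    """Parse one raw code string into a :class:`RegionCode`.

    Case-insensitive; whitespace is rejected.  Positions are assigned
    0..len-1 in input order and ``reduced`` is False.

    >>> parse_code_string("B021BB2DDDB10B").code_string
    'B021BB2DDDB10B'
    """
    if not raw:
        raise CodeParseError("empty code string")
    genes = []
    for i, ch in enumerate(raw):
        c = _canonical(ch)
        if c not in CODE_ALPHABET:
            raise CodeParseError(
                f"invalid code character {ch!r} at position {i} in region {region_id!r}"
            )
        gid = gene_ids[i] if gene_ids is not None else f"{region_id}_g{i:05d}"
        genes.append(GeneRecord(gene_id=gid, position=i, code=c))
    return RegionCode(region_id=region_id, genes=tuple(genes))


def condense_tandem_arrays(
    genes: Sequence[GeneRecord], max_interrupters: int = 3
) -> list[GeneRecord]:
    """Collapse tandem gene arrays onto a single mother gene.

    Within each maximal cluster of genes sharing a ``family_id`` and
    separated pairwise by at most ``max_interrupters`` unrelated genes, the
    leftmost gene keeps its code and every other member is recoded ``D``.
    Interrupter genes are untouched.
    """
    if max_interrupters < 0:
        raise ValueError("max_interrupters must be >= 0")
    out = list(genes)
    last_seen: dict[str, int] = {}  # family -> index in `genes` of cluster tail
    mother: dict[str, int] = {}  # family -> index of current cluster mother
    for i, g in enumerate(out):
        fam = g.family_id
        if fam is None:
            continue
        prev = last_seen.get(fam)
        if prev is not None and (i - prev - 1) <= max_interrupters:
            out[i] = replace(g, code="D")
            logger.info(
                "condense: %s recoded D (duplicate of %s)",
                g.gene_id,
                out[mother[fam]].gene_id,
            )
        else:
            mother[fam] = i  # new cluster; this gene is the mother
        last_seen[fam] = i
    return out


def _drop_long_runs(codes: list[GeneRecord], threshold: int) -> list[GeneRecord]:
    """Remove maximal runs of identical 1s or 2s strictly longer than *threshold*."""
    kept: list[GeneRecord] = []
    i = 0
    while i < len(codes):
        j = i
        while j < len(codes) and codes[j].code == codes[i].code:
            j += 1
        run = codes[i:j]
        if codes[i].code in "12" and len(run) > threshold:
            logger.info(
                "reduce: dropped run of %d %r genes (%s..%s) as putative translocation",
                len(run),
                codes[i].code,
                run[0].gene_id,
                run[-1].gene_id,
            )
        else:
            kept.extend(run)
        i = j
    return kept


def reduce_region(
    region: RegionCode,
    drop_long_runs_over: Optional[int] = DEFAULT_LONG_RUN_THRESHOLD,
    long_runs_on_raw: bool = False,
) -> RegionCode:
    """Reduce a region to its essential ``{B,1,2}`` code.

    Steps, in order: drop ``D``/``N``/``0`` genes; optionally drop maximal
    runs of ``1`` or ``2`` strictly longer than ``drop_long_runs_over``
    (putative segmental translocations); trim both ends so the region starts
    and ends with ``B``.  Original positions are preserved on the surviving
    records, so run statistics can be mapped back.

    ``long_runs_on_raw=True`` measures runs on the string before
    ``D``/``N``/``0`` removal (a ``0`` then splits a run); the default
    measures them after removal, matching the essential-code reduction.

    >>> reduce_region(parse_code_string("B021BB2DDDB10B")).code_string
    'B21BB2B1B'
    """
    if region.reduced:
        return region
    genes = list(region.genes)
    if long_runs_on_raw and drop_long_runs_over is not None:
        genes = _drop_long_runs(genes, drop_long_runs_over)
    kept = [g for g in genes if g.code in "B12"]
    for g in genes:
        if g.code not in "B12":
            logger.info("reduce: dropped %s (code %s)", g.gene_id, g.code)
    if not long_runs_on_raw and drop_long_runs_over is not None:
        kept = _drop_long_runs(kept, drop_long_runs_over)
    if not any(g.code == "B" for g in kept):
        raise UntrimmableRegionError(
            f"region {region.region_id!r} has no retained (B) gene after removal"
        )
    first = next(i for i, g in enumerate(kept) if g.code == "B")
    last = max(i for i, g in enumerate(kept) if g.code == "B")
    for g in kept[:first] + kept[last + 1 :]:
        logger.info("reduce: trimmed terminal %s (code %s)", g.gene_id, g.code)
    return RegionCode(
        region_id=region.region_id,
        genes=tuple(kept[first : last + 1]),
        homeolog_labels=region.homeolog_labels,
        reduced=True,
    )


# ---------------------------------------------------------------------------
# File dialects
# ---------------------------------------------------------------------------

def read_code_table(path: str | Path) -> CodeTable:
    """Read the tab-separated dialect: region_id, gene_id, code[, family_id]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "family_id" in df.columns:
        df["family_id"] = df["family_id"].replace("", pd.NA)
    df["code"] = df["code"].map(_canonical)
    return CodeTable(rows=df, source=str(path))


def write_code_table(table: CodeTable, path: str | Path) -> None:
    df = table.rows.copy()
    df["family_id"] = df["family_id"].fillna("")
    df.to_csv(path, sep="\t", index=False)


def read_code_fasta(path: str | Path) -> list[RegionCode]:
    """Read the FASTA-like dialect: ``>region_id`` then a raw code string."""
    from Bio import SeqIO

    regions = []
    for rec in SeqIO.parse(str(path), "fasta"):
        regions.append(parse_code_string(str(rec.seq), region_id=rec.id))
    return regions


def regions_from_table(table: CodeTable) -> list[RegionCode]:
    """Group a :class:`CodeTable` into per-region :class:`RegionCode` objects."""
    out = []
    for rid, grp in table.rows.groupby("region_id", sort=False):
        genes = tuple(
            GeneRecord(
                gene_id=row.gene_id,
                position=i,
                code=row.code,
                family_id=None if pd.isna(row.family_id) else row.family_id,
            )
            for i, row in enumerate(grp.itertuples(index=False))
        )
        out.append(RegionCode(region_id=str(rid), genes=genes))
    return out


def table_from_regions(regions: Iterable[RegionCode]) -> CodeTable:
    """Flatten regions back into a long-format :class:`CodeTable`."""
    rows = [
        {
            "region_id": r.region_id,
            "gene_id": g.gene_id,
            "code": g.code,
            "family_id": g.family_id,
        }
        for r in regions
        for g in r.genes
    ]
    return CodeTable(rows=pd.DataFrame(rows))
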