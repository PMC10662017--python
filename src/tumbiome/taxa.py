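"""Taxonomic count tables built from classifier reports.

Reads per-sample Kraken2-style reports (or Bracken abundance tables),
assembles an integer taxon x sample count matrix together with each taxon's
lineage and each sample's human-aligned read count, aggregates counts to any
taxonomic rank, and applies the minimum-supporting-read inclusion rule used
when screening low-abundance classifier calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "TaxonLineage",
    "TaxonCountTable",
    "MinReadRule",
    "parse_kraken_report",
    "parse_bracken",
    "build_count_table",
    "aggregate_lineage",
    "apply_min_reads",
    "write_table",
    "read_table",
]

#: Rank ladder from broadest to finest. "domain" and "kingdom" both appear
#: because classifier databases mix the two conventions.
RANKS = (
    "domain",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)

_RANK_CODE_MAP = {
    "D": "domain",
    "K": "kingdom",
    "P": "phylum",
    "C": "class",
    "O": "order",
    "F": "family",
    "G": "genus",
    "S": "species",
}

#: taxid used for the synthetic "unclassified at this rank" row produced by
#: aggregate_lineage when a taxon has no ancestor at the requested rank.
UNCLASSIFIED_TAXID = -1

HUMAN_TAXID = 9606


class KrakenParseError(ValueError):
    """Raised when a classifier report line cannot be parsed."""


def rank_code_to_rank(code: str) -> str | None:
    """Map a Kraken2 rank code (possibly suffixed, e.g. ``S1``) to a rank name.

    Suffixed species codes (``S1``, ``S2`` ...) denote strains.  Codes with
    no place on the ladder (``U``, ``R``, intermediate clades) map to None.
    """
    if not code:
        return None
    base, suffix = code[0], code[1:]
    if base == "S" and suffix:
        return "strain"
    if suffix:
        return None  # sub-levels of non-species ranks have no ladder slot
    return _RANK_CODE_MAP.get(base)


@dataclass(frozen=True)
class TaxonLineage:
    """One node of a taxonomy: identifier, name, rank, and parent link."""

    taxid: int
    name: str
    rank: str | None
    parent_taxid: int | None

    def __post_init__(self) -> None:
        if self.rank is not None and self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r} for taxid {self.taxid}")


@dataclass
class TaxonCountTable:
    """Integer taxon x sample count matrix with lineage and human-read sidecars.

    counts
        Non-negative integer DataFrame, rows indexed by taxid, columns by
        sample identifier.
    lineages
        Mapping taxid -> TaxonLineage covering at least every row taxid;
        parent links may reference additional (non-row) entries so that
        chains can be walked up to any rank.
    human_reads
        Per-sample human-aligned read count, used as the denominator of the
        microbial-load sample filter.
    """

    counts: pd.DataFrame
    lineages: dict[int, TaxonLineage]
    human_reads: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, copy=False)
        self.counts.index.name = None
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes}")
        missing = [t for t in self.counts.index if t not in self.lineages]
        if missing:
            raise ValueError(f"taxa without lineage entries: {missing[:5]}")
        self.human_reads = self.human_reads.reindex(self.counts.columns)
        if self.human_reads.isna().any():
            absent = self.human_reads.index[self.human_reads.isna()].tolist()
            raise ValueError(f"samples without human read counts: {absent[:5]}")
        self.human_reads = self.human_reads.astype(np.int64)

    # -- conveniences -----------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list[int]:
        return list(self.counts.index)

    def library_sizes(self) -> pd.Series:
        """Total microbial reads per sample."""
        return self.counts.sum(axis=0)

    def name_of(self, taxid: int) -> str:
        if taxid in self.lineages:
            return self.lineages[taxid].name
        return str(taxid)

    def lineage_chain(self, taxid: int) -> list[TaxonLineage]:
        """Walk parent links from taxid to the root, guarding against cycles."""
        chain: list[TaxonLineage] = []
        seen: set[int] = set()
        cur: int | None = taxid
        while cur is not None and cur in self.lineages:
            if cur in seen:
                raise ValueError(f"lineage cycle detected at taxid {cur}")
            seen.add(cur)
            node = self.lineages[cur]
            chain.append(node)
            cur = node.parent_taxid
        return chain

    def subset_samples(self, keep: Iterable[str]) -> "TaxonCountTable":
        keep = [s for s in self.counts.columns if s in set(keep)]
        return TaxonCountTable(
            counts=self.counts.loc[:, keep].copy(),
            lineages=dict(self.lineages),
            human_reads=self.human_reads.loc[keep].copy(),
        )

    def subset_taxa(self, keep: Iterable[int]) -> "TaxonCountTable":
        keep_set = set(keep)
        keep_idx = [t for t in self.counts.index if t in keep_set]
        return TaxonCountTable(
            counts=self.counts.loc[keep_idx].copy(),
            lineages=dict(self.lineages),
            human_reads=self.human_reads.copy(),
        )


@dataclass(frozen=True)
class MinReadRule:
    """Minimum supporting reads for a classifier call to be trusted.

    Entries with count <= threshold are zeroed (strict "greater than"),
    either per (taxon, sample) entry or on the taxon's cohort total.
    """

    threshold: int = 5
    mode: str = "entry"  # "entry" or "taxon_total"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.mode not in ("entry", "taxon_total"):
            raise ValueError("mode must be 'entry' or 'taxon_total'")


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

def parse_kraken_report(path: str | Path) -> pd.DataFrame:
    """Parse a Kraken2 6-column report into a tidy DataFrame.

    Columns: pct, clade_reads, direct_reads, rank_code, taxid, name, depth.
    The leading-space indentation of the name field encodes tree depth
    (2 spaces per level) and is preserved in the ``depth`` column.
    """
    records = []
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise KrakenParseError(
                    f"{path}:{lineno}: expected >=6 tab-separated fields, got {len(fields)}"
                )
            pct_s, clade_s, direct_s, rank_code, taxid_s, name = fields[:6]
            try:
                clade_reads = int(clade_s)
                direct_reads = int(direct_s)
                taxid = int(taxid_s)
            except ValueError as exc:
                raise KrakenParseError(f"{path}:{lineno}: non-integer count field") from exc
            try:
                pct = float(pct_s)
            except ValueError as exc:
                raise KrakenParseError(f"{path}:{lineno}: non-numeric percentage") from exc
            depth = (len(name) - len(name.lstrip(" "))) // 2
            records.append(
                (pct, clade_reads, direct_reads, rank_code, taxid, name.strip(), depth)
            )
    return pd.DataFrame(
        records,
        columns=["pct", "clade_reads", "direct_reads", "rank_code", "taxid", "name", "depth"],
    )


def parse_bracken(path: str | Path) -> pd.DataFrame:
    """Parse a Bracken abundance TSV (name, taxid, taxlvl, kraken_assigned_reads,
    added_reads, new_est_reads, fraction)."""
    df = pd.read_csv(path, sep="\t")
    expected = {"name", "taxonomy_id", "taxonomy_lvl", "new_est_reads"}
    alt = {"name", "taxid", "taxlvl", "new_est_reads"}
    cols = set(df.columns)
    if not (expected <= cols or alt <= cols):
        raise KrakenParseError(f"{path}: not a recognisable Bracken table (columns {sorted(cols)})")
    taxid_col = "taxonomy_id" if "taxonomy_id" in cols else "taxid"
    lvl_col = "taxonomy_lvl" if "taxonomy_lvl" in cols else "taxlvl"
    out = df.rename(columns={taxid_col: "taxid", lvl_col: "rank_code"})[
        ["name", "taxid", "rank_code", "new_est_reads"]
    ].copy()
    out["taxid"] = out["taxid"].astype(int)
    out["new_est_reads"] = out["new_est_reads"].astype(int)
    return out


def _lineages_from_report(report: pd.DataFrame) -> dict[int, TaxonLineage]:
    """Reconstruct parent links from the indentation structure of a report."""
    lineages: dict[int, TaxonLineage] = {}
    stack: list[tuple[int, int]] = []  # (depth, taxid)
    for row in report.itertuples(index=False):
        while stack and stack[-1][0] >= row.depth:
            stack.pop()
        parent = stack[-1][1] if stack else None
        lineages[row.taxid] = TaxonLineage(
            taxid=row.taxid,
            name=row.name,
            rank=rank_code_to_rank(row.rank_code),
            parent_taxid=parent,
        )
        stack.append((row.depth, row.taxid))
    return lineages


def build_count_table(
    reports: Mapping[str, pd.DataFrame] | Iterable[tuple[str, pd.DataFrame]],
    level: str = "S",
    human_reads: Mapping[str, int] | None = None,
    exclude_human: bool = True,
) -> TaxonCountTable:
    """Assemble a TaxonCountTable from parsed per-sample Kraken2 reports.

    Clade read counts at the requested rank code are used so that per-rank
    tables are self-consistent with downstream lineage aggregation.  Human
    reads are taken from the Homo sapiens clade entry when present in a
    report, otherwise from the ``human_reads`` mapping; a sample with
    neither is an error.
    """
    if isinstance(reports, Mapping):
        pairs = list(reports.items())
    else:
        pairs = list(reports)
    if not pairs:
        raise ValueError("at least one report is required")
    names = [s for s, _ in pairs]
    if len(set(names)) != len(names):
        dupes = sorted({s for s in names if names.count(s) > 1})
        raise ValueError(f"duplicate sample names: {dupes}")
    if rank_code_to_rank(level) is None:
        raise ValueError(f"invalid target rank code {level!r}")

    lineages: dict[int, TaxonLineage] = {}
    columns: dict[str, pd.Series] = {}
    human: dict[str, int] = {}
    for sample, report in pairs:
        lineages.update(_lineages_from_report(report))
        at_level = report[report["rank_code"] == level]
        human_rows = report[report["taxid"] == HUMAN_TAXID]
        if not human_rows.empty:
            human[sample] = int(human_rows["clade_reads"].iloc[0])
        elif human_reads is not None and sample in human_reads:
            human[sample] = int(human_reads[sample])
        else:
            raise ValueError(
                f"sample {sample!r}: no Homo sapiens entry in report and no external human read count"
            )
        col = at_level.set_index("taxid")["clade_reads"]
        if exclude_human:
            col = col.drop(index=HUMAN_TAXID, errors="ignore")
        columns[sample] = col

    counts = pd.DataFrame(columns).fillna(0).astype(np.int64)
    counts = counts.sort_index()
    counts = counts[names]
    if counts.empty:
        warnings.warn(f"no taxa at rank code {level!r}; count table is empty")
    return TaxonCountTable(
        counts=counts,
        lineages=lineages,
        human_reads=pd.Series(human, dtype=np.int64)[names],
    )


# ---------------------------------------------------------------------------
# rank aggregation and minimum-read rule
# ---------------------------------------------------------------------------

def _ancestor_at_rank(table: TaxonCountTable, taxid: int, target_rank: str) -> int | None:
    for node in table.lineage_chain(taxid):
        if node.rank == target_rank:
            return node.taxid
    return None


def aggregate_lineage(table: TaxonCountTable, target_rank: str) -> TaxonCountTable:
    """Sum counts into ancestors at ``target_rank``.

    Per-sample totals over resolvable taxa are conserved exactly.  Taxa with
    no ancestor at the requested rank are summed into an explicit
    "unclassified-at-rank" row (taxid -1) rather than silently dropped.
    """
    if target_rank not in RANKS:
        raise ValueError(f"unknown rank {target_rank!r}")
    mapping: dict[int, int] = {}
    for taxid in table.counts.index:
        anc = _ancestor_at_rank(table, taxid, target_rank)
        mapping[taxid] = anc if anc is not None else UNCLASSIFIED_TAXID
    grouped = table.counts.groupby(table.counts.index.map(mapping)).sum()
    grouped = grouped.sort_index()
    lineages = dict(table.lineages)
    if UNCLASSIFIED_TAXID in grouped.index:
        lineages[UNCLASSIFIED_TAXID] = TaxonLineage(
            taxid=UNCLASSIFIED_TAXID,
            name=f"unclassified-at-{target_rank}",
            rank=target_rank,
            parent_taxid=None,
        )
    return TaxonCountTable(
        counts=grouped, lineages=lineages, human_reads=table.human_reads.copy()
    )


def apply_min_reads(table: TaxonCountTable, rule: MinReadRule = MinReadRule()) -> TaxonCountTable:
    """Zero entries (or taxa) with too few supporting reads; drop empty rows.

    The rule is strict: a count must exceed the threshold to be kept, so the
    default threshold of 5 keeps 6 and discards 5.  Idempotent.
    """
    counts = table.counts.copy()
    if rule.mode == "entry":
        counts = counts.where(counts > rule.threshold, 0)
    else:
        total = counts.sum(axis=1)
        counts.loc[total <= rule.threshold] = 0
    counts = counts.loc[counts.sum(axis=1) > 0]
    return TaxonCountTable(
        counts=counts, lineages=dict(table.lineages), human_reads=table.human_reads.copy()
    )


# ---------------------------------------------------------------------------
# serialization: counts TSV + lineage sidecar TSV + human-read TSV
# ---------------------------------------------------------------------------

def write_table(table: TaxonCountTable, prefix: str | Path) -> None:
    """Write ``<prefix>.counts.tsv``, ``<prefix>.lineage.tsv``, ``<prefix>.human.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table.counts.to_csv(Path(str(prefix) + ".counts.tsv"), sep="\t", index_label="taxid")
    rows = [
        {
            "taxid": lin.taxid,
            "name": lin.name,
            "rank": lin.rank if lin.rank is not None else "",
            "parent_taxid": "" if lin.parent_taxid is None else lin.parent_taxid,
        }
        for lin in table.lineages.values()
    ]
    pd.DataFrame(rows, columns=["taxid", "name", "rank", "parent_taxid"]).to_csv(
        Path(str(prefix) + ".lineage.tsv"), sep="\t", index=False
    )
    table.human_reads.rename("human_reads").to_csv(
        Path(str(prefix) + ".human.tsv"), sep="\t", index_label="sample"
    )


def read_table(prefix: str | Path) -> TaxonCountTable:
    """Inverse of :func:`write_table`; round-trips counts exactly."""
    prefix = Path(prefix)
    counts = pd.read_csv(Path(str(prefix) + ".counts.tsv"), sep="\t", index_col="taxid")
    counts.columns = counts.columns.astype(str)
    counts.index.name = None
    lin_df = pd.read_csv(
        Path(str(prefix) + ".lineage.tsv"), sep="\t", dtype={"name": str}
    )
    lineages: dict[int, TaxonLineage] = {}
    for row in lin_df.itertuples(index=False):
        rank = None if pd.isna(row.rank) or row.rank == "" else str(row.rank)
        parent = None if pd.isna(row.parent_taxid) else int(row.parent_taxid)
        lineages[int(row.taxid)] = TaxonLineage(
            taxid=int(row.taxid), name=str(row.name), rank=rank, parent_taxid=parent
        )
    human = pd.read_csv(Path(str(prefix) + ".human.tsv"), sep="\t", index_col="sample")[
        "human_reads"
    ]
    human.index = human.index.astype(str)
    return TaxonCountTable(counts=counts.astype(np.int64), lineages=lineages, human_reads=human)
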