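"""Contaminant removal for low-biomass tumor RNA-seq microbiome tables.

Four phases, applied in order:

1. microbial-load sample filter — samples whose total microbial read count
   exceeds a fraction (default 20%) of their human-aligned reads are
   discarded as extreme outliers;
2. small-batch sample filter — samples are batched by technical covariates
   (sequencing site, preservation method, flow cell) and batches with fewer
   than 10 samples are removed, because contaminant statistics are
   unreliable in tiny batches;
3. frequency-based statistical taxon filter — a reagent contaminant
   contributes a roughly fixed mass of nucleic acid, so its *relative*
   abundance scales inversely with the input RNA concentration of the
   sample; taxa whose log relative abundance tracks -log(concentration) are
   flagged;
4. literature filter — taxa on a curated deny list of common sequencing
   contaminants are flagged, unless on a spare list of organisms with
   strong literature precedence as human commensals.

The statistical test compares a contaminant model M1 (slope fixed at -1,
free intercept) against a non-contaminant model M0 (slope 0) on
log(relative abundance) vs log(concentration), using the statistic
lambda = SS1 / (SS1 + SS0) referred to its permutation distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .taxa import TaxonCountTable

__all__ = [
    "FilterConfig",
    "ContaminantCall",
    "filter_microbial_load",
    "filter_small_batches",
    "frequency_contaminant_test",
    "classify_contaminants",
    "remove_taxa",
    "read_taxon_list",
]

MISSING_BATCH = "missing"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and lists for the four contaminant-removal phases."""

    max_load_ratio: float = 0.20
    min_batch_size: int = 10
    batch_fields: tuple[str, ...] = ("sequencing_site", "preservation", "flow_cell")
    contaminant_p_threshold: float = 0.10
    deny_list: frozenset[str] = frozenset()
    spare_list: frozenset[str] = frozenset()
    n_permutations: int = 1000
    min_positive: int = 5  # samples with positive abundance and concentration
    match_lineage: bool = True  # deny/spare match at any rank in the lineage

    def __post_init__(self) -> None:
        if not self.max_load_ratio > 0:
            raise ValueError("max_load_ratio must be > 0")
        if self.min_batch_size < 1:
            raise ValueError("min_batch_size must be >= 1")
        if not 0 < self.contaminant_p_threshold < 1:
            raise ValueError("contaminant_p_threshold must be in (0, 1)")


@dataclass(frozen=True)
class ContaminantCall:
    """Per-taxon verdict of the statistical + literature filters.

    ``final_contaminant`` is (statistical OR literature) AND NOT spared:
    sparing by literature precedence overrides both flag sources.
    """

    taxid: int
    name: str
    p_value: float | None
    flagged_statistical: bool
    flagged_literature: bool
    spared: bool

    @property
    def final_contaminant(self) -> bool:
        return (self.flagged_statistical or self.flagged_literature) and not self.spared


# ---------------------------------------------------------------------------
# sample filters (projections: retained counts are never altered)
# ---------------------------------------------------------------------------

def filter_microbial_load(
    table: TaxonCountTable, config: FilterConfig = FilterConfig()
) -> tuple[TaxonCountTable, pd.DataFrame]:
    """Drop samples whose microbial load exceeds ``max_load_ratio`` x human reads.

    The comparison is strict: a ratio exactly at the threshold is retained.
    Returns the filtered table and a removal record (sample, ratio).
    """
    if (table.human_reads == 0).any():
        bad = table.human_reads.index[table.human_reads == 0].tolist()
        raise ValueError(f"human read count is zero for samples {bad}; load ratio undefined")
    ratio = table.library_sizes() / table.human_reads
    removed_mask = ratio > config.max_load_ratio
    removed = pd.DataFrame(
        {"sample": ratio.index[removed_mask], "ratio": ratio[removed_mask].to_numpy()}
    )
    kept = [s for s in table.samples if not removed_mask[s]]
    return table.subset_samples(kept), removed


def assign_batches(metadata: pd.DataFrame, batch_fields: Sequence[str]) -> pd.Series:
    """Batch key per sample: tuple of batch-field values rendered as a string.

    Missing values are mapped to an explicit "missing" token (with a
    warning) so the sample still lands in a well-defined batch.
    """
    for f in batch_fields:
        if f not in metadata.columns:
            raise KeyError(f"batch field {f!r} not in metadata")
    sub = metadata.loc[:, list(batch_fields)].copy()
    if sub.isna().any().any():
        warnings.warn("missing batch field values assigned to the 'missing' batch key")
        sub = sub.fillna(MISSING_BATCH)
    return sub.astype(str).agg("|".join, axis=1)


def filter_small_batches(
    table: TaxonCountTable,
    metadata: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
) -> tuple[TaxonCountTable, pd.DataFrame]:
    """Drop all samples belonging to batches smaller than ``min_batch_size``.

    A batch of exactly ``min_batch_size`` samples is retained ("fewer than"
    is strict).
    """
    keys = assign_batches(metadata.loc[table.samples], config.batch_fields)
    sizes = keys.value_counts()
    small = sizes.index[sizes < config.min_batch_size]
    removed_mask = keys.isin(small)
    removed = pd.DataFrame(
        {
            "sample": keys.index[removed_mask],
            "batch": keys[removed_mask].to_numpy(),
            "batch_size": sizes[keys[removed_mask]].to_numpy(),
        }
    )
    kept = [s for s in table.samples if not removed_mask[s]]
    return table.subset_samples(kept), removed


# ---------------------------------------------------------------------------
# frequency-based statistical taxon filter
# ---------------------------------------------------------------------------

def _lambda_from_cross(ss_y: float, ss_x: float, cross: np.ndarray) -> np.ndarray:
    """lambda = SS1/(SS1+SS0) where SS1 = SS(y + x) and SS0 = SS(y).

    With centered sums of squares, SS(y + x) = SS(y) + SS(x) + 2*cross where
    cross = sum((y - ybar)(x - xbar)); SS(y) and SS(x) are invariant under
    permutation of x, so the whole statistic is a monotone function of the
    cross-term.
    """
    ss1 = ss_y + ss_x + 2.0 * cross
    return ss1 / (ss1 + ss_y)


def frequency_contaminant_test(
    abundance: np.ndarray | pd.Series,
    concentration: np.ndarray | pd.Series,
    n_permutations: int = 1000,
    min_positive: int = 5,
    rng: np.random.Generator | int | None = 0,
) -> float | None:
    """Permutation p-value for the fixed-mass (1/concentration) contaminant model.

    Fits, on log(abundance) vs log(concentration) over samples where both
    are positive, the contaminant model M1 (slope -1, free intercept) and
    the non-contaminant model M0 (slope 0, free intercept) by least
    squares, and returns the lower-tail permutation probability of
    lambda = SS1/(SS1+SS0) under random relabelling of the concentrations.
    Small p means M1 fits better than chance: the taxon behaves like a
    contaminant.

    Returns None (never flags) when fewer than ``min_positive`` usable
    samples exist or the concentrations are constant.
    """
    a = np.asarray(abundance, dtype=float)
    c = np.asarray(concentration, dtype=float)
    mask = np.isfinite(a) & np.isfinite(c) & (a > 0) & (c > 0)
    if int(mask.sum()) < min_positive:
        return None
    y = np.log(a[mask])
    x = np.log(c[mask])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    yc = y - y.mean()
    xc = x - x.mean()
    ss_y = float(yc @ yc)
    ss_x = float(xc @ xc)
    lam_obs = float(_lambda_from_cross(ss_y, ss_x, np.array([yc @ xc]))[0])

    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    perm = np.empty(n_permutations)
    xmat = np.tile(xc, (n_permutations, 1))
    xmat = rng.permuted(xmat, axis=1)
    cross = xmat @ yc
    lam_perm = _lambda_from_cross(ss_y, ss_x, cross)
    p = (1.0 + float(np.sum(lam_perm <= lam_obs))) / (n_permutations + 1.0)
    return p


def _names_in_lineage(table: TaxonCountTable, taxid: int, match_lineage: bool) -> set[str]:
    if match_lineage:
        return {node.name.lower() for node in table.lineage_chain(taxid)}
    return {table.name_of(taxid).lower()}


def classify_contaminants(
    table: TaxonCountTable,
    metadata: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
    concentration_col: str = "concentration",
    seed: int = 0,
) -> list[ContaminantCall]:
    """Run the statistical and literature filters over every taxon.

    The statistical test runs on species-level relative abundances pooled
    over the cohort in ``table``.  Deny/spare matching is case-insensitive
    by taxon name, at any rank of the lineage when ``config.match_lineage``.
    """
    if concentration_col not in metadata.columns:
        raise KeyError(f"metadata lacks concentration column {concentration_col!r}")
    conc = metadata.loc[table.samples, concentration_col].to_numpy(dtype=float)
    lib = table.library_sizes().to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = table.counts.to_numpy(dtype=float) / np.where(lib > 0, lib, np.nan)

    deny = {n.lower() for n in config.deny_list}
    spare = {n.lower() for n in config.spare_list}
    calls: list[ContaminantCall] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(table.counts.shape[0])
    for i, taxid in enumerate(table.counts.index):
        p = frequency_contaminant_test(
            rel[i],
            conc,
            n_permutations=config.n_permutations,
            min_positive=config.min_positive,
            rng=np.random.default_rng(child_seeds[i]),
        )
        names = _names_in_lineage(table, taxid, config.match_lineage)
        calls.append(
            ContaminantCall(
                taxid=int(taxid),
                name=table.name_of(taxid),
                p_value=p,
                flagged_statistical=(p is not None and p < config.contaminant_p_threshold),
                flagged_literature=bool(names & deny),
                spared=bool(names & spare),
            )
        )
    return calls


def remove_taxa(table: TaxonCountTable, calls: Iterable[ContaminantCall]) -> TaxonCountTable:
    """Drop rows called final contaminants; all other entries are untouched."""
    drop = {c.taxid for c in calls if c.final_contaminant}
    keep = [t for t in table.taxa if t not in drop]
    if not keep:
        warnings.warn("all taxa flagged as contaminants; returning an empty table")
    return table.subset_taxa(keep)


def calls_to_frame(calls: Iterable[ContaminantCall]) -> pd.DataFrame:
    """Tabular view of contaminant calls (for logs and serialization)."""
    return pd.DataFrame(
        [
            {
                "taxid": c.taxid,
                "name": c.name,
                "p_value": np.nan if c.p_value is None else c.p_value,
                "flagged_statistical": c.flagged_statistical,
                "flagged_literature": c.flagged_literature,
                "spared": c.spared,
                "final_contaminant": c.final_contaminant,
            }
            for c in calls
        ]
    )


def read_taxon_list(path: str | Path) -> frozenset[str]:
    """Read a one-name-per-line taxon list; '#' starts a comment."""
    names = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.append(line)
    return frozenset(names)
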