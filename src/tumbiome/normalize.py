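"""Normalization of decontaminated count tables.

Two complementary outputs are produced from a filtered count table:

* a real-valued log2-scale abundance matrix with per-observation precision
  weights (log-CPM transform with a fitted mean-variance trend), from which
  named technical covariates (sequencing center, preservation method) are
  regressed out while named biological covariates (cancer type) are
  preserved — used for correlation analyses; and
* a rarefied presence/absence table (single seeded subsample of every
  sample down to the lowest common read depth, presence = any read) — used
  for prevalence-stratified survival analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .taxa import TaxonCountTable

__all__ = [
    "NormalizedAbundance",
    "PrevalenceTable",
    "voom_transform",
    "snm_normalize",
    "relative_abundance",
    "rarefy",
    "prevalence",
]


@dataclass
class NormalizedAbundance:
    """log2-scale abundance values with per-observation precision weights."""

    values: pd.DataFrame  # taxa x samples, log2 counts-per-million
    weights: pd.DataFrame  # same shape, > 0
    bio_vars: list[str] = field(default_factory=list)
    adj_vars: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights must have identical shape")
        if not np.all(np.isfinite(self.weights.to_numpy())) or (
            self.weights.to_numpy() <= 0
        ).any():
            raise ValueError("weights must be finite and positive")
        overlap = set(self.bio_vars) & set(self.adj_vars)
        if overlap:
            raise ValueError(f"variables both preserved and removed: {sorted(overlap)}")


@dataclass
class PrevalenceTable:
    """Boolean presence matrix derived from a rarefied count table."""

    presence: pd.DataFrame  # taxa x samples, bool
    rarefaction_depth: int
    seed: int


# ---------------------------------------------------------------------------
# log-CPM transform with precision weights
# ---------------------------------------------------------------------------

def _design_matrix(
    metadata: pd.DataFrame, samples: Sequence[str], variables: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded one-hot columns for categorical variables."""
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    md = metadata.loc[list(samples)]
    for var in variables:
        if var not in md.columns:
            raise KeyError(f"variable {var!r} not in metadata")
        levels = pd.unique(md[var].astype(str))
        for lev in levels[1:]:  # first level is the reference
            cols.append((md[var].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{var}[{lev}]")
    return np.column_stack(cols), names


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return
    # identify aliased columns greedily for the error message
    aliased = []
    kept: list[int] = []
    for j in range(design.shape[1]):
        cand = design[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j])
    raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def _fit_trend(values: np.ndarray, fitted: np.ndarray, resid_sd: np.ndarray, span: float):
    """LOESS trend of sqrt(residual sd) on average log2 abundance.

    Returns a callable predicting sqrt-sd at arbitrary log2 abundance,
    clamped to the fitted range at the extremes.
    """
    sx = values.mean(axis=1)
    sy = np.sqrt(resid_sd)
    order = np.argsort(sx)
    smooth = lowess(sy[order], sx[order], frac=span, it=0, delta=0.0, return_sorted=True)
    gx, gy = smooth[:, 0], np.clip(smooth[:, 1], 1e-6, None)

    def predict(x: np.ndarray) -> np.ndarray:
        return np.interp(x, gx, gy)  # np.interp clamps outside the range

    return predict


def voom_transform(
    table: TaxonCountTable,
    metadata: pd.DataFrame | None = None,
    design_vars: Sequence[str] = (),
    span: float = 0.5,
) -> NormalizedAbundance:
    """log2 counts-per-million with precision weights from a mean-variance trend.

    values = log2((count + 0.5) / (library_size + 1) * 1e6).  Per taxon, an
    ordinary least-squares fit on the design (intercept only when no
    variables are given) yields residual standard deviations whose square
    roots are smoothed against average log2 abundance by local linear
    regression (tricube weights, span 0.5).  Each observation's weight is
    the predicted sqrt-sd at its fitted log2 abundance raised to the -4,
    i.e. the reciprocal of the predicted variance.
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 taxa and 2 samples")
    lib = counts.sum(axis=0)
    zero_lib = np.flatnonzero(lib == 0)
    if zero_lib.size:
        bad = [table.samples[i] for i in zero_lib]
        raise ValueError(f"zero library size for samples {bad}")
    values = np.log2((counts + 0.5) / (lib + 1.0) * 1e6)

    if metadata is not None and design_vars:
        design, names = _design_matrix(metadata, table.samples, design_vars)
        _check_full_rank(design, names)
    else:
        design = np.ones((counts.shape[1], 1))
    # taxa-wise OLS in one shot: coefs (p x taxa)
    coef, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    fitted = (design @ coef).T
    resid = values - fitted
    dof = counts.shape[1] - design.shape[1]
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom for the variance trend")
    resid_sd = np.sqrt((resid**2).sum(axis=1) / dof)

    predict = _fit_trend(values, fitted, resid_sd, span)
    # predict at fitted log2-cpm of each observation
    w = predict(fitted) ** (-4.0)
    idx, cols = table.counts.index, table.counts.columns
    return NormalizedAbundance(
        values=pd.DataFrame(values, index=idx, columns=cols),
        weights=pd.DataFrame(w, index=idx, columns=cols),
    )


def snm_normalize(
    norm: NormalizedAbundance,
    metadata: pd.DataFrame,
    bio_vars: Sequence[str],
    adj_vars: Sequence[str],
    tol: float = 1e-6,
    max_iter: int = 50,
    span: float = 0.5,
    refit_weights: bool = False,
) -> NormalizedAbundance:
    """Remove technical covariate variance while preserving biological variance.

    Per taxon, a weighted least-squares fit of the log2 values on
    [intercept | bio one-hot | adj one-hot] (precision weights from the
    log-CPM transform) is computed and the fitted adjustment-variable
    component subtracted; the regression is repeated until the adjustment
    coefficient matrix is stable to ``tol`` in max-norm (or ``max_iter``
    iterations).  By default the precision weights stay fixed throughout,
    so an exactly planted technical shift is removed exactly on an
    orthogonal design; ``refit_weights=True`` re-derives the
    mean-variance trend from the adjusted values between iterations.

    With no adjustment variables the values are returned unchanged.
    """
    if not adj_vars:
        return NormalizedAbundance(
            values=norm.values.copy(),
            weights=norm.weights.copy(),
            bio_vars=list(bio_vars),
            adj_vars=[],
        )
    samples = list(norm.values.columns)
    x_bio, bio_names = _design_matrix(metadata, samples, bio_vars)
    x_adj, adj_names = _design_matrix(metadata, samples, adj_vars)
    x_adj = x_adj[:, 1:]  # drop duplicate intercept
    adj_names = adj_names[1:]
    design = np.column_stack([x_bio, x_adj])
    _check_full_rank(design, bio_names + adj_names)
    n_bio = x_bio.shape[1]

    y = norm.values.to_numpy(dtype=float)
    w = norm.weights.to_numpy(dtype=float)
    prev_beta_adj = None
    adjusted = y
    for _ in range(max_iter):
        beta_adj = np.empty((y.shape[0], x_adj.shape[1]))
        fitted_all = np.empty_like(y)
        for i in range(y.shape[0]):
            wi = w[i]
            xw = design * wi[:, None]
            beta = np.linalg.solve(design.T @ xw, xw.T @ y[i])
            beta_adj[i] = beta[n_bio:]
            fitted_all[i] = design @ beta
        adjusted = y - (x_adj @ beta_adj.T).T
        if prev_beta_adj is not None and np.max(np.abs(beta_adj - prev_beta_adj)) < tol:
            break
        prev_beta_adj = beta_adj
        if refit_weights:
            # re-derive the precision-weight trend from the adjusted values
            coef, *_ = np.linalg.lstsq(x_bio, adjusted.T, rcond=None)
            fitted_bio = (x_bio @ coef).T
            resid = adjusted - fitted_bio
            dof = max(adjusted.shape[1] - x_bio.shape[1], 1)
            resid_sd = np.sqrt((resid**2).sum(axis=1) / dof)
            predict = _fit_trend(adjusted, fitted_bio, resid_sd, span)
            w = predict(fitted_bio) ** (-4.0)

    return NormalizedAbundance(
        values=pd.DataFrame(adjusted, index=norm.values.index, columns=norm.values.columns),
        weights=pd.DataFrame(w, index=norm.values.index, columns=norm.values.columns),
        bio_vars=list(bio_vars),
        adj_vars=list(adj_vars),
    )


# ---------------------------------------------------------------------------
# relative abundance, rarefaction, prevalence
# ---------------------------------------------------------------------------

def relative_abundance(table: TaxonCountTable, include_human: bool = False) -> pd.DataFrame:
    """Per-sample relative abundances; columns sum to 1.

    With ``include_human`` the human-aligned read count enters the
    denominator and appears as an extra "human" row, giving the human and
    microbial portions of each sample on a common scale.
    """
    counts = table.counts.astype(float)
    if include_human:
        denom = counts.sum(axis=0) + table.human_reads
        if (denom == 0).any():
            raise ValueError("zero total reads (microbial + human) for some sample")
        rel = counts / denom
        rel.loc["human"] = table.human_reads / denom
        return rel
    denom = counts.sum(axis=0)
    if (denom == 0).any():
        bad = denom.index[denom == 0].tolist()
        raise ValueError(f"zero microbial library size for samples {bad}")
    return counts / denom


def rarefy(
    table: TaxonCountTable, depth: int | str = "min", seed: int = 0
) -> TaxonCountTable:
    """Subsample every sample's reads, without replacement, to a common depth.

    ``depth="min"`` uses the smallest library size (no samples dropped).
    With an explicit depth, samples below it are dropped with a warning.
    Each column is one multivariate-hypergeometric draw; deterministic for
    a fixed seed.
    """
    lib = table.library_sizes()
    if depth == "min":
        depth_i = int(lib.min())
    else:
        depth_i = int(depth)
    if depth_i <= 0:
        raise ValueError("rarefaction depth must be > 0")
    drop = lib.index[lib < depth_i].tolist()
    if drop:
        warnings.warn(f"dropping {len(drop)} samples below rarefaction depth {depth_i}")
    kept = [s for s in table.samples if s not in set(drop)]
    rng = np.random.default_rng(seed)
    # draw in canonical (sorted-taxid) order so the result is invariant to
    # the row ordering of the input table
    canon = table.counts.sort_index()
    out = {}
    for s in kept:
        col = canon[s].to_numpy()
        out[s] = rng.multivariate_hypergeometric(col, depth_i)
    counts = pd.DataFrame(out, index=canon.index).reindex(table.counts.index)
    return TaxonCountTable(
        counts=counts, lineages=dict(table.lineages), human_reads=table.human_reads[kept]
    )


def prevalence(table: TaxonCountTable, seed: int = 0, depth: int | None = None) -> PrevalenceTable:
    """Presence calls from a rarefied table: any read supports presence."""
    pres = table.counts >= 1
    d = int(table.library_sizes().min()) if depth is None else depth
    return PrevalenceTable(presence=pres, rarefaction_depth=d, seed=seed)
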