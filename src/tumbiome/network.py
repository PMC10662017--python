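"""Concordant microbe-gene correlation networks.

All microbes are correlated with all genes (Spearman) separately in a
discovery and a validation cohort; pairs whose correlation direction agrees
in both cohorts are kept and the most extreme tail of the validation-cohort
correlations (2.5% per tail by default) defines the edges of a bipartite
network.  Degree, betweenness, and closeness centrality rank microbes by
their connectedness to host transcription.  A random-matrix null (iid
normal matrices pushed through the identical pipeline) shows what the
degree distribution looks like without biological structure, and a
preranked running-sum enrichment test relates a high-centrality microbe's
gene neighbourhood to annotated pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "MicrobeGeneNetwork",
    "correlate_microbes_genes",
    "concordant_edge_select",
    "build_network",
    "random_network_null",
    "degree_distribution_fit",
    "preranked_enrichment",
    "read_gmt",
]


# ---------------------------------------------------------------------------
# mass Spearman correlation
# ---------------------------------------------------------------------------

def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, x)


def spearman_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided t-approximation p.

    ``a`` (m x n) vs ``b`` (g x n): returns (m x g) rho and p matrices.
    Average ranks handle ties, making each entry identical to a pairwise
    Spearman call.
    """
    if a.shape[1] != b.shape[1]:
        raise ValueError("matrices must share the sample axis")
    n = a.shape[1]
    ra = _rank_rows(a)
    rb = _rank_rows(b)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    sa = np.sqrt((ra**2).sum(axis=1))
    sb = np.sqrt((rb**2).sum(axis=1))
    sa[sa == 0] = np.nan  # constant rows: rho undefined
    sb[sb == 0] = np.nan
    rho = (ra @ rb.T) / np.outer(sa, sb)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return rho, p


def correlate_microbes_genes(
    microbes: pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho and p for every microbe-gene pair over shared samples.

    Returns a long table (microbe, gene, rho, p).
    """
    shared = [s for s in microbes.columns if s in set(genes.columns)]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, found {len(shared)}")
    rho, p = spearman_matrix(
        microbes[shared].to_numpy(dtype=float), genes[shared].to_numpy(dtype=float)
    )
    m_idx = np.repeat(np.arange(len(microbes.index)), len(genes.index))
    g_idx = np.tile(np.arange(len(genes.index)), len(microbes.index))
    return pd.DataFrame(
        {
            "microbe": np.asarray(microbes.index)[m_idx],
            "gene": np.asarray(genes.index)[g_idx],
            "rho": rho.ravel(),
            "p": p.ravel(),
        }
    )


def pair_correlations(
    micro_a: pd.DataFrame,
    genes_a: pd.DataFrame,
    micro_b: pd.DataFrame,
    genes_b: pd.DataFrame,
) -> pd.DataFrame:
    """Two-cohort correlation table with concordance flags.

    Cohort A is the discovery set, cohort B the validation set.  A pair is
    concordant when both correlations are defined and share a sign.
    """
    ca = correlate_microbes_genes(micro_a, genes_a).rename(
        columns={"rho": "rho_A", "p": "p_A"}
    )
    cb = correlate_microbes_genes(micro_b, genes_b).rename(
        columns={"rho": "rho_B", "p": "p_B"}
    )
    pairs = ca.merge(cb, on=["microbe", "gene"])
    sign_a = np.sign(pairs["rho_A"])
    sign_b = np.sign(pairs["rho_B"])
    pairs["concordant"] = (
        pairs["rho_A"].notna()
        & pairs["rho_B"].notna()
        & (sign_a == sign_b)
        & (sign_a != 0)
    )
    return pairs


def concordant_edge_select(
    pairs: pd.DataFrame, tail_fraction: float = 0.025
) -> pd.DataFrame:
    """Extreme-tail edges among concordant pairs.

    Pairs are restricted to the concordant set and ranked by the
    validation-cohort rho (signed value); the highest and lowest
    ``tail_fraction`` are kept.  Ties at either cutoff are all included,
    so the edge count can slightly exceed the nominal quantile count.
    """
    if not tail_fraction < 0.5:
        raise ValueError("tail_fraction must be < 0.5")
    conc = pairs.loc[pairs["concordant"]].copy()
    if conc.empty:
        return conc
    k = int(np.floor(len(conc) * tail_fraction))
    if k == 0:
        k = 1
    rho = conc["rho_B"].to_numpy()
    srt = np.sort(rho)
    low_cut = srt[k - 1]
    high_cut = srt[-k]
    keep = (rho <= low_cut) | (rho >= high_cut)
    return conc.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# bipartite graph and centralities
# ---------------------------------------------------------------------------

@dataclass
class MicrobeGeneNetwork:
    """Bipartite microbe-gene graph with node centralities."""

    graph: nx.Graph
    microbes: list
    genes: list
    degree: pd.Series
    betweenness: pd.Series
    closeness: pd.Series

    def microbe_centralities(self) -> pd.DataFrame:
        """Centrality table restricted to microbe nodes (one row per taxon)."""
        return pd.DataFrame(
            {
                "degree": self.degree.loc[self.microbes],
                "closeness": self.closeness.loc[self.microbes],
                "betweenness": self.betweenness.loc[self.microbes],
            }
        ).sort_values("degree", ascending=False)


def build_network(edges: pd.DataFrame, harmonic_closeness: bool = False) -> MicrobeGeneNetwork:
    """Build the bipartite graph and compute degree/betweenness/closeness.

    Edge weights record the validation-cohort rho but all centralities are
    computed on the unweighted graph.  Closeness is per-component
    (harmonic closeness available), betweenness is normalized shortest-path
    betweenness.
    """
    if edges.empty:
        raise ValueError("edge list is empty")
    g = nx.Graph()
    microbes = sorted(pd.unique(edges["microbe"]).tolist(), key=str)
    genes = sorted(pd.unique(edges["gene"]).tolist(), key=str)
    g.add_nodes_from([("m", m) for m in microbes], bipartite=0)
    g.add_nodes_from([("g", x) for x in genes], bipartite=1)
    for row in edges.itertuples(index=False):
        weight = getattr(row, "rho_B", getattr(row, "rho", 1.0))
        g.add_edge(("m", row.microbe), ("g", row.gene), weight=float(weight))
    degree = pd.Series(dict(g.degree()), dtype=int)
    betweenness = pd.Series(nx.betweenness_centrality(g, normalized=True))
    if harmonic_closeness:
        closeness = pd.Series(nx.harmonic_centrality(g), dtype=float)
        if len(g) > 1:
            closeness = closeness / (len(g) - 1)
    else:
        closeness = pd.Series(nx.closeness_centrality(g))

    def strip(series: pd.Series) -> pd.Series:
        s = series.copy()
        s.index = [name for _, name in s.index]
        return s

    return MicrobeGeneNetwork(
        graph=g,
        microbes=microbes,
        genes=genes,
        degree=strip(degree),
        betweenness=strip(betweenness),
        closeness=strip(closeness),
    )


# ---------------------------------------------------------------------------
# random-matrix null
# ---------------------------------------------------------------------------

def random_network_null(
    n_samples: int = 100,
    n_microbes: int = 100,
    n_genes: int = 1000,
    replicates: int = 20,
    tail_fraction: float = 0.025,
    seed: int = 0,
) -> pd.DataFrame:
    """Degree-distribution null from structureless data.

    Per replicate, two cohorts of iid standard-normal microbe
    (n_microbes x n_samples) and gene (n_genes x n_samples) matrices are
    pushed through the identical correlate -> concordance filter ->
    extreme-tail selection -> degree pipeline.  Returns one row per
    replicate with pair/edge counts and degree-shape diagnostics
    (skewness, excess kurtosis); the per-microbe degrees are in the
    ``degrees`` column as arrays.
    """
    if min(n_samples, n_microbes, n_genes) < 4:
        raise ValueError("all dimensions must be >= 4")
    rng = np.random.default_rng(seed)
    rows = []
    samples = [f"s{i}" for i in range(n_samples)]
    for rep in range(replicates):
        mats = [
            rng.standard_normal((n_microbes, n_samples)),
            rng.standard_normal((n_genes, n_samples)),
            rng.standard_normal((n_microbes, n_samples)),
            rng.standard_normal((n_genes, n_samples)),
        ]
        ma = pd.DataFrame(mats[0], index=[f"m{i}" for i in range(n_microbes)], columns=samples)
        ga = pd.DataFrame(mats[1], index=[f"g{i}" for i in range(n_genes)], columns=samples)
        mb = pd.DataFrame(mats[2], index=ma.index, columns=samples)
        gb = pd.DataFrame(mats[3], index=ga.index, columns=samples)
        pairs = pair_correlations(ma, ga, mb, gb)
        edges = concordant_edge_select(pairs, tail_fraction=tail_fraction)
        degrees = (
            edges.groupby("microbe").size().reindex(ma.index, fill_value=0).to_numpy()
        )
        rows.append(
            {
                "replicate": rep,
                "n_pairs": len(pairs),
                "n_concordant": int(pairs["concordant"].sum()),
                "n_edges": len(edges),
                "degree_mean": float(degrees.mean()),
                "degree_skewness": float(stats.skew(degrees)),
                "degree_excess_kurtosis": float(stats.kurtosis(degrees)),
                "degrees": degrees,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# degree-distribution shape
# ---------------------------------------------------------------------------

def _zeta_tail_fit(deg: np.ndarray, dmin: int) -> tuple[float, float]:
    """Discrete power-law ML exponent for degrees >= dmin and its KS distance.

    The model CDF is evaluated through the Hurwitz zeta survival function
    at the observed values, so arbitrarily large hub degrees cost nothing.
    """
    tail = np.sort(deg[deg >= dmin])
    n = tail.size
    mean_log = float(np.mean(np.log(tail)))
    # exact discrete MLE: minimize ln zeta(alpha, dmin) + alpha * mean(ln d)
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda a: np.log(special.zeta(a, dmin)) + a * mean_log,
        bounds=(1.01, 20.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    alpha = float(res.x)
    vals = np.unique(tail)
    z0 = special.zeta(alpha, dmin)
    model_cdf = 1.0 - special.zeta(alpha, vals + 1) / z0
    emp_cdf = np.searchsorted(tail, vals, side="right") / n
    return alpha, float(np.max(np.abs(emp_cdf - model_cdf)))


def degree_distribution_fit(
    degrees: np.ndarray | Sequence[int], min_tail_fraction: float = 0.10
) -> tuple[float | None, bool]:
    """Power-law tail exponent (discrete MLE, KS-chosen dmin) and heavy-tail flag.

    The lower cutoff dmin is chosen by minimizing the KS distance between
    the tail and the fitted zeta model; candidate cutoffs are restricted
    to tails holding at least ``min_tail_fraction`` of the nonzero-degree
    nodes (floor 10) because the KS statistic is too noisy on tiny tails
    to anchor the estimate.

    heavy_tail_flag is True when the degree distribution has excess
    kurtosis > 1 *and* the fitted exponent lies in (1.5, 4) — the regime
    of hub-dominated empirical networks.  Degenerate inputs (all equal
    degrees, or fewer than 10 nonzero-degree nodes) yield a null fit.
    """
    deg = np.asarray(degrees, dtype=float)
    deg = deg[deg >= 1]
    if deg.size < 10 or np.unique(deg).size < 2:
        return None, False
    kurt = float(stats.kurtosis(deg))
    min_tail = max(int(np.ceil(min_tail_fraction * deg.size)), 10)
    best_alpha, best_ks = None, np.inf
    for dmin in np.unique(deg.astype(int)):
        tail_n = int((deg >= dmin).sum())
        if tail_n < min_tail or dmin < 1:
            continue
        alpha, ks = _zeta_tail_fit(deg.astype(int), int(dmin))
        if ks < best_ks:
            best_alpha, best_ks = alpha, ks
    if best_alpha is None:
        return None, False
    heavy = kurt > 1.0 and 1.5 < best_alpha < 4.0
    return float(best_alpha), bool(heavy)


# ---------------------------------------------------------------------------
# preranked gene-set enrichment
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name, description, tab-separated members."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def _enrichment_score(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Weighted KS running-sum enrichment score (weight exponent 1)."""
    hit_w = weights * in_set
    total_hit = hit_w.sum()
    n_miss = (~in_set.astype(bool)).sum()
    if total_hit == 0 or n_miss == 0:
        return 0.0
    step = hit_w / total_hit - (~in_set.astype(bool)) / n_miss
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def preranked_enrichment(
    ranked_genes: pd.Series | Mapping[str, float],
    gene_sets: Mapping[str, Sequence[str]],
    n_permutations: int = 1000,
    min_size: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked gene-set enrichment with gene-label permutation p-values.

    Genes are sorted by the ranking statistic (descending); the enrichment
    score is the extreme of the weighted Kolmogorov-Smirnov running sum
    with weight |statistic|.  The null distribution draws the same number
    of member positions uniformly from the ranking; p is one-sided on the
    observed ES sign, and BH correction is applied across the surviving
    sets.  Sets with fewer than ``min_size`` members in the ranking are
    skipped with a warning.
    """
    ranked = pd.Series(dict(ranked_genes)) if not isinstance(ranked_genes, pd.Series) else ranked_genes
    ranked = ranked.sort_values(ascending=False)
    genes = ranked.index.to_numpy()
    weights = np.abs(ranked.to_numpy(dtype=float))
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    rows = []
    usable = False
    for name, members in gene_sets.items():
        idx = np.array(sorted({pos[g] for g in members if g in pos}), dtype=int)
        if idx.size < min_size:
            warnings.warn(f"gene set {name!r}: only {idx.size} members in ranking; skipped")
            continue
        usable = True
        in_set = np.zeros(genes.size, dtype=float)
        in_set[idx] = 1.0
        es = _enrichment_score(in_set, weights)
        null = np.empty(n_permutations)
        k = idx.size
        for b in range(n_permutations):
            perm_idx = rng.choice(genes.size, size=k, replace=False)
            mask = np.zeros(genes.size, dtype=float)
            mask[perm_idx] = 1.0
            null[b] = _enrichment_score(mask, weights)
        if es >= 0:
            p = (1.0 + float(np.sum(null >= es))) / (n_permutations + 1.0)
        else:
            p = (1.0 + float(np.sum(null <= es))) / (n_permutations + 1.0)
        rows.append({"set": name, "size": int(k), "es": es, "p": p})
    if not usable and gene_sets:
        return pd.DataFrame(columns=["set", "size", "es", "p", "q"])
    out = pd.DataFrame(rows)
    if not out.empty:
        from .association import bh_adjust

        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
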