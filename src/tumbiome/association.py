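"""Clinical association of taxa with survival and host variables.

Per-cancer and pooled ("all") analyses:

* overall survival — Cox proportional hazards with a single binary
  presence/absence covariate (Efron tie handling), significance from the
  likelihood-ratio test;
* continuous host variables (age, BMI, hypoxia score, immune-cell
  fractions) — Spearman rank correlation of normalized microbe abundance;
* Benjamini-Hochberg FDR within each (cohort, stratum, covariate,
  rank-level) family;
* the discovery/validation concordance intersection: a taxon-covariate
  association counts only when significant in both cohorts with the same
  direction of effect.

The Cox fit is a dedicated one-parameter solver: the partial likelihood of
a single binary covariate is concave in the log hazard ratio, so a bounded
scalar maximization is exact, fast enough for tens of thousands of
per-taxon fits, and returns a flagged null (never raises) on monotone
likelihoods from complete separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "CoxResult",
    "CoxEngine",
    "cox_presence",
    "multi_threshold_survival",
    "spearman_assoc",
    "hypoxia_score",
    "bh_adjust",
    "concordance_intersect",
    "survival_associations",
    "covariate_associations",
]

_BETA_BOUND = 15.0  # |log HR| beyond this is monotone-likelihood territory


@dataclass(frozen=True)
class CoxResult:
    """Single-covariate Cox fit: log hazard ratio and LRT p-value."""

    log_hr: float | None
    p: float | None
    converged: bool

    @property
    def is_null(self) -> bool:
        return self.log_hr is None


NULL_COX = CoxResult(log_hr=None, p=None, converged=False)


class CoxEngine:
    """Precomputed survival ordering for repeated single-covariate Cox fits.

    Sorting and tie-grouping depend only on (time, event), so one engine
    serves every taxon tested against the same survival data.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray) -> None:
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
        if (time < 0).any():
            raise ValueError("survival times must be >= 0")
        order = np.argsort(time, kind="stable")
        self.time = time[order]
        self.event = event[order]
        self.order = order
        self.n = time.size
        ev_idx = np.flatnonzero(self.event)
        self._ev_idx = ev_idx
        if ev_idx.size:
            ev_times = self.time[ev_idx]
            starts = np.flatnonzero(np.r_[True, np.diff(ev_times) != 0])
            self._grp_first_ev = ev_idx[starts]  # first event index per tied group
            self._grp_sizes = np.diff(np.r_[starts, ev_idx.size])
            # index of first at-risk sample (ascending order) per group
            self._risk_start = np.searchsorted(self.time, ev_times[starts], side="left")
            self._grp_id = np.repeat(np.arange(starts.size), self._grp_sizes)
            self._l_within = np.arange(ev_idx.size) - np.repeat(starts, self._grp_sizes)

    def loglik(self, beta: float, z_sorted: np.ndarray) -> float:
        """Efron partial log-likelihood for a binary covariate at ``beta``."""
        if self._ev_idx.size == 0:
            return 0.0
        r = np.exp(beta * z_sorted)
        suffix = np.cumsum(r[::-1])[::-1]  # suffix[i] = sum r[i:]
        risk_sum = suffix[self._risk_start]  # per tied group
        d_sum = np.add.reduceat(r[self._ev_idx], np.r_[0, np.cumsum(self._grp_sizes)[:-1]])
        s = float(z_sorted[self._ev_idx].sum())
        frac = self._l_within / self._grp_sizes[self._grp_id]
        terms = np.log(risk_sum[self._grp_id] - frac * d_sum[self._grp_id])
        return beta * s - float(terms.sum())

    def fit_binary(self, z: np.ndarray) -> CoxResult:
        """Maximize the one-parameter partial likelihood; LRT vs beta = 0."""
        z = np.asarray(z, dtype=float)
        zs = z[self.order]
        n1 = int(z.sum())
        if n1 == 0 or n1 == z.size or not self.event.any():
            return NULL_COX
        res = minimize_scalar(
            lambda b: -self.loglik(b, zs),
            bounds=(-_BETA_BOUND, _BETA_BOUND),
            method="bounded",
            options={"xatol": 1e-8},
        )
        beta = float(res.x)
        if abs(beta) > _BETA_BOUND - 1.0:
            return NULL_COX  # monotone likelihood / separation
        lrt = 2.0 * (self.loglik(beta, zs) - self.loglik(0.0, zs))
        p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
        return CoxResult(log_hr=beta, p=p, converged=True)


def cox_presence(
    presence: np.ndarray | pd.Series,
    time: np.ndarray | pd.Series,
    event: np.ndarray | pd.Series,
) -> CoxResult:
    """Cox PH fit of overall survival on a presence/absence indicator.

    Returns a flagged null when a presence group is empty, there are no
    events, or the partial likelihood is monotone.
    """
    z = np.asarray(presence, dtype=bool).astype(float)
    engine = CoxEngine(np.asarray(time, dtype=float), np.asarray(event, dtype=bool))
    return engine.fit_binary(z)


def multi_threshold_survival(
    abundance: np.ndarray | pd.Series,
    time: np.ndarray | pd.Series,
    event: np.ndarray | pd.Series,
    quantile_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Survival association re-tested across abundance dichotomization cutoffs.

    At each quantile of the abundance distribution the samples are split
    into low/high groups and the presence-style Cox fit repeated; rows
    where a side is empty are null.  Complements the presence analysis by
    asking whether the association persists across abundance thresholds.
    """
    a = np.asarray(abundance, dtype=float)
    if quantile_grid is None:
        quantile_grid = np.round(np.arange(0.1, 0.91, 0.1), 10)
    engine = CoxEngine(np.asarray(time, dtype=float), np.asarray(event, dtype=bool))
    rows = []
    degenerate = np.unique(a).size < 2
    for q in quantile_grid:
        thr = float(np.quantile(a, q))
        if degenerate:
            rows.append((q, thr, None, None))
            continue
        z = (a > thr).astype(float)
        res = engine.fit_binary(z)
        rows.append((q, thr, res.log_hr, res.p))
    return pd.DataFrame(rows, columns=["quantile", "threshold", "log_hr", "p"])


# ---------------------------------------------------------------------------
# rank correlations, hypoxia score, FDR
# ---------------------------------------------------------------------------

def spearman_assoc(
    abundance: np.ndarray | pd.Series, covariate: np.ndarray | pd.Series
) -> tuple[float | None, float | None]:
    """Spearman rho (average ranks for ties) with two-sided t-approximation p.

    Pairs with a missing value on either side are deleted; fewer than 4
    complete pairs or a constant vector yields a null result.
    """
    a = np.asarray(abundance, dtype=float)
    c = np.asarray(covariate, dtype=float)
    mask = np.isfinite(a) & np.isfinite(c)
    if int(mask.sum()) < 4:
        return None, None
    a, c = a[mask], c[mask]
    if np.ptp(a) == 0 or np.ptp(c) == 0:
        return None, None
    rho, p = stats.spearmanr(a, c)
    return float(rho), float(p)


def hypoxia_score(
    expression: pd.DataFrame, signature_genes: Sequence[str]
) -> pd.Series:
    """Median-split hypoxia metagene score.

    For each signature gene present in the expression matrix a sample
    scores +1 when its expression is strictly above the cohort median for
    that gene, else -1; the per-gene scores are summed.  Range is
    [-k, +k] for k genes found.
    """
    present = [g for g in signature_genes if g in expression.index]
    missing = sorted(set(signature_genes) - set(present))
    if not present:
        raise ValueError("no signature genes found in the expression matrix")
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent from expression matrix")
    sub = expression.loc[present]
    med = sub.median(axis=1)
    signs = np.where(sub.gt(med, axis=0), 1, -1)
    return pd.Series(signs.sum(axis=0), index=expression.columns, dtype=int)


def bh_adjust(p_values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN/None entries pass through."""
    p = np.array(
        [np.nan if v is None else float(v) for v in np.asarray(p_values, dtype=object)],
        dtype=float,
    )
    mask = np.isfinite(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pm = p[mask]
    m = pm.size
    if m:
        order = np.argsort(pm, kind="stable")
        ranked = pm[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qm = np.empty(m)
        qm[order] = np.minimum(ranked, 1.0)
        q[mask] = qm
    return q


# ---------------------------------------------------------------------------
# association drivers and the concordance intersection
# ---------------------------------------------------------------------------

ASSOC_COLUMNS = [
    "taxon",
    "rank_level",
    "stratum",
    "covariate",
    "estimate",
    "p",
    "q",
    "direction",
    "cohort",
]


def _finalize(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=ASSOC_COLUMNS)
    if df.empty:
        return df
    for _, idx in df.groupby(["stratum", "covariate", "rank_level"]).groups.items():
        df.loc[idx, "q"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    df["direction"] = np.sign(df["estimate"].astype(float))
    return df


def survival_associations(
    presence: pd.DataFrame,
    metadata: pd.DataFrame,
    cohort: str,
    rank_level: str = "species",
    stratum_col: str = "cancer_type",
    time_col: str = "os_days",
    event_col: str = "os_event",
    include_all: bool = True,
    per_cancer: bool = True,
    min_group: int = 1,
) -> pd.DataFrame:
    """Presence-stratified Cox survival association per cancer type and pooled.

    BH correction is applied within each (stratum, covariate, rank-level)
    family.  Non-converged or degenerate fits yield NaN estimates that BH
    passes through.  ``per_cancer=False`` restricts to the pooled "all"
    stratum.
    """
    md = metadata.loc[presence.columns]
    strata: list[tuple[str, list[str]]] = []
    if include_all:
        strata.append(("all", list(presence.columns)))
    if per_cancer:
        for ct, sub in md.groupby(stratum_col, sort=True):
            strata.append((str(ct), list(sub.index)))
    records: list[dict] = []
    for stratum, samples in strata:
        sub_md = md.loc[samples]
        engine = CoxEngine(
            sub_md[time_col].to_numpy(dtype=float), sub_md[event_col].to_numpy(dtype=bool)
        )
        sub_pres = presence[samples]
        for taxon in sub_pres.index:
            z = sub_pres.loc[taxon].to_numpy(dtype=bool)
            if z.sum() < min_group or (~z).sum() < min_group:
                res = NULL_COX
            else:
                res = engine.fit_binary(z.astype(float))
            records.append(
                {
                    "taxon": taxon,
                    "rank_level": rank_level,
                    "stratum": stratum,
                    "covariate": "survival",
                    "estimate": np.nan if res.log_hr is None else res.log_hr,
                    "p": np.nan if res.p is None else res.p,
                    "q": np.nan,
                    "direction": np.nan,
                    "cohort": cohort,
                }
            )
    return _finalize(records)


def covariate_associations(
    abundance: pd.DataFrame,
    covariates: pd.DataFrame,
    cohort: str,
    rank_level: str = "species",
    metadata: pd.DataFrame | None = None,
    stratum_col: str = "cancer_type",
    include_all: bool = True,
) -> pd.DataFrame:
    """Spearman association of each taxon with each continuous covariate.

    ``covariates`` is samples x variables (age, BMI, hypoxia score,
    immune-cell fractions...).  Strata follow the metadata cancer-type
    column when metadata is given, plus the pooled "all" stratum.
    """
    samples = [s for s in abundance.columns if s in covariates.index]
    if not samples:
        raise ValueError("no shared samples between abundance and covariates")
    strata: list[tuple[str, list[str]]] = []
    if include_all:
        strata.append(("all", samples))
    if metadata is not None:
        md = metadata.loc[samples]
        for ct, sub in md.groupby(stratum_col, sort=True):
            strata.append((str(ct), list(sub.index)))
    records: list[dict] = []
    for stratum, ss in strata:
        sub_ab = abundance[ss]
        sub_cov = covariates.loc[ss]
        for cov_name in sub_cov.columns:
            cvals = sub_cov[cov_name].to_numpy(dtype=float)
            for taxon in sub_ab.index:
                rho, p = spearman_assoc(sub_ab.loc[taxon].to_numpy(dtype=float), cvals)
                records.append(
                    {
                        "taxon": taxon,
                        "rank_level": rank_level,
                        "stratum": stratum,
                        "covariate": cov_name,
                        "estimate": np.nan if rho is None else rho,
                        "p": np.nan if p is None else p,
                        "q": np.nan,
                        "direction": np.nan,
                        "cohort": cohort,
                    }
                )
    return _finalize(records)


KEY_COLS = ["taxon", "rank_level", "stratum", "covariate"]


def concordance_intersect(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    alpha: float = 0.05,
    use_q: bool = True,
) -> pd.DataFrame:
    """Associations significant in both cohorts with agreeing direction.

    Results are matched on (taxon, rank-level, stratum, covariate);
    unmatched keys are ignored.  Significance uses BH q-values by default
    (raw p with ``use_q=False``).  The output carries both cohorts'
    estimates.
    """
    col = "q" if use_q else "p"
    merged = results_a.merge(results_b, on=KEY_COLS, suffixes=("_A", "_B"))
    ok = (
        (merged[f"{col}_A"] < alpha)
        & (merged[f"{col}_B"] < alpha)
        & (merged["direction_A"] == merged["direction_B"])
        & merged["direction_A"].notna()
        & (merged["direction_A"] != 0)
    )
    out = merged.loc[ok, KEY_COLS + [
        "estimate_A", "p_A", "q_A", "estimate_B", "p_B", "q_B", "direction_A"
    ]].copy()
    return out.rename(columns={"direction_A": "direction"}).reset_index(drop=True)
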