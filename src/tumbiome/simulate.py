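"""Synthetic tumor-RNA-seq microbiome cohorts with planted structure.

Generates everything the pipeline consumes — taxon count tables with
lineages and human read counts, sample metadata (technical batch
variables, input RNA concentration, clinical and survival fields), gene
expression, and a truth ledger — with four kinds of planted signal:

* reagent-style contaminants whose expected relative abundance is
  proportional to 1 / input RNA concentration;
* multiplicative batch effects on a subset of taxa, keyed to the
  preservation method;
* survival effects: per-sample exponential hazards scaled by
  exp(log HR x presence) for planted taxa, with administrative censoring
  tuned to roughly 40% events;
* a hub microbe whose abundance is linearly coupled to a block of genes.

Counts are negative binomial (overdispersion typical of classifier count
tables) with per-taxon occupancy, so presence/absence structure exists
independently of abundance.  Paired discovery/validation cohorts share
every planted truth but have independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .taxa import TaxonCountTable, TaxonLineage

__all__ = ["FixtureSpec", "Cohort", "CohortTruth", "generate_cohort", "generate_cohort_pair"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic cohort."""

    n_samples: int = 100
    n_taxa: int = 200
    n_genes: int = 1000
    n_contaminants: int = 30
    contaminant_noise_cv: float = 0.10
    batch_effect_size: float = 2.0  # log2 shift on affected taxa
    batch_taxa_fraction: float = 0.5
    cancer_effect_size: float = 1.0  # log2 shift marking a cancer type
    planted_survival_taxa: tuple[tuple[int, float], ...] = ()  # (taxon index, log HR)
    planted_hub: tuple[int, int, float] | None = None  # (microbe index, n genes, rho)
    cancer_types: tuple[str, ...] = ("lung", "colorectal", "sarcoma")
    cancer_proportions: tuple[float, ...] = (0.40, 0.35, 0.25)
    concentration_mu: float = 1.0  # lognormal parameters of input RNA concentration
    concentration_sigma: float = 0.6
    nb_dispersion: float = 0.5
    baseline_mean_log: float = np.log(50.0)
    baseline_mean_sd: float = 1.0
    baseline_hazard: float = 1.0 / 1500.0  # per day
    target_event_fraction: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contaminants > self.n_taxa:
            raise ValueError("more contaminants than taxa")
        if (self.planted_survival_taxa or self.planted_hub) and (
            self.n_contaminants >= self.n_taxa
        ):
            raise ValueError("no non-contaminant taxa left for planted effects")
        if len(self.cancer_types) != len(self.cancer_proportions):
            raise ValueError("cancer_types and cancer_proportions length mismatch")


@dataclass
class CohortTruth:
    """Every planted parameter, sufficient to score recovery downstream."""

    contaminant_taxids: list[int]
    survival_taxa: list[tuple[int, float]]  # (taxid, log HR)
    hub: tuple[int, list[str], float] | None  # (taxid, gene names, rho)
    batch_taxids: list[int]
    batch_effect_size: float
    cancer_effect_taxids: list[int]
    cancer_effect_type: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.contaminant_taxids:
            rows.append({"kind": "contaminant", "taxid": t, "value": np.nan, "extra": ""})
        for t, hr in self.survival_taxa:
            rows.append({"kind": "survival", "taxid": t, "value": hr, "extra": ""})
        if self.hub is not None:
            rows.append(
                {
                    "kind": "hub",
                    "taxid": self.hub[0],
                    "value": self.hub[2],
                    "extra": ",".join(self.hub[1]),
                }
            )
        for t in self.batch_taxids:
            rows.append(
                {"kind": "batch", "taxid": t, "value": self.batch_effect_size, "extra": ""}
            )
        for t in self.cancer_effect_taxids:
            rows.append(
                {"kind": "cancer", "taxid": t, "value": np.nan, "extra": self.cancer_effect_type}
            )
        rows.append({"kind": "seed", "taxid": -1, "value": self.seed, "extra": ""})
        return pd.DataFrame(rows, columns=["kind", "taxid", "value", "extra"])


@dataclass
class Cohort:
    """One synthetic cohort: counts, metadata, expression, planted truth."""

    label: str
    table: TaxonCountTable
    metadata: pd.DataFrame  # indexed by sample
    expression: pd.DataFrame  # genes x samples
    truth: CohortTruth


# ---------------------------------------------------------------------------

SPECIES_BASE = 1000
GENUS_BASE = 100000
PHYLUM_BASE = 200000
DOMAIN_TAXID = 300000


def _make_lineages(n_taxa: int) -> dict[int, TaxonLineage]:
    """Toy 4-level taxonomy: species -> genus (5 each) -> phylum (50) -> domain."""
    lineages: dict[int, TaxonLineage] = {
        DOMAIN_TAXID: TaxonLineage(DOMAIN_TAXID, "Bacteria", "domain", None)
    }
    for i in range(n_taxa):
        genus_id = GENUS_BASE + i // 5
        phylum_id = PHYLUM_BASE + i // 50
        if phylum_id not in lineages:
            lineages[phylum_id] = TaxonLineage(
                phylum_id, f"phylum{i // 50}", "phylum", DOMAIN_TAXID
            )
        if genus_id not in lineages:
            lineages[genus_id] = TaxonLineage(genus_id, f"genus{i // 5}", "genus", phylum_id)
        sp = SPECIES_BASE + i
        lineages[sp] = TaxonLineage(sp, f"species{i}", "species", genus_id)
    return lineages


def _draw_truth(spec: FixtureSpec) -> CohortTruth:
    """Plant-parameter draw shared between paired cohorts."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    taxids = np.arange(SPECIES_BASE, SPECIES_BASE + spec.n_taxa)
    contaminants = list(map(int, taxids[: spec.n_contaminants]))
    clean = taxids[spec.n_contaminants :]
    survival = [
        (int(clean[i % len(clean)]), float(hr)) for i, hr in spec.planted_survival_taxa
    ]
    hub = None
    if spec.planted_hub is not None:
        m_idx, n_corr, rho = spec.planted_hub
        hub_taxid = int(clean[m_idx % len(clean)])
        gene_names = [f"gene{j}" for j in range(min(n_corr, spec.n_genes))]
        hub = (hub_taxid, gene_names, float(rho))
    n_batch = int(round(spec.batch_taxa_fraction * spec.n_taxa))
    batch_taxids = sorted(map(int, rng.choice(taxids, size=n_batch, replace=False)))
    n_cancer = max(spec.n_taxa // 10, 1)
    cancer_taxids = sorted(map(int, rng.choice(clean, size=min(n_cancer, clean.size), replace=False)))
    return CohortTruth(
        contaminant_taxids=contaminants,
        survival_taxa=survival,
        hub=hub,
        batch_taxids=batch_taxids,
        batch_effect_size=spec.batch_effect_size,
        cancer_effect_taxids=cancer_taxids,
        cancer_effect_type=spec.cancer_types[0],
        seed=spec.seed,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion * mu^2."""
    mu = np.clip(mu, 1e-9, None)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_cohort(
    spec: FixtureSpec,
    label: str = "discovery",
    sequencing_site: str = "centerA",
    truth: CohortTruth | None = None,
    noise_seed: int | None = None,
) -> Cohort:
    """Generate one cohort; supply ``truth`` to reuse planted parameters."""
    if truth is None:
        truth = _draw_truth(spec)
    seed = spec.seed if noise_seed is None else noise_seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    n, t = spec.n_samples, spec.n_taxa
    samples = [f"{label}_{i:03d}" for i in range(n)]
    taxids = np.arange(SPECIES_BASE, SPECIES_BASE + t)
    tax_pos = {tx: i for i, tx in enumerate(taxids)}

    # metadata -------------------------------------------------------------
    concentration = rng.lognormal(spec.concentration_mu, spec.concentration_sigma, size=n)
    preservation = rng.choice(["FF", "FFPE"], size=n, p=[0.75, 0.25])
    flow_cell = rng.choice(["fc1", "fc2"], size=n)
    cancer_type = rng.choice(spec.cancer_types, size=n, p=spec.cancer_proportions)
    age = np.clip(rng.normal(62, 12, size=n), 18, 95).round(1)
    bmi = np.clip(rng.normal(28, 6, size=n), 15, 60).round(1)
    human_reads = rng.lognormal(np.log(1e6), 0.3, size=n).astype(np.int64)

    # counts ---------------------------------------------------------------
    base_mean = rng.lognormal(spec.baseline_mean_log, spec.baseline_mean_sd, size=t)
    occupancy = rng.uniform(0.3, 0.8, size=t)
    for taxid, _ in truth.survival_taxa:
        occupancy[tax_pos[taxid]] = 0.5  # balanced groups for survival stratification
    present = rng.random((t, n)) < occupancy[:, None]
    mu = np.broadcast_to(base_mean[:, None], (t, n)).copy()

    # contaminants: expected abundance proportional to 1/concentration
    c_idx = np.array([tax_pos[tx] for tx in truth.contaminant_taxids], dtype=int)
    if c_idx.size:
        k = rng.lognormal(np.log(100.0), 0.5, size=c_idx.size)
        median_c = np.exp(spec.concentration_mu)
        noise = rng.lognormal(
            0.0, spec.contaminant_noise_cv, size=(c_idx.size, n)
        )
        mu[c_idx, :] = (k[:, None] * median_c / concentration[None, :]) * noise
        present[c_idx, :] = True  # reagent contamination hits every sample

    # cancer-type biological effect on a taxon subset
    ce_idx = np.array([tax_pos[tx] for tx in truth.cancer_effect_taxids], dtype=int)
    in_type = cancer_type == truth.cancer_effect_type
    if ce_idx.size and in_type.any():
        mu[np.ix_(ce_idx, np.flatnonzero(in_type))] *= 2.0**spec.cancer_effect_size

    # technical batch effect keyed to preservation method
    b_idx = np.array([tax_pos[tx] for tx in truth.batch_taxids], dtype=int)
    is_ffpe = preservation == "FFPE"
    if b_idx.size and is_ffpe.any():
        mu[np.ix_(b_idx, np.flatnonzero(is_ffpe))] *= 2.0**truth.batch_effect_size

    counts = _nb_draw(rng, mu, spec.nb_dispersion) * present
    counts_df = pd.DataFrame(counts.astype(np.int64), index=taxids, columns=samples)
    table = TaxonCountTable(
        counts=counts_df,
        lineages=_make_lineages(t),
        human_reads=pd.Series(human_reads, index=samples),
    )

    # survival -------------------------------------------------------------
    log_hr = np.zeros(n)
    for taxid, hr in truth.survival_taxa:
        log_hr += hr * (counts[tax_pos[taxid]] > 0)
    hazard = spec.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    horizon = -np.log(1.0 - spec.target_event_fraction) / spec.baseline_hazard
    os_event = t_event <= horizon
    os_days = np.minimum(t_event, horizon).round(1)

    metadata = pd.DataFrame(
        {
            "cohort": label,
            "cancer_type": cancer_type,
            "sequencing_site": sequencing_site,
            "preservation": preservation,
            "flow_cell": flow_cell,
            "concentration": concentration,
            "human_reads": human_reads,
            "age_at_collection": age,
            "bmi": bmi,
            "os_days": os_days,
            "os_event": os_event.astype(int),
        },
        index=pd.Index(samples, name="sample"),
    )

    # expression -----------------------------------------------------------
    gene_names = [f"gene{j}" for j in range(spec.n_genes)]
    gene_mean = rng.normal(8.0, 2.0, size=spec.n_genes)
    expr = gene_mean[:, None] + rng.standard_normal((spec.n_genes, n))
    if truth.hub is not None:
        hub_taxid, hub_genes, rho = truth.hub
        z = np.log1p(counts[tax_pos[hub_taxid]].astype(float))
        z = (z - z.mean()) / (z.std() or 1.0)
        for g in hub_genes:
            j = int(g.removeprefix("gene"))
            expr[j] = gene_mean[j] + rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    expression = pd.DataFrame(expr, index=gene_names, columns=samples)

    return Cohort(label=label, table=table, metadata=metadata, expression=expression, truth=truth)


def generate_cohort_pair(spec: FixtureSpec) -> tuple[Cohort, Cohort]:
    """Two cohorts with identical planted truths and independent noise.

    The discovery/validation pair mirrors a two-dataset design; the cohorts
    get distinct sequencing centers so the cohort label can serve as the
    technical variable in normalization.
    """
    truth = _draw_truth(spec)
    a = generate_cohort(
        spec, label="discovery", sequencing_site="centerA", truth=truth, noise_seed=spec.seed * 2 + 1
    )
    b = generate_cohort(
        spec, label="validation", sequencing_site="centerB", truth=truth, noise_seed=spec.seed * 2 + 2
    )
    return a, b
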