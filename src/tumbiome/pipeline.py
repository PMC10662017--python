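"""End-to-end orchestration of the quantification pipeline.

Stage order follows the decontamination design: minimum-read rule ->
microbial-load sample filter -> small-batch sample filter -> statistical
taxon filter -> literature taxon filter -> normalization (log-CPM weights +
technical-covariate removal) -> relative abundance / rarefied prevalence ->
survival and covariate associations -> two-cohort concordance -> microbe-gene
network.  Stages can be toggled off in the config; every removal is recorded
in a per-phase ledger so the read loss at each step is reproducible from the
run directory.

Outputs are deterministic for a fixed config + seed: every table carries a
header comment with the config hash and seed, and the in-directory run log
is timestamp-free (timestamps go to stderr only).
"""

from __future__ import annotations

import hashlib
import io
import sys
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import association, contamination, network, normalize, simulate, taxa

__all__ = ["default_config", "run_pipeline", "config_hash"]

STAGES = (
    "min_reads",
    "load_filter",
    "batch_filter",
    "statistical_filter",
    "literature_filter",
    "normalize",
    "prevalence",
    "associate",
    "concord",
    "network",
)


def default_config(seed: int = 0) -> dict:
    """Config skeleton for a fully simulated paired-cohort run."""
    return {
        "seed": seed,
        "simulate": {"pair": True, "n_samples": 60, "n_taxa": 80, "n_genes": 200},
        "stages": {s: True for s in STAGES},
        "min_reads": {"threshold": 5, "mode": "entry"},
        "filters": {
            "max_load_ratio": 0.20,
            "min_batch_size": 10,
            "batch_fields": ["sequencing_site", "preservation", "flow_cell"],
            "contaminant_p_threshold": 0.10,
            "n_permutations": 1000,
            "deny_list": None,
            "spare_list": None,
        },
        "normalization": {
            "bio_vars": ["cancer_type"],
            "adj_vars": ["sequencing_site", "preservation"],
        },
        "rarefy": {"depth": "min"},
        "association": {"alpha": 0.05, "use_q": True},
        "network": {"tail_fraction": 0.025},
    }


def config_hash(config: Mapping[str, Any]) -> str:
    blob = yaml.safe_dump(_plain(config), sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _plain(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


class _Log:
    """Run log: timestamp-free file content, timestamped stderr echo."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def __call__(self, msg: str) -> None:
        self.lines.append(msg)
        print(f"[{time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)

    def dump(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n", encoding="utf-8")


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index: bool = True, index_label=None) -> None:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=index, index_label=index_label, float_format="%.10g")
    path.write_text(f"# {header}\n" + buf.getvalue(), encoding="utf-8")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_cohorts(config: Mapping[str, Any]) -> list[simulate.Cohort]:
    if "simulate" in config and config["simulate"]:
        sim = dict(config["simulate"])
        pair = sim.pop("pair", True)
        spec = simulate.FixtureSpec(seed=int(config.get("seed", 0)), **sim)
        if pair:
            return list(simulate.generate_cohort_pair(spec))
        return [simulate.generate_cohort(spec)]
    cohorts = []
    for entry in config["inputs"]["cohorts"]:
        table = taxa.read_table(entry["table_prefix"])
        metadata = pd.read_csv(entry["metadata"], sep="\t", index_col="sample")
        expression = None
        if entry.get("expression"):
            expression = pd.read_csv(entry["expression"], sep="\t", index_col=0)
        cohorts.append(
            simulate.Cohort(
                label=entry["label"],
                table=table,
                metadata=metadata,
                expression=expression,
                truth=None,
            )
        )
    return cohorts


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> Path:
    """Execute the enabled stages and write a reproducible run directory.

    Returns the run directory path.  Raises :class:`StageError` naming the
    failing stage; partial outputs written so far are left in place.
    """
    outdir = Path(outdir)
    tables = outdir / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    log = _Log()
    chash = config_hash(config)
    seed = int(config.get("seed", 0))
    header = f"config_hash={chash} seed={seed}"
    stages = {s: bool(config.get("stages", {}).get(s, True)) for s in STAGES}
    fcfg_raw = dict(config.get("filters", {}))
    deny = (
        contamination.read_taxon_list(fcfg_raw.pop("deny_list"))
        if fcfg_raw.get("deny_list")
        else (fcfg_raw.pop("deny_list", None) or frozenset())
    )
    spare = (
        contamination.read_taxon_list(fcfg_raw.pop("spare_list"))
        if fcfg_raw.get("spare_list")
        else (fcfg_raw.pop("spare_list", None) or frozenset())
    )
    fcfg = contamination.FilterConfig(
        max_load_ratio=float(fcfg_raw.get("max_load_ratio", 0.20)),
        min_batch_size=int(fcfg_raw.get("min_batch_size", 10)),
        batch_fields=tuple(fcfg_raw.get("batch_fields", ("sequencing_site", "preservation", "flow_cell"))),
        contaminant_p_threshold=float(fcfg_raw.get("contaminant_p_threshold", 0.10)),
        n_permutations=int(fcfg_raw.get("n_permutations", 1000)),
        deny_list=frozenset(deny),
        spare_list=frozenset(spare),
    )

    (outdir / "config.yaml").write_text(
        yaml.safe_dump(_plain(config), sort_keys=True), encoding="utf-8"
    )
    log(f"run start config_hash={chash} seed={seed}")

    ledger_rows: list[dict] = []

    def record(phase: str, cohort: str, status: str, n_removed: int, reads_removed: int, detail: str = "") -> None:
        ledger_rows.append(
            {
                "phase": phase,
                "cohort": cohort,
                "status": status,
                "n_removed": n_removed,
                "reads_removed": reads_removed,
                "detail": detail,
            }
        )

    try:
        cohorts = _load_cohorts(config)
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc
    log(f"loaded {len(cohorts)} cohorts: {[c.label for c in cohorts]}")

    results: dict[str, pd.DataFrame] = {}
    normalized: dict[str, normalize.NormalizedAbundance] = {}
    filtered: dict[str, taxa.TaxonCountTable] = {}

    for cohort in cohorts:
        label = cohort.label
        table = cohort.table
        total0 = int(table.counts.to_numpy().sum())

        def run_stage(stage: str, fn):
            nonlocal table
            if not stages[stage]:
                record(stage, label, "skipped", 0, 0)
                return
            before_reads = int(table.counts.to_numpy().sum())
            before_taxa = len(table.taxa)
            before_samples = len(table.samples)
            try:
                table, detail = fn(table)
            except Exception as exc:  # noqa: BLE001
                raise StageError(stage, exc) from exc
            after_reads = int(table.counts.to_numpy().sum())
            removed_items = (before_taxa - len(table.taxa)) + (
                before_samples - len(table.samples)
            )
            record(stage, label, "run", removed_items, before_reads - after_reads, detail)
            log(
                f"{label}: {stage} removed {removed_items} items, "
                f"{before_reads - after_reads} reads"
            )

        mr = config.get("min_reads", {})
        rule = taxa.MinReadRule(
            threshold=int(mr.get("threshold", 5)), mode=mr.get("mode", "entry")
        )
        run_stage("min_reads", lambda tb: (taxa.apply_min_reads(tb, rule), ""))

        def _load(tb):
            out, removed = contamination.filter_microbial_load(tb, fcfg)
            return out, ";".join(removed["sample"].astype(str))

        run_stage("load_filter", _load)

        def _batch(tb):
            out, removed = contamination.filter_small_batches(tb, cohort.metadata, fcfg)
            return out, ";".join(removed["sample"].astype(str))

        run_stage("batch_filter", _batch)

        calls: list[contamination.ContaminantCall] = []
        if stages["statistical_filter"] or stages["literature_filter"]:
            try:
                sub_cfg = fcfg
                if not stages["literature_filter"]:
                    sub_cfg = contamination.FilterConfig(
                        **{
                            **{f: getattr(fcfg, f) for f in (
                                "max_load_ratio", "min_batch_size", "batch_fields",
                                "contaminant_p_threshold", "n_permutations",
                                "min_positive", "match_lineage",
                            )},
                            "deny_list": frozenset(),
                            "spare_list": frozenset(),
                        }
                    )
                calls = contamination.classify_contaminants(
                    table, cohort.metadata, sub_cfg, seed=seed
                )
                if not stages["statistical_filter"]:
                    calls = [
                        contamination.ContaminantCall(
                            c.taxid, c.name, c.p_value, False, c.flagged_literature, c.spared
                        )
                        for c in calls
                    ]
                _write_tsv(
                    contamination.calls_to_frame(calls),
                    tables / f"{label}.contaminant_calls.tsv",
                    header,
                    index=False,
                )
            except Exception as exc:  # noqa: BLE001
                raise StageError("statistical_filter", exc) from exc

        def _remove_contaminants(tb):
            out = contamination.remove_taxa(tb, calls)
            stat = sum(1 for c in calls if c.final_contaminant and c.flagged_statistical)
            lit = sum(
                1
                for c in calls
                if c.final_contaminant and c.flagged_literature and not c.flagged_statistical
            )
            return out, f"statistical={stat};literature_only={lit}"

        if stages["statistical_filter"] or stages["literature_filter"]:
            run_stage(
                "statistical_filter" if stages["statistical_filter"] else "literature_filter",
                _remove_contaminants,
            )
            if stages["statistical_filter"] and stages["literature_filter"]:
                record("literature_filter", label, "run", 0, 0, "applied with statistical filter")
            elif stages["statistical_filter"] and not stages["literature_filter"]:
                record("literature_filter", label, "skipped", 0, 0)
        else:
            record("statistical_filter", label, "skipped", 0, 0)
            record("literature_filter", label, "skipped", 0, 0)

        filtered[label] = table
        taxa.write_table(table, tables / f"{label}.filtered")
        log(f"{label}: {len(table.taxa)} taxa x {len(table.samples)} samples retained "
            f"({int(table.counts.to_numpy().sum())}/{total0} reads)")

        # normalization -----------------------------------------------------
        ncfg = config.get("normalization", {})
        if stages["normalize"]:
            try:
                md = cohort.metadata.loc[table.samples]
                bio = list(ncfg.get("bio_vars", ["cancer_type"]))
                adj = [
                    v
                    for v in ncfg.get("adj_vars", ["preservation"])
                    if md[v].nunique() > 1
                ]
                bio = [v for v in bio if md[v].nunique() > 1]
                va = normalize.voom_transform(table, md, bio + adj)
                na = normalize.snm_normalize(va, md, bio, adj)
                normalized[label] = na
                _write_tsv(na.values, tables / f"{label}.normalized.tsv", header, index_label="taxid")
                _write_tsv(na.weights, tables / f"{label}.weights.tsv", header, index_label="taxid")
                record("normalize", label, "run", 0, 0, f"bio={bio};adj={adj}")
            except Exception as exc:  # noqa: BLE001
                raise StageError("normalize", exc) from exc
        else:
            record("normalize", label, "skipped", 0, 0)

        # relative abundance / rarefied prevalence -------------------------
        if stages["prevalence"]:
            try:
                rel = normalize.relative_abundance(table)
                _write_tsv(rel, tables / f"{label}.relabund.tsv", header, index_label="taxid")
                depth = config.get("rarefy", {}).get("depth", "min")
                rare = normalize.rarefy(table, depth=depth, seed=seed)
                prev = normalize.prevalence(rare, seed=seed)
                results[f"{label}.prevalence"] = prev.presence
                _write_tsv(
                    prev.presence.astype(int),
                    tables / f"{label}.prevalence.tsv",
                    header,
                    index_label="taxid",
                )
                record("prevalence", label, "run", 0, 0, f"depth={prev.rarefaction_depth}")
            except Exception as exc:  # noqa: BLE001
                raise StageError("prevalence", exc) from exc
        else:
            record("prevalence", label, "skipped", 0, 0)

        # associations ------------------------------------------------------
        if stages["associate"] and f"{label}.prevalence" in results:
            try:
                md = cohort.metadata.loc[filtered[label].samples]
                assoc = association.survival_associations(
                    results[f"{label}.prevalence"], md, cohort=label
                )
                covars = md[["age_at_collection", "bmi"]].rename(
                    columns={"age_at_collection": "age"}
                )
                if label in normalized:
                    cov_assoc = association.covariate_associations(
                        normalized[label].values, covars, cohort=label, metadata=md
                    )
                    assoc = pd.concat([assoc, cov_assoc], ignore_index=True)
                results[f"{label}.assoc"] = assoc
                _write_tsv(assoc, tables / f"{label}.associations.tsv", header, index=False)
                record("associate", label, "run", 0, 0, f"n={len(assoc)}")
            except Exception as exc:  # noqa: BLE001
                raise StageError("associate", exc) from exc
        else:
            record("associate", label, "skipped", 0, 0)

    # concordance ----------------------------------------------------------
    acfg = config.get("association", {})
    if (
        stages["concord"]
        and len(cohorts) == 2
        and all(f"{c.label}.assoc" in results for c in cohorts)
    ):
        try:
            conc = association.concordance_intersect(
                results[f"{cohorts[0].label}.assoc"],
                results[f"{cohorts[1].label}.assoc"],
                alpha=float(acfg.get("alpha", 0.05)),
                use_q=bool(acfg.get("use_q", True)),
            )
            _write_tsv(conc, tables / "concordant.tsv", header, index=False)
            record("concord", "pair", "run", 0, 0, f"n={len(conc)}")
        except Exception as exc:  # noqa: BLE001
            raise StageError("concord", exc) from exc
    else:
        record("concord", "pair", "skipped", 0, 0)

    # network ---------------------------------------------------------------
    netcfg = config.get("network", {})
    if (
        stages["network"]
        and len(cohorts) == 2
        and all(c.expression is not None for c in cohorts)
        and all(c.label in normalized for c in cohorts)
    ):
        try:
            a, b = cohorts
            shared = sorted(
                set(normalized[a.label].values.index) & set(normalized[b.label].values.index)
            )
            pairs = network.pair_correlations(
                normalized[a.label].values.loc[shared],
                a.expression[normalized[a.label].values.columns],
                normalized[b.label].values.loc[shared],
                b.expression[normalized[b.label].values.columns],
            )
            edges = network.concordant_edge_select(
                pairs, tail_fraction=float(netcfg.get("tail_fraction", 0.025))
            )
            _write_tsv(edges, tables / "edges.tsv", header, index=False)
            if not edges.empty:
                net = network.build_network(edges)
                cent = net.microbe_centralities()
                _write_tsv(cent, tables / "centrality.tsv", header, index_label="taxon")
            record("network", "pair", "run", 0, 0, f"edges={len(edges)}")
        except Exception as exc:  # noqa: BLE001
            raise StageError("network", exc) from exc
    else:
        record("network", "pair", "skipped", 0, 0)

    ledger = pd.DataFrame(ledger_rows)
    _write_tsv(ledger, outdir / "removal_ledger.tsv", header, index=False)
    log("run complete")
    log.dump(outdir / "run.log")
    return outdir
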