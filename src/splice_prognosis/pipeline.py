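"""End-to-end orchestration: simulate -> preprocess -> survival scan ->
differential expression -> cross-cohort overlap/concordance ->
enrichment -> risk signature -> report.

Every stage boundary is a plain TSV/JSON file so any stage can be rerun
standalone or fed externally produced tables (e.g. a DEG table from a
different engine dropped in before the overlap stage). A run manifest
records the configuration hash, seed, thresholds, library versions and
every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diff_expression, io as cio
from .enrichment import DEFAULT_ENRICH_FDR, cluster_pvalue_matrix, enrich, summarize_terms
from .overlap import concordance
from .signature import classify_risk, derive_signature, evaluate_signature
from .simulate import (
    ModuleSpec,
    SimulatedCohort,
    SyntheticCohortConfig,
    TranscriptSpec,
    simulate_pair,
)
from .survival import scan_optimal_cutoff

__all__ = ["PipelineConfig", "PipelineError", "RunManifest", "run_pipeline", "load_config"]

log = logging.getLogger("splice_prognosis")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Thresholds and inputs of a full analysis run.

    Thresholds default to the study constants: genes analyzed at mean
    TPM > 1, transcripts at mean TPM > 5, DEGs at FDR < 1e-5, enriched
    terms at FDR < 1e-3, top 20% of the DEG table for cross-cohort
    comparison, scan window 10th-90th percentile, 25% expression strata
    and a 2-of-n high-risk vote.
    """

    seed: int = 1
    outdir: str = "results"
    cohort_effect_scale: float = 1.6
    simulation: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    gene_mean_tpm_min: float = 1.0
    transcript_mean_tpm_min: float = 5.0
    deg_fdr: float = 1e-5
    enrich_fdr: float = DEFAULT_ENRICH_FDR
    top_deg_fraction: float = 0.20
    scan_lo_pct: float = 10.0
    scan_hi_pct: float = 90.0
    strata_fraction: float = 0.25
    vote_threshold: int = 2
    min_generality: int = 0
    n_decoy_sets: int = 20
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.top_deg_fraction <= 1:
            raise ValueError("top_deg_fraction must be in (0, 1]")
        if not 0 < self.strata_fraction <= 0.5:
            raise ValueError("strata_fraction must be in (0, 0.5]")
        if not 0 <= self.scan_lo_pct < self.scan_hi_pct <= 100:
            raise ValueError("scan percentile window invalid")
        for name in ("gene_mean_tpm_min", "transcript_mean_tpm_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("deg_fdr", "enrich_fdr"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        # the simulation inherits the run seed
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    The ``simulation`` block maps onto the generator config, with
    transcripts and modules given as lists of mappings.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("simulation", {})
    if "transcripts" in sim_raw:
        sim_raw["transcripts"] = tuple(TranscriptSpec(**t) for t in sim_raw["transcripts"])
    if "modules" in sim_raw:
        sim_raw["modules"] = tuple(ModuleSpec(**m) for m in sim_raw["modules"])
    for key in ("background_log10_mean_range", "library_factor_range"):
        if key in sim_raw:
            sim_raw[key] = tuple(sim_raw[key])
    sim = SyntheticCohortConfig(**sim_raw)
    return PipelineConfig(simulation=sim, **raw)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict[str, str]
    started: str
    finished: str = ""
    status: str = "running"
    failed_stage: str = ""
    outputs: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _versions() -> dict[str, str]:
    import lifelines
    import scipy
    import sklearn
    import statsmodels

    return {
        "splice_prognosis": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "lifelines": lifelines.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _decoy_gene_sets(cohort: SimulatedCohort, n_sets: int, seed: int) -> cio.GeneSetCollection:
    """Module gene sets from the truth plus random decoy sets of the same
    size, forming the GMT collection for the enrichment stage."""
    sets = {
        sid: (f"module {sid}", frozenset(genes))
        for sid, genes in cohort.truth.module_genes.items()
    }
    pool = [g for g in cohort.gene_tpm.feature_ids if g.startswith("BG")]
    size = 40 if not sets else len(next(iter(sets.values()))[1])
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0xFFFFFFFF, 0x6D7]))
    for i in range(n_sets):
        if len(pool) < size:
            break
        members = rng.choice(pool, size=size, replace=False)
        sets[f"DECOY{i + 1:03d}"] = (f"random decoy {i + 1}", frozenset(map(str, members)))
    return cio.GeneSetCollection(sets)


def _write_scans(scans: dict, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "transcript_id": tid,
                "cutoff": s.cutoff,
                "p_value": s.p_value,
                "direction": s.direction,
                "n_high": s.n_high,
                "n_low": s.n_low,
                "n_candidates": len(s.candidate_cutoffs),
            }
            for tid, s in scans.items()
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_cox(cohort: SimulatedCohort, tx_ids: list[str], path: Path) -> None:
    """Univariate Cox per transcript plus one joint multivariate fit,
    confirming the scan's prognostic calls; covariates are log2(TPM+1)."""
    from .survival import cox_fit

    t, e = cohort.clinical.aligned(cohort.tx_tpm.sample_ids)
    X = np.log2(cohort.tx_tpm.data.loc[tx_ids].T.to_numpy() + 1.0)
    rows = []
    for j, tid in enumerate(tx_ids):
        fit = cox_fit(X[:, [j]], times=t, events=e, names=[tid])
        rows.append(("univariate", tid, fit.coef[0], fit.hazard_ratio[0],
                     fit.se[0], fit.p[0], fit.converged))
    multi = cox_fit(X, times=t, events=e, names=tx_ids)
    for j, tid in enumerate(tx_ids):
        rows.append(("multivariate", tid, multi.coef[j], multi.hazard_ratio[j],
                     multi.se[j], multi.p[j], multi.converged))
    pd.DataFrame(
        rows,
        columns=["model", "transcript_id", "coef", "hazard_ratio", "se", "p", "converged"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full two-cohort analysis and write all stage outputs.

    Identical config and seed give identical numeric tables. A failing
    stage aborts with the stage named; outputs of completed stages are
    retained and the manifest is written with ``status: failed``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        versions=_versions(),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    stage = "simulate"
    state: dict = {}
    try:
        state["cohorts"] = _stage_simulate(config, outdir, manifest)
        stage = "prep"
        _stage_prep(config, state, outdir, manifest)
        stage = "scan"
        _stage_scan(config, state, outdir, manifest)
        stage = "signature"
        _stage_signature(config, state, outdir, manifest)
        stage = "deg"
        _stage_deg(config, state, outdir, manifest)
        stage = "overlap"
        _stage_overlap(config, state, outdir, manifest)
        stage = "enrich"
        _stage_enrich(config, state, outdir, manifest)
        stage = "cluster"
        _stage_cluster(config, state, outdir, manifest)
        if config.make_plots:
            stage = "plots"
            _stage_plots(config, state, outdir, manifest)
    except Exception as exc:
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        (outdir / "manifest.json").write_text(manifest.to_json())
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    manifest.status = "complete"
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(manifest.to_json())
    for stage_files in manifest.outputs.values():
        for f in stage_files:
            assert (outdir / f).exists()
    return manifest


def _record(manifest: RunManifest, stage: str, *names: str) -> None:
    manifest.outputs.setdefault(stage, []).extend(names)


def _stage_simulate(config, outdir: Path, manifest) -> dict[str, SimulatedCohort]:
    a, b = simulate_pair(config.simulation, config.cohort_effect_scale)
    cohorts = {"A": a, "B": b}
    for name, c in cohorts.items():
        cio.write_expression(c.tx_tpm, outdir / f"cohort{name}_tx_tpm.tsv")
        cio.write_expression(c.tx_counts, outdir / f"cohort{name}_tx_counts.tsv")
        cio.write_expression(c.gene_tpm, outdir / f"cohort{name}_gene_tpm.tsv")
        cio.write_expression(c.gene_counts, outdir / f"cohort{name}_gene_counts.tsv")
        cio.write_clinical(c.clinical, outdir / f"cohort{name}_clinical.tsv")
        pd.DataFrame(
            {
                "transcript_id": list(c.truth.transcript_directions),
                "true_direction": list(c.truth.transcript_directions.values()),
            }
        ).to_csv(outdir / f"cohort{name}_truth.tsv", sep="\t", index=False)
        _record(
            manifest,
            "simulate",
            *[
                f"cohort{name}_{k}.tsv"
                for k in ("tx_tpm", "tx_counts", "gene_tpm", "gene_counts", "clinical", "truth")
            ],
        )
    log.info("simulated cohorts A/B: n=%d each, seed=%d", config.simulation.n_samples, config.seed)
    return cohorts


def _stage_prep(config, state, outdir: Path, manifest) -> None:
    state["genes"] = {}
    state["transcripts"] = {}
    for name, c in state["cohorts"].items():
        genes = cio.filter_by_mean_tpm(c.gene_tpm, config.gene_mean_tpm_min)
        tx_means = c.tx_tpm.data.mean(axis=1)
        focal = [t.transcript_id for t in c.config.transcripts]
        kept_tx = [t for t in focal if tx_means[t] > config.transcript_mean_tpm_min]
        state["genes"][name] = genes
        state["transcripts"][name] = kept_tx
        genes.data.mean(axis=1).rename("mean_tpm").to_frame().assign(
            kept=True
        ).to_csv(outdir / f"cohort{name}_genes_kept.tsv", sep="\t", float_format="%.6g")
        _record(manifest, "prep", f"cohort{name}_genes_kept.tsv")
        log.info(
            "cohort %s: %d genes pass mean TPM > %g; transcripts analyzed (mean TPM > %g): %s",
            name, genes.shape[0], config.gene_mean_tpm_min,
            config.transcript_mean_tpm_min, ",".join(kept_tx),
        )
    common = [t for t in state["transcripts"]["A"] if t in state["transcripts"]["B"]]
    if not common:
        raise ValueError("no transcript passes the expression filter in both cohorts")
    state["signature_transcripts"] = common


def _stage_scan(config, state, outdir: Path, manifest) -> None:
    state["scans"] = {}
    for name, c in state["cohorts"].items():
        t, e = c.clinical.aligned(c.tx_tpm.sample_ids)
        scans = {
            tid: scan_optimal_cutoff(
                c.tx_tpm.data.loc[tid].to_numpy(),
                times=t,
                events=e,
                lo_pct=config.scan_lo_pct,
                hi_pct=config.scan_hi_pct,
                feature_id=tid,
            )
            for tid in state["transcripts"][name]
        }
        state["scans"][name] = scans
        _write_scans(scans, outdir / f"cohort{name}_scans.tsv")
        _record(manifest, "scan", f"cohort{name}_scans.tsv")
        _write_cox(c, list(scans), outdir / f"cohort{name}_cox.tsv")
        _record(manifest, "scan", f"cohort{name}_cox.tsv")
        log.info(
            "cohort %s scan window %g-%g pct: %s", name, config.scan_lo_pct, config.scan_hi_pct,
            {t: f"{s.direction}@{s.cutoff:.3g} (p={s.p_value:.2g})" for t, s in scans.items()},
        )


def _stage_signature(config, state, outdir: Path, manifest) -> None:
    state["risk_calls"] = {}
    for name, c in state["cohorts"].items():
        scans = {t: state["scans"][name][t] for t in state["signature_transcripts"]}
        model = derive_signature(scans, vote_threshold=config.vote_threshold)
        X = c.tx_tpm.data.loc[model.transcript_ids].T
        calls = classify_risk(model, X)
        result = evaluate_signature(calls, c.clinical)
        state["risk_calls"][name] = calls
        calls.to_csv(outdir / f"cohort{name}_risk_calls.tsv", sep="\t", index=False)
        payload = {
            "transcripts": [
                {"transcript_id": t, "cutoff": cu, "risk_side": sd}
                for t, cu, sd in zip(model.transcript_ids, model.cutoffs, model.risk_sides)
            ],
            "vote_threshold": model.vote_threshold,
            "logrank_chi2": result.statistic,
            "logrank_p": result.p_value,
            "n_high": int((calls["risk_class"] == "high").sum()),
            "n_low": int((calls["risk_class"] == "low").sum()),
        }
        (outdir / f"cohort{name}_signature.json").write_text(json.dumps(payload, indent=2))
        _record(manifest, "signature", f"cohort{name}_risk_calls.tsv", f"cohort{name}_signature.json")
        log.info("cohort %s signature (votes >= %d): log-rank p = %.3g",
                 name, config.vote_threshold, result.p_value)


def _stage_deg(config, state, outdir: Path, manifest) -> None:
    state["deg_top"] = {}
    state["deg_sig"] = {}
    for name, c in state["cohorts"].items():
        kept_genes = state["genes"][name].feature_ids
        counts = cio.ExpressionMatrix(
            c.gene_counts.data.loc[kept_genes], unit="count"
        )
        lists_top, lists_sig = {}, {}
        for tid in state["transcripts"][name]:
            expr = c.tx_tpm.data.loc[tid]
            high, low = cio.quantile_strata(expr, config.strata_fraction)
            table = diff_expression.deg_test(counts, high, low)
            table.to_csv(outdir / f"cohort{name}_{tid}_deg.tsv", sep="\t", index=False,
                         float_format="%.6g")
            lists_top[tid] = diff_expression.top_fraction(table, config.top_deg_fraction)
            lists_sig[tid] = diff_expression.significant(table, config.deg_fdr)
            _record(manifest, "deg", f"cohort{name}_{tid}_deg.tsv")
        calls = state["risk_calls"][name]
        high = list(calls.loc[calls["risk_class"] == "high", "sample_id"])
        low = list(calls.loc[calls["risk_class"] == "low", "sample_id"])
        table = diff_expression.deg_test(counts, high, low)
        table.to_csv(outdir / f"cohort{name}_risk_deg.tsv", sep="\t", index=False,
                     float_format="%.6g")
        lists_top["risk"] = diff_expression.top_fraction(table, config.top_deg_fraction)
        lists_sig["risk"] = diff_expression.significant(table, config.deg_fdr)
        _record(manifest, "deg", f"cohort{name}_risk_deg.tsv")
        state["deg_top"][name] = lists_top
        state["deg_sig"][name] = lists_sig
        log.info("cohort %s DEG: FDR < %g, top fraction %g of %d tested genes",
                 name, config.deg_fdr, config.top_deg_fraction, counts.shape[0])


def _stage_overlap(config, state, outdir: Path, manifest) -> None:
    background = sorted(
        set(state["genes"]["A"].feature_ids) & set(state["genes"]["B"].feature_ids)
    )
    results = {}
    shared_lists = set(state["deg_top"]["A"]) & set(state["deg_top"]["B"])
    for key in sorted(shared_lists):
        la = state["deg_top"]["A"][key]
        lb = state["deg_top"]["B"][key]
        la = la[la["gene"].isin(background)]
        lb = lb[lb["gene"].isin(background)]
        r = concordance(la, lb, len(background))
        results[key] = {
            "background": r.background,
            "size1": r.size1,
            "size2": r.size2,
            "overlap": r.overlap,
            "consistent": r.consistent,
            "p_value": r.p_value,
            "log10_p": r.log10_p,
            "concordance": None if np.isnan(r.concordance) else r.concordance,
            "significant": r.significant,
        }
        log.info("overlap %s: k=%d s=%d concordance=%s log10p=%.2f",
                 key, r.overlap, r.consistent, results[key]["concordance"], r.log10_p)
    (outdir / "overlap.json").write_text(json.dumps(results, indent=2))
    _record(manifest, "overlap", "overlap.json")
    state["overlap"] = results


def _stage_enrich(config, state, outdir: Path, manifest) -> None:
    rows = []
    for name, c in state["cohorts"].items():
        sets = _decoy_gene_sets(c, config.n_decoy_sets, config.seed)
        universe = state["genes"][name].feature_ids
        for key, table in state["deg_sig"][name].items():
            for direction in ("up", "down"):
                query = table.loc[table["direction"] == direction, "gene"]
                query = [g for g in query if g in set(universe)]
                if not query:
                    continue
                res = enrich(query, universe, sets, fdr=config.enrich_fdr)
                res.insert(0, "cohort", name)
                res.insert(1, "list", key)
                res.insert(2, "direction", direction)
                rows.append(res)
    if rows:
        full = pd.concat(rows, ignore_index=True)
    else:
        full = pd.DataFrame(
            columns=["cohort", "list", "direction", "term", "name", "query_size",
                     "set_size", "universe_size", "overlap", "pvalue", "qvalue", "significant"]
        )
    full.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    sig = full[full["significant"] == True]  # noqa: E712
    if not sig.empty:
        summary = summarize_terms(
            sig.rename(columns={"list": "query_list"})[["cohort", "direction", "term", "overlap"]],
            min_generality=config.min_generality,
        )
    else:
        summary = pd.DataFrame(columns=["term", "generality", "direction_score", "mean_gene_count"])
    summary.to_csv(outdir / "term_summary.tsv", sep="\t", index=False, float_format="%.6g")
    _record(manifest, "enrich", "enrichment.tsv", "term_summary.tsv")
    log.info("enrichment: %d significant calls at FDR < %g", len(sig), config.enrich_fdr)
    state["enrichment"] = full


def _stage_cluster(config, state, outdir: Path, manifest) -> None:
    rows = sorted(set(state["scans"]["A"]) & set(state["scans"]["B"]))
    if len(rows) < 2:
        log.info("cluster: fewer than 2 shared transcripts, skipped")
        return
    pmat = pd.DataFrame(
        {name: [state["scans"][name][t].p_value for t in rows] for name in ("A", "B")},
        index=rows,
    )
    res = cluster_pvalue_matrix(pmat)
    payload = {
        "row_labels": res.row_labels,
        "col_labels": res.col_labels,
        "row_linkage": res.row_linkage.tolist(),
    }
    (outdir / "pvalue_clustering.json").write_text(json.dumps(payload, indent=2))
    _record(manifest, "cluster", "pvalue_clustering.json")


def _stage_plots(config, state, outdir: Path, manifest) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .survival import km_estimate

    for name, c in state["cohorts"].items():
        calls = state["risk_calls"][name]
        fig, ax = plt.subplots(figsize=(5, 4))
        for cls, color in (("high", "tab:red"), ("low", "tab:blue")):
            ids = calls.loc[calls["risk_class"] == cls, "sample_id"]
            t, e = c.clinical.aligned(ids)
            km = km_estimate(t, e)
            ax.step(
                np.concatenate([[0], km.event_times]),
                np.concatenate([[1.0], km.survival]),
                where="post", label=f"{cls} risk (n={len(ids)})", color=color,
            )
        ax.set_xlabel("days")
        ax.set_ylabel("overall survival")
        ax.set_ylim(0, 1.02)
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(outdir / f"cohort{name}_km_signature.svg")
        plt.close(fig)
        _record(manifest, "plots", f"cohort{name}_km_signature.svg")
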