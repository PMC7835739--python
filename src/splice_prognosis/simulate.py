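"""Synthetic two-cohort data with the structure the analysis assumes.

The generator emulates a gene whose expression is dominated (~95%) by
one transcript plus several minor transcripts, proportional-hazards
survival driven by transcript-specific log-hazards of both signs,
right-censoring, and gene modules whose expression responds to a driver
transcript's level with a consistent direction — the features needed to
exercise optimal-cutoff scanning, differential expression, cross-cohort
overlap/concordance and the risk signature end to end, with a known
ground truth.

Expression marginals are log-normal: each transcript of the focal gene
shares a per-sample gene-level factor (inducing transcript-gene
correlation) and adds independent mean-corrected log-normal noise, so
configured mean TPMs are matched in expectation. Survival times are
exponential with rate ``baseline_hazard * exp(sum_t beta_t * z_t)``
where ``z_t`` is the within-cohort z-score of log transcript TPM —
the simplest model consistent with proportional hazards. Censoring is
independent exponential, calibrated by bisection to the configured
expected censored fraction. Counts are TPM values scaled by a per-sample
library factor and rounded.

Randomness is organized as named sub-streams of one global seed
(per cohort, per transcript, per module, per stage), so adding a
feature does not shift the draws of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix

__all__ = [
    "TranscriptSpec",
    "ModuleSpec",
    "SyntheticCohortConfig",
    "SyntheticTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_pair",
]


def _stream(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic named RNG sub-stream of a global seed."""
    keys = [int(seed) & 0xFFFFFFFF] + [zlib.crc32(l.encode()) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass(frozen=True)
class TranscriptSpec:
    """One transcript of the focal gene.

    ``share`` is its fraction of the gene's mean TPM; ``log_hazard`` the
    per-unit-z-score log hazard ratio of its expression (negative means
    high expression is protective); ``sigma`` the transcript-specific
    log-normal noise SD (natural-log scale).
    """

    transcript_id: str
    share: float
    log_hazard: float = 0.0
    sigma: float = 0.25


@dataclass(frozen=True)
class ModuleSpec:
    """A gene module responding to one driver transcript.

    Member genes shift by ``direction * effect * z(driver)`` log2-units
    plus N(0, noise_sd) module noise on top of their baseline.
    """

    set_id: str
    driver: str
    direction: str  # "up" or "down"
    n_genes: int = 40
    effect: float = 0.8
    noise_sd: float = 0.5


def _default_transcripts() -> tuple[TranscriptSpec, ...]:
    # the dominant transcript tracks the gene; minor isoforms carry
    # larger isoform-specific variation (splicing regulation is only
    # loosely coupled to overall gene expression)
    return (
        TranscriptSpec("TX1", share=0.950, log_hazard=-0.7, sigma=0.25),
        TranscriptSpec("TX2", share=0.015, log_hazard=-0.7, sigma=0.5),
        TranscriptSpec("TX3", share=0.020, log_hazard=+0.7, sigma=0.5),
        TranscriptSpec("TX4", share=0.013, log_hazard=+0.7, sigma=0.5),
    )


def _default_modules() -> tuple[ModuleSpec, ...]:
    return (
        ModuleSpec("MOD_TX1_UP", driver="TX1", direction="up"),
        ModuleSpec("MOD_TX1_DOWN", driver="TX1", direction="down"),
        ModuleSpec("MOD_TX3_UP", driver="TX3", direction="up"),
        ModuleSpec("MOD_TX3_DOWN", driver="TX3", direction="down"),
    )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults give 300 patients, a focal gene of mean 520 TPM dominated
    95% by one transcript, four prognostic transcripts with log-hazards
    of +-0.7 (two favorable, two unfavorable), 2000 background genes of
    which four 40-gene modules respond to transcript level, an
    exponential baseline hazard of 1/1500 per day (median overall
    survival around three years) and 50% expected censoring — a
    TCGA-like bulk cohort at desk scale.
    """

    n_samples: int = 300
    focal_gene: str = "GENE1"
    gene_mean_tpm: float = 520.0
    gene_sigma: float = 0.4
    transcripts: tuple[TranscriptSpec, ...] = field(default_factory=_default_transcripts)
    residual_id: str = "TX_RES"
    n_background_genes: int = 2000
    background_log10_mean_range: tuple[float, float] = (0.3, 2.0)
    background_sigma: float = 0.5
    modules: tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    baseline_hazard: float = 1.0 / 1500.0  # per day
    censoring_rate: float = 0.5
    library_factor_range: tuple[float, float] = (25.0, 35.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring rate must lie in [0, 1)")
        if self.gene_mean_tpm <= 0 or self.gene_sigma < 0:
            raise ValueError("gene mean/sigma invalid")
        if not self.transcripts:
            raise ValueError("at least one transcript is required")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids) or self.residual_id in ids:
            raise ValueError("transcript ids must be unique and distinct from the residual id")
        shares = np.array([t.share for t in self.transcripts])
        if np.any(shares <= 0) or shares.sum() > 1.0 + 1e-9:
            raise ValueError("transcript shares must be positive and sum to <= 1")
        if any(t.sigma < 0 for t in self.transcripts):
            raise ValueError("transcript sigma must be non-negative")
        lo, hi = self.library_factor_range
        if not 0 < lo <= hi:
            raise ValueError("library factor range invalid")
        total_module_genes = sum(m.n_genes for m in self.modules)
        if total_module_genes > self.n_background_genes:
            raise ValueError("module genes exceed the background gene count")
        for m in self.modules:
            if m.direction not in ("up", "down"):
                raise ValueError(f"module {m.set_id}: direction must be up/down")
            if m.driver not in ids:
                raise ValueError(f"module {m.set_id}: unknown driver transcript {m.driver!r}")
            if m.n_genes <= 0 or m.effect < 0 or m.noise_sd < 0:
                raise ValueError(f"module {m.set_id}: invalid n_genes/effect/noise")


@dataclass
class SyntheticTruth:
    """Ground truth the pipeline is expected to recover."""

    transcript_directions: dict[str, str]  # favorable (beta<0) / unfavorable / none
    module_genes: dict[str, list[str]]
    module_directions: dict[str, str]
    module_drivers: dict[str, str]


@dataclass
class SimulatedCohort:
    name: str
    tx_tpm: ExpressionMatrix
    tx_counts: ExpressionMatrix
    gene_tpm: ExpressionMatrix
    gene_counts: ExpressionMatrix
    clinical: ClinicalTable
    truth: SyntheticTruth
    tx_gene_map: dict[str, str]
    config: SyntheticCohortConfig


def _truth_direction(beta: float) -> str:
    if beta < 0:
        return "favorable"
    if beta > 0:
        return "unfavorable"
    return "none"


def _calibrate_censoring(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving the target expected censored
    fraction, found by bisection on mean(lc / (lc + rate))."""
    if target <= 0:
        return 0.0

    def frac(lc: float) -> float:
        return float(np.mean(lc / (lc + rates)))

    lo, hi = 1e-12, float(rates.max())
    while frac(hi) < target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(
    config: SyntheticCohortConfig,
    *,
    cohort_label: str = "A",
    baseline_scale: float = 1.0,
) -> SimulatedCohort:
    """Draw one cohort: transcript/gene matrices, survival and truth.

    ``cohort_label`` names the RNG sub-stream (so paired cohorts get
    independent noise from one seed); ``baseline_scale`` rescales all
    baseline mean TPMs without touching effect signs.
    """
    config.validate()
    if baseline_scale <= 0:
        raise ValueError("baseline scale must be positive")
    n = config.n_samples
    seed = config.seed
    samples = [f"{cohort_label}{i + 1:04d}" for i in range(n)]

    # focal gene: shared per-sample factor plus per-transcript noise
    u = _stream(seed, cohort_label, "focal").normal(size=n)
    gene_factor = np.exp(config.gene_sigma * u - 0.5 * config.gene_sigma**2)
    shares = {t.transcript_id: t.share for t in config.transcripts}
    resid = 1.0 - sum(shares.values())
    if resid > 1e-9:
        shares[config.residual_id] = resid
    sigmas = {t.transcript_id: t.sigma for t in config.transcripts}
    sigmas.setdefault(config.residual_id, 0.25)
    tx_rows = {}
    for tid, share in shares.items():
        sig = sigmas[tid]
        eps = _stream(seed, cohort_label, "tx", tid).normal(size=n)
        mean_t = baseline_scale * config.gene_mean_tpm * share
        tx_rows[tid] = mean_t * gene_factor * np.exp(sig * eps - 0.5 * sig**2)
    tx_df = pd.DataFrame(tx_rows, index=samples).T
    tx_df.index.name = "transcript_id"

    # z-scored log expression drives both survival and modules
    z = {}
    for t in config.transcripts:
        logx = np.log(tx_df.loc[t.transcript_id].to_numpy())
        sd = logx.std()
        z[t.transcript_id] = (logx - logx.mean()) / sd if sd > 0 else np.zeros(n)

    # background genes and modules
    gene_rows = {}
    bg_ids = [f"BG{i + 1:05d}" for i in range(config.n_background_genes)]
    if config.n_background_genes:
        rng_bg = _stream(seed, cohort_label, "background")
        lo, hi = config.background_log10_mean_range
        means = 10.0 ** rng_bg.uniform(lo, hi, size=config.n_background_genes) * baseline_scale
        noise = rng_bg.normal(size=(config.n_background_genes, n))
        sig = config.background_sigma
        base = means[:, None] * np.exp(sig * noise - 0.5 * sig**2)
        for i, gid in enumerate(bg_ids):
            gene_rows[gid] = base[i]
    module_genes: dict[str, list[str]] = {}
    cursor = 0
    for m in config.modules:
        members = bg_ids[cursor : cursor + m.n_genes]
        cursor += m.n_genes
        module_genes[m.set_id] = members
        sign = 1.0 if m.direction == "up" else -1.0
        zdrv = z[m.driver]
        eta = _stream(seed, cohort_label, "module", m.set_id).normal(
            scale=m.noise_sd, size=(m.n_genes, n)
        )
        for j, gid in enumerate(members):
            gene_rows[gid] = gene_rows[gid] * 2.0 ** (sign * m.effect * zdrv + eta[j])

    gene_df = pd.DataFrame({config.focal_gene: tx_df.sum(axis=0)}, index=samples).T
    if gene_rows:
        gene_df = pd.concat([gene_df, pd.DataFrame(gene_rows, index=samples).T])
    gene_df.index.name = "gene_id"

    # survival under proportional hazards with exponential baseline
    log_rr = np.zeros(n)
    for t in config.transcripts:
        log_rr += t.log_hazard * z[t.transcript_id]
    rates = config.baseline_hazard * np.exp(log_rr)
    t_event = _stream(seed, cohort_label, "survival").exponential(1.0 / rates)
    lc = _calibrate_censoring(rates, config.censoring_rate)
    if lc > 0:
        t_cens = _stream(seed, cohort_label, "censor").exponential(1.0 / lc, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, int)
    clinical = ClinicalTable(
        pd.DataFrame({"sample_id": samples, "time_days": time, "event": event})
    )

    lib = _stream(seed, cohort_label, "library").uniform(*config.library_factor_range, size=n)
    tx_counts = np.round(tx_df.to_numpy() * lib[None, :])
    gene_counts = np.round(gene_df.to_numpy() * lib[None, :])

    truth = SyntheticTruth(
        transcript_directions={
            t.transcript_id: _truth_direction(t.log_hazard) for t in config.transcripts
        },
        module_genes=module_genes,
        module_directions={m.set_id: m.direction for m in config.modules},
        module_drivers={m.set_id: m.driver for m in config.modules},
    )
    tx_gene_map = {tid: config.focal_gene for tid in tx_df.index}
    return SimulatedCohort(
        name=cohort_label,
        tx_tpm=ExpressionMatrix(tx_df, unit="tpm"),
        tx_counts=ExpressionMatrix(
            pd.DataFrame(tx_counts, index=tx_df.index, columns=samples), unit="count"
        ),
        gene_tpm=ExpressionMatrix(gene_df, unit="tpm"),
        gene_counts=ExpressionMatrix(
            pd.DataFrame(gene_counts, index=gene_df.index, columns=samples), unit="count"
        ),
        clinical=clinical,
        truth=truth,
        tx_gene_map=tx_gene_map,
        config=config,
    )


def simulate_pair(
    config: SyntheticCohortConfig, cohort_effect_scale: float = 1.0
) -> tuple[SimulatedCohort, SimulatedCohort]:
    """Two cohorts with independent noise and shared effect signs.

    The second cohort's baseline expression is rescaled by
    ``cohort_effect_scale`` (emulating an independent cohort measured on
    a shifted expression scale); all prognostic and module directions
    are identical by construction.
    """
    if cohort_effect_scale <= 0:
        raise ValueError("cohort_effect_scale must be positive")
    a = simulate_cohort(config, cohort_label="A")
    b = simulate_cohort(config, cohort_label="B", baseline_scale=cohort_effect_scale)
    return a, b
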