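"""Synthetic TNBC cohort generator with known ground truth.

Emulates the statistical structure the analysis assumes: 54 tumors in three
latent immuno-clusters (15/18/21) with graded activation of an immune gene
program (hot / cold / intermediate), stromal TILs density driven by the CD8
program, blood counts whose platelet-to-lymphocyte ratio is lowest in the
inflamed cluster, and recurrence times enriched in the non-inflamed clusters.
Every signature gene is present under its real HGNC symbol so all scoring
operations run unmodified; the remaining immune-program genes are synthetic
filler symbols.

Expression is Gaussian on the log2 scale (the convention of RMA-normalized
array data).  Each immune gene carries a cluster-specific activation equal to
the configured scalar shift plus a gene-level heterogeneity term, so the three
clusters span distinct programs rather than a single collinear gradient.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort_io import (
    CBCRecord,
    ClinicalRecord,
    ExpressionMatrix,
    ValidationError,
)
from .signatures import SignatureConfig

__all__ = ["SyntheticConfig", "SyntheticCohort", "simulate_cohort", "truth_report"]

CLUSTER_NAMES = ("ImA", "ImB", "ImC")
DAYS_PER_YEAR = 365.0


@dataclasses.dataclass
class SyntheticConfig:
    """Generating parameters; defaults are the emulated study conditions."""

    n_samples: int = 54
    cluster_sizes: tuple[int, ...] = (15, 18, 21)
    n_immune_genes: int = 708
    n_background_genes: int = 2000
    #: log2-unit activation of the immune program per cluster (hot/cold/warm)
    immune_activation_shift: tuple[float, ...] = (1.5, 0.0, 0.5)
    #: gene-level sd of cluster-specific activation around the scalar shift
    cluster_profile_sd: float = 0.5
    #: log2-unit shift of the aggressive-program genes DDIT4/POLR1C per cluster
    aggressive_shift: tuple[float, ...] = (0.0, 1.0, 0.5)
    #: log2-unit shift of the stromal program per cluster
    stromal_shift: tuple[float, ...] = (0.0, 0.3, 0.6)
    noise_sd: float = 0.6
    baseline_mean: float = 6.0
    baseline_sd: float = 0.8
    #: TILs% = clamp(intercept + slope * CD8-program mean + N(0, noise), 0, 100)
    tils_intercept: float = -110.0
    tils_slope: float = 20.0
    tils_noise_sd: float = 15.0
    #: per-cluster lognormal medians of the platelet-to-lymphocyte ratio
    plr_medians: tuple[float, ...] = (132.0, 162.0, 176.0)
    plr_sigma: float = 0.25
    lymphocyte_medians: tuple[float, ...] = (2.0, 1.85, 1.6)
    lymphocyte_sigma: float = 0.22
    neutrophil_median: float = 4.4
    neutrophil_sigma: float = 0.30
    monocyte_median: float = 0.5
    monocyte_sigma: float = 0.30
    #: 5-year event probability in the inflamed cluster
    event_prob_inflamed: float = 0.13
    #: recurrence hazard of the non-inflamed clusters relative to the inflamed
    hazard_ratio_noninflamed: float = 3.0
    censor_years: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != self.n_samples:
            raise ValidationError(
                f"cluster sizes {self.cluster_sizes} must sum to n_samples "
                f"{self.n_samples}"
            )
        if any(s <= 0 for s in self.cluster_sizes):
            raise ValidationError("every cluster must have positive size")
        k = len(self.cluster_sizes)
        for name in ("immune_activation_shift", "aggressive_shift", "stromal_shift",
                     "plr_medians", "lymphocyte_medians"):
            if len(getattr(self, name)) != k:
                raise ValidationError(f"{name} must have one entry per cluster")
        for name in ("noise_sd", "cluster_profile_sd", "plr_sigma",
                     "lymphocyte_sigma", "neutrophil_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if any(m <= 0 for m in self.plr_medians):
            raise ValidationError("PLR medians must be > 0")
        if not 0 < self.event_prob_inflamed < 1:
            raise ValidationError("event_prob_inflamed must be in (0, 1)")


@dataclasses.dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    cbc: list[CBCRecord]
    clinical: list[ClinicalRecord]
    truth_labels: pd.Series          # per-sample generating cluster name
    truth_params: SyntheticConfig
    immune_genes: list[str]          # the clustering gene set
    cd8_genes: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


def _signature_symbols(sig: SignatureConfig) -> tuple[list[str], list[str]]:
    """(immune-program symbols, stromal symbols) from the configured panels."""
    immune: list[str] = list(sig.cyt_genes) + list(sig.tis_gene_list) + ["CCL5"]
    for name, genes in sig.gene_sets.sets.items():
        if name == sig.estimate_stromal_set:
            continue
        immune += genes
    immune += list(sig.ips_weights["gene"])
    stromal = list(sig.gene_sets[sig.estimate_stromal_set])
    immune = [g for g in dict.fromkeys(immune) if g not in set(stromal)]
    return immune, stromal


def simulate_cohort(
    config: SyntheticConfig | None = None,
    signature_config: SignatureConfig | None = None,
) -> SyntheticCohort:
    """Draw a full cohort (expression + CBC + clinical) with ground truth."""
    config = config or SyntheticConfig()
    sig = signature_config or SignatureConfig()
    rng = np.random.default_rng(config.seed)
    k = len(config.cluster_sizes)
    n = config.n_samples

    labels_int = np.repeat(np.arange(k), config.cluster_sizes)
    sample_ids = [f"TN{i + 1:03d}" for i in range(n)]
    names = list(CLUSTER_NAMES[:k]) if k <= 3 else [f"Im{i}" for i in range(k)]
    truth = pd.Series([names[c] for c in labels_int],
                      index=pd.Index(sample_ids, name="sample_id"), name="truth")

    immune_named, stromal_genes = _signature_symbols(sig)
    aggressive_only = ["DDIT4", "POLR1C"]
    immune_named = [g for g in immune_named if g not in aggressive_only]
    n_filler = config.n_immune_genes - len(immune_named)
    if n_filler < 0:
        raise ValidationError(
            f"n_immune_genes={config.n_immune_genes} smaller than the "
            f"{len(immune_named)} named signature genes"
        )
    filler = [f"IMM{i + 1:04d}" for i in range(n_filler)]
    immune_genes = immune_named + filler
    background = [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    genes = immune_genes + aggressive_only + stromal_genes + background

    def block(gene_list, shifts, profile_sd):
        g = len(gene_list)
        base = rng.normal(config.baseline_mean, config.baseline_sd, size=g)
        act = np.asarray(shifts)[None, :] + rng.normal(0, profile_sd, size=(g, k))
        return base[:, None] + act[:, labels_int]

    mean = np.vstack([
        block(immune_genes, config.immune_activation_shift, config.cluster_profile_sd),
        block(aggressive_only, config.aggressive_shift, 0.0),
        block(stromal_genes, config.stromal_shift, config.cluster_profile_sd / 2),
        block(background, np.zeros(k), 0.0),
    ])
    X = mean + rng.normal(0, config.noise_sd, size=mean.shape)
    expr = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=sample_ids), scale_tag="log2"
    )

    # TILs follow the per-sample CD8-program mean (log2 scale)
    cd8_genes = [g for g in sig.gene_sets[sig.cd8_set] if g in expr.values.index]
    cd8_mean = expr.values.loc[cd8_genes].mean(axis=0).to_numpy()
    tils = np.clip(
        config.tils_intercept + config.tils_slope * cd8_mean
        + rng.normal(0, config.tils_noise_sd, size=n),
        0.0, 100.0,
    )

    # CBC: lognormal lymphocytes; platelets drawn so PLR has the configured
    # per-cluster lognormal median (the signal lives in platelets/PLR).
    lymph_med = np.asarray(config.lymphocyte_medians)[labels_int]
    lymph = lymph_med * np.exp(rng.normal(0, config.lymphocyte_sigma, size=n))
    plr = np.asarray(config.plr_medians)[labels_int] * np.exp(
        rng.normal(0, config.plr_sigma, size=n)
    )
    platelets = plr * lymph
    neut = config.neutrophil_median * np.exp(
        rng.normal(0, config.neutrophil_sigma, size=n)
    )
    mono = config.monocyte_median * np.exp(
        rng.normal(0, config.monocyte_sigma, size=n)
    )
    cbc = [
        CBCRecord(sample_id=sid, neutrophils=float(ne), lymphocytes=float(ly),
                  platelets=float(pl), monocytes=float(mo))
        for sid, ne, ly, pl, mo in zip(sample_ids, neut, lymph, platelets, mono)
    ]

    # recurrence: exponential with cluster-dependent hazard, administratively
    # censored at the configured horizon
    horizon = config.censor_years * DAYS_PER_YEAR
    lam_inflamed = -np.log(1.0 - config.event_prob_inflamed) / horizon
    hazards = np.where(labels_int == 0, lam_inflamed,
                       lam_inflamed * config.hazard_ratio_noninflamed)
    t_event = rng.exponential(1.0 / hazards)
    observed = np.minimum(t_event, horizon)
    event = (t_event <= horizon).astype(int)
    ages = np.clip(rng.normal(55, 11, size=n), 28, 85)
    clinical = [
        ClinicalRecord(sample_id=sid, age_years=float(a), tils_percent=float(t),
                       time_to_event_days=float(tt), event_flag=int(e))
        for sid, a, t, tt, e in zip(sample_ids, ages, tils, observed, event)
    ]

    return SyntheticCohort(
        expression=expr, cbc=cbc, clinical=clinical, truth_labels=truth,
        truth_params=config, immune_genes=immune_genes, cd8_genes=cd8_genes,
    )


def truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Configured generating parameters next to empirical cohort summaries,
    one row per true cluster."""
    cfg = cohort.truth_params
    expr = cohort.expression.values
    labels = cohort.truth_labels
    from .cohort_io import cbc_to_frame, clinical_to_frame

    cbc = cbc_to_frame(cohort.cbc)
    clin = clinical_to_frame(cohort.clinical)
    plr = cbc["platelets"] / cbc["lymphocytes"]
    immune_mean = expr.loc[cohort.immune_genes].mean(axis=0)
    horizon = cfg.censor_years * DAYS_PER_YEAR
    lam0 = -np.log(1.0 - cfg.event_prob_inflamed) / horizon

    rows = []
    for i, name in enumerate(labels.unique()):
        members = labels.index[labels == name]
        lam = lam0 if i == 0 else lam0 * cfg.hazard_ratio_noninflamed
        rows.append({
            "cluster": name,
            "n": len(members),
            "config_activation_shift": cfg.immune_activation_shift[i],
            "empirical_immune_mean": float(immune_mean[members].mean()),
            "empirical_tils_mean": float(clin.loc[members, "tils_percent"].mean()),
            "config_plr_median": cfg.plr_medians[i],
            "empirical_plr_median": float(plr[members].median()),
            "config_censor_fraction": float(np.exp(-lam * horizon)),
            "empirical_censor_fraction": float(
                1.0 - clin.loc[members, "event_flag"].mean()
            ),
        })
    return pd.DataFrame(rows).set_index("cluster")
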