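"""End-to-end orchestration: simulate or load a cohort, score it, cluster it,
optionally deconvolve it, run the association statistics and write a
reproducible results bundle with a provenance manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import clustering as clust
from .cohort_io import (
    ValidationError,
    cbc_to_frame,
    clinical_to_frame,
    read_cbc_table,
    read_clinical_table,
    read_expression_matrix,
    write_results_bundle,
)
from .deconvolution import deconvolve_cohort, read_signature_matrix
from .signatures import SignatureConfig, compute_panel, dichotomize_by_median
from .synthetic import SyntheticConfig, simulate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "report_summary"]


@dataclasses.dataclass
class RunConfig:
    """Declarative run description; exactly one of simulate / input paths."""

    seed: int
    out_dir: str
    simulate: dict | None = None
    expression_path: str | None = None
    cbc_path: str | None = None
    clinical_path: str | None = None
    signature_matrix_path: str | None = None
    run_deconvolution: bool = False
    deconvolution_perms: int = 100
    rank_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    n_runs: int = 50
    target_k: int = 3
    min_cluster_size: int | None = None
    nmf_max_iter: int = 700
    nmf_tol: float = 1e-6
    clustering_genes: list[str] | None = None

    def __post_init__(self) -> None:
        has_sim = self.simulate is not None
        has_paths = self.expression_path is not None
        if has_sim == has_paths:
            raise ValidationError(
                "RunConfig: exactly one of a simulate block or input paths"
            )
        if self.seed is None:
            raise ValidationError("RunConfig: seed is mandatory")
        if self.run_deconvolution and not self.signature_matrix_path:
            raise ValidationError(
                "RunConfig: deconvolution requested without a signature matrix"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class PipelineResult:
    panel: pd.DataFrame
    clusters: pd.DataFrame
    cluster_summary: pd.DataFrame
    associations: pd.DataFrame
    deconvolution: pd.DataFrame | None
    manifest: dict
    truth_labels: pd.Series | None = None


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    """One deterministic child seed per stage from a single master seed."""
    out = {}
    for name in names:
        h = hashlib.sha256(f"{master}:{name}".encode()).digest()
        out[name] = int.from_bytes(h[:4], "big") % (2**31 - 1)
    return out


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim_cfg = SyntheticConfig(**{**config.simulate, "seed": config.seed})
        cohort = simulate_cohort(sim_cfg)
        return (cohort.expression, cbc_to_frame(cohort.cbc),
                clinical_to_frame(cohort.clinical), cohort.truth_labels,
                cohort.immune_genes)
    expr, _ = read_expression_matrix(config.expression_path)
    cbc = clin = None
    if config.cbc_path:
        records, _ = read_cbc_table(config.cbc_path)
        cbc = cbc_to_frame(records)
    if config.clinical_path:
        records, _ = read_clinical_table(config.clinical_path)
        clin = clinical_to_frame(records)
    for name, df in (("cbc", cbc), ("clinical", clin)):
        if df is not None:
            extra = set(df.index) - set(expr.sample_ids)
            if extra:
                raise ValidationError(
                    f"pre-flight: {name} table has samples absent from the "
                    f"expression matrix: {sorted(extra)[:5]}"
                )
    return expr, cbc, clin, None, config.clustering_genes


def _associations_table(
    plr: pd.Series, nlr: pd.Series, labels: pd.Series, panel: pd.DataFrame,
    clinical: pd.DataFrame | None,
) -> pd.DataFrame:
    """Tidy association table: KW across clusters, multinomial ORs for PLR,
    Spearman links between systemic ratios and local scores, and dichotomized
    2x2 ORs of PLR x aggressive score."""
    rows = []
    idx = labels.index
    groups = [plr.reindex(idx)[labels == c].dropna() for c in sorted(labels.unique())]
    if all(len(g) for g in groups):
        h, p = assoc.kruskal_wallis(*groups)
        rows.append({"marker": "plr", "contrast": "kruskal_wallis_clusters",
                     "estimate": h, "p": p})
    age = clinical["age_years"].reindex(idx) if clinical is not None else None
    try:
        mn = assoc.multinomial_logistic(
            plr.reindex(idx), labels, ref=sorted(labels.unique())[0],
            unit_scale=10.0, age=age,
        )
        for cls, res in mn.items():
            rows.append({"marker": "plr", "contrast": f"multinomial_{res.label}",
                         "estimate": res.estimate, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p": res.p_value,
                         "scaling": res.scaling, "adjustment": res.adjustment})
    except (ValidationError, np.linalg.LinAlgError):
        pass
    for score in ("tis", "cyt", "aggressive"):
        rho, p = assoc.spearman(plr.reindex(idx), panel[score].reindex(idx))
        rows.append({"marker": "plr", "contrast": f"spearman_vs_{score}",
                     "estimate": rho, "p": p})
    high_plr = dichotomize_by_median(plr.reindex(idx)) == "high"
    high_aggr = dichotomize_by_median(panel["aggressive"].reindex(idx)) == "high"
    t = assoc.ContingencyTable2x2(
        a=int((high_plr & high_aggr).sum()), b=int((high_plr & ~high_aggr).sum()),
        c=int((~high_plr & high_aggr).sum()), d=int((~high_plr & ~high_aggr).sum()),
    )
    try:
        res = assoc.odds_ratio_2x2(t, label="high PLR x high aggressive")
        rows.append({"marker": "plr", "contrast": "or_high_aggressive",
                     "estimate": res.estimate, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p": res.p_value})
    except ValidationError:
        pass
    rho, p = assoc.spearman(nlr.reindex(idx), panel["tis"].reindex(idx))
    rows.append({"marker": "nlr", "contrast": "spearman_vs_tis",
                 "estimate": rho, "p": p})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    timings: dict[str, float] = {}
    seeds = _stage_seeds(config.seed, ["cluster", "deconvolve"])

    t0 = time.perf_counter()
    expr, cbc, clinical, truth, clustering_genes = _load_inputs(config)
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sig_cfg = SignatureConfig()
    panel = compute_panel(expr, sig_cfg)
    timings["score"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if clustering_genes is None:
        from .synthetic import _signature_symbols
        immune, _ = _signature_symbols(sig_cfg)
        clustering_genes = immune
    sub = expr.to_log2().subset_genes(list(clustering_genes))
    if sub.shape[0] < 2:
        raise ValidationError("clustering: fewer than 2 clustering genes present")
    V, offset = clust.nonneg_shift(sub.values.to_numpy())
    rank, coph_table, results = clust.select_rank(
        V, rank_grid=config.rank_grid, n_runs=config.n_runs,
        seed=seeds["cluster"], max_iter=config.nmf_max_iter, tol=config.nmf_tol,
    )
    initial = clust.consensus_labels(results[rank])
    assignment = clust.refine_or_fallback(
        initial, V, min_size=config.min_cluster_size,
        target_k=config.target_k, sample_ids=expr.sample_ids,
    )
    assignment = clust.rename_by_score(assignment, panel["immune_score"])
    timings["cluster"] = time.perf_counter() - t0

    deconv = None
    if config.run_deconvolution:
        t0 = time.perf_counter()
        sig_matrix = read_signature_matrix(config.signature_matrix_path)
        deconv = deconvolve_cohort(
            expr, sig_matrix, n_perm=config.deconvolution_perms,
            seed=seeds["deconvolve"],
        )
        timings["deconvolve"] = time.perf_counter() - t0

    labels = assignment.labels
    clusters_df = pd.DataFrame({
        "im_cluster": labels.reindex(expr.sample_ids),
    }, index=pd.Index(expr.sample_ids, name="sample_id"))
    clusters_df["excluded"] = clusters_df.index.isin(assignment.excluded_samples)

    t0 = time.perf_counter()
    associations = pd.DataFrame()
    if cbc is not None:
        markers = assoc.compute_ratios(cbc)
        associations = _associations_table(
            markers.plr, markers.nlr, labels, panel, clinical
        )
    frac_cols = None
    if deconv is not None:
        frac_cols = deconv.drop(
            columns=["rmse", "pearson_r", "permutation_p"], errors="ignore"
        )
    summary = clust.characterize_clusters(
        labels, panel, deconv=frac_cols, clinical=clinical, cbc=cbc,
    )
    timings["associate"] = time.perf_counter() - t0

    manifest_extra = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "nonneg_shift_offset": offset,
        "selected_rank": int(rank),
        "cophenetic_table": coph_table.to_dict("records"),
        "refinement_log": assignment.refinement_log,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    bundle = write_results_bundle(
        config.out_dir, panel, clusters_df,
        associations if not associations.empty else None,
        manifest_extra=manifest_extra, seed=config.seed,
    )
    summary.to_csv(Path(config.out_dir) / "cluster_summary.csv")
    if deconv is not None:
        deconv.to_csv(Path(config.out_dir) / "deconvolution.csv")
    manifest = json.loads((Path(config.out_dir) / "manifest.json").read_text())
    manifest["bundle"] = bundle
    return PipelineResult(
        panel=panel, clusters=clusters_df, cluster_summary=summary,
        associations=associations, deconvolution=deconv, manifest=manifest,
        truth_labels=truth,
    )


def report_summary(result: PipelineResult) -> str:
    """Human-readable markdown report of a finished run."""
    lines = ["# Immuno-cluster run summary", ""]
    cols = [c for c in ("n", "median_cyt", "median_tis", "median_aggressive",
                        "median_ims", "median_plr", "pct_tils_high", "n_events")
            if c in result.cluster_summary.columns]
    lines.append("## Per-cluster summary")
    lines.append("")
    lines.append(result.cluster_summary[cols].round(2).to_markdown())
    lines.append("")
    if result.associations is None or result.associations.empty:
        lines.append("## Associations")
        lines.append("")
        lines.append("No blood-count table provided; association stage omitted.")
    else:
        lines.append("## Associations")
        lines.append("")
        lines.append(result.associations.round(4).to_markdown(index=False))
    excluded = result.clusters["excluded"].sum()
    lines.append("")
    lines.append(f"Excluded samples (small-cluster refinement): {int(excluded)}")
    return "\n".join(lines)
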