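"""Per-sample immune signature scores.

Implements the scores used to characterize the immuno-clusters: cytolytic
activity (CYT, log2 geometric mean of GZMA and PRF1), the 18-gene tumor
inflammation signature (TIS, plain mean of log2 expression), the three-gene
aggressive score, the integrative immune score IMS = CYT*TIS - aggressive,
single-sample GSEA (rank-weighted running-sum enrichment), ESTIMATE-style
stromal/immune/purity scores, and a 0-10 immunophenoscore summarizing MHC,
immunomodulator, effector and suppressor programs.

Gene lists and weights are editable text shipped with the package; every
formula operates on whatever lists are configured.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort_io import ExpressionMatrix, GeneSetCollection, ValidationError

__all__ = [
    "SignatureConfig",
    "cyt_score",
    "tis_score",
    "aggressive_score",
    "ims_score",
    "ssgsea",
    "estimate_scores",
    "immunophenoscore",
    "dichotomize_by_median",
    "tils_high_flag",
    "compute_panel",
]

#: published coefficients of the three-gene prognostic aggressive score
AGGRESSIVE_COEFFS = {"CCL5": -0.393, "DDIT4": 0.443, "POLR1C": 0.490}

#: ESTIMATE purity transform: purity = cos(c0 + c1 * estimate_score)
PURITY_CONSTANTS = (0.6049872018, 0.0001467884)


def _data_path(name: str) -> Path:
    return Path(resources.files("tnbc_immune").joinpath("data", name))


def load_default_gene_sets() -> GeneSetCollection:
    from .cohort_io import read_gene_sets_gmt

    return read_gene_sets_gmt(_data_path("signatures.gmt"))


def load_tis_genes() -> list[str]:
    lines = _data_path("tis_genes.txt").read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def load_ips_weights() -> pd.DataFrame:
    return pd.read_csv(_data_path("ips_weights.csv"))


@dataclasses.dataclass
class SignatureConfig:
    """All gene lists, coefficients and knobs behind the signature panel."""

    cyt_genes: tuple[str, str] = ("GZMA", "PRF1")
    tis_gene_list: list[str] = dataclasses.field(default_factory=load_tis_genes)
    aggressive_coeffs: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(AGGRESSIVE_COEFFS)
    )
    ssgsea_alpha: float = 0.25
    ssgsea_min_set_size: int = 5
    ssgsea_normalize: bool = True
    estimate_immune_set: str = "ESTIMATE_IMMUNE"
    estimate_stromal_set: str = "ESTIMATE_STROMAL"
    cd8_set: str = "CD8_T_ACTIVATED"
    purity_constants: tuple[float, float] = PURITY_CONSTANTS
    gene_sets: GeneSetCollection = dataclasses.field(
        default_factory=load_default_gene_sets
    )
    ips_weights: pd.DataFrame = dataclasses.field(default_factory=load_ips_weights)
    tils_high_threshold: float = 20.0

    def __post_init__(self) -> None:
        if self.ssgsea_min_set_size < 2:
            raise ValidationError("ssgsea_min_set_size must be >= 2")
        cats = set(self.ips_weights["category"])
        expected = {"MHC", "immunomodulator", "effector", "suppressor"}
        if cats != expected:
            raise ValidationError(
                f"ips_weights must cover categories {sorted(expected)}, got {sorted(cats)}"
            )


def _log2_values(expr: ExpressionMatrix) -> pd.DataFrame:
    return expr.to_log2().values


def _require_genes(values: pd.DataFrame, genes, score: str) -> pd.DataFrame:
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise ValidationError(f"{score}: gene(s) {missing} absent from matrix")
    return values.loc[list(genes)]


def cyt_score(expr: ExpressionMatrix, config: SignatureConfig | None = None) -> pd.Series:
    """Cytolytic activity: log2 geometric mean of GZMA and PRF1.

    On log2 data this is the arithmetic mean of the two log2 values, which is
    exactly log2 of the geometric mean of the linear intensities.
    """
    config = config or SignatureConfig()
    sub = _require_genes(_log2_values(expr), config.cyt_genes, "cyt_score")
    return sub.mean(axis=0).rename("cyt")


def tis_score(expr: ExpressionMatrix, config: SignatureConfig | None = None) -> pd.Series:
    """Tumor inflammation signature: unweighted mean of log2 expression over
    the configured (default 18-gene) panel; absent genes are warned about."""
    config = config or SignatureConfig()
    values = _log2_values(expr)
    present = [g for g in config.tis_gene_list if g in values.index]
    absent = [g for g in config.tis_gene_list if g not in values.index]
    if not present:
        raise ValidationError("tis_score: no TIS genes present in matrix")
    if absent:
        warnings.warn(f"tis_score: absent TIS genes {absent}", stacklevel=2)
    return values.loc[present].mean(axis=0).rename("tis")


def aggressive_score(
    expr: ExpressionMatrix, config: SignatureConfig | None = None
) -> pd.Series:
    """Three-gene prognostic score: -0.393*CCL5 + 0.443*DDIT4 + 0.490*POLR1C
    on normalized log2 expression."""
    config = config or SignatureConfig()
    coeffs = config.aggressive_coeffs
    sub = _require_genes(_log2_values(expr), coeffs.keys(), "aggressive_score")
    w = pd.Series(coeffs)
    return sub.mul(w, axis=0).sum(axis=0).rename("aggressive")


def ims_score(cyt, tis, aggressive) -> pd.Series:
    """Integrative immune score: IMS = (CYT * TIS) - aggressive, elementwise."""
    cyt, tis, aggressive = (np.asarray(v, dtype=float) for v in (cyt, tis, aggressive))
    if not (cyt.shape == tis.shape == aggressive.shape):
        raise ValidationError("ims_score: input lengths differ")
    return pd.Series(cyt * tis - aggressive, name="ims")


def _ssgsea_sample(
    x: np.ndarray, in_set: np.ndarray, alpha: float, name_key: np.ndarray
) -> float:
    # Ascending average ranks: ties share a rank, highest expression -> rank n.
    ranks = rankdata(x, method="average")
    # walk from highest to lowest; ties broken by gene name so the score is
    # invariant to the row order of the input file
    order = np.lexsort((name_key, -x))
    hit = in_set[order]
    w = ranks[order] ** alpha * hit
    denom_in = w.sum()
    n_out = len(x) - int(in_set.sum())
    if denom_in == 0 or n_out == 0:
        return 0.0
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum(~hit) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(
    expr: ExpressionMatrix,
    gene_sets: GeneSetCollection | dict[str, list[str]],
    alpha: float = 0.25,
    min_size: int = 5,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample GSEA enrichment scores, samples x sets.

    Per sample, genes are ranked by expression (average ranks for ties) and the
    ranked list is walked from the top, accumulating in-set increments weighted
    by rank^alpha (normalized by the in-set total) minus uniform out-of-set
    increments; the score is the sum of the running-sum differences.  Sets
    smaller than ``min_size`` after intersection with the matrix genes are
    skipped with a warning.  ``normalize=True`` rescales all scores by the
    overall score range across samples and sets (cohort-level rescaling).

    Scores depend only on within-sample ranks, so they are invariant to gene
    order in the file and to monotone per-sample transforms.
    """
    sets = gene_sets.sets if isinstance(gene_sets, GeneSetCollection) else gene_sets
    values = _log2_values(expr)
    genes = values.index
    X = values.to_numpy()
    name_key = np.argsort(np.argsort(genes.astype(str)))
    out: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        in_set = np.asarray(genes.isin(set(members)))
        if in_set.sum() < min_size:
            warnings.warn(
                f"ssgsea: set {name!r} has {int(in_set.sum())} genes after "
                f"intersection (< {min_size}); skipped",
                stacklevel=2,
            )
            continue
        out[name] = np.array(
            [_ssgsea_sample(X[:, j], in_set, alpha, name_key)
             for j in range(X.shape[1])]
        )
    scores = pd.DataFrame(out, index=values.columns)
    if normalize and not scores.empty:
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
    return scores


def purity_from_estimate(
    estimate_score, constants: tuple[float, float] = PURITY_CONSTANTS
):
    """Tumor purity fraction cos(c0 + c1 * estimate_score).

    Defined only while the cosine argument stays in [0, pi/2]; outside that
    domain the result is NaN (undefined) rather than a clamped fraction."""
    c0, c1 = constants
    arg = c0 + c1 * np.asarray(estimate_score, dtype=float)
    purity = np.cos(arg)
    return np.where((arg >= 0) & (arg <= math.pi / 2), purity, np.nan)


def estimate_scores(
    expr: ExpressionMatrix, config: SignatureConfig | None = None
) -> pd.DataFrame:
    """Stromal, immune and combined ESTIMATE-style scores plus tumor purity.

    Stromal/immune scores are unnormalized ssGSEA on the two configured marker
    sets; purity = cos(c0 + c1 * estimate_score).  Purity is reported only when
    the cosine argument lies in [0, pi/2]; outside that domain the fraction is
    undefined (NaN) rather than clamped.
    """
    config = config or SignatureConfig()
    sets = {
        "stromal_score": config.gene_sets[config.estimate_stromal_set],
        "immune_score": config.gene_sets[config.estimate_immune_set],
    }
    scores = ssgsea(
        expr, sets, alpha=config.ssgsea_alpha,
        min_size=config.ssgsea_min_set_size, normalize=False,
    )
    for col in ("stromal_score", "immune_score"):
        if col not in scores:
            raise ValidationError(f"estimate_scores: required set for {col} missing")
    scores["estimate_score"] = scores["stromal_score"] + scores["immune_score"]
    c0, c1 = config.purity_constants
    arg = c0 + c1 * scores["estimate_score"]
    purity = np.cos(arg)
    valid = (arg >= 0) & (arg <= math.pi / 2)
    scores["purity"] = purity.where(valid)
    return scores


def immunophenoscore(
    expr: ExpressionMatrix, ips_weights: pd.DataFrame | None = None
) -> pd.DataFrame:
    """0-10 immunophenoscore from four weighted gene programs.

    Genes are z-scored across samples; each category's score is the weighted
    mean of its gene z-scores; the raw score is the mean over the four
    categories; discretization: 0 if raw <= 0, else ceil(10 * raw / 3) capped
    at 10.  Returns per-category means, the raw score and the integer IPS.
    """
    weights = ips_weights if ips_weights is not None else load_ips_weights()
    values = _log2_values(expr)
    z = values.sub(values.mean(axis=1), axis=0)
    sd = values.std(axis=1, ddof=0)
    z = z.div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    out = {}
    for cat, grp in weights.groupby("category"):
        present = grp[grp["gene"].isin(z.index)]
        if present.empty:
            raise ValidationError(f"immunophenoscore: no genes present for {cat!r}")
        sub = z.loc[present["gene"]]
        w = present["weight"].to_numpy()[:, None]
        out[cat] = pd.Series((sub.to_numpy() * w).mean(axis=0), index=z.columns)
    df = pd.DataFrame(out)
    df["ips_raw"] = df[["MHC", "immunomodulator", "effector", "suppressor"]].mean(axis=1)
    df["ips"] = [
        0 if raw <= 0 else min(10, math.ceil(10 * raw / 3)) for raw in df["ips_raw"]
    ]
    return df


def dichotomize_by_median(values) -> pd.Series:
    """Split at the median: 'low' for values <= median, 'high' above.

    Ties at the median go to the low group (the <=median row convention of the
    association tables)."""
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise ValidationError("dichotomize_by_median: need >= 2 values")
    med = s.median()
    if s.nunique() == 1:
        warnings.warn("dichotomize_by_median: all values identical", stacklevel=2)
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")


def tils_high_flag(tils_percent, threshold: float = 20.0) -> pd.Series:
    """True where stromal TILs density is at or above the clinically relevant
    threshold (default 20%, boundary inclusive)."""
    s = pd.Series(tils_percent, dtype=float)
    if ((s < 0) | (s > 100)).any():
        raise ValidationError("tils_high_flag: TILs % outside [0, 100]")
    return (s >= threshold).rename("tils_high")


def compute_panel(
    expr: ExpressionMatrix, config: SignatureConfig | None = None
) -> pd.DataFrame:
    """Full per-sample signature panel: CYT, TIS, aggressive, IMS, ssGSEA
    scores for every configured set, ESTIMATE scores/purity and IPS."""
    config = config or SignatureConfig()
    cyt = cyt_score(expr, config)
    tis = tis_score(expr, config)
    aggr = aggressive_score(expr, config)
    ims = ims_score(cyt, tis, aggr)
    ims.index = cyt.index
    panel = pd.concat([cyt, tis, aggr, ims.rename("ims")], axis=1)
    enr = ssgsea(
        expr, config.gene_sets, alpha=config.ssgsea_alpha,
        min_size=config.ssgsea_min_set_size, normalize=config.ssgsea_normalize,
    )
    enr = enr.rename(columns={name: f"ssgsea_{name}" for name in enr.columns})
    est = estimate_scores(expr, config)
    ips = immunophenoscore(expr, config.ips_weights)[["ips_raw", "ips"]]
    return pd.concat([panel, enr, est, ips], axis=1)
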