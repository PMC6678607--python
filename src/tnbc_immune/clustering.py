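"""Consensus NMF immuno-clustering with cophenetic rank selection and
biologically-motivated refinement.

The immune-gene submatrix (shifted to be nonnegative) is factorized many times
with multiplicative updates for the squared-Euclidean objective; each run
assigns every sample to the basis component with the largest coefficient, and
co-assignment frequencies form the consensus matrix.  The factorization rank
is chosen by the cophenetic correlation of the consensus-derived distances.
Final clusters are refined in two steps: clusters below a minimum size are
excluded outright (their samples are dropped from downstream statistics), and
remaining clusters are merged pairwise by highest Pearson correlation of their
mean-expression centroids until the target count is reached.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort_io import ValidationError

__all__ = [
    "NMFModel",
    "ConsensusResult",
    "ClusterAssignment",
    "nonneg_shift",
    "nmf_factorize",
    "consensus_cluster",
    "select_rank",
    "consensus_labels",
    "refine_clusters",
    "refine_or_fallback",
    "rename_by_score",
    "characterize_clusters",
]

_EPS = 1e-10


@dataclasses.dataclass
class NMFModel:
    W: np.ndarray           # genes x rank, columns unit L2 norm
    H: np.ndarray           # rank x samples
    rank: int
    objective: float        # final squared-Euclidean reconstruction error
    objectives: np.ndarray  # objective trace (one entry per check)
    n_iter: int
    converged: bool
    seed: object

    def labels(self) -> np.ndarray:
        """Per-sample assignment: argmax coefficient, lowest index on ties."""
        return self.H.argmax(axis=0)


@dataclasses.dataclass
class ConsensusResult:
    consensus: np.ndarray   # samples x samples co-assignment frequencies
    n_runs: int
    rank: int
    cophenetic: float


@dataclasses.dataclass
class ClusterAssignment:
    labels: pd.Series               # final cluster label per retained sample
    excluded_samples: list[str]
    refinement_log: list[dict]

    @property
    def n_clusters(self) -> int:
        return self.labels.nunique()


def nonneg_shift(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shift a (possibly negative) log2 matrix to nonnegative by subtracting
    its global minimum; returns (shifted, offset) so the offset is auditable."""
    offset = float(np.min(X))
    if offset >= 0:
        return np.asarray(X, dtype=float), 0.0
    return X - offset, offset


def nmf_factorize(
    V: np.ndarray,
    rank: int,
    seed,
    max_iter: int = 2000,
    tol: float = 1e-6,
    check_every: int = 10,
) -> NMFModel:
    """Multiplicative-update NMF for the squared-Euclidean objective.

    Stops when the relative objective change between successive checks falls
    below ``tol`` or after ``max_iter`` iterations.  W columns are rescaled to
    unit L2 norm with compensation in H, which leaves the product unchanged.
    The multiplicative updates guarantee a non-increasing objective.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValidationError(
            "nmf_factorize: V has negative entries; shift to nonnegative first "
            "(see nonneg_shift)"
        )
    n_genes, n_samples = V.shape
    if not 1 <= rank < min(n_genes, n_samples):
        raise ValidationError(f"rank {rank} must be in [1, min(dims)) for {V.shape}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(V.mean(), _EPS) / rank)
    W = rng.uniform(0.0, 1.0, (n_genes, rank)) * scale
    H = rng.uniform(0.0, 1.0, (rank, n_samples)) * scale

    objectives = []
    prev = None
    converged = False
    v_sq = float((V**2).sum())
    it = 0
    for it in range(1, max_iter + 1):
        WtV = W.T @ V
        H *= WtV / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        if it % check_every == 0 or it == max_iter:
            # ||V - WH||^2 via Gram matrices (no full reconstruction)
            WtV = W.T @ V
            WtW = W.T @ W
            obj = float(v_sq - 2.0 * np.sum(WtV * H) + np.sum(WtW * (H @ H.T)))
            obj = max(obj, 0.0)
            objectives.append(obj)
            if prev is not None and abs(prev - obj) <= tol * max(prev, _EPS):
                converged = True
                break
            prev = obj

    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    H = H * norms[:, None]
    final = float(((V - W @ H) ** 2).sum())
    return NMFModel(
        W=W, H=H, rank=rank, objective=final,
        objectives=np.asarray(objectives), n_iter=it, converged=converged, seed=seed,
    )


def _batched_consensus_labels(
    V: np.ndarray,
    rank: int,
    children,
    max_iter: int,
    tol: float,
    n_keep: int,
    check_every: int = 10,
) -> np.ndarray:
    """Per-run argmax assignments from gene-subsampled factorizations, all
    runs updated in one stacked (single-precision) multiplicative loop.

    Converged runs are frozen and removed from the batch; assignment only
    needs the argmax of H, for which float32 is ample.
    """
    n_runs = len(children)
    n_genes, n_samples = V.shape
    dtype = np.float32
    eps = dtype(1e-10)
    Vb = np.empty((n_runs, n_keep, n_samples), dtype=dtype)
    W = np.empty((n_runs, n_keep, rank), dtype=dtype)
    H = np.empty((n_runs, rank, n_samples), dtype=dtype)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        rows = (rng.choice(n_genes, size=n_keep, replace=False)
                if n_keep < n_genes else np.arange(n_genes))
        Vb[i] = V[rows]
        scale = np.sqrt(max(float(Vb[i].mean()), 1e-10) / rank)
        W[i] = rng.uniform(0.0, 1.0, (n_keep, rank)) * scale
        H[i] = rng.uniform(0.0, 1.0, (rank, n_samples)) * scale

    labels = np.zeros((n_runs, n_samples), dtype=np.int64)
    active = np.arange(n_runs)
    v_sq = (Vb.astype(np.float64) ** 2).sum(axis=(1, 2))
    prev = None
    for it in range(1, max_iter + 1):
        Wt = W.transpose(0, 2, 1)
        H *= (Wt @ Vb) / (Wt @ W @ H + eps)
        Ht = H.transpose(0, 2, 1)
        W *= (Vb @ Ht) / (W @ (H @ Ht) + eps)
        if it % check_every == 0 or it == max_iter:
            Wt = W.transpose(0, 2, 1)
            WtV = Wt @ Vb
            WtW = Wt @ W
            obj = (v_sq
                   - 2.0 * np.einsum("rks,rks->r", WtV, H, dtype=np.float64)
                   + np.einsum("rkl,rkl->r", WtW, H @ H.transpose(0, 2, 1),
                               dtype=np.float64))
            if prev is not None:
                done = np.abs(prev - obj) <= tol * np.maximum(prev, 1e-10)
                if it == max_iter:
                    done = np.ones_like(done)
                if done.any():
                    labels[active[done]] = H[done].argmax(axis=1)
                    keep = ~done
                    active = active[keep]
                    if active.size == 0:
                        break
                    Vb, W, H = Vb[keep], W[keep], H[keep]
                    v_sq, obj = v_sq[keep], obj[keep]
            prev = obj
    if active.size:
        labels[active] = H.argmax(axis=1)
    return labels


def consensus_cluster(
    V: np.ndarray,
    rank: int,
    n_runs: int = 100,
    seed=0,
    max_iter: int = 700,
    tol: float = 1e-6,
    subsample_genes: float = 0.9,
) -> ConsensusResult:
    """Consensus matrix over ``n_runs`` perturbed factorizations and its
    cophenetic correlation coefficient.

    Each run draws a random ``subsample_genes`` fraction of the rows (the
    standard data-perturbation scheme of consensus clustering; restarts on
    the identical matrix can make spurious finer splits look deterministic)
    and factorizes it from a fresh random initialization; samples are
    assigned by argmax coefficient.  consensus[i, j] is the fraction of runs
    assigning samples i and j together.  The cophenetic coefficient is the
    Pearson correlation between the (1 - consensus) distances and the
    cophenetic distances of their average-linkage dendrogram; a degenerate
    all-equal distance matrix gets 1.0 when the consensus is a perfect 0/1
    block structure and 0.0 otherwise.
    """
    V = np.asarray(V, dtype=float)
    n_genes, n_samples = V.shape
    if n_runs < 2:
        raise ValidationError("consensus_cluster: n_runs must be >= 2")
    if rank >= n_samples:
        raise ValidationError(f"rank {rank} >= n_samples {n_samples}")
    if not 0 < subsample_genes <= 1:
        raise ValidationError("subsample_genes must be in (0, 1]")
    n_keep = max(rank + 1, int(round(subsample_genes * n_genes)))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    labels = _batched_consensus_labels(
        np.ascontiguousarray(V), rank, ss.spawn(n_runs), max_iter, tol, n_keep
    )
    C = (labels[:, :, None] == labels[:, None, :]).mean(axis=0)
    return ConsensusResult(
        consensus=C, n_runs=n_runs, rank=rank, cophenetic=_cophenetic(C)
    )


def _cophenetic(consensus: np.ndarray) -> float:
    d = squareform(1.0 - consensus, checks=False)
    if d.size == 0 or d.std() == 0:
        perfect = np.all(np.isclose(consensus, 0) | np.isclose(consensus, 1))
        return 1.0 if perfect else 0.0
    Z = linkage(d, method="average")
    c, _ = cophenet(Z, d)
    return float(c)


def select_rank(
    V: np.ndarray,
    rank_grid=range(2, 8),
    n_runs: int = 50,
    seed=0,
    max_iter: int = 700,
    tol: float = 1e-6,
    subsample_genes: float = 0.9,
    refine_runs: int | None = None,
) -> tuple[int, pd.DataFrame, dict[int, ConsensusResult]]:
    """Pick the factorization rank maximizing the cophenetic coefficient.

    Two-stage estimate: every rank on the grid gets an ``n_runs`` consensus;
    the two leading ranks are then re-estimated with a fresh ``refine_runs``
    ensemble and compared on those refined values (the cophenetic gap
    between neighbouring candidate ranks is routinely of the same order as
    the Monte-Carlo noise of a small consensus, so the simulation effort is
    concentrated where the decision is close).  Ties go to the smallest
    rank.  Returns the chosen rank, the per-rank audit table and the
    per-rank consensus results (so the chosen consensus need not be
    recomputed); ``refine_runs`` defaults to three times ``n_runs`` and 0
    gives the plain single-stage rule.
    """
    grid = list(rank_grid)
    if not grid:
        raise ValidationError("select_rank: empty rank grid")
    if refine_runs is None:
        refine_runs = 3 * n_runs
    results: dict[int, ConsensusResult] = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(grid) + 2)
    for rank, child in zip(grid, children):
        results[rank] = consensus_cluster(
            V, rank, n_runs=n_runs, seed=child, max_iter=max_iter, tol=tol,
            subsample_genes=subsample_genes,
        )
    coph = {r: results[r].cophenetic for r in grid}
    stage1 = dict(coph)

    def argmax_smallest(candidates, values):
        best = min(candidates)
        for r in sorted(candidates):
            if values[r] > values[best] + 1e-12:
                best = r
        return best

    if refine_runs > n_runs and len(grid) > 1:
        leaders = sorted(grid, key=lambda r: (-coph[r], r))[:2]
        for rank, child in zip(sorted(leaders), children[len(grid):]):
            results[rank] = consensus_cluster(
                V, rank, n_runs=refine_runs, seed=child, max_iter=max_iter,
                tol=tol, subsample_genes=subsample_genes,
            )
            coph[rank] = results[rank].cophenetic
        best = argmax_smallest(leaders, coph)
    else:
        best = argmax_smallest(grid, coph)
    table = pd.DataFrame({
        "rank": grid,
        "cophenetic": [coph[r] for r in grid],
        "cophenetic_stage1": [stage1[r] for r in grid],
        "n_runs": [results[r].n_runs for r in grid],
    })
    return best, table, results


def consensus_labels(result: ConsensusResult) -> np.ndarray:
    """Deterministic initial labels: average-linkage cut of the consensus
    distance matrix into ``rank`` clusters."""
    d = squareform(1.0 - result.consensus, checks=False)
    if d.std() == 0:
        return np.zeros(result.consensus.shape[0], dtype=int)
    Z = linkage(d, method="average")
    return fcluster(Z, t=result.rank, criterion="maxclust") - 1


def refine_clusters(
    labels,
    V: np.ndarray | pd.DataFrame,
    min_size: int | None = None,
    target_k: int = 3,
    sample_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Two-step refinement of an initial consensus assignment.

    Step 1 excludes every cluster smaller than ``min_size`` (default
    ``max(4, 10% of n)``); its samples are flagged and dropped from all
    downstream statistics.  Step 2 repeatedly merges the pair of clusters
    whose mean-expression centroids over the clustering gene set are most
    Pearson-correlated, until ``target_k`` clusters remain.  Deterministic:
    ties in correlation break on the lowest cluster-id pair.
    """
    V = np.asarray(V, dtype=float)
    labels = np.asarray(labels)
    n = labels.shape[0]
    if V.shape[1] != n:
        raise ValidationError("refine_clusters: V columns must match labels length")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    if min_size is None:
        min_size = max(4, int(round(0.10 * n)))

    log: list[dict] = []
    keep = np.ones(n, dtype=bool)
    ids, sizes = np.unique(labels, return_counts=True)
    for cid, size in zip(ids, sizes):
        if size < min_size:
            keep &= labels != cid
            log.append({"action": "exclude", "cluster": int(cid), "size": int(size)})
    excluded = [sample_ids[i] for i in range(n) if not keep[i]]

    current = {int(c): set(np.flatnonzero(keep & (labels == c)))
               for c in np.unique(labels[keep])}
    if len(current) < target_k:
        raise ValidationError(
            f"refine_clusters: {len(current)} clusters after exclusion, "
            f"cannot reach target_k={target_k}"
        )

    def centroid(members: set[int]) -> np.ndarray:
        return V[:, sorted(members)].mean(axis=1)

    while len(current) > target_k:
        keys = sorted(current)
        cents = {c: centroid(current[c]) for c in keys}
        best_pair, best_r = None, -np.inf
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                r = float(np.corrcoef(cents[a], cents[b])[0, 1])
                if r > best_r + 1e-15:
                    best_pair, best_r = (a, b), r
        a, b = best_pair
        log.append({
            "action": "merge", "clusters": [a, b], "pearson_r": best_r,
            "sizes": [len(current[a]), len(current[b])],
        })
        current[a] = current[a] | current[b]
        del current[b]

    final = pd.Series(index=pd.Index(sample_ids, name="sample_id"), dtype=object)
    for new_id, (_, members) in enumerate(sorted(current.items())):
        for i in members:
            final.iloc[i] = new_id
    final = final.dropna().astype(int)
    return ClusterAssignment(labels=final, excluded_samples=excluded, refinement_log=log)


def refine_or_fallback(
    initial: np.ndarray,
    V: np.ndarray,
    min_size: int | None,
    target_k: int,
    sample_ids: list[str],
) -> ClusterAssignment:
    """Refine when enough clusters exist; otherwise keep the consensus labels
    as-is with a note in the log (a selected rank below the target cannot be
    split further)."""
    if len(np.unique(initial)) < target_k:
        labels = pd.Series(initial, index=pd.Index(sample_ids, name="sample_id"))
        return ClusterAssignment(
            labels=labels, excluded_samples=[],
            refinement_log=[{
                "action": "skip_refinement",
                "reason": f"{len(np.unique(initial))} consensus clusters "
                          f"< target_k={target_k}",
            }],
        )
    return refine_clusters(initial, V, min_size=min_size, target_k=target_k,
                           sample_ids=sample_ids)


def rename_by_score(
    assignment: ClusterAssignment, score: pd.Series, names: tuple[str, ...] = ("ImA", "ImB", "ImC")
) -> ClusterAssignment:
    """Rename final clusters by descending mean of ``score`` (typically the
    immune score), so the most immune-active cluster becomes the first name."""
    labels = assignment.labels
    means = score.reindex(labels.index).groupby(labels).mean()
    order = means.sort_values(ascending=False).index
    if len(order) > len(names):
        raise ValidationError(
            f"rename_by_score: {len(order)} clusters but only {len(names)} names"
        )
    mapping = {old: names[i] for i, old in enumerate(order)}
    return ClusterAssignment(
        labels=labels.map(mapping).rename("im_cluster"),
        excluded_samples=assignment.excluded_samples,
        refinement_log=assignment.refinement_log + [{"action": "rename", "map": mapping}],
    )


def characterize_clusters(
    labels: pd.Series,
    panel: pd.DataFrame,
    deconv: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    cbc: pd.DataFrame | None = None,
    tils_threshold: float = 20.0,
) -> pd.DataFrame:
    """Per-cluster summary: median signature scores, mean deconvolved
    fractions and presence rates, percent TILs-high and median PLR."""
    labels = labels.dropna()
    if labels.empty:
        raise ValidationError("characterize_clusters: no labelled samples")
    rows = {}
    for cid, members in labels.groupby(labels).groups.items():
        members = list(members)
        if not members:
            raise ValidationError(f"characterize_clusters: empty cluster {cid}")
        row: dict[str, float] = {"n": len(members)}
        sub = panel.reindex(members)
        for col in panel.columns:
            row[f"median_{col}"] = float(sub[col].median())
        if deconv is not None:
            dsub = deconv.reindex(members)
            for ct in deconv.columns:
                row[f"mean_frac_{ct}"] = float(dsub[ct].mean())
                row[f"present_pct_{ct}"] = float((dsub[ct] > 0).mean() * 100)
        if clinical is not None:
            csub = clinical.reindex(members)
            row["pct_tils_high"] = float(
                (csub["tils_percent"] >= tils_threshold).mean() * 100
            )
            row["n_events"] = int(csub["event_flag"].sum())
        if cbc is not None:
            bsub = cbc.reindex(members)
            row["median_plr"] = float((bsub["platelets"] / bsub["lymphocytes"]).median())
            row["median_nlr"] = float((bsub["neutrophils"] / bsub["lymphocytes"]).median())
        rows[cid] = row
    return pd.DataFrame(rows).T.rename_axis("cluster")
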