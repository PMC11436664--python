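"""Multiple factor analysis, clustering, and complexity target points.

The statistical pipeline that turns a model-by-metric table into design
guidance:

1. **MFA** — a PCA generalization in which the variables are partitioned
   into groups (here geometric {C, P_t, D_t} and informational {R, H_t, J})
   and each group's standardized variables are down-weighted by the square
   root of the group's first PCA eigenvalue, so no group dominates the
   ordination.  The Complexity Index is projected as a *supplementary*
   quantitative variable: correlated with the dimensions but never
   influencing them.
2. **KSP rule** — eigenvalue retention threshold 1 + 2*sqrt((p-1)/(n-1)).
3. **HCPC** — Ward hierarchical clustering on principal-component scores,
   with v-test cluster description.
4. **CTP selection** — among models with positive Dim.1 score, those whose
   Euclidean distance from the origin of the Dim.1 x Dim.2 plane reaches
   the mean of such distances; the per-metric mean +/- SD over that subset
   are the complexity target points a new design should meet or surpass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr

from .complexity_table import METRIC_COLUMNS, MetricTable
from .errors import DegenerateInputError, ParameterError, SchemaError

__all__ = [
    "DEFAULT_GROUPS",
    "MFAResult",
    "ClusterResult",
    "CTPResult",
    "mfa",
    "ksp_retention",
    "hcpc",
    "describe_clusters",
    "select_ctp",
]

DEFAULT_GROUPS = {
    "geometric": ["C", "P_t", "D_t"],
    "informational": ["R", "H_t", "J"],
}


@dataclass
class MFAResult:
    eigenvalues: np.ndarray
    inertia_pct: np.ndarray
    scores: pd.DataFrame  # models x dimensions (Dim.1, Dim.2, ...)
    loadings: pd.DataFrame  # correlation of each active variable with each dim
    contributions: pd.DataFrame  # variable contributions per dim (%, sum 100)
    group_weights: dict  # group name -> 1/lambda1 column weight
    supplementary_cor: pd.Series | None  # corr of supplementary var with dims
    ksp_threshold: float
    n_retained: int
    retained_by_rule: int
    groups: dict = field(default_factory=dict)
    supplementary: str | None = None

    @property
    def dim_names(self) -> list[str]:
        return list(self.scores.columns)

    def to_json(self) -> str:
        return json.dumps(
            {
                "eigenvalues": self.eigenvalues.tolist(),
                "inertia_pct": self.inertia_pct.tolist(),
                "scores": self.scores.round(6).to_dict(orient="index"),
                "contributions": self.contributions.round(4).to_dict(orient="index"),
                "supplementary_cor": None
                if self.supplementary_cor is None
                else self.supplementary_cor.round(6).to_dict(),
                "ksp_threshold": self.ksp_threshold,
                "n_retained": self.n_retained,
                "groups": self.groups,
                "supplementary": self.supplementary,
            },
            indent=2,
        )


def ksp_retention(n: int, p: int, eigenvalues=None) -> tuple[float, int]:
    """Karlis-Saporta-Spinaki retention threshold and retained count.

    threshold = 1 + 2*sqrt((p - 1)/(n - 1)); dimensions whose eigenvalue
    reaches the threshold are retained.  At least 2 dimensions are always
    kept for the planar ordination plots; ``retained_by_rule`` on the MFA
    result records what the rule alone would keep.
    """
    if n <= 1 or p <= 1:
        raise ParameterError("KSP rule needs n > 1 observations and p > 1 variables")
    threshold = 1.0 + 2.0 * np.sqrt((p - 1) / (n - 1))
    if eigenvalues is None:
        return float(threshold), 2
    kept = int(np.sum(np.asarray(eigenvalues) >= threshold))
    return float(threshold), kept


def mfa(
    table: MetricTable,
    groups: dict | None = None,
    supplementary: str | None = "CI",
    standardize: str = "population",
) -> MFAResult:
    """Grouped multiple factor analysis of a model-by-metric table.

    Each active variable is centered and scaled (population SD by default);
    each group's block is divided by the square root of its first PCA
    eigenvalue; the weighted matrix is decomposed by SVD with uniform row
    weights 1/n.  Dimension signs are fixed deterministically: Dim.1 so the
    supplementary variable correlates non-negatively with it (falling back
    to a positive loading sum), higher dimensions so their largest-loading
    variable loads positively.
    """
    groups = dict(groups) if groups else dict(DEFAULT_GROUPS)
    active = [v for vs in groups.values() for v in vs]
    if len(set(active)) != len(active):
        raise ParameterError("a variable appears in more than one group")
    missing = [v for v in active if v not in table.df.columns]
    if missing:
        raise SchemaError(f"table lacks active variables: {missing}")
    n = len(table)
    if n < 3:
        raise ParameterError("MFA needs at least 3 models")

    X = table.df[active].to_numpy(dtype=float)
    ddof = 0 if standardize == "population" else 1
    sd = X.std(axis=0, ddof=ddof)
    zero = np.asarray(active)[sd <= 0]
    if len(zero):
        raise DegenerateInputError(f"zero-variance variable(s): {zero.tolist()}")
    Z = (X - X.mean(axis=0)) / sd

    col_weight = np.empty(len(active))
    group_weights = {}
    pos = 0
    for gname, gvars in groups.items():
        block = Z[:, pos : pos + len(gvars)]
        lam1 = np.linalg.svd(block / np.sqrt(n), compute_uv=False)[0] ** 2
        group_weights[gname] = 1.0 / lam1
        col_weight[pos : pos + len(gvars)] = 1.0 / lam1
        pos += len(gvars)

    W = Z * np.sqrt(col_weight)
    U, S, Vt = np.linalg.svd(W / np.sqrt(n), full_matrices=False)
    eig = S**2
    scores = U * S * np.sqrt(n)
    inertia = 100.0 * eig / eig.sum()

    # variable loadings = correlations of standardized vars with the scores
    with np.errstate(invalid="ignore", divide="ignore"):
        score_sd = scores.std(axis=0, ddof=0)
        safe = np.where(score_sd > 0, score_sd, 1.0)
        load = (Z.T @ scores) / n / safe[None, :]
        load[:, score_sd <= 0] = 0.0
    contrib = 100.0 * Vt.T**2  # columns sum to 100 per dimension

    dims = [f"Dim.{i + 1}" for i in range(len(eig))]
    supp_vals = None
    if supplementary is not None:
        if supplementary not in table.df.columns:
            raise SchemaError(f"supplementary variable {supplementary!r} not in table")
        supp_vals = table.df[supplementary].to_numpy(dtype=float)

    # deterministic sign conventions (signs are arbitrary in any SVD)
    for d in range(len(eig)):
        if score_sd[d] <= 0:
            continue
        if d == 0:
            ref = (
                np.corrcoef(scores[:, 0], supp_vals)[0, 1]
                if supp_vals is not None
                else load[:, 0].sum()
            )
        else:
            ref = load[np.argmax(np.abs(load[:, d])), d]
        if ref < 0:
            scores[:, d] *= -1.0
            load[:, d] *= -1.0

    supp_cor = None
    if supp_vals is not None:
        cors = []
        for d in range(len(eig)):
            cors.append(
                float(np.corrcoef(scores[:, d], supp_vals)[0, 1])
                if score_sd[d] > 0
                else 0.0
            )
        supp_cor = pd.Series(cors, index=dims, name=supplementary)

    threshold, kept = ksp_retention(n, len(active), eig)
    result = MFAResult(
        eigenvalues=eig,
        inertia_pct=inertia,
        scores=pd.DataFrame(scores, index=table.model_ids, columns=dims),
        loadings=pd.DataFrame(load, index=active, columns=dims),
        contributions=pd.DataFrame(contrib, index=active, columns=dims),
        group_weights=group_weights,
        supplementary_cor=supp_cor,
        ksp_threshold=threshold,
        n_retained=max(kept, 2),
        retained_by_rule=kept,
        groups={k: list(v) for k, v in groups.items()},
        supplementary=supplementary,
    )
    return result


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    assignments: pd.Series  # model_id -> cluster id (1..k)
    linkage_matrix: np.ndarray
    k: int
    n_dims: int
    descriptions: pd.DataFrame | None = None

    def members(self, cluster: int) -> list[str]:
        return self.assignments.index[self.assignments == cluster].tolist()


def hcpc(result: MFAResult, k: int = 3, n_dims: int | None = None) -> ClusterResult:
    """Ward clustering (Ward.D2) of models in principal-component space.

    ``n_dims`` defaults to the first five dimensions (the conventional
    default of factor-analysis clustering tools), capped at what the
    decomposition provides.  Rows are processed in lexicographic model-id
    order so merge tie-breaking never depends on input row order; cluster
    ids 1..k are assigned by ascending mean Dim.1 score, which puts the
    simplest designs in cluster 1.
    """
    ids = result.scores.index.to_numpy()
    n = len(ids)
    if not 2 <= k <= n:
        raise ParameterError(f"k must be in [2, {n}], got {k}")
    if n_dims is None:
        n_dims = min(5, result.scores.shape[1])
    pts = result.scores.iloc[:, :n_dims]
    order = np.argsort(ids)
    pts_sorted = pts.to_numpy()[order]
    Z = linkage(pts_sorted, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    assignments = pd.Series(index=ids[order], data=raw, name="cluster")
    # relabel clusters by ascending mean Dim.1
    dim1 = result.scores["Dim.1"]
    means = {c: dim1[assignments.index[assignments == c]].mean() for c in np.unique(raw)}
    relabel = {c: i + 1 for i, c in enumerate(sorted(means, key=means.get))}
    assignments = assignments.map(relabel)
    return ClusterResult(
        assignments=assignments.loc[ids],  # back to table order
        linkage_matrix=Z,
        k=int(k),
        n_dims=int(n_dims),
    )


def describe_clusters(
    table: MetricTable,
    clusters: ClusterResult,
    variables: list[str] | None = None,
    v_threshold: float = 1.96,
) -> pd.DataFrame:
    """v-test description of each cluster by each quantitative variable.

    v = (mean_c - mean) / sqrt((s^2 / n_c) * (N - n_c) / (N - 1)) with s^2
    the population variance — the standardized deviation of the cluster
    mean from the global mean under random allocation.  |v| >= 1.96 marks a
    characterizing variable.  Singleton clusters give undefined (NaN) v for
    zero-variance denominators handled conservatively.
    """
    if variables is None:
        variables = METRIC_COLUMNS + ["CI"]
    df = table.df.set_index("model_id")
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise SchemaError(f"table lacks variables: {missing}")
    N = len(df)
    rows = []
    for c in sorted(clusters.assignments.unique()):
        members = clusters.assignments.index[clusters.assignments == c]
        n_c = len(members)
        for var in variables:
            x = df[var].to_numpy(dtype=float)
            s2 = x.var(ddof=0)
            mean_c = df.loc[members, var].mean()
            if n_c == N or s2 <= 0:
                v = np.nan
            else:
                v = (mean_c - x.mean()) / np.sqrt((s2 / n_c) * (N - n_c) / (N - 1))
            rows.append(
                {
                    "cluster": c,
                    "variable": var,
                    "cluster_mean": mean_c,
                    "overall_mean": x.mean(),
                    "v_test": v,
                    "characterizing": bool(abs(v) >= v_threshold) if np.isfinite(v) else False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# complexity target points
# ---------------------------------------------------------------------------


@dataclass
class CTPResult:
    distances: pd.Series  # model_id -> Euclidean distance in Dim.1 x Dim.2
    threshold: float  # mean distance over positive-Dim.1 models
    selected: list[str]
    ctp_mean: pd.Series  # per metric (C, P_t, D_t, R, H_t, J, CI)
    ctp_sd: pd.Series  # sample SD (n-1 denominator)
    threshold_sd: float  # spread of the distances entering the threshold

    def to_json(self) -> str:
        return json.dumps(
            {
                "threshold": self.threshold,
                "threshold_sd": self.threshold_sd,
                "selected": self.selected,
                "ctp_mean": self.ctp_mean.round(6).to_dict(),
                "ctp_sd": self.ctp_sd.round(6).to_dict(),
                "distances": self.distances.round(6).to_dict(),
            },
            indent=2,
        )


def select_ctp(
    table: MetricTable,
    scores: pd.DataFrame | None = None,
    use_printed_distances: bool = False,
) -> CTPResult:
    """Select the "complex" models and average their metrics into CTPs.

    Needs Dim.1 scores plus either Dim.2 scores (``scores`` with columns
    Dim.1, Dim.2) or — with ``use_printed_distances`` — the table's own
    ``dim1_score``/``dim12_distance`` columns, which makes the selection
    independent of any ordination implementation.

    distance  = sqrt(Dim.1**2 + Dim.2**2)
    threshold = mean distance over models with Dim.1 > 0
    selected  = models with Dim.1 > 0 and distance >= threshold (ties kept)
    """
    df = table.df.set_index("model_id")
    if use_printed_distances:
        for col in ("dim1_score", "dim12_distance"):
            if col not in df.columns:
                raise SchemaError(f"table lacks required column {col!r}")
        dim1 = df["dim1_score"].astype(float)
        dist = df["dim12_distance"].astype(float)
    else:
        if scores is None:
            raise ParameterError("provide MFA scores or set use_printed_distances")
        dim1 = scores["Dim.1"].astype(float)
        dist = np.sqrt(scores["Dim.1"] ** 2 + scores["Dim.2"] ** 2)
        dim1 = dim1.loc[df.index]
        dist = dist.loc[df.index]
    positive = dim1 > 0
    if not positive.any():
        raise DegenerateInputError("no model has a positive Dim.1 score")
    pool = dist[positive]
    threshold = float(pool.mean())
    threshold_sd = float(pool.std(ddof=1)) if len(pool) > 1 else 0.0
    selected = dist.index[(positive) & (dist >= threshold)].tolist()
    cols = METRIC_COLUMNS + ["CI"]
    sub = df.loc[selected, cols].astype(float)
    return CTPResult(
        distances=dist.rename("distance"),
        threshold=threshold,
        selected=selected,
        ctp_mean=sub.mean(),
        ctp_sd=sub.std(ddof=1),
        threshold_sd=threshold_sd,
    )


def dim1_ci_correlation(result: MFAResult, table: MetricTable) -> tuple[float, float]:
    """Pearson correlation (r, p) of Dim.1 scores with the Complexity Index."""
    r, p = pearsonr(result.scores["Dim.1"].to_numpy(), table.df["CI"].to_numpy(dtype=float))
    return float(r), float(p)
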