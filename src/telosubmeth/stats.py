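"""Statistical layer: normality-gated two-sample tests, varimax-rotated PCA
with Kaiser component selection, and hierarchical genotype clustering.

The gated test applies Shapiro–Wilk to both groups and uses Student's t
(two-sided, equal variance) only when both look normal at alpha = 0.05,
otherwise the two-sided Mann–Whitney U.  No multiple-testing correction is
applied by default; each comparison is judged at p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.multivariate.factor_rotation import rotate_factors

SHAPIRO_ALPHA = 0.05


@dataclass
class GatedTestResult:
    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    p_two_sided: float
    shapiro_p: tuple[float, float]  # per group; NaN when undefined
    n: tuple[int, int]
    flags: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_two_sided < 0.05


def gated_two_sample_test(a, b) -> GatedTestResult:
    """Two-sample comparison with a Shapiro–Wilk normality gate.

    Both groups normal (Shapiro p >= 0.05) -> equal-variance Student t;
    otherwise Mann–Whitney U.  Constant groups make Shapiro undefined and
    fall back to Mann–Whitney, flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"need >= 3 values per group, got {len(a)} and {len(b)}")
    flags = []
    ps = []
    for g in (a, b):
        if np.ptp(g) == 0:
            ps.append(np.nan)
            flags.append("constant_group")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ps.append(stats.shapiro(g).pvalue)
    normal = all(not np.isnan(p) and p >= SHAPIRO_ALPHA for p in ps)
    if normal:
        res = stats.ttest_ind(a, b, equal_var=True)
        used = "t_test"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        used = "mann_whitney"
    return GatedTestResult(
        test_used=used,
        statistic=float(res.statistic),
        p_two_sided=float(res.pvalue),
        shapiro_p=(ps[0], ps[1]),
        n=(len(a), len(b)),
        flags=flags,
    )


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # features x rotated components
    eigenvalues: np.ndarray  # of the correlation matrix, all components
    selected_components: list[str]
    variance_explained: pd.Series  # percent, per rotated component
    score_correlations: pd.DataFrame | None = None  # components x anchors (r, p)

    @property
    def total_variance_explained(self) -> float:
        return float(self.variance_explained.sum())


def _varimax_kaiser(loadings: np.ndarray) -> np.ndarray:
    """Varimax rotation with Kaiser row normalization."""
    h = np.sqrt((loadings**2).sum(axis=1))
    h[h == 0] = 1.0
    normed = loadings / h[:, None]
    rotated, _ = rotate_factors(normed, "varimax", tol=1e-6, max_tries=500)
    return rotated * h[:, None]


def pca_varimax(
    table: pd.DataFrame,
    anchor_columns: list[str] | None = None,
    *,
    eigenvalue_min: float = 1.0,
    anchor_alpha: float = 0.05,
    anchor_r_min: float = 0.3,
) -> PCAResult:
    """Standardized PCA with varimax rotation and Kaiser selection.

    Columns are z-scored, components are extracted from the correlation
    matrix, and those with eigenvalue > ``eigenvalue_min`` are varimax
    rotated (Kaiser-normalized, tol 1e-6).  If ``anchor_columns`` are named
    (the wild-type CGm/CHGm/CHHm levels), a rotated component is *selected*
    only when it correlates with at least one anchor both significantly
    (p < ``anchor_alpha``) and appreciably (|r| >= ``anchor_r_min``);
    otherwise all retained components are selected.  The correlation is
    computed leave-one-out: the component's scores are re-derived without
    the anchor's own loading before correlating with the anchor, so a
    component must share variance with the anchor through *other* features
    — a noise component that merely recapitulates the anchor column is not
    selected.

    Rows with any missing value are dropped (complete-case).  Constant and
    linearly dependent columns reduce the usable rank; components beyond
    the rank are dropped with a warning.
    """
    data = table.dropna()
    if len(data) < 3:
        raise ValueError("need >= 3 complete-case rows")
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep_cols = sd > 0
    if not keep_cols.all():
        warnings.warn(
            f"dropping constant columns: {list(data.columns[~keep_cols])}"
        )
    data = data.loc[:, keep_cols]
    X = data.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    n, p = Z.shape
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    rank = int(np.linalg.matrix_rank(corr))
    retained = [
        i for i in range(min(rank, p)) if eigvals[i] > eigenvalue_min
    ]
    if not retained:
        warnings.warn("no component passes the eigenvalue criterion")
        return PCAResult(
            loadings=pd.DataFrame(index=data.columns),
            eigenvalues=eigvals,
            selected_components=[],
            variance_explained=pd.Series(dtype=float),
        )
    A = eigvecs[:, retained] * np.sqrt(eigvals[retained])  # unrotated loadings
    L = _varimax_kaiser(A)
    # order rotated components by explained variance, fix sign (largest |loading| positive)
    ssl = (L**2).sum(axis=0)
    order2 = np.argsort(ssl)[::-1]
    L = L[:, order2]
    for j in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] *= -1
    names = [f"RC{j + 1}" for j in range(L.shape[1])]
    loadings = pd.DataFrame(L, index=data.columns, columns=names)
    var_exp = pd.Series((L**2).sum(axis=0) / p * 100.0, index=names)
    # component scores via least squares on standardized data
    scores = Z @ L @ np.linalg.pinv(L.T @ L) if L.size else np.empty((n, 0))
    selected = names
    score_corr = None
    if anchor_columns:
        anchors = [c for c in anchor_columns if c in data.columns]
        rows = {}
        selected = []
        columns = list(data.columns)
        for j, name in enumerate(names):
            entry = {}
            keep = False
            for c in anchors:
                mask = np.array([col != c for col in columns])
                Lj = L[mask, j : j + 1]
                denom = float((Lj**2).sum())
                if denom <= 1e-12:
                    r, pv = np.nan, np.nan
                else:
                    loo_scores = (Z[:, mask] @ Lj / denom).ravel()
                    r, pv = stats.pearsonr(loo_scores, data[c].to_numpy(dtype=float))
                entry[c + "_r"] = r
                entry[c + "_p"] = pv
                if not np.isnan(r) and pv < anchor_alpha and abs(r) >= anchor_r_min:
                    keep = True
            rows[name] = entry
            if keep:
                selected.append(name)
        score_corr = pd.DataFrame(rows).T
    return PCAResult(
        loadings=loadings,
        eigenvalues=eigvals,
        selected_components=selected,
        variance_explained=var_exp,
        score_correlations=score_corr,
    )


@dataclass
class ClusterTree:
    """Single-linkage hierarchy over genotype methylomes."""

    labels: list[str]
    linkage: np.ndarray
    distances: pd.DataFrame  # pairwise Euclidean, labels x labels
    n_sites: int

    def cut(self, k: int) -> dict[str, int]:
        """Partition the samples into k flat clusters."""
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(x) for x in assignment)))

    def groups(self, k: int) -> set[frozenset[str]]:
        part: dict[int, set] = {}
        for label, c in self.cut(k).items():
            part.setdefault(c, set()).add(label)
        return {frozenset(v) for v in part.values()}

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return self.labels[node.id]
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

        return f"({walk(tree.left)},{walk(tree.right)});"


def cluster_genotypes(profiles: list) -> ClusterTree:
    """Single-linkage clustering of samples on shared methylation sites.

    The feature vector of each sample is its per-cytosine level (percent)
    over the sites covered in *all* samples (CG, CHG and CHH together);
    distance is Euclidean, linkage is nearest-point (single).
    """
    if len(profiles) < 3:
        raise ValueError("need >= 3 samples to cluster")
    labels = [p.genotype for p in profiles]
    if len(set(labels)) != len(labels):
        labels = [f"{p.genotype}#{i}" for i, p in enumerate(profiles)]
    keys = ["end_id", "pos", "strand"]
    mats = []
    for p in profiles:
        mats.append(p.records.set_index(keys)["level"])
    joined = pd.concat(mats, axis=1, join="inner", keys=labels)
    if joined.shape[0] < 2:
        raise ValueError(f"only {joined.shape[0]} sites shared across all samples")
    X = joined.to_numpy(dtype=float).T  # samples x sites
    d = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(d, method="single")
    dm = pd.DataFrame(
        hierarchy.distance.squareform(d), index=labels, columns=labels
    )
    return ClusterTree(labels=labels, linkage=Z, distances=dm, n_sites=joined.shape[0])
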