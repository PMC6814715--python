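"""The cartilage anabolic-axis screen over a recombinant-inbred expression panel.

The procedure mirrors a reference-population co-expression screen: collapse
microarray probes to one row per gene, correlate a supplied list of cartilage
matrix genes across strains, keep the highly intercorrelated core, extract
the first principal component of the standardized core ("Factor 1", the
anabolic axis), and correlate every candidate regulator gene with the axis
scores, ranking the most negatively correlated candidates first.

Factor extraction is unrotated PCA on the correlation matrix (z-scored
genes) — the default extraction of the statistical software named by the
study and the only choice under which "the first axis" is well defined.
Loadings are reported on the factor-analysis scale, i.e. the Pearson
correlation between each gene and the factor scores; the axis is oriented so
that the mean matrix-gene loading is positive, making "negative correlation
with the anabolic axis" reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import GeneSet, log_filter

logger = logging.getLogger("chondrax")


@dataclass(frozen=True)
class AnabolicAxis:
    """Factor 1 of the matrix-gene submatrix.

    ``loadings``: per-matrix-gene correlation with the factor scores.
    ``scores``: per-strain factor score, standardized to mean 0 / variance 1
    (sample variance).  ``variance_explained``: first-eigenvalue share.
    """

    loadings: pd.Series
    scores: pd.Series
    variance_explained: float


# ---------------------------------------------------------------------------
# probe collapse
# ---------------------------------------------------------------------------

def collapse_probes(raw: pd.DataFrame, probes: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe x strain matrix to one row per gene.

    Per gene, the retained probe must not overlap a known SNP, must perfectly
    and uniquely match its target transcript, and among qualifying probes the
    one with the highest mean expression wins.  Genes with no qualifying
    probe are dropped and logged.
    """
    missing = set(raw.index) - set(probes["probe_id"])
    if missing:
        raise ValueError(f"probes absent from annotation table: {sorted(missing)[:5]}")
    ann = probes.set_index("probe_id").loc[list(raw.index)]
    ok = (~ann["snp_overlap"]) & ann["perfect_unique_match"]
    qualified = ann[ok]
    # highest mean expression wins; ties broken by probe_id ascending for determinism
    best = (
        qualified.sort_values(["mean_expression"], ascending=False, kind="mergesort")
        .reset_index()
        .drop_duplicates("gene_symbol", keep="first")
    )
    dropped = set(ann["gene_symbol"]) - set(best["gene_symbol"])
    if dropped:
        logger.info("collapse_probes: %d gene(s) with no qualifying probe dropped", len(dropped))
    panel = raw.loc[best["probe_id"]]
    panel.index = pd.Index(best["gene_symbol"].tolist(), name="gene")
    panel = panel.sort_index()
    log_filter("collapse_probes", len(raw), len(panel))
    return panel


# ---------------------------------------------------------------------------
# correlation and clustering
# ---------------------------------------------------------------------------

def pairwise_correlation(panel: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix between genes across strains.

    Pairwise-complete over missing values; needs at least 3 complete strains
    per pair.  A gene constant across strains has undefined correlations,
    reported as NaN with a warning.  The diagonal is exactly 1 for
    non-degenerate genes.
    """
    sub = panel.loc[genes] if genes is not None else panel
    cm = sub.T.corr(method="pearson", min_periods=3)
    constant = sub.std(axis=1, ddof=1) == 0
    if constant.any():
        logger.warning(
            "constant gene(s) across strains, correlations undefined: %s",
            sorted(sub.index[constant]),
        )
        cm.loc[constant, :] = np.nan
        cm.loc[:, constant] = np.nan
    good = ~constant
    np.fill_diagonal(cm.values, np.where(good, 1.0, np.nan))
    return cm


def uncentered_correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - sum(xy) / sqrt(sum(x^2) sum(y^2)) — cosine distance without centering."""
    return 1.0 - float(np.dot(x, y) / np.sqrt(np.dot(x, x) * np.dot(y, y)))


def cluster_correlation(
    cm: pd.DataFrame, linkage: str = "complete", distance: str = "euclidean"
) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of the rows of a correlation matrix.

    ``distance`` is ``euclidean`` or ``uncentered-correlation`` (the cosine
    distance, as used by the classic Cluster program); ``linkage`` is
    ``complete``.  Returns (leaf order, SciPy linkage matrix).  Leaf order is
    deterministic; it is stable under label permutation up to the mirror
    flips inherent to dendrograms.
    """
    if linkage != "complete":
        raise ValueError(f"unsupported linkage {linkage!r}")
    values = cm.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("correlation matrix contains missing values; drop degenerate genes first")
    if distance == "euclidean":
        d = pdist(values, metric="euclidean")
    elif distance == "uncentered-correlation":
        d = pdist(values, metric="cosine")
    else:
        raise ValueError(f"unsupported distance {distance!r}")
    Z = hierarchy.linkage(d, method="complete")
    leaves = hierarchy.leaves_list(Z)
    return [cm.index[i] for i in leaves], Z


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick tree with merge heights."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def select_intercorrelated(cm: pd.DataFrame, tau: float = 0.5) -> list[str]:
    """Greedy selection of the highly intercorrelated core of a gene list.

    Iteratively drops the gene whose mean pairwise correlation with the other
    retained genes is lowest, until every retained gene's mean correlation is
    at least ``tau`` (or two genes remain).  Ties break to the
    alphabetically first gene; NaN correlations are ignored in the mean.
    Returns retained genes in input order.
    """
    retained = list(cm.index)
    while len(retained) > 2:
        sub = cm.loc[retained, retained].to_numpy(dtype=float)
        np.fill_diagonal(sub, np.nan)
        with np.errstate(all="ignore"):
            means = np.nanmean(sub, axis=1)
        means = np.where(np.isnan(means), -np.inf, means)
        if means.min() >= tau:
            break
        # deterministic worst gene: lowest mean, then alphabetical
        order = sorted(range(len(retained)), key=lambda i: (means[i], retained[i]))
        worst = retained[order[0]]
        retained.remove(worst)
        logger.debug("select_intercorrelated: dropped %s (mean r %.3f < %.3f)",
                     worst, means[order[0]], tau)
    log_filter("select_intercorrelated", len(cm), len(retained), tau)
    return retained


# ---------------------------------------------------------------------------
# factor extraction
# ---------------------------------------------------------------------------

def extract_axis(panel: pd.DataFrame, matrix_genes: list[str]) -> AnabolicAxis:
    """Extract Factor 1 from the standardized matrix-gene submatrix.

    Each matrix gene is z-scored across strains; Factor 1 is the first
    principal component of the strains x genes standardized submatrix
    (equivalently, the leading eigenvector of the gene correlation matrix).
    Strains with any missing matrix-gene value are dropped first.  Scores are
    re-standardized to mean 0 / unit sample variance and the axis is flipped
    if the mean loading is negative.
    """
    if len(matrix_genes) < 2:
        raise ValueError("need at least 2 matrix genes")
    missing = set(matrix_genes) - set(panel.index)
    if missing:
        raise ValueError(f"matrix genes absent from panel: {sorted(missing)}")
    sub = panel.loc[matrix_genes]  # genes x strains
    complete = sub.notna().all(axis=0)
    if (~complete).any():
        logger.info("extract_axis: dropping %d strain(s) with missing matrix-gene values",
                    int((~complete).sum()))
    sub = sub.loc[:, complete]
    n = sub.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 complete strains, have {n}")
    X = sub.T.to_numpy(dtype=float)  # strains x genes
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(matrix_genes, sd) if s == 0]
        raise ValueError(f"matrix gene(s) constant across strains: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    C = (Z.T @ Z) / (n - 1)  # correlation matrix of the genes
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    v1 = eigvecs[:, order[0]]
    raw_scores = Z @ v1
    scores = (raw_scores - raw_scores.mean()) / raw_scores.std(ddof=1)
    # factor-analysis scale: loading_g = corr(x_g, scores) = v1_g * sqrt(eig1) / ...
    loadings = (Z.T @ scores) / (n - 1)
    if loadings.mean() < 0:
        loadings, scores = -loadings, -scores
    return AnabolicAxis(
        loadings=pd.Series(loadings, index=pd.Index(matrix_genes, name="gene")),
        scores=pd.Series(scores, index=sub.columns.rename("strain")),
        variance_explained=float(eigvals[0] / eigvals.sum()),
    )


# ---------------------------------------------------------------------------
# regulator screen
# ---------------------------------------------------------------------------

def correlation_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r with the exact two-sided t-distribution p.

    p is from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, the exact
    null for Pearson r under bivariate normality.
    """
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return np.nan, np.nan, n
    xv, yv = x[mask], y[mask]
    if xv.std() == 0 or yv.std() == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def screen_regulators(
    panel: pd.DataFrame, axis: AnabolicAxis, candidates: list[str]
) -> pd.DataFrame:
    """Correlate candidate regulators with the Factor 1 scores.

    Candidate genes (e.g. the GO-annotated regulator universe, supplied
    externally) are correlated with the per-strain axis scores; the result is
    ranked most-negative first (ties by gene id).  Returns a DataFrame indexed
    by gene with columns ``r``, ``p``, ``n``, ``rank``.
    """
    missing = set(candidates) - set(panel.index)
    if missing:
        raise ValueError(f"candidates absent from panel: {sorted(missing)[:5]}")
    strains = axis.scores.index
    y = axis.scores.to_numpy(dtype=float)
    rows = []
    for gene in candidates:
        x = panel.loc[gene, strains].to_numpy(dtype=float)
        r, p, n = correlation_with_p(x, y)
        rows.append({"gene": gene, "r": r, "p": p, "n": n})
    df = pd.DataFrame(rows).set_index("gene")
    df = df.sort_values(["r", "gene"], ascending=[True, True], kind="mergesort",
                        na_position="last")
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def rank_within_category(
    result: pd.DataFrame, category: GeneSet, gene: str, ordering: str = "absolute"
) -> tuple[int, int]:
    """Rank of a named gene within a gene-set category of the screen result.

    ``ordering='absolute'`` ranks by \\|r\\| descending (default: the strongest
    correlate of either sign is rank 1); ``'signed'`` ranks by r ascending
    (most negative first).  Category members absent from the screen are
    logged and excluded from the denominator.  Returns (rank, category size
    in screen).
    """
    members = sorted(category.members)
    present = [m for m in members if m in result.index]
    absent = set(members) - set(present)
    if absent:
        logger.info("rank_within_category: %d member(s) absent from screen: %s",
                    len(absent), sorted(absent)[:5])
    if gene not in present:
        raise ValueError(f"gene {gene!r} is not a screened member of category {category.name!r}")
    sub = result.loc[present]
    if ordering == "absolute":
        key = sub["r"].abs().rename("key")
        ordered = sub.assign(key=key).reset_index().sort_values(
            ["key", "gene"], ascending=[False, True], kind="mergesort"
        ).set_index("gene")
    elif ordering == "signed":
        ordered = sub.reset_index().sort_values(
            ["r", "gene"], ascending=[True, True], kind="mergesort"
        ).set_index("gene")
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    rank = int(np.nonzero(ordered.index == gene)[0][0]) + 1
    return rank, len(present)
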