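"""Preranked gene-set enrichment from scratch.

The enrichment score (ES) is the signed extremum of the classic weighted
Kolmogorov-Smirnov running sum over a ranked gene list: stepping down the
list, a gene in the set increments the sum by |score|^weight normalized over
the in-list set members, and a gene outside the set decrements it by
1/(N - n_set).  Significance comes from a gene-label permutation null
(the preranked convention): random same-size sets are drawn from the list
and two p-values are reported.  The primary ``p`` is the sign-blind
magnitude comparison, (1 + #{|ES_perm| >= |ES|}) / (1 + n_perm), which is
uniform under the null; ``p_signed`` is the classic sign-stratified nominal
p, (1 + #{same-sign |ES_perm| >= |ES|}) / (1 + #same-sign permutations).
NES = ES / mean(|ES_perm| of matching sign).  The +1 correction bounds both
away from zero at finite permutation counts.

Ranking scores are, in the intended application, shrunken log2 fold changes;
ties are broken by gene id before the walk so results are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet, sort_ranked

logger = logging.getLogger("chondrax")


class DisjointSetError(ValueError):
    """The gene set shares no member with the ranked list (distinct from ES = 0)."""


@dataclass(frozen=True)
class EnrichmentResult:
    """Preranked GSEA output for one gene set."""

    es: float
    nes: float
    p: float         # sign-blind |ES| permutation p (uniform under the null)
    p_signed: float  # sign-stratified nominal p (classic GSEA convention)
    n_perm: int
    n_hits: int
    running_sum: np.ndarray | None = None


def _prepare(ranked: pd.Series, gene_set: GeneSet, weight: float):
    ranked = sort_ranked(ranked)
    genes = ranked.index.to_numpy()
    in_set = np.isin(genes, list(gene_set.members))
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise DisjointSetError(
            f"gene set {gene_set.name!r} shares no member with the ranked list"
        )
    scores = ranked.to_numpy(dtype=float)
    abs_w = np.abs(scores) ** weight if weight != 0 else np.ones_like(scores)
    return ranked, in_set, n_hits, abs_w


def _es_from_hits(hit_pos: np.ndarray, hit_weights: np.ndarray, n_total: int):
    """ES from sorted 0-based hit positions; O(n_hits) per evaluation.

    The running sum is piecewise linear between hits, so its extrema occur
    immediately before or at hit positions; both are enumerated in walk order
    and the value of largest magnitude (earliest on ties) is the ES.
    """
    n = hit_pos.size
    if n == n_total:
        # degenerate: no miss steps, the sum climbs monotonically to 1
        return 1.0
    total = hit_weights.sum()
    if total <= 0:
        # all-zero scores with positive weight: fall back to equal increments
        hit_weights = np.ones(n)
        total = float(n)
    cum = np.cumsum(hit_weights) / total
    miss = 1.0 / (n_total - n)
    i = np.arange(n)
    after = cum - miss * (hit_pos + 1 - (i + 1))      # value at each hit
    before = np.concatenate(([0.0], cum[:-1])) - miss * (hit_pos - i)  # just before
    walk = np.empty(2 * n)
    walk[0::2] = before
    walk[1::2] = after
    return float(walk[np.argmax(np.abs(walk))])


def enrichment_score(
    ranked: pd.Series,
    gene_set: GeneSet,
    weight: float = 1.0,
    return_running_sum: bool = False,
) -> tuple[float, np.ndarray | None]:
    """Weighted KS enrichment score of a gene set in a ranked list.

    Returns (es, running_sum); the trace is the dense per-position running
    sum, computed only on request.
    """
    ranked, in_set, n_hits, abs_w = _prepare(ranked, gene_set, weight)
    N = len(ranked)
    if n_hits >= N:
        logger.warning("gene set covers the whole ranked list; ES degenerates to 1")
    hit_pos = np.nonzero(in_set)[0]
    es = _es_from_hits(hit_pos, abs_w[hit_pos], N)
    trace = None
    if return_running_sum:
        steps = np.full(N, 0.0 if n_hits == N else -1.0 / (N - n_hits))
        hw = abs_w[hit_pos]
        total = hw.sum()
        if total <= 0:
            hw = np.ones(n_hits)
            total = float(n_hits)
        steps[hit_pos] = hw / total
        trace = np.cumsum(steps)
    return es, trace


def permutation_p(
    ranked: pd.Series,
    gene_set: GeneSet,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Gene-label permutation test for preranked enrichment.

    Draws ``n_perm`` random same-size gene sets from the list and compares
    their ES magnitudes with the observed one: sign-blind for the primary
    ``p`` and within the same-sign stratum for ``p_signed``.  NES is the
    observed ES over the mean same-sign null |ES|.  Deterministic given
    ``seed`` (or an explicit ``rng``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    ranked, in_set, n_hits, abs_w = _prepare(ranked, gene_set, weight)
    N = len(ranked)
    if n_hits >= N:
        raise ValueError("gene set must be smaller than the ranked list for a permutation null")
    hit_pos = np.nonzero(in_set)[0]
    es = _es_from_hits(hit_pos, abs_w[hit_pos], N)

    es_perm = np.empty(n_perm)
    for k in range(n_perm):
        pos = np.sort(rng.choice(N, size=n_hits, replace=False))
        es_perm[k] = _es_from_hits(pos, abs_w[pos], N)

    same_sign = np.sign(es_perm) == np.sign(es) if es != 0 else np.ones(n_perm, bool)
    matched = same_sign & (np.abs(es_perm) >= abs(es))
    p = (1 + int((np.abs(es_perm) >= abs(es)).sum())) / (1 + n_perm)
    p_signed = (1 + int(matched.sum())) / (1 + int(same_sign.sum()))
    same_sign_mag = np.abs(es_perm[same_sign])
    if same_sign_mag.size:
        nes = es / same_sign_mag.mean()
    else:
        logger.warning("no same-sign permutation ES; NES undefined")
        nes = float("nan")
    return EnrichmentResult(
        es=es, nes=float(nes), p=p, p_signed=p_signed, n_perm=n_perm, n_hits=n_hits
    )


def gsea_preranked(
    ranked: pd.Series,
    gene_sets: list[GeneSet],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Run the permutation test for several sets; optional BH correction across sets."""
    rng = np.random.default_rng(seed)
    rows = []
    for gs in gene_sets:
        res = permutation_p(ranked, gs, weight=weight, n_perm=n_perm, rng=rng)
        rows.append({"set": gs.name, "size": res.n_hits, "es": res.es, "nes": res.nes,
                     "p": res.p, "p_signed": res.p_signed})
    df = pd.DataFrame(rows).set_index("set")
    if adjust and len(df):
        df["q"] = _benjamini_hochberg(df["p"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked_p = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked_p[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# target-set fold-change comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Welch t comparison of log2 fold changes between target and other genes."""

    mean_targets: float
    mean_others: float
    difference: float
    t: float
    p: float
    n_targets: int
    n_others: int
    box_targets: dict
    box_others: dict


def _box_stats(x: np.ndarray) -> dict:
    """Quartiles plus whiskers at 1.5 x IQR clipped to the data range."""
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo = float(x[x >= q1 - 1.5 * iqr].min())
    hi = float(x[x <= q3 + 1.5 * iqr].max())
    return {"q1": float(q1), "median": float(med), "q3": float(q3),
            "whisker_low": lo, "whisker_high": hi}


def compare_target_foldchanges(de: pd.DataFrame, targets: GeneSet) -> GroupComparison:
    """Welch two-sample t test of log2FC for target-set genes vs all others."""
    in_set = de.index.isin(list(targets.members))
    a = de.loc[in_set, "log2fc"].to_numpy(dtype=float)
    b = de.loc[~in_set, "log2fc"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 genes per group")
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.isclose(a.mean(), b.mean()):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        mean_targets=float(a.mean()),
        mean_others=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        t=float(t),
        p=float(p),
        n_targets=len(a),
        n_others=len(b),
        box_targets=_box_stats(a),
        box_others=_box_stats(b),
    )
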