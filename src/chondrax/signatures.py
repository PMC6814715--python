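"""Gene-signature construction from differential-expression tables.

Each builder applies the literal filter stated in the study design, with
strict inequalities throughout and a consistent direction convention:
positive log2 fold change means higher in the first-named condition.

- Cartilage signature: linear fold change > 5 (upregulated) with FDR
  q < 1e-5 in *both* chondrocyte-vs-fibroblast contrasts.
- Osteoarthritis signatures: |fold change| > 2 with q < 1e-5 in damaged vs
  intact cartilage, split by direction and mapped to mouse symbols through a
  supplied ortholog table.
- SOX9 targets: log2 fold change < -2 after Sox9 deletion AND an associated
  ChIP-seq peak (peak calls are an input).
- DEGs: |fold change| > 3 with q < 1e-5, per contrast, split by direction.

Every returned :class:`~chondrax.io.GeneSet` carries a provenance string
sufficient to regenerate the set bit-exactly from the same inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneSet, log_filter

logger = logging.getLogger("chondrax")


def _check_fc(fc_min: float) -> None:
    if fc_min <= 0:
        raise ValueError(f"fold-change threshold must be positive, got {fc_min}")


def build_two_contrast_signature(
    deA: pd.DataFrame,
    deB: pd.DataFrame,
    fc_min: float = 5.0,
    q_max: float = 1e-5,
    up_only: bool = True,
    name: str = "cartilage_signature",
) -> GeneSet:
    """Genes passing fold change > fc_min and q < q_max in both contrasts.

    With ``up_only`` (the default) only upregulation counts — the signature
    is genes higher in chondrocytes than fibroblasts in both comparisons;
    set it False to accept |fold change| > fc_min in a shared direction.
    """
    _check_fc(fc_min)
    lfc_min = math.log2(fc_min)
    shared = deA.index.intersection(deB.index)
    a, b = deA.loc[shared], deB.loc[shared]
    if up_only:
        ok = (a["log2fc"] > lfc_min) & (b["log2fc"] > lfc_min)
    else:
        ok = (
            (a["log2fc"].abs() > lfc_min)
            & (b["log2fc"].abs() > lfc_min)
            & (np.sign(a["log2fc"]) == np.sign(b["log2fc"]))
        )
    ok &= (a["q"] < q_max) & (b["q"] < q_max)
    members = frozenset(shared[ok])
    log_filter("two_contrast_signature", len(shared), len(members), (fc_min, q_max))
    return GeneSet(
        name=name,
        members=members,
        description=f"FC>{fc_min} ({'up only' if up_only else 'shared direction'}), "
                    f"q<{q_max} in both contrasts",
    )


def build_oa_sets(
    de: pd.DataFrame,
    fc_min: float = 2.0,
    q_max: float = 1e-5,
    ortholog_map: Mapping[str, str] | None = None,
    name_prefix: str = "oa_signature",
) -> tuple[GeneSet, GeneSet]:
    """Up- and down-regulated signatures from a damaged-vs-intact DE table.

    Genes with |fold change| > fc_min and q < q_max are split on the sign of
    the log2 fold change, then passed through the ortholog map (e.g.
    human -> mouse); unmapped symbols are dropped with a logged count.
    """
    _check_fc(fc_min)
    lfc_min = math.log2(fc_min)
    sig = de[(de["log2fc"].abs() > lfc_min) & (de["q"] < q_max)]
    up = list(sig.index[sig["log2fc"] > 0])
    down = list(sig.index[sig["log2fc"] < 0])

    def _map(symbols: list[str]) -> frozenset[str]:
        if ortholog_map is None:
            return frozenset(symbols)
        mapped = [ortholog_map[s] for s in symbols if s in ortholog_map]
        n_unmapped = len(symbols) - len(mapped)
        if n_unmapped:
            logger.info("build_oa_sets: %d symbol(s) without ortholog dropped", n_unmapped)
        return frozenset(mapped)

    desc = f"|FC|>{fc_min}, q<{q_max}, damaged vs intact"
    up_set = GeneSet(f"{name_prefix}_up", _map(up), desc + ", upregulated")
    down_set = GeneSet(f"{name_prefix}_down", _map(down), desc + ", downregulated")
    log_filter("oa_sets", len(de), len(up_set) + len(down_set), (fc_min, q_max))
    return up_set, down_set


def build_sox9_targets(
    de: pd.DataFrame,
    peak_flags: Mapping[str, bool] | pd.Series,
    log2fc_max: float = -2.0,
    name: str = "sox9_targets",
) -> GeneSet:
    """Genes strongly downregulated after Sox9 deletion and ChIP-peak associated.

    Membership requires log2 fold change strictly below ``log2fc_max`` (the
    stated rule is on the log2 scale) AND a true peak flag.
    """
    flags = pd.Series(peak_flags).astype(bool)
    ok = de["log2fc"] < log2fc_max
    with_peak = [g for g in de.index[ok] if bool(flags.get(g, False))]
    log_filter("sox9_targets", len(de), len(with_peak), log2fc_max)
    return GeneSet(
        name=name,
        members=frozenset(with_peak),
        description=f"log2FC<{log2fc_max} after Sox9 deletion, with ChIP-seq peak",
    )


def select_degs(
    de: pd.DataFrame, fc_min: float = 3.0, q_max: float = 1e-5
) -> tuple[list[str], list[str]]:
    """Differentially expressed genes: |fold change| > fc_min and q < q_max.

    Strict inequalities; the linear-scale reading of "fold change".  Returns
    (upregulated, downregulated) gene lists, each sorted.
    """
    _check_fc(fc_min)
    lfc_min = math.log2(fc_min)
    sig = de[(de["log2fc"].abs() > lfc_min) & (de["q"] < q_max)]
    up = sorted(sig.index[sig["log2fc"] > 0])
    down = sorted(sig.index[sig["log2fc"] < 0])
    log_filter("select_degs", len(de), len(up) + len(down), (fc_min, q_max))
    return up, down


@dataclass(frozen=True)
class ConsistencyPartition:
    """Three-way DEG consistency: genes moving the same way in every contrast."""

    consistent: frozenset[str]
    inconsistent: frozenset[str]
    fraction: float

    @property
    def percent(self) -> float:
        """Consistent share of the DEG union, as a percentage to two decimals."""
        return round(100.0 * self.fraction, 2)


def consistent_deg_partition(
    deg_lists: Sequence[tuple[list[str], list[str]]],
) -> ConsistencyPartition:
    """Partition the DEG union of several contrasts by direction consistency.

    A gene is consistent iff it is a DEG in *all* contrasts and always with
    the same direction; every other gene of the union is inconsistent.
    ``fraction`` = |consistent| / |union|.
    """
    if not deg_lists:
        raise ValueError("need at least one (up, down) DEG pair")
    ups = [set(u) for u, _ in deg_lists]
    downs = [set(d) for _, d in deg_lists]
    for i, (u, d) in enumerate(zip(ups, downs)):
        overlap = u & d
        if overlap:
            raise ValueError(f"contrast {i}: gene(s) both up and down: {sorted(overlap)[:5]}")
    union = set().union(*ups, *downs)
    all_up = set.intersection(*ups) if ups else set()
    all_down = set.intersection(*downs) if downs else set()
    consistent = all_up | all_down
    fraction = len(consistent) / len(union) if union else float("nan")
    return ConsistencyPartition(
        consistent=frozenset(consistent),
        inconsistent=frozenset(union - consistent),
        fraction=fraction,
    )
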