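"""Tankyrase substrate nomination: PSSM scoring and the candidate funnel.

Tankyrase recognizes substrates through an eight-residue binding motif.  Each
octapeptide window of a protein is scored against an 8 x 20 position-specific
scoring matrix (PSSM) and normalized into a tankyrase-targeting score (TTS):

    TTS(peptide) = sum_pos PSSM[pos, residue_pos] / sum_pos max_res PSSM[pos, res]

so the per-position-argmax peptide scores exactly 1.  The screening cutoff in
the study design is 0.385, the TTS of the mouse AXIN1/AXIN2 binding motifs
(the weakest-scoring of the well-established substrates).

The nomination funnel then runs, in order: co-IP mass-spectrometry hit
filtering (replication and IgG-control rules), max-TTS thresholding, pathway
membership (e.g. an externally supplied chondrogenesis protein list), and
intrinsic-disorder annotation of the surviving motifs.  Every stage logs its
input and output counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, GeneSet, log_filter

logger = logging.getLogger("chondrax")

MOTIF_LENGTH = 8

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class PSSM:
    """An 8-position x 20-amino-acid scoring matrix.

    Rows are motif positions 1..8; columns follow the canonical alphabetical
    residue order of :data:`chondrax.io.AMINO_ACIDS`.  Entries may be negative
    (the published matrix's sign conventions are external); the only structural
    requirement is that the maximal achievable raw score is positive so the
    TTS normalization is well defined.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.shape != (MOTIF_LENGTH, 20):
            raise ValueError(f"PSSM must be {MOTIF_LENGTH}x20, got {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("PSSM entries must be finite")
        if arr.max(axis=1).sum() <= 0:
            raise ValueError("sum of per-position maxima must be positive")
        arr.setflags(write=False)
        object.__setattr__(self, "scores", arr)

    @property
    def position_maxima(self) -> np.ndarray:
        return self.scores.max(axis=1)

    @property
    def max_raw(self) -> float:
        """The raw score of the best achievable octapeptide (TTS denominator)."""
        return float(self.position_maxima.sum())

    @property
    def min_raw(self) -> float:
        return float(self.scores.min(axis=1).sum())

    def residue_indices(self, peptide: str) -> np.ndarray:
        if len(peptide) != MOTIF_LENGTH:
            raise ValueError(f"peptide must have length {MOTIF_LENGTH}, got {len(peptide)!r}")
        try:
            return np.array([_AA_INDEX[aa] for aa in peptide.upper()])
        except KeyError as exc:
            raise ValueError(f"non-standard residue {exc.args[0]!r} in peptide {peptide!r}") from None

    def raw_score(self, peptide: str) -> float:
        idx = self.residue_indices(peptide)
        return float(self.scores[np.arange(MOTIF_LENGTH), idx].sum())

    def argmax_peptide(self) -> str:
        """The per-position argmax octapeptide (ties to the alphabetically first residue)."""
        return "".join(AMINO_ACIDS[i] for i in self.scores.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    """One octapeptide window with its TTS and (optional) disorder annotation."""

    protein_id: str
    start: int  # 1-based
    peptide: str
    tts: float
    disorder: float | None = None


def tts(peptide: str, pssm: PSSM) -> float:
    """Tankyrase-targeting score of an 8-mer: raw PSSM sum over the maximal one.

    Lies in [0, 1] for non-negative matrices; may be negative for matrices
    with negative entries, in which case the raw value is reported unclipped.
    """
    return pssm.raw_score(peptide) / pssm.max_raw


def scan_protein(protein_id: str, sequence: str, pssm: PSSM) -> tuple[list[MotifHit], float]:
    """Score every length-8 sliding window of a protein.

    Windows containing residues outside the 20-letter standard alphabet
    (X, U, B, Z, ...) are skipped and counted rather than invalidating the
    whole protein.  Returns (hits, max_tts); max_tts is 0.0 when no window
    is valid.
    """
    sequence = sequence.upper()
    L = len(sequence)
    hits: list[MotifHit] = []
    n_skipped = 0
    denom = pssm.max_raw
    # positions of standard residues; a window is valid iff all 8 are standard
    valid = np.array([aa in _AA_INDEX for aa in sequence], dtype=bool)
    for start0 in range(L - MOTIF_LENGTH + 1):
        if not valid[start0 : start0 + MOTIF_LENGTH].all():
            n_skipped += 1
            continue
        pep = sequence[start0 : start0 + MOTIF_LENGTH]
        hits.append(MotifHit(protein_id, start0 + 1, pep, pssm.raw_score(pep) / denom))
    if n_skipped:
        logger.debug("%s: skipped %d windows with non-standard residues", protein_id, n_skipped)
    max_tts = max((h.tts for h in hits), default=0.0)
    return hits, max_tts


def derive_cutoff(reference_peptides: Sequence[str], pssm: PSSM) -> float:
    """TTS cutoff from reference substrate motifs (e.g. mouse AXIN1/AXIN2 TBDs).

    If the reference peptides do not share one TTS the minimum is used, with a
    warning — the conservative choice that keeps all references above cutoff.
    """
    if not reference_peptides:
        raise ValueError("need at least one reference peptide")
    scores = [tts(p, pssm) for p in reference_peptides]
    if max(scores) - min(scores) > 1e-9:
        logger.warning(
            "reference peptides disagree on TTS (%s); using the minimum",
            ", ".join(f"{s:.3f}" for s in scores),
        )
    return min(scores)


# ---------------------------------------------------------------------------
# mass-spectrometry hit filtering
# ---------------------------------------------------------------------------

def filter_ms_hits(table: pd.DataFrame, min_count: int = 2, min_replicates: int = 2) -> set[str]:
    """Apply the co-IP replication and control rules to an MS hit table.

    A protein is excluded outright if it appears in any IgG-control row.
    Within each biological replicate a protein counts as detected only when
    its spectral count is at least ``min_count`` (within-replicate singletons
    are noise); proteins detected in at least ``min_replicates`` biological
    replicates are retained.
    """
    if table.empty:
        return set()
    proteins = set(table["protein_id"].str.upper())
    igg = set(table.loc[table["igg_control"], "protein_id"].str.upper())
    experimental = table[~table["igg_control"]]
    detected = experimental[experimental["spectral_count"] >= min_count]
    reps = detected.assign(protein_id=detected["protein_id"].str.upper()).groupby(
        "protein_id"
    )["replicate_id"].nunique()
    retained = set(reps.index[reps >= min_replicates]) - igg
    log_filter("ms_hits", len(proteins), len(retained),
               {"min_count": min_count, "min_replicates": min_replicates})
    return retained


# ---------------------------------------------------------------------------
# disorder annotation
# ---------------------------------------------------------------------------

_DISORDER_AGG = {"mean": np.mean, "min": np.min, "max": np.max}


def annotate_disorder(
    hits: Iterable[MotifHit],
    profile: Mapping[str, np.ndarray],
    tts_cutoff: float,
    agg: str = "mean",
) -> list[MotifHit]:
    """Fill per-hit disorder from per-residue profiles for hits at/above cutoff.

    The disorder of a motif is the arithmetic mean (configurable: min/max) of
    the eight per-residue scores.  Hits below the TTS cutoff keep ``None``.
    Missing residue coverage is an error naming the protein and positions.
    """
    if agg not in _DISORDER_AGG:
        raise ValueError(f"unknown disorder aggregation {agg!r}")
    fn = _DISORDER_AGG[agg]
    out: list[MotifHit] = []
    for hit in hits:
        if hit.tts < tts_cutoff:
            out.append(hit)
            continue
        arr = np.asarray(profile.get(hit.protein_id, ()), dtype=float)
        lo, hi = hit.start - 1, hit.start - 1 + MOTIF_LENGTH
        window = arr[lo:hi] if arr.size >= hi else np.array([])
        if window.size < MOTIF_LENGTH or not np.isfinite(window).all():
            raise ValueError(
                f"disorder profile for {hit.protein_id} does not cover residues "
                f"{hit.start}..{hit.start + MOTIF_LENGTH - 1}"
            )
        out.append(replace(hit, disorder=float(fn(window))))
    return out


# ---------------------------------------------------------------------------
# the nomination funnel
# ---------------------------------------------------------------------------

def prioritize_candidates(
    sequences: Mapping[str, str],
    pssm: PSSM,
    pathway: GeneSet,
    tts_cutoff: float,
    ms_table: pd.DataFrame,
    disorder_profiles: Mapping[str, np.ndarray] | None = None,
    disorder_agg: str = "mean",
    disorder_min: float | None = None,
    min_count: int = 2,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Run the substrate-nomination funnel over a co-IP proteome.

    Stages, in order: MS replication/control filter -> motif scan with
    max-TTS >= cutoff -> pathway membership -> disorder annotation of
    passing motifs.  Identifiers are joined on upper-cased symbols.
    ``disorder_min`` is annotation-only by default (None); when set, a
    passing protein must additionally carry at least one above-cutoff motif
    with disorder >= disorder_min.

    Returns one row per protein in the MS table with columns
    ``ms_retained, n_replicates, n_windows, max_tts, in_pathway, passes``
    plus a ``hits`` column carrying the annotated :class:`MotifHit` list.
    """
    retained = filter_ms_hits(ms_table, min_count=min_count, min_replicates=min_replicates)
    seq_by_id = {pid.upper(): seq for pid, seq in sequences.items()}
    if disorder_profiles is not None:
        disorder_profiles = {pid.upper(): prof for pid, prof in disorder_profiles.items()}
    pathway_ids = {m.upper() for m in pathway.members}
    experimental = ms_table[~ms_table["igg_control"]]
    n_reps = (
        experimental[experimental["spectral_count"] >= min_count]
        .assign(protein_id=lambda d: d["protein_id"].str.upper())
        .groupby("protein_id")["replicate_id"]
        .nunique()
    )

    rows = []
    all_proteins = sorted({p.upper() for p in ms_table["protein_id"]})
    for pid in all_proteins:
        ms_ok = pid in retained
        seq = seq_by_id.get(pid)
        if ms_ok and seq is None:
            logger.warning("no sequence for MS-retained protein %s; max_tts set to 0", pid)
        hits: list[MotifHit] = []
        max_tts = 0.0
        n_windows = 0
        if seq is not None:
            hits, max_tts = scan_protein(pid, seq, pssm)
            n_windows = len(hits)
        in_pathway = pid in pathway_ids
        passes = ms_ok and n_windows >= 1 and max_tts >= tts_cutoff and in_pathway
        if passes and disorder_profiles is not None:
            hits = annotate_disorder(hits, disorder_profiles, tts_cutoff, agg=disorder_agg)
            if disorder_min is not None:
                passes = any(h.disorder is not None and h.disorder >= disorder_min
                             for h in hits)
        rows.append(
            {
                "protein_id": pid,
                "ms_retained": ms_ok,
                "n_replicates": int(n_reps.get(pid, 0)),
                "n_windows": n_windows,
                "max_tts": max_tts,
                "in_pathway": in_pathway,
                "passes": passes,
                "hits": hits,
            }
        )
    out = pd.DataFrame(rows).set_index("protein_id")
    n_ms = int(out["ms_retained"].sum())
    n_tts = int((out["ms_retained"] & (out["n_windows"] >= 1) & (out["max_tts"] >= tts_cutoff)).sum())
    log_filter("funnel/ms", len(out), n_ms)
    log_filter("funnel/tts", n_ms, n_tts, tts_cutoff)
    log_filter("funnel/pathway", n_tts, int(out["passes"].sum()))
    return out


def histogram_max_tts(candidates: pd.DataFrame, bin_width: float = 0.1) -> pd.DataFrame:
    """Fixed-width histogram of per-protein max TTS over [0, 1].

    Bins are right-open except the last, which includes 1.0; counts sum to the
    number of proteins (values outside [0, 1] are clipped into the end bins,
    which only occurs for matrices with negative entries).
    """
    if bin_width <= 0 or bin_width > 1:
        raise ValueError("bin_width must lie in (0, 1]")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    vals = np.clip(candidates["max_tts"].to_numpy(dtype=float), 0.0, 1.0)
    idx = np.minimum(np.searchsorted(edges, vals, side="right") - 1, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
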