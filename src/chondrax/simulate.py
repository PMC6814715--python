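"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Every generator is a pure function of its spec and seed; a single global seed
fans out to per-generator streams through numpy's ``SeedSequence`` spawn keys
(a fixed integer per generator), so adding a generator never perturbs the
draws of another.  Ground truth is always returned alongside the synthetic
input, so downstream checks consume only (input, truth) pairs.

The expression panel follows a single-factor linear-Gaussian model,

    x_{g,s} = mu_g + lambda_g * f_s + eps_{g,s},
    f_s ~ N(0, 1),  eps ~ N(0, sigma^2),

the minimal model under which extracting "Factor 1" by PCA is consistent:
cartilage matrix genes load positively, planted regulators load with their
stated sign, and background genes load zero.  Default dimensions match the
emulated reference-population panel: 16 strains, 14 positively loading
matrix genes, one strongly negative regulator, sigma = 0.3 (a realistic
noise share against unit factor variance for log-intensity microarray data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, GeneSet
from .motif import MOTIF_LENGTH, PSSM, tts

logger = logging.getLogger("chondrax")

#: Spawn-key per generator; append-only so streams stay stable.
_STREAMS = {
    "panel": 0,
    "pssm": 1,
    "proteins": 2,
    "ms_hits": 3,
    "de_tables": 4,
    "ranked_list": 5,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named stream of a global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# expression panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelSpec:
    """Specification of a strains x genes single-factor expression panel."""

    n_strains: int = 16
    n_genes: int = 500
    matrix_genes: tuple[str, ...] = tuple(f"Matg{i:02d}" for i in range(1, 15))
    matrix_loading: float = 1.0
    regulators: tuple[tuple[str, float], ...] = (("Regneg", -0.8),)
    baseline: float = 8.0
    sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_strains < 3:
            raise ValueError("need at least 3 strains for a meaningful correlation screen")
        reg_names = {g for g, _ in self.regulators}
        if reg_names & set(self.matrix_genes):
            raise ValueError("matrix genes and regulators must be disjoint")
        n_special = len(self.matrix_genes) + len(self.regulators)
        if self.n_genes < n_special:
            raise ValueError("n_genes smaller than the number of planted genes")


def simulate_panel(spec: PanelSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a genes x strains log-expression panel from the factor model.

    Returns (panel, truth) where truth holds the latent per-strain factor
    ``f`` and the per-gene loading ``lambda`` as pandas Series.
    """
    rng = stream_rng(spec.seed, "panel")
    strains = [f"BXD{i + 1:02d}" for i in range(spec.n_strains)]
    reg_names = [g for g, _ in spec.regulators]
    n_bg = spec.n_genes - len(spec.matrix_genes) - len(reg_names)
    background = [f"Gene{i:04d}" for i in range(1, n_bg + 1)]
    genes = list(spec.matrix_genes) + reg_names + background

    lam = np.zeros(len(genes))
    lam[: len(spec.matrix_genes)] = spec.matrix_loading
    lam[len(spec.matrix_genes) : len(spec.matrix_genes) + len(reg_names)] = [
        l for _, l in spec.regulators
    ]
    f = rng.standard_normal(spec.n_strains)
    eps = rng.normal(0.0, spec.sigma, size=(len(genes), spec.n_strains))
    values = spec.baseline + lam[:, None] * f[None, :] + eps
    panel = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=strains)
    truth = {
        "f": pd.Series(f, index=pd.Index(strains, name="strain")),
        "lambda": pd.Series(lam, index=panel.index),
    }
    return panel, truth


def simulate_panel_noiseless(spec: PanelSpec) -> tuple[pd.DataFrame, dict]:
    """The sigma -> 0 limit of :func:`simulate_panel` (exact, no noise draw)."""
    panel, truth = simulate_panel(spec)
    values = spec.baseline + truth["lambda"].to_numpy()[:, None] * truth["f"].to_numpy()[None, :]
    return pd.DataFrame(values, index=panel.index, columns=panel.columns), truth


# ---------------------------------------------------------------------------
# PSSM and proteins
# ---------------------------------------------------------------------------

def simulate_pssm(seed: int = 0) -> PSSM:
    """A random non-negative 8 x 20 scoring matrix with fine score granularity."""
    rng = stream_rng(seed, "pssm")
    return PSSM(rng.uniform(0.0, 1.0, size=(MOTIF_LENGTH, 20)))


@dataclass(frozen=True)
class MotifPlantSpec:
    """Proteins of uniform-random residues with motifs planted at target TTS levels."""

    n_proteins: int = 50
    protein_length: int = 300
    planted: tuple[tuple[str, int, float], ...] = ()  # (protein id, 1-based start, level)
    seed: int = 0

    def __post_init__(self) -> None:
        for pid, pos, level in self.planted:
            if not 1 <= pos <= self.protein_length - MOTIF_LENGTH + 1:
                raise ValueError(
                    f"planted motif for {pid} at {pos} exceeds protein length "
                    f"{self.protein_length}"
                )


def construct_peptide(pssm: PSSM, target: float, tol: float = 0.02) -> str:
    """Build an octapeptide whose TTS is within ``tol`` of ``target``.

    Greedy descent from the per-position-argmax peptide: at each step the
    single-residue substitution that brings the TTS closest to the target is
    taken, as long as it improves.  Deterministic, and guaranteed to
    terminate because the absolute error strictly decreases.
    """
    min_tts = pssm.min_raw / pssm.max_raw
    if target > 1.0 + 1e-12 or target < min_tts - tol:
        raise ValueError(
            f"target TTS {target} unreachable (achievable range [{min_tts:.3f}, 1.0])"
        )
    peptide = list(pssm.argmax_peptide())
    idx = pssm.residue_indices("".join(peptide))
    raw = float(pssm.scores[np.arange(MOTIF_LENGTH), idx].sum())
    denom = pssm.max_raw
    err = abs(raw / denom - target)
    for _ in range(500):
        if err <= tol:
            break
        best = None
        for pos in range(MOTIF_LENGTH):
            deltas = pssm.scores[pos] - pssm.scores[pos, idx[pos]]
            cand_err = np.abs((raw + deltas) / denom - target)
            j = int(np.argmin(cand_err))
            if best is None or cand_err[j] < best[0]:
                best = (float(cand_err[j]), pos, j)
        if best is None or best[0] >= err:
            break
        err, pos, j = best
        raw += float(pssm.scores[pos, j] - pssm.scores[pos, idx[pos]])
        idx[pos] = j
        peptide[pos] = AMINO_ACIDS[j]
    if err > tol:
        raise ValueError(f"could not reach target TTS {target} within ±{tol}")
    return "".join(peptide)


def simulate_proteins(
    spec: MotifPlantSpec, pssm: PSSM, tol: float = 0.02
) -> tuple[dict[str, str], pd.DataFrame]:
    """Uniform-random protein sequences with planted high-scoring octapeptides.

    Returns ({protein id: sequence}, truth table of planted (protein_id,
    start, peptide, tts) rows with the achieved TTS).
    """
    rng = stream_rng(spec.seed, "proteins")
    ids = [f"Prot{i:03d}" for i in range(1, spec.n_proteins + 1)]
    aa = np.array(list(AMINO_ACIDS))
    sequences = {
        pid: "".join(rng.choice(aa, size=spec.protein_length)) for pid in ids
    }
    truth_rows = []
    for pid, start, level in spec.planted:
        if pid not in sequences:
            raise ValueError(f"planted protein {pid!r} not among generated ids")
        pep = construct_peptide(pssm, level, tol=tol)
        seq = sequences[pid]
        sequences[pid] = seq[: start - 1] + pep + seq[start - 1 + MOTIF_LENGTH :]
        truth_rows.append(
            {"protein_id": pid, "start": start, "peptide": pep, "tts": tts(pep, pssm)}
        )
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "start", "peptide", "tts"])
    return sequences, truth


# ---------------------------------------------------------------------------
# mass-spectrometry hit tables
# ---------------------------------------------------------------------------

def simulate_ms_hits(
    n_true: int,
    n_noise: int,
    n_replicates: int = 3,
    igg_fraction_noise: float = 0.2,
    igg_fraction_true: float = 0.0,
    seed: int = 0,
    true_ids: Sequence[str] | None = None,
    noise_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Co-IP hit table with planted true interactors and structured noise.

    True interactors get spectral counts >= 2 in at least two biological
    replicates.  Noise proteins get within-replicate singleton counts or
    presence in a single replicate only, so the replication filter removes
    them; a configurable fraction of each class is additionally marked
    present in the IgG control.  Truth labels are the true interactors *not*
    marked IgG-positive (an IgG-contaminated true interactor is, by the
    stated rules, correctly excluded).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 biological replicates")
    rng = stream_rng(seed, "ms_hits")
    reps = [f"BR{i + 1}" for i in range(n_replicates)]
    if true_ids is None:
        true_ids = [f"True{i:03d}" for i in range(1, n_true + 1)]
    if noise_ids is None:
        noise_ids = [f"Noise{i:03d}" for i in range(1, n_noise + 1)]
    rows = []
    igg_true = set()
    for pid in true_ids:
        n_det = int(rng.integers(2, n_replicates + 1))
        which = rng.choice(n_replicates, size=n_det, replace=False)
        for r in which:
            rows.append((pid, reps[r], int(rng.integers(2, 12)), False))
        if rng.random() < igg_fraction_true:
            igg_true.add(pid)
            rows.append((pid, "IgG", int(rng.integers(1, 5)), True))
    for pid in noise_ids:
        if rng.random() < 0.5:  # within-replicate singletons, possibly many replicates
            n_det = int(rng.integers(1, n_replicates + 1))
            which = rng.choice(n_replicates, size=n_det, replace=False)
            for r in which:
                rows.append((pid, reps[r], 1, False))
        else:  # real counts but in a single replicate only
            r = int(rng.integers(0, n_replicates))
            rows.append((pid, reps[r], int(rng.integers(2, 8)), False))
        if rng.random() < igg_fraction_noise:
            rows.append((pid, "IgG", int(rng.integers(1, 5)), True))
    table = pd.DataFrame(
        rows, columns=["protein_id", "replicate_id", "spectral_count", "igg_control"]
    )
    truth = {p.upper() for p in true_ids} - {p.upper() for p in igg_true}
    return table, truth


# ---------------------------------------------------------------------------
# differential-expression tables and ranked lists
# ---------------------------------------------------------------------------

def simulate_de_tables(
    n_genes: int = 1000,
    n_signature: int = 20,
    n_tables: int = 2,
    fold_change: float = 10.0,
    q_signature: float = 1e-8,
    background_lfc_sd: float = 0.5,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], list[str]]:
    """DE tables with planted signature genes beyond stated thresholds.

    Planted genes receive log2 fold changes at (or jittered above) the target
    fold change with q at ``q_signature`` scale; background genes get mild
    null fold changes and uniform q.  Returns (tables, planted gene list).
    """
    if n_signature > n_genes:
        raise ValueError("more signature genes than genes")
    rng = stream_rng(seed, "de_tables")
    genes = [f"Gene{i:04d}" for i in range(1, n_genes + 1)]
    planted = genes[:n_signature]
    tables = []
    lfc_target = np.log2(fold_change)
    for _ in range(n_tables):
        lfc = rng.normal(0.0, background_lfc_sd, size=n_genes)
        q = rng.uniform(0.0, 1.0, size=n_genes)
        lfc[:n_signature] = lfc_target + np.abs(rng.normal(0.0, 0.2, size=n_signature))
        q[:n_signature] = q_signature * rng.uniform(0.1, 1.0, size=n_signature)
        tables.append(
            pd.DataFrame({"log2fc": lfc, "q": q}, index=pd.Index(genes, name="gene"))
        )
    return tables, planted


def simulate_ranked_list(
    n_genes: int = 1000,
    set_size: int = 50,
    delta: float = 1.0,
    seed: int = 0,
    set_name: str = "planted_set",
) -> tuple[pd.Series, GeneSet]:
    """Ranked list with a planted enriched set.

    Background scores are N(0, 1); the ``set_size`` planted members get a
    mean shift ``delta`` (delta = 0 gives an exact null for calibration).
    Returns (descending ranked Series, planted GeneSet).
    """
    if set_size >= n_genes:
        raise ValueError("set must be smaller than the list")
    rng = stream_rng(seed, "ranked_list")
    genes = [f"Gene{i:04d}" for i in range(1, n_genes + 1)]
    scores = rng.standard_normal(n_genes)
    members = list(rng.choice(genes, size=set_size, replace=False))
    scores[np.isin(genes, members)] += delta
    ranked = pd.Series(scores, index=pd.Index(genes, name="gene")).sort_values(
        ascending=False
    )
    from .io import sort_ranked

    return sort_ranked(ranked), GeneSet(set_name, frozenset(members), f"delta={delta}")
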