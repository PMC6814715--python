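"""Readers and writers for the tabular and sequence formats the pipeline touches.

The native tabular dialect is TSV (UTF-8, ``.`` decimal separator), matching
GeneNetwork exports.  Expression matrices are returned as pandas DataFrames
with genes as rows and strains as columns; missing cells are carried as NaN
with an explicit mask available via ``DataFrame.isna()`` — they are never
silently imputed, and each downstream operation declares its own policy.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("chondrax")

#: Canonical one-letter codes of the 20 standard amino acids, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class DuplicateLabelError(FormatError):
    """A label that must be unique occurs more than once."""


def log_filter(name: str, n_in: int, n_out: int, threshold: object = None) -> None:
    """Audit-log a filtering step: input count, output count, threshold used."""
    logger.info("filter %s: %d -> %d (threshold=%r)", name, n_in, n_out, threshold)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Pipeline-wide thresholds and reproducibility settings.

    Defaults are the study's stated values: tankyrase-targeting-score cutoff
    0.385 (the AXIN1/AXIN2 motif score), differential-expression cutoffs
    |FC| > 3 with q < 1e-5, signature cutoffs FC > 5 / |FC| > 2 with q < 1e-5,
    preranked GSEA with weight exponent 1 and 1000 permutations.
    """

    seed: int = 0
    intercorrelation_tau: float = 0.5
    tts_cutoff: float = 0.385
    disorder_cutoff: float | None = None  # annotation-only unless set
    deg_fc_min: float = 3.0
    deg_q_max: float = 1e-5
    signature_fc_min: float = 5.0
    signature_q_max: float = 1e-5
    oa_fc_min: float = 2.0
    oa_q_max: float = 1e-5
    sox9_log2fc_max: float = -2.0
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000

    def __post_init__(self) -> None:
        if not -1.0 <= self.intercorrelation_tau <= 1.0:
            raise ValueError("intercorrelation_tau must lie in [-1, 1]")
        if not 0.0 <= self.tts_cutoff <= 1.0:
            raise ValueError("tts_cutoff must lie in [0, 1]")
        for name in ("deg_q_max", "signature_q_max", "oa_q_max"):
            q = getattr(self, name)
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("deg_fc_min", "signature_fc_min", "oa_fc_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gsea_n_perm < 1:
            raise ValueError("gsea_n_perm must be >= 1")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_manifest(path: str | Path, config: Config, extra: Mapping | None = None) -> None:
    """Write a JSON run manifest (config, seed, package versions)."""
    import chondrax

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "chondrax": chondrax.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with a provenance note."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x strains expression TSV.

    One header row of strain ids, one leading label column of gene/probe ids.
    Empty cells become NaN.  Ragged rows and duplicate labels raise.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    width = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row at line {i} ({len(row)} fields, expected {width})"
            )
    strains = header[1:]
    _check_unique(strains, "strain", path)
    genes = [r[0] for r in rows[1:]]
    _check_unique(genes, "gene/probe", path)
    values = [[_parse_cell(c) for c in r[1:]] for r in rows[1:]]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=strains, dtype=float)
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", na_rep="")


def _parse_cell(cell: str) -> float:
    cell = cell.strip()
    if cell == "" or cell.upper() in {"NA", "NAN"}:
        return np.nan
    return float(cell)


def _check_unique(labels: Sequence[str], kind: str, path: Path) -> None:
    seen: dict[str, int] = {}
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
    dups = [lab for lab, n in seen.items() if n > 1]
    if dups:
        raise DuplicateLabelError(f"{path}: duplicate {kind} label(s): {sorted(dups)}")


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation TSV.

    Columns: probe_id, gene_symbol, snp_overlap, perfect_unique_match,
    mean_expression.  Booleans accept 0/1/true/false.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    required = {"probe_id", "gene_symbol", "snp_overlap", "perfect_unique_match", "mean_expression"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing probe-table columns {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise DuplicateLabelError(f"{path}: duplicate probe_id(s): {dups}")
    if not np.isfinite(df["mean_expression"]).all():
        raise FormatError(f"{path}: non-finite mean_expression values")
    for col in ("snp_overlap", "perfect_unique_match"):
        df[col] = df[col].map(_parse_bool)
    return df


def _parse_bool(v: object) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer, float)):
        return bool(int(v))
    s = str(v).strip().lower()
    if s in {"true", "t", "1", "yes"}:
        return True
    if s in {"false", "f", "0", "no"}:
        return False
    raise FormatError(f"cannot parse boolean value {v!r}")


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

def read_pssm(path: str | Path):
    """Read an 8 x 20 position-specific scoring matrix TSV.

    The header row carries the 20 standard amino-acid one-letter codes in any
    order; the 8 data rows are motif positions 1..8.  Columns are reordered to
    the canonical alphabet so scores are independent of file column order.
    """
    from .motif import PSSM

    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = [str(c).strip().upper() for c in df.columns]
    if sorted(cols) != sorted(AMINO_ACIDS):
        bad = set(cols) - set(AMINO_ACIDS)
        if bad:
            raise FormatError(f"{path}: non-standard residue column(s) {sorted(bad)}")
        raise FormatError(f"{path}: expected the 20 standard amino-acid columns, got {cols}")
    if df.shape[0] != 8:
        raise FormatError(f"{path}: expected 8 position rows, got {df.shape[0]}")
    df.columns = cols
    df = df[list(AMINO_ACIDS)]
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite PSSM entries")
    return PSSM(values)


def write_pssm(pssm, path: str | Path) -> None:
    df = pd.DataFrame(pssm.scores, index=pd.RangeIndex(1, 9, name="position"),
                      columns=list(AMINO_ACIDS))
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT / RNK
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one set per line — name, description, members (tab-sep)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i} has {len(fields)} fields, need >= 3")
            name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            if len(set(members)) < len(members):
                logger.warning("%s: line %d (%s) has duplicate members; stored once", path, i, name)
            sets.append(GeneSet(name=name, members=frozenset(members), description=desc))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def sort_ranked(scores: Mapping[str, float] | pd.Series) -> pd.Series:
    """Order gene scores descending; ties broken by gene id ascending.

    The deterministic tie-break makes ranked lists byte-reproducible, which
    exact-reproduction tests rely on.
    """
    s = pd.Series(dict(scores), dtype=float) if not isinstance(scores, pd.Series) else scores.astype(float)
    if s.index.duplicated().any():
        dups = s.index[s.index.duplicated()].tolist()
        raise DuplicateLabelError(f"duplicate gene(s) in ranked list: {sorted(set(dups))}")
    df = s.rename("score").rename_axis("gene").reset_index()
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return df.set_index("gene")["score"]


def read_rnk(path: str | Path) -> pd.Series:
    """Read a two-column RNK file (gene, score) into a descending ranked Series."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], comment="#")
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise DuplicateLabelError(f"{path}: duplicate gene(s): {sorted(set(dups))}")
    return sort_ranked(pd.Series(df["score"].to_numpy(dtype=float), index=df["gene"]))


def write_rnk(ranked: pd.Series, path: str | Path) -> None:
    sort_ranked(ranked).to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# DE tables, MS hits, disorder profiles
# ---------------------------------------------------------------------------

def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV (gene, log2fc, q), indexed by gene."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = {"gene", "log2fc", "q"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing DE columns {sorted(missing)}")
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise DuplicateLabelError(f"{path}: duplicate gene(s): {sorted(set(dups))}")
    if ((df["q"] < 0) | (df["q"] > 1)).any():
        raise FormatError(f"{path}: q values outside [0, 1]")
    return df.set_index("gene")[["log2fc", "q"]].astype(float)


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_ms_hits(path: str | Path) -> pd.DataFrame:
    """Read an MS hit TSV: protein_id, replicate_id, spectral_count, igg_control."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "replicate_id": str})
    missing = {"protein_id", "replicate_id", "spectral_count", "igg_control"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing MS-hit columns {sorted(missing)}")
    df["igg_control"] = df["igg_control"].map(_parse_bool)
    df["spectral_count"] = df["spectral_count"].astype(int)
    if (df["spectral_count"] < 0).any():
        raise FormatError(f"{path}: negative spectral counts")
    noncontrol = df[~df["igg_control"]]
    if noncontrol.duplicated(["protein_id", "replicate_id"]).any():
        raise FormatError(f"{path}: duplicate (protein, replicate) rows outside controls")
    return df


def write_ms_hits(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_disorder_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Read per-residue disorder scores (protein_id, position 1-based, score).

    Returns a dict of dense per-protein arrays (index 0 = residue 1); positions
    absent from the file are NaN.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = {"protein_id", "position", "score"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing disorder columns {sorted(missing)}")
    profiles: dict[str, np.ndarray] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        pos = grp["position"].to_numpy(dtype=int)
        if (pos < 1).any():
            raise FormatError(f"{path}: non-positive residue position for {pid}")
        arr = np.full(pos.max(), np.nan)
        arr[pos - 1] = grp["score"].to_numpy(dtype=float)
        profiles[pid] = arr
    return profiles


def write_disorder_tsv(profiles: Mapping[str, np.ndarray], path: str | Path) -> None:
    rows = []
    for pid in profiles:
        arr = np.asarray(profiles[pid], dtype=float)
        for i, v in enumerate(arr, start=1):
            if np.isfinite(v):
                rows.append((pid, i, v))
    pd.DataFrame(rows, columns=["protein_id", "position", "score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into {id: sequence} (uppercased)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DuplicateLabelError(f"{path}: duplicate FASTA id {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list, ignoring blanks and '#' comments."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
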