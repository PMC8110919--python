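"""Readers and writers for every external artifact of the pipeline.

The on-disk formats are deliberately plain: peptide read files are text with
one 12mer per line, the proteome is FASTA, and every derived table (kmer
tables, control background, score matrices, per-protein statistics) is TSV
with a fixed, documented column schema.  Floating-point columns are written
with 12 significant digits so that write -> read round-trips are lossless at
working precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET = frozenset(STANDARD_AA)

#: Display-library read length in residues.
READ_LENGTH = 12

#: Below this many unique reads a sample is flagged as thin.  Production
#: screens yield >= 1e6 unique 12mers per sample; desk-scale fixtures are far
#: smaller, so this is a warning threshold, not a hard requirement.
MIN_READS_WARNING = 10_000

CASE = "case"
CONTROL = "control"


class SchemaError(ValueError):
    """A table file does not carry the columns its schema requires."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSet:
    """One sample's unique 12mer peptide reads.

    ``reads`` is an ordered tuple of unique peptides (first-seen order is
    preserved so downstream iteration is deterministic); set semantics are
    enforced at construction.  ``n_dropped`` counts input lines rejected for
    wrong length or non-standard letters, ``n_duplicates`` counts collapsed
    repeats.
    """

    sample_id: str
    reads: tuple[str, ...]
    n_dropped: int = 0
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        if len(set(self.reads)) != len(self.reads):
            raise ValueError(f"sample {self.sample_id!r}: reads are not unique")
        for r in self.reads:
            if len(r) != READ_LENGTH or not STANDARD_AA_SET.issuperset(r):
                raise ValueError(
                    f"sample {self.sample_id!r}: invalid read {r!r} "
                    f"(need {READ_LENGTH} standard amino-acid letters)"
                )

    @property
    def n_reads(self) -> int:
        """Number of unique 12mers (the N_S of the enrichment model)."""
        return len(self.reads)

    @classmethod
    def from_iterable(cls, sample_id: str, lines: Iterable[str]) -> "ReadSet":
        """Build a ReadSet from raw peptide lines, dropping invalid entries."""
        seen: dict[str, None] = {}
        dropped = dups = 0
        for line in lines:
            pep = line.strip().upper()
            if not pep:
                continue
            if len(pep) != READ_LENGTH or not STANDARD_AA_SET.issuperset(pep):
                dropped += 1
                continue
            if pep in seen:
                dups += 1
            else:
                seen[pep] = None
        return cls(sample_id, tuple(seen), n_dropped=dropped, n_duplicates=dups)


@dataclass(frozen=True)
class ProteinRecord:
    """A single proteome entry (accession, free-text description, sequence)."""

    protein_id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SampleManifest:
    """Assignment of samples to cohorts plus the path of each read file."""

    rows: tuple[tuple[str, str, str], ...]  # (sample_id, path, cohort)

    def __post_init__(self) -> None:
        ids = [sid for sid, _, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("manifest sample_ids are not unique")
        bad = sorted({c for _, _, c in self.rows} - {CASE, CONTROL})
        if bad:
            raise ValueError(f"manifest cohort labels must be case/control, got {bad}")
        if len(self.control_ids) < 2:
            raise ValueError(
                "manifest needs at least 2 control samples "
                "(the background standard deviation is otherwise undefined)"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.rows]

    @property
    def case_ids(self) -> list[str]:
        return [sid for sid, _, c in self.rows if c == CASE]

    @property
    def control_ids(self) -> list[str]:
        return [sid for sid, _, c in self.rows if c == CONTROL]

    def path_of(self, sample_id: str) -> str:
        for sid, path, _ in self.rows:
            if sid == sample_id:
                return path
        raise KeyError(sample_id)

    def cohort_of(self, sample_id: str) -> str:
        for sid, _, c in self.rows:
            if sid == sample_id:
                return c
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["sample_id", "path", "cohort"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleManifest":
        missing = {"sample_id", "path", "cohort"} - set(df.columns)
        if missing:
            raise SchemaError(f"manifest is missing columns: {sorted(missing)}")
        return cls(tuple(
            (str(r.sample_id), str(r.path), str(r.cohort)) for r in df.itertuples()
        ))


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def load_reads(path: str | Path, sample_id: str | None = None,
               min_reads_warning: int = MIN_READS_WARNING) -> ReadSet:
    """Load one sample's peptide reads from a plain-text file.

    One peptide per line; duplicates are collapsed, lines of the wrong length
    or containing non-standard letters are dropped (and counted).  Raises
    ``ValueError`` if no valid read survives filtering.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    with open(path) as fh:
        rs = ReadSet.from_iterable(sample_id, fh)
    if rs.n_dropped:
        logger.info("%s: dropped %d invalid read lines", path, rs.n_dropped)
    if rs.n_reads == 0:
        raise ValueError(f"no valid {READ_LENGTH}mer reads in {path}")
    if rs.n_reads < min_reads_warning:
        logger.warning(
            "%s: only %d unique reads (production screens carry >= 1e6)",
            path, rs.n_reads,
        )
    return rs


def write_reads(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in readset.reads:
            fh.write(r + "\n")


# ---------------------------------------------------------------------------
# Proteome FASTA
# ---------------------------------------------------------------------------

def load_proteome(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA into a list of :class:`ProteinRecord`.

    The accession is the full first whitespace-delimited token of the header
    (UniProt-style ``sp|P14678|RSMB_HUMAN`` tokens are kept intact); sequences
    are uppercased and may contain non-standard letters (X/U/B/Z), which the
    scoring layer masks.  File order is preserved.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate accession {pid!r} in {path}")
        seen.add(pid)
        desc = rec.description[len(pid):].strip() if rec.description.startswith(pid) else rec.description
        records.append(ProteinRecord(pid, desc, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA entries in {path}")
    return records


def write_proteome(records: Sequence[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Generic TSV persistence
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def write_table(df: pd.DataFrame, path: str | Path,
                comments: Mapping[str, object] | None = None) -> None:
    """Write a DataFrame as TSV, with optional ``# key=json`` header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (comments or {}).items():
            fh.write(f"# {key}={json.dumps(val)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path: str | Path, required: Sequence[str] = (),
               ) -> tuple[pd.DataFrame, dict[str, object]]:
    """Read a TSV written by :func:`write_table`; returns (frame, comments).

    Raises :class:`SchemaError` naming any required column that is absent.
    """
    path = Path(path)
    comments: dict[str, object] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("# ") and "=" in line:
                key, _, raw = line[2:].rstrip("\n").partition("=")
                comments[key] = json.loads(raw)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df, comments


# Column schemas (the contract of every table the pipeline persists).
KMER_TABLE_COLUMNS = ["kmer", "k", "n", "e", "E", "F"]
BACKGROUND_COLUMNS = ["kmer", "k", "mean", "sd", "n_controls"]
SCORES_COLUMNS = ["sample_id", "protein_id", "piwas_score", "piwas_loc"]
PROTEIN_STATS_COLUMNS = [
    "protein_id", "outlier_sum", "os_null_mean", "os_null_sd", "os_z",
    "os_p", "os_fdr", "mw_p", "ks_p", "hedges_g", "loc_ks_p",
    "dominant_epitopes", "dominant_locs",
]


def write_scores(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df[SCORES_COLUMNS], path)


def read_scores(path: str | Path) -> pd.DataFrame:
    df, _ = read_table(path, required=SCORES_COLUMNS)
    return df


def write_protein_stats(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df[PROTEIN_STATS_COLUMNS], path)


def read_protein_stats(path: str | Path) -> pd.DataFrame:
    df, _ = read_table(path, required=PROTEIN_STATS_COLUMNS)
    for col in ("dominant_epitopes", "dominant_locs"):
        df[col] = df[col].fillna("").astype(str)
    return df


def read_manifest(path: str | Path) -> SampleManifest:
    df, _ = read_table(path, required=["sample_id", "path", "cohort"])
    # Relative read paths are resolved against the manifest's directory.
    base = Path(path).parent
    rows = []
    for r in df.itertuples():
        p = Path(str(r.path))
        if not p.is_absolute():
            p = base / p
        rows.append((str(r.sample_id), str(p), str(r.cohort)))
    return SampleManifest(tuple(rows))


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    write_table(manifest.to_frame(), path)


# KmerTable / ControlBackground TSV round-trips.  The heavier numeric types
# live in their own modules; imports are deferred to avoid cycles.

def write_kmer_table(table, path: str | Path) -> None:
    """Persist one sample's per-kmer table (one k per file)."""
    rows = pd.DataFrame({
        "kmer": sorted(table.E),
    })
    rows["k"] = table.k
    rows["n"] = [table.n[km] for km in rows["kmer"]]
    rows["e"] = [table.e[km] for km in rows["kmer"]]
    rows["E"] = [table.E[km] for km in rows["kmer"]]
    if table.F is not None:
        rows["F"] = [table.F.get(km, float("nan")) for km in rows["kmer"]]
    else:
        rows["F"] = float("nan")
    comments = {
        "sample_id": table.sample_id,
        "read_count": table.read_count,
        "read_length": table.read_length,
        "aa_freqs": {aa: table.aa_freqs[aa] for aa in sorted(table.aa_freqs)},
    }
    write_table(rows, path, comments=comments)


def read_kmer_table(path: str | Path):
    from .enrichment import KmerTable

    df, comments = read_table(path, required=KMER_TABLE_COLUMNS)
    if df.empty:
        raise ValueError(f"{path}: kmer table has no rows")
    ks = df["k"].unique()
    if len(ks) != 1:
        raise ValueError(f"{path}: a kmer table file must carry a single k, got {list(ks)}")
    has_f = df["F"].notna().all()
    return KmerTable(
        sample_id=str(comments["sample_id"]),
        k=int(ks[0]),
        n=dict(zip(df["kmer"], df["n"].astype(int))),
        e=dict(zip(df["kmer"], df["e"].astype(float))),
        E=dict(zip(df["kmer"], df["E"].astype(float))),
        aa_freqs={str(a): float(v) for a, v in comments["aa_freqs"].items()},
        read_count=int(comments["read_count"]),
        read_length=int(comments.get("read_length", READ_LENGTH)),
        F=dict(zip(df["kmer"], df["F"].astype(float))) if has_f else None,
    )


def write_background(bg, path: str | Path) -> None:
    kmers = sorted(bg.mean)
    rows = pd.DataFrame({
        "kmer": kmers,
        "k": [len(km) for km in kmers],
        "mean": [bg.mean[km] for km in kmers],
        "sd": [bg.sd[km] for km in kmers],
        "n_controls": bg.n_controls,
    })
    write_table(rows, path, comments={
        "control_ids": list(bg.control_ids),
        "sd_floor": {str(k): v for k, v in sorted(bg.sd_floor.items())},
    })


def read_background(path: str | Path):
    from .background import ControlBackground

    df, comments = read_table(path, required=BACKGROUND_COLUMNS)
    return ControlBackground(
        control_ids=tuple(str(s) for s in comments["control_ids"]),
        mean=dict(zip(df["kmer"], df["mean"].astype(float))),
        sd=dict(zip(df["kmer"], df["sd"].astype(float))),
        sd_floor={int(k): float(v) for k, v in comments["sd_floor"].items()},
    )
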