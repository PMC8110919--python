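"""End-to-end orchestration: manifest + proteome -> ranked antigen table.

The pipeline is the composition of the individual stages — enrich each
sample, build the control background, normalize, tile/score every protein,
and rank by cohort statistics — with all intermediate tables persisted as
TSV.  A single seed drives every source of randomness, and a rerun with
identical inputs and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .background import ControlBackground, build_background, normalize
from .core import DEFAULT_WINDOW, NORMALIZED_F, MODES, proteome_kmers, score_cohort
from .enrichment import DEFAULT_KS, KmerTable, enrich
from .io import ProteinRecord, ReadSet, SampleManifest
from .stats import DEFAULT_N_PERM, rank_proteome

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully resolved parameters of one pipeline run."""

    proteome: str
    manifest: str
    out_dir: str
    ks: tuple[int, ...] = DEFAULT_KS
    window: int = DEFAULT_WINDOW
    mode: str = NORMALIZED_F
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    sd_floor: float | None = None  # None -> percentile policy of the background
    score_threshold: float = 6.0
    min_reads_warning: int = pio.MIN_READS_WARNING
    keep_intermediate: bool = True
    restrict_background: bool = True

    def validate(self) -> None:
        if self.window < 0:
            raise ValueError(f"window_w: must be >= 0, got {self.window}")
        if self.mode not in MODES:
            raise ValueError(f"mode: must be one of {MODES}, got {self.mode!r}")
        if self.n_perm < 100:
            raise ValueError(f"n_perm: must be >= 100, got {self.n_perm}")
        if self.sd_floor is not None and self.sd_floor <= 0:
            raise ValueError("sd_floor: must be positive when given")
        if self.score_threshold != self.score_threshold:  # NaN guard
            raise ValueError("score_threshold: must not be NaN")
        for name in ("proteome", "manifest"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"{name}: path {path} does not exist")


_CONFIG_ALIASES = {"window_w": "window", "w": "window", "permutations": "n_perm"}


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys produce a warning (forward compatibility), invalid values
    an error naming the offending field.  The resolved configuration is
    echoed to the log.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for key, val in raw.items():
        key = _CONFIG_ALIASES.get(key, key)
        if key not in known:
            logger.warning("%s: unknown config key %r ignored", path, key)
            continue
        if key == "ks":
            val = tuple(int(k) for k in val)
        kwargs[key] = val
    missing = {"proteome", "manifest", "out_dir"} - set(kwargs)
    if missing:
        raise ValueError(f"{path}: missing required keys {sorted(missing)}")
    base = Path(path).parent
    for key in ("proteome", "manifest", "out_dir"):
        p = Path(kwargs[key])
        kwargs[key] = str(p if p.is_absolute() else base / p)
    config = RunConfig(**kwargs)
    config.validate()
    logger.info("resolved config: %s", dataclasses.asdict(config))
    return config


@dataclass
class RunResult:
    """Outputs of a pipeline run (frames in memory, paths on disk)."""

    scores: pd.DataFrame
    protein_stats: pd.DataFrame
    background: ControlBackground
    out_dir: Path | None = None
    log: dict = field(default_factory=dict)


def enrich_samples(readsets: Mapping[str, ReadSet],
                   ks: Sequence[int] = DEFAULT_KS,
                   restrict_to: set[str] | None = None,
                   ) -> dict[str, dict[int, KmerTable]]:
    """Enrich every sample, optionally keeping only proteome kmers."""
    tables: dict[str, dict[int, KmerTable]] = {}
    for sid, rs in readsets.items():
        full = enrich(rs, ks)
        if restrict_to is not None:
            full = {k: t.restricted(restrict_to) for k, t in full.items()}
        tables[sid] = full
    return tables


def analyze_cohort(proteins: Sequence[ProteinRecord],
                   readsets: Mapping[str, ReadSet],
                   manifest: SampleManifest,
                   *,
                   ks: Sequence[int] = DEFAULT_KS,
                   window: int = DEFAULT_WINDOW,
                   mode: str = NORMALIZED_F,
                   n_perm: int = DEFAULT_N_PERM,
                   seed: int = 0,
                   sd_floor: float | None = None,
                   score_threshold: float = 6.0,
                   restrict_background: bool = True) -> RunResult:
    """In-memory pipeline: enrich -> background -> normalize -> score -> rank.

    ``restrict_background`` bounds memory by restricting the kmer tables and
    the background to kmers occurring in the target proteome — kmers outside
    it can never contribute to a protein score.
    """
    missing = [sid for sid in manifest.sample_ids if sid not in readsets]
    if missing:
        raise ValueError(f"manifest samples without read sets: {missing}")
    keep = proteome_kmers(proteins, ks) if restrict_background else None
    tables = enrich_samples({sid: readsets[sid] for sid in manifest.sample_ids},
                            ks, restrict_to=keep)
    bg = build_background(
        [tables[sid][k] for sid in manifest.control_ids for k in ks],
        restrict_to=keep, sd_floor=sd_floor)
    if mode == NORMALIZED_F:
        tables = {sid: {k: normalize(t, bg, restrict_to=keep)
                        for k, t in per_k.items()}
                  for sid, per_k in tables.items()}
    scores = score_cohort(proteins, tables, mode=mode, w=window)
    stats = rank_proteome(scores, manifest, n_perm=n_perm, seed=seed,
                          proteins=proteins, score_threshold=score_threshold,
                          w=window)
    return RunResult(scores=scores, protein_stats=stats, background=bg)


def run_pipeline(config: RunConfig) -> RunResult:
    """File-based pipeline run; writes every declared output under out_dir.

    Outputs: ``background.tsv``, ``scores.tsv``, ``protein_stats.tsv``,
    ``run_log.json`` and (with ``keep_intermediate``) one kmer table per
    sample and k under ``kmer_tables/``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pio.read_manifest(config.manifest)
    proteins = pio.load_proteome(config.proteome)

    readsets: dict[str, ReadSet] = {}
    dropped: dict[str, int] = {}
    for sid in manifest.sample_ids:
        try:
            rs = pio.load_reads(manifest.path_of(sid), sid,
                                min_reads_warning=config.min_reads_warning)
        except Exception as exc:
            raise RuntimeError(f"stage=load_reads sample={sid}: {exc}") from exc
        readsets[sid] = rs
        dropped[sid] = rs.n_dropped

    result = analyze_cohort(
        proteins, readsets, manifest,
        ks=config.ks, window=config.window, mode=config.mode,
        n_perm=config.n_perm, seed=config.seed, sd_floor=config.sd_floor,
        score_threshold=config.score_threshold,
        restrict_background=config.restrict_background,
    )

    if config.keep_intermediate:
        kdir = out_dir / "kmer_tables"
        kdir.mkdir(exist_ok=True)
        # Tables are re-derived restricted to the proteome; persist the raw
        # (unrestricted) enrichments so the cache is reusable elsewhere.
        for sid, rs in readsets.items():
            for k, table in enrich(rs, config.ks).items():
                pio.write_kmer_table(table, kdir / f"{sid}_k{k}.tsv")
    pio.write_background(result.background, out_dir / "background.tsv")
    pio.write_scores(result.scores, out_dir / "scores.tsv")
    pio.write_protein_stats(result.protein_stats, out_dir / "protein_stats.tsv")

    log = {
        "piwas_version": __version__,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()},
        "n_samples": len(manifest.sample_ids),
        "n_cases": len(manifest.case_ids),
        "n_controls": len(manifest.control_ids),
        "n_proteins": len(proteins),
        "dropped_reads": dropped,
        "background_sd_floor": result.background.sd_floor,
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.out_dir = out_dir
    result.log = log
    return result
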