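"""Synthetic serology cohorts and power experiments.

Two distinct jobs live here.

1. ``generate_cohort`` emulates the structure of a random-peptide display
   screen: each sample is a set of unique 12mer reads with i.i.d. letters
   from a background amino-acid composition; a configurable fraction of the
   case samples is "planted" — a fraction of their reads carries a
   contiguous fragment (>= 5 residues, the minimal linear paratope contact)
   of a chosen protein epitope, at a random offset with random flanks.
   ``plant_rate`` is the per-read magnitude proxy, ``prevalence`` the
   fraction of case samples carrying the signal.

2. ``power_curve`` reproduces the magnitude/prevalence power experiments:
   case score vectors for one protein are scaled by factors over [0.1, 2],
   or resampled from their "high" (> 6) and "low" pools to a target
   prevalence (1000 resamplings with replacement), and the outlier-sum
   permutation statistics are recomputed against the untouched controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .io import CASE, CONTROL, ProteinRecord, ReadSet, SampleManifest, STANDARD_AA
from .stats import DEFAULT_N_PERM, outlier_sum, permutation_null

logger = logging.getLogger(__name__)

_UNIFORM_AA = {aa: 1.0 / len(STANDARD_AA) for aa in STANDARD_AA}

#: Amino-acid composition preset loosely mimicking an NNK-style random
#: library (codon-degeneracy biased, Leu/Ser/Arg-heavy), for users who want
#: a non-uniform background.
NNK_LIKE_AA_FREQS: dict[str, float] = {
    "A": 0.0625, "C": 0.03125, "D": 0.03125, "E": 0.03125, "F": 0.03125,
    "G": 0.0625, "H": 0.03125, "I": 0.03125, "K": 0.03125, "L": 0.09375,
    "M": 0.03125, "N": 0.03125, "P": 0.0625, "Q": 0.03125, "R": 0.09375,
    "S": 0.09375, "T": 0.0625, "V": 0.0625, "W": 0.03125, "Y": 0.03125,
}


@dataclass
class SyntheticCohortConfig:
    """Study conditions of a synthetic screen.

    Defaults are the desk-scale planted-epitope conditions used throughout
    the test suite: 20 cases vs 50 controls, 2e4 unique reads per sample,
    201 proteins of 300 residues, an 11-residue epitope planted into 2% of
    the reads of half of the case samples.
    """

    n_cases: int = 20
    n_controls: int = 50
    reads_per_sample: int = 20_000
    aa_freqs: Mapping[str, float] | None = None  # None -> uniform over 20 letters
    proteome_path: str | None = None  # FASTA; overrides decoy generation
    n_decoys: int = 200
    decoy_length: int = 300
    epitope_protein: str | None = None  # default: first generated protein
    epitope_start: int = 150
    epitope_length: int = 11
    plant_rate: float = 0.02
    prevalence: float = 0.5
    min_fragment: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must lie in [0, 1]")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if not 8 <= self.epitope_length <= 12:
            raise ValueError("epitope_length must lie in [8, 12]")
        if self.min_fragment < 5:
            raise ValueError("min_fragment must be >= 5 (a linear epitope-"
                             "paratope contact spans at least 5 residues)")
        if self.min_fragment > self.epitope_length:
            raise ValueError("min_fragment exceeds epitope_length")
        if self.reads_per_sample > 0.1 * 20 ** pio.READ_LENGTH:
            raise ValueError("reads_per_sample exceeds 10% of sequence space; "
                             "unique sampling would stall")
        freqs = self.aa_freqs if self.aa_freqs is not None else _UNIFORM_AA
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"aa_freqs must sum to 1, got {total}")


@dataclass
class SyntheticCohort:
    """In-memory result of :func:`generate_cohort`."""

    proteins: list[ProteinRecord]
    readsets: dict[str, ReadSet]
    manifest: SampleManifest
    truth: pd.DataFrame  # protein_id, epitope_start, epitope_end, sample_id, planted_flag
    epitope_protein: str
    epitope_interval: tuple[int, int]  # [start, end) 0-based


def _aa_arrays(freqs: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    letters = sorted(freqs)
    return (np.array(letters, dtype="<U1"),
            np.array([freqs[a] for a in letters], dtype=float))


def _random_read_block(rng: np.random.Generator, m: int,
                       letters: np.ndarray, probs: np.ndarray) -> list[str]:
    idx = rng.choice(letters.size, size=(m, pio.READ_LENGTH), p=probs)
    return ["".join(row) for row in letters[idx]]


def _unique_reads(rng, n, letters, probs, seeded: dict[str, None] | None = None) -> tuple[str, ...]:
    reads: dict[str, None] = dict(seeded) if seeded else {}
    while len(reads) < n:
        for r in _random_read_block(rng, n - len(reads) + 16, letters, probs):
            if len(reads) >= n:
                break
            reads.setdefault(r, None)
    return tuple(reads)


def _planted_read(rng: np.random.Generator, epitope: str, min_fragment: int,
                  letters: np.ndarray, probs: np.ndarray) -> str:
    frag_len = int(rng.integers(min_fragment, min(pio.READ_LENGTH, len(epitope)) + 1))
    frag_start = int(rng.integers(0, len(epitope) - frag_len + 1))
    offset = int(rng.integers(0, pio.READ_LENGTH - frag_len + 1))
    flanks = _random_read_block(rng, 1, letters, probs)[0]
    frag = epitope[frag_start:frag_start + frag_len]
    return flanks[:offset] + frag + flanks[offset + frag_len:]


def generate_cohort(config: SyntheticCohortConfig,
                    out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; reproducible bit-for-bit from the seed.

    If ``out_dir`` is given, the proteome FASTA, one read file per sample,
    ``manifest.tsv`` and ``truth.tsv`` are written there.
    """
    rng = np.random.default_rng(config.seed)
    freqs = dict(config.aa_freqs) if config.aa_freqs is not None else dict(_UNIFORM_AA)
    letters, probs = _aa_arrays(freqs)

    # Proteome: loaded or generated decoys with i.i.d. background letters.
    if config.proteome_path is not None:
        proteins = pio.load_proteome(config.proteome_path)
    else:
        proteins = []
        for i in range(config.n_decoys + 1):
            idx = rng.choice(letters.size, size=config.decoy_length, p=probs)
            proteins.append(ProteinRecord(
                f"SYN{i:04d}", f"synthetic decoy protein {i}",
                "".join(letters[idx])))
    target_id = config.epitope_protein or proteins[0].protein_id
    by_id = {p.protein_id: p for p in proteins}
    if target_id not in by_id:
        raise ValueError(f"epitope protein {target_id!r} not in the proteome")
    target = by_id[target_id]
    start, length = config.epitope_start, config.epitope_length
    if start < 0 or start + length > target.length:
        raise ValueError(
            f"epitope [{start}, {start + length}) falls outside "
            f"{target_id!r} (length {target.length})")
    epitope = target.sequence[start:start + length]

    n_planted = int(round(config.prevalence * config.n_cases))
    sample_plan: list[tuple[str, str, bool]] = []
    for i in range(config.n_cases):
        sample_plan.append((f"CASE{i + 1:03d}", CASE, i < n_planted))
    for i in range(config.n_controls):
        sample_plan.append((f"CTRL{i + 1:03d}", CONTROL, False))

    readsets: dict[str, ReadSet] = {}
    for sid, cohort, planted in sample_plan:
        if planted and config.plant_rate > 0:
            n_plant = int(round(config.plant_rate * config.reads_per_sample))
            seeded: dict[str, None] = {}
            while len(seeded) < n_plant:
                seeded.setdefault(
                    _planted_read(rng, epitope, config.min_fragment, letters, probs),
                    None)
            reads = _unique_reads(rng, config.reads_per_sample, letters, probs, seeded)
        else:
            reads = _unique_reads(rng, config.reads_per_sample, letters, probs)
        readsets[sid] = ReadSet(sid, reads)

    out_path = Path(out_dir) if out_dir is not None else None
    # Paths are kept relative to the cohort directory so equal-seed runs are
    # byte-identical wherever they are written; read_manifest resolves them.
    manifest = SampleManifest(tuple(
        (sid, f"{sid}.txt", cohort) for sid, cohort, _ in sample_plan))
    truth = pd.DataFrame({
        "protein_id": target_id,
        "epitope_start": start,
        "epitope_end": start + length,
        "sample_id": [sid for sid, _, _ in sample_plan],
        "planted_flag": [int(p) for _, _, p in sample_plan],
    })

    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        pio.write_proteome(proteins, out_path / "proteome.fasta")
        for sid, rs in readsets.items():
            pio.write_reads(rs, out_path / f"{sid}.txt")
        pio.write_manifest(manifest, out_path / "manifest.tsv")
        pio.write_table(truth, out_path / "truth.tsv")

    return SyntheticCohort(proteins, readsets, manifest, truth,
                           target_id, (start, start + length))


# ---------------------------------------------------------------------------
# Power experiments on score vectors
# ---------------------------------------------------------------------------

@dataclass
class PowerExperimentConfig:
    """Grid experiment over signal magnitude and prevalence.

    ``case_scores``/``control_scores`` are per-sample protein scores of the
    antigen under study.  Magnitude points rescale the case vector; the
    prevalence points resample it with replacement from its "high"
    (> ``high_threshold``) and "low" pools, each position independently
    high with the target probability.  Values exactly at the threshold
    belong to the low pool.
    """

    case_scores: Sequence[float]
    control_scores: Sequence[float]
    scaling_grid: Sequence[float] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.1, 2.0001, 0.1), 10)))
    prevalence_grid: Sequence[float] = field(
        default_factory=lambda: (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
                                 0.6, 0.7, 0.8, 0.9, 1.0))
    high_threshold: float = 6.0
    n_resamples: int = 1000
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.scaling_grid) == 0 or len(self.prevalence_grid) == 0:
            raise ValueError("grids must be non-empty")
        if not np.isfinite(self.high_threshold):
            raise ValueError("high_threshold must be finite")


def scale_magnitude(case_scores: Sequence[float], factor: float) -> np.ndarray:
    """Rescale the case score vector (controls are never touched)."""
    return np.asarray(case_scores, dtype=float) * factor


def resample_prevalence(case_scores: Sequence[float], prevalence: float,
                        threshold: float = 6.0,
                        rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Resample the case vector to a target high-signal prevalence.

    Each output position is independently drawn (with replacement) from the
    "high" pool (> threshold) with probability ``prevalence``, else from the
    "low" pool.  Raises when a required pool is empty.
    """
    rng = np.random.default_rng(rng)
    scores = np.asarray(case_scores, dtype=float)
    high = scores[scores > threshold]
    low = scores[scores <= threshold]
    if prevalence > 0 and high.size == 0:
        raise ValueError(f"high pool (> {threshold}) is empty")
    if prevalence < 1 and low.size == 0:
        raise ValueError(f"low pool (<= {threshold}) is empty")
    take_high = rng.random(scores.size) < prevalence
    out = np.empty(scores.size)
    n_high = int(take_high.sum())
    if n_high:
        out[take_high] = rng.choice(high, size=n_high, replace=True)
    if n_high < scores.size:
        out[~take_high] = rng.choice(low, size=scores.size - n_high, replace=True)
    return out


MAGNITUDE = "magnitude"
PREVALENCE = "prevalence"


def power_curve(config: PowerExperimentConfig, axis: str) -> pd.DataFrame:
    """Outlier-sum significance along a magnitude or prevalence grid.

    One row per grid point with the outlier sum, permutation z and normal-
    tail p; prevalence points aggregate ``n_resamples`` resampled cohorts,
    reporting the median with the interquartile band of the resampled
    p-values.  Each grid point uses its own RNG stream derived from
    ``(seed, axis, point index)``.
    """
    if axis not in (MAGNITUDE, PREVALENCE):
        raise ValueError(f"axis must be {MAGNITUDE!r} or {PREVALENCE!r}")
    control = np.asarray(config.control_scores, dtype=float)
    case = np.asarray(config.case_scores, dtype=float)
    grid = config.scaling_grid if axis == MAGNITUDE else config.prevalence_grid
    axis_key = 0 if axis == MAGNITUDE else 1

    rows = []
    for i, point in enumerate(grid):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(axis_key, i)))
        if axis == MAGNITUDE:
            vec = scale_magnitude(case, float(point))
            res = permutation_null(vec, control, n_perm=config.n_perm, rng=rng)
            rows.append((float(point), res.observed, res.os_z, res.os_p,
                         float("nan"), float("nan")))
        else:
            os_vals = np.empty(config.n_resamples)
            z_vals = np.empty(config.n_resamples)
            p_vals = np.empty(config.n_resamples)
            for r in range(config.n_resamples):
                vec = resample_prevalence(case, float(point),
                                          config.high_threshold, rng)
                res = permutation_null(vec, control, n_perm=config.n_perm, rng=rng)
                os_vals[r], z_vals[r], p_vals[r] = res.observed, res.os_z, res.os_p
            q25, q75 = np.percentile(p_vals, [25.0, 75.0])
            rows.append((float(point), float(np.median(os_vals)),
                         float(np.median(z_vals)), float(np.median(p_vals)),
                         float(q25), float(q75)))
    out = pd.DataFrame(rows, columns=["grid_value", "outlier_sum", "os_z",
                                      "os_p", "os_p_q25", "os_p_q75"])
    out.insert(0, "axis", axis)
    return out
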