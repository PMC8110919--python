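"""Tiling kmer enrichments onto proteins and the windowed maximum score.

For a protein p of length L and a sample s, every 5mer and 6mer of p is
looked up in the sample's kmer table, giving two position-indexed value
tracks G (either raw enrichment E or control-normalized F).  The protein
score is the maximum over window starts i of

    sum_{k in {5,6}} sum_{j = i..min(i+w, L-k)} G(kmer(j, k, p))

i.e. a sliding window of w+1 kmer starts per k, both k contributions added
into a single sum; the score's argmax position marks the candidate epitope.
With the default w = 5 the window of w+1 6mers spans 11 residues, the
length of a reported dominant epitope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .background import ControlBackground
from .enrichment import DEFAULT_KS, KmerTable
from .io import STANDARD_AA_SET, ProteinRecord

logger = logging.getLogger(__name__)

#: Scoring modes: raw enrichment or control-normalized enrichment.
RAW_E = "raw_E"
NORMALIZED_F = "normalized_F"
MODES = (RAW_E, NORMALIZED_F)

DEFAULT_WINDOW = 5
MIN_K = min(DEFAULT_KS)


@dataclass
class PiwasTrack:
    """Per-position window sums of one (sample, protein) pair."""

    sample_id: str
    protein_id: str
    window_w: int
    mode: str
    values: np.ndarray  # window sum per valid start position
    score: float
    loc: int  # 0-based start of the first maximal window


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _g_lookup(table: KmerTable, mode: str) -> Mapping[str, float]:
    if mode == RAW_E:
        return table.E
    if table.F is None:
        raise ValueError(
            f"sample {table.sample_id!r} k={table.k}: normalized scoring requested "
            "but the table has not been normalized against a background"
        )
    return table.F


def proteome_kmers(proteins: Iterable[ProteinRecord],
                   ks: Sequence[int] = DEFAULT_KS) -> set[str]:
    """All standard-letter kmers occurring in the given proteins."""
    out: set[str] = set()
    for prot in proteins:
        seq = prot.sequence
        for k in ks:
            for i in range(len(seq) - k + 1):
                km = seq[i:i + k]
                if STANDARD_AA_SET.issuperset(km):
                    out.add(km)
    return out


def tile_protein(protein: ProteinRecord,
                 tables: Mapping[int, KmerTable],
                 mode: str = NORMALIZED_F) -> dict[int, np.ndarray]:
    """Per-k vectors of G values along the protein.

    For each k the vector has one entry per kmer start (length L-k+1, empty
    when L < k).  Kmers absent from the table take the value of E = 0 under
    the chosen mode; windows covering a non-standard letter (X/U/B/Z) are
    masked to 0 — such kmers cannot occur in a standard-letter peptide
    library.
    """
    _check_mode(mode)
    seq = protein.sequence
    L = len(seq)
    bad = [i for i, c in enumerate(seq) if c not in STANDARD_AA_SET]
    if bad:
        logger.debug("%s: %d non-standard residues masked", protein.protein_id, len(bad))
    out: dict[int, np.ndarray] = {}
    for k, table in tables.items():
        if L < k:
            out[k] = np.empty(0)
            continue
        g = _g_lookup(table, mode)
        vals = np.fromiter(
            (g.get(seq[i:i + k], 0.0) for i in range(L - k + 1)),
            dtype=float, count=L - k + 1,
        )
        for i in bad:
            lo = max(0, i - k + 1)
            vals[lo:min(i, L - k) + 1] = 0.0
        out[k] = vals
    return out


def _window_sums(values: np.ndarray, starts: np.ndarray, w: int) -> np.ndarray:
    """Sum values[i .. min(i+w, end)] for each start i (empty ranges give 0)."""
    cs = np.concatenate(([0.0], np.cumsum(values)))
    lo = np.minimum(starts, len(values))
    hi = np.maximum(np.minimum(starts + w + 1, len(values)), lo)
    return cs[hi] - cs[lo]


def window_scores(tracks: Mapping[int, np.ndarray], protein_length: int,
                  w: int = DEFAULT_WINDOW) -> np.ndarray:
    """Window sums over all valid start positions [0, L - 5]."""
    if w < 0:
        raise ValueError("window width w must be >= 0")
    n_starts = protein_length - MIN_K + 1
    if n_starts <= 0:
        return np.empty(0)
    starts = np.arange(n_starts)
    total = np.zeros(n_starts)
    for vals in tracks.values():
        total += _window_sums(vals, starts, w)
    return total


def piwas_track(protein: ProteinRecord, tables: Mapping[int, KmerTable],
                mode: str = NORMALIZED_F, w: int = DEFAULT_WINDOW) -> PiwasTrack:
    """Full windowed track plus (score, loc) for one sample and protein."""
    sample_ids = {t.sample_id for t in tables.values()}
    if len(sample_ids) != 1:
        raise ValueError(f"tables of mixed samples passed: {sorted(sample_ids)}")
    values = window_scores(tile_protein(protein, tables, mode), protein.length, w)
    if values.size == 0:
        score, loc = 0.0, 0
    else:
        loc = int(np.argmax(values))  # first index attaining the max
        score = float(values[loc])
    if not np.isfinite(score):
        raise ValueError(f"non-finite score for protein {protein.protein_id!r}")
    return PiwasTrack(sample_ids.pop(), protein.protein_id, w, mode, values, score, loc)


def piwas_score(protein: ProteinRecord, tables: Mapping[int, KmerTable],
                mode: str = NORMALIZED_F, w: int = DEFAULT_WINDOW) -> tuple[float, int]:
    """The protein score and its 0-based argmax window start."""
    t = piwas_track(protein, tables, mode, w)
    return t.score, t.loc


def score_cohort(proteins: Sequence[ProteinRecord],
                 tables_by_sample: Mapping[str, Mapping[int, KmerTable]],
                 mode: str = NORMALIZED_F, w: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Score every sample against every protein.

    Returns a long-form frame (sample_id, protein_id, piwas_score,
    piwas_loc), deterministic given its inputs: rows are ordered by the
    given sample order, then protein order, and the scores themselves do
    not depend on either order.
    """
    _check_mode(mode)
    rows = []
    for sid, tables in tables_by_sample.items():
        g = {k: _g_lookup(t, mode) for k, t in tables.items()}
        for prot in proteins:
            seq, L = prot.sequence, prot.length
            tracks: dict[int, np.ndarray] = {}
            for k in tables:
                if L < k:
                    tracks[k] = np.empty(0)
                    continue
                gk = g[k]
                tracks[k] = np.fromiter(
                    (gk.get(seq[i:i + k], 0.0) for i in range(L - k + 1)),
                    dtype=float, count=L - k + 1,
                )
            values = window_scores(tracks, L, w)
            if values.size == 0:
                score, loc = 0.0, 0
            else:
                loc = int(np.argmax(values))
                score = float(values[loc])
            rows.append((sid, prot.protein_id, score, loc))
    return pd.DataFrame(rows, columns=["sample_id", "protein_id",
                                       "piwas_score", "piwas_loc"])


def extract_epitope(protein: ProteinRecord, loc: int,
                    w: int = DEFAULT_WINDOW) -> str:
    """Peptide under the window starting at ``loc``.

    The window of w+1 6mers spans w+6 residues, so interior windows yield
    (w+6)-residue epitopes — 11 with the default w = 5; windows near the
    C-terminus are truncated.
    """
    L = protein.length
    if not 0 <= loc <= max(L - MIN_K, 0):
        raise ValueError(f"loc {loc} is not a valid window start for length {L}")
    return protein.sequence[loc:loc + min(w + 6, L - loc)]


def dominant_epitopes(protein: ProteinRecord,
                      case_scores: Sequence[float],
                      case_locs: Sequence[int],
                      score_threshold: float = 6.0,
                      w: int = DEFAULT_WINDOW) -> list[tuple[str, int, int]]:
    """Cluster the argmax locations of high-scoring case samples.

    Case samples with score > ``score_threshold`` contribute their argmax
    location; locations are clustered by single linkage on the integer line
    (gap <= w merges).  Each cluster reports (epitope at the modal location,
    modal location, supporting sample count), ordered by support descending
    then location ascending.  Returns [] when no case clears the threshold.
    """
    if len(case_scores) != len(case_locs):
        raise ValueError("case_scores and case_locs differ in length")
    locs = sorted(int(l) for s, l in zip(case_scores, case_locs) if s > score_threshold)
    if not locs:
        return []
    clusters: list[list[int]] = [[locs[0]]]
    for loc in locs[1:]:
        if loc - clusters[-1][-1] <= w:
            clusters[-1].append(loc)
        else:
            clusters.append([loc])
    out = []
    for cluster in clusters:
        counts: dict[int, int] = {}
        for loc in cluster:
            counts[loc] = counts.get(loc, 0) + 1
        modal = min(sorted(counts), key=lambda l: (-counts[l], l))
        out.append((extract_epitope(protein, modal, w), modal, len(cluster)))
    out.sort(key=lambda t: (-t[2], t[1]))
    return out
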