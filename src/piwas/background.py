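"""Control-cohort background and z-normalization of kmer enrichments.

For every kmer the control cohort W defines a vector of enrichment values
C = {E_w(kmer) : w in W}; a control in which the kmer was never observed
contributes E = 0 (absence is a real observation, not missing data).  A
sample's normalized enrichment is the number-of-standard-deviations score

    F = (E - mean(C)) / sd(C)

Kmers whose control standard deviation is (near-)zero would otherwise give
unbounded F; their sd is floored at ``sd_floor``, by default the 1st
percentile of all strictly positive per-kmer sds in the background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .enrichment import KmerTable

logger = logging.getLogger(__name__)

_SD_FLOOR_FALLBACK = 1e-12


@dataclass
class ControlBackground:
    """Per-kmer mean/sd of enrichment across the control cohort.

    Kmers never observed in any control are not stored; they behave as
    mean = 0, sd = 0 (floored) when queried.  ``sd_floor`` is kept per k:
    expected counts — and with them the spread of enrichment values — differ
    by roughly an alphabet factor between 5mers and 6mers, so a single
    pooled floor would leave one k essentially unfloored.
    """

    control_ids: tuple[str, ...]
    mean: dict[str, float]
    sd: dict[str, float]
    sd_floor: dict[int, float]

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)

    def floor_for(self, k: int) -> float:
        return self.sd_floor.get(k, min(self.sd_floor.values(), default=_SD_FLOOR_FALLBACK))

    def effective_sd(self, kmer: str) -> float:
        return max(self.sd.get(kmer, 0.0), self.floor_for(len(kmer)))

    def is_degenerate(self, kmer: str) -> bool:
        """True when the floor (not the observed sd) drives normalization."""
        return self.sd.get(kmer, 0.0) < self.floor_for(len(kmer))

    def normalized_value(self, kmer: str, E: float) -> float:
        return (E - self.mean.get(kmer, 0.0)) / self.effective_sd(kmer)


def build_background(tables: Sequence[KmerTable], *,
                     restrict_to: Iterable[str] | None = None,
                     sd_floor: float | dict[int, float] | None = None,
                     ddof: int = 1) -> ControlBackground:
    """Build the control background from the control samples' kmer tables.

    Parameters
    ----------
    tables
        KmerTables of the control samples, any mix of k values; each
        (sample, k) pair must appear at most once.
    restrict_to
        Optional kmer set (e.g. all kmers of a target proteome) to bound
        memory; kmers outside it are ignored.
    sd_floor
        Override for the degenerate-sd floor: a single value applied to all
        k, or a mapping k -> floor.  Default: per k, the 1st percentile of
        the strictly positive sds among that k's kmers.
    ddof
        Delta degrees of freedom of the standard deviation; 1 (sample sd)
        by default, 0 gives the population convention.
    """
    control_ids: list[str] = []
    seen_pairs: set[tuple[str, int]] = set()
    for t in tables:
        pair = (t.sample_id, t.k)
        if pair in seen_pairs:
            raise ValueError(f"duplicate kmer table for sample {t.sample_id!r}, k={t.k}")
        seen_pairs.add(pair)
        if t.sample_id not in control_ids:
            control_ids.append(t.sample_id)
    n = len(control_ids)
    if n < 2:
        raise ValueError(f"need >= 2 control samples to define a background, got {n}")

    keep = None if restrict_to is None else (
        restrict_to if isinstance(restrict_to, (set, frozenset, dict)) else set(restrict_to)
    )
    sums: dict[str, float] = {}
    sumsqs: dict[str, float] = {}
    for t in tables:
        for kmer, Ev in t.E.items():
            if keep is not None and kmer not in keep:
                continue
            sums[kmer] = sums.get(kmer, 0.0) + Ev
            sumsqs[kmer] = sumsqs.get(kmer, 0.0) + Ev * Ev

    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    denom = n - ddof
    for kmer, s in sums.items():
        m = s / n
        var = (sumsqs[kmer] - n * m * m) / denom
        mean[kmer] = m
        sd[kmer] = float(np.sqrt(max(var, 0.0)))

    ks = sorted({t.k for t in tables})
    if isinstance(sd_floor, dict):
        floors = {int(k): float(v) for k, v in sd_floor.items()}
    elif sd_floor is not None:
        floors = {k: float(sd_floor) for k in ks}
    else:
        floors = {}
        for k in ks:
            positive = np.array([v for km, v in sd.items()
                                 if len(km) == k and v > 0.0])
            if positive.size:
                floors[k] = float(np.percentile(positive, 1.0))
            else:
                floors[k] = _SD_FLOOR_FALLBACK
                logger.warning("background has no k=%d kmer with positive sd; "
                               "sd floor falls back to %g", k, _SD_FLOOR_FALLBACK)
    if any(v <= 0 for v in floors.values()):
        raise ValueError("sd_floor must be positive")

    return ControlBackground(tuple(control_ids), mean, sd, floors)


def normalize(table: KmerTable, bg: ControlBackground, *,
              restrict_to: Iterable[str] | None = None) -> KmerTable:
    """Return a copy of ``table`` with F = (E - mean)/max(sd, sd_floor).

    F is computed over the union of the sample's kmers and the background's
    kmers of the same k (sample-absent kmers enter with E = 0).  With
    ``restrict_to`` the union is intersected with the given kmer set, the
    usual choice being the kmers of the target proteome.
    """
    keep = None if restrict_to is None else (
        restrict_to if isinstance(restrict_to, (set, frozenset, dict)) else set(restrict_to)
    )
    kmers = set(table.E)
    kmers.update(km for km in bg.mean if len(km) == table.k)
    if keep is not None:
        kmers &= set(keep)
    degenerate = 0
    F: dict[str, float] = {}
    for km in sorted(kmers):
        if bg.is_degenerate(km):
            degenerate += 1
        F[km] = bg.normalized_value(km, table.E.get(km, 0.0))
    if degenerate:
        logger.debug("%s k=%d: %d kmers normalized with the sd floor",
                     table.sample_id, table.k, degenerate)
    return replace(table, F=F)
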