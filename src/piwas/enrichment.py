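"""Per-sample kmer enrichment from 12mer peptide read sets.

Each unique 12mer read is decomposed into its constituent 5mers and 6mers.
For a sample S and a kmer, the observed count ``n`` is the number of unique
12mers containing that kmer at least once, the expected count under the
sample's amino-acid composition is

    e = N_S * (L_seq - k + 1) * prod_i p_i

where ``N_S`` is the number of unique 12mers, ``L_seq`` = 12 is the read
length and ``p_i`` the proportion of the kmer's i-th letter among all
residues of all reads.  Enrichment is ``E = n / e``.  Only observed kmers
(``n >= 1``) are materialized; an unobserved kmer has an implicit ``E = 0``.

``N_S`` deliberately counts *unique* 12mers, matching the definition of
``n`` (duplicated reads carry no extra information after library selection
and sequencing).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io import READ_LENGTH, ReadSet

logger = logging.getLogger(__name__)

#: The kmer sizes the method tiles onto proteins.
DEFAULT_KS: tuple[int, ...] = (5, 6)


class InestimableKmerError(ValueError):
    """A kmer's expected count is zero because a letter never occurs in the sample."""


@dataclass
class KmerTable:
    """One sample's kmer -> (n, e, E[, F]) map for a single k.

    ``F`` (the control-normalized enrichment) is ``None`` until the table is
    normalized against a :class:`~piwas.background.ControlBackground`; after
    normalization its keys may be a superset of ``E``'s (background kmers the
    sample never observed enter with ``E = 0``).
    """

    sample_id: str
    k: int
    n: dict[str, int]
    e: dict[str, float]
    E: dict[str, float]
    aa_freqs: dict[str, float]
    read_count: int
    read_length: int = READ_LENGTH
    F: dict[str, float] | None = None

    def enrichment(self, kmer: str) -> float:
        """E for a kmer; unobserved kmers return 0."""
        return self.E.get(kmer, 0.0)

    def restricted(self, kmers: Iterable[str]) -> "KmerTable":
        """Copy of this table keeping only the given kmers.

        Used to bound memory when only kmers occurring in a target proteome
        matter downstream.
        """
        keep = [km for km in kmers if km in self.E] if not isinstance(kmers, (set, frozenset, dict)) \
            else [km for km in self.E if km in kmers]
        return replace(
            self,
            n={km: self.n[km] for km in keep},
            e={km: self.e[km] for km in keep},
            E={km: self.E[km] for km in keep},
            F=None if self.F is None else {km: self.F[km] for km in self.F if km in kmers},
        )


def decompose(read: str, k: int, *, allow_any_k: bool = False) -> list[str]:
    """All consecutive kmers of a 12mer read, in position order.

    Returns the ``L_seq - k + 1`` windows (8 for k=5, 7 for k=6); duplicates
    are retained — per-read uniqueness is the caller's concern.
    """
    if len(read) != READ_LENGTH:
        raise ValueError(f"read {read!r} does not have length {READ_LENGTH}")
    if k not in DEFAULT_KS and not allow_any_k:
        raise ValueError(f"k must be one of {DEFAULT_KS}, got {k}")
    if not 1 <= k <= len(read):
        raise ValueError(f"k={k} out of range for read length {len(read)}")
    return [read[i:i + k] for i in range(len(read) - k + 1)]


def aa_frequencies(reads: ReadSet) -> dict[str, float]:
    """Amino-acid proportions over all positions of all unique reads."""
    if reads.n_reads == 0:
        raise ValueError("cannot compute amino-acid frequencies of an empty read set")
    counts: Counter[str] = Counter()
    for read in reads.reads:
        counts.update(read)
    total = sum(counts.values())
    return {aa: counts[aa] / total for aa in sorted(counts)}


def expected_count(kmer: str, reads: ReadSet,
                   aa_freqs: Mapping[str, float] | None = None) -> float:
    """Expected kmer count under the sample's letter composition.

    Raises :class:`InestimableKmerError` if a letter of the kmer has zero
    proportion in the sample (the expected count would be 0 and enrichment
    undefined); this can only happen for externally supplied query kmers,
    never for observed ones.
    """
    if aa_freqs is None:
        aa_freqs = aa_frequencies(reads)
    prod = 1.0
    for letter in kmer:
        p = aa_freqs.get(letter, 0.0)
        if p <= 0.0:
            raise InestimableKmerError(
                f"kmer {kmer!r}: letter {letter!r} has zero proportion in "
                f"sample {reads.sample_id!r}"
            )
        prod *= p
    return reads.n_reads * (READ_LENGTH - len(kmer) + 1) * prod


def enrich(reads: ReadSet, ks: Sequence[int] = DEFAULT_KS) -> dict[int, KmerTable]:
    """Compute the full per-kmer enrichment table of one sample.

    Returns one :class:`KmerTable` per requested k.  ``n`` counts unique
    12mers containing the kmer at least once (a kmer occurring twice in one
    read still contributes 1); ``E = n / e``.
    """
    freqs = aa_frequencies(reads)
    n_windows = {k: READ_LENGTH - k + 1 for k in ks}
    tables: dict[int, KmerTable] = {}
    for k in ks:
        counts: Counter[str] = Counter()
        for read in reads.reads:
            counts.update(set(decompose(read, k)))
        e: dict[str, float] = {}
        E: dict[str, float] = {}
        base = reads.n_reads * n_windows[k]
        for kmer, n in counts.items():
            prod = 1.0
            for letter in kmer:
                prod *= freqs[letter]
            ek = base * prod
            e[kmer] = ek
            E[kmer] = n / ek
        tables[k] = KmerTable(
            sample_id=reads.sample_id,
            k=k,
            n=dict(counts),
            e=e,
            E=E,
            aa_freqs=freqs,
            read_count=reads.n_reads,
        )
    return tables


def log_enrichment(table: KmerTable, kmer: str, floor: float = 1e-12) -> float:
    """log10 enrichment for reporting/plotting; E is floored to stay finite."""
    return math.log10(max(table.enrichment(kmer), floor))
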