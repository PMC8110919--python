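"""Case-vs-control statistics over per-protein score distributions.

The primary ranking statistic is the outlier sum of Tibshirani & Hastie:
case and control scores are pooled, standardized by the combined median and
scaled MAD, and the case values strictly above the upper outer fence
(q75 + IQR of the standardized pool) are summed.  Its null distribution is
obtained from random case/control relabellings; since the statistic is a
sum of i.i.d. contributions the permutation z-score is converted to an
upper-tail normal p-value, and Benjamini-Hochberg FDR is applied across the
proteome.  Mann-Whitney U, two-sample Kolmogorov-Smirnov (on scores and on
epitope locations) and Hedges' g complete the per-protein summary.

Standardization and the fence depend only on the pooled multiset of values
and are therefore invariant under relabelling; the permutation null is
computed as vectorized subset sums of the once-standardized pool, which is
exactly equivalent to recomputing the full statistic per permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import DEFAULT_WINDOW, dominant_epitopes
from .io import CASE, ProteinRecord, SampleManifest

logger = logging.getLogger(__name__)

#: Consistency constant making the MAD estimate the sd under normality.
MAD_SCALE = 1.4826

DEFAULT_N_PERM = 1000


@dataclass(frozen=True)
class OutlierSumNull:
    """Permutation-null summary of the outlier sum for one protein."""

    observed: float
    null_mean: float
    null_sd: float
    os_z: float
    os_p: float
    degenerate: bool = False


def _standardized_fence(combined: np.ndarray) -> tuple[np.ndarray, float]:
    """Median/MAD-standardized pool and its upper outer fence."""
    med = np.median(combined)
    mad = MAD_SCALE * np.median(np.abs(combined - med))
    if mad == 0.0:
        # Degenerate spread; an epsilon-scale floor keeps z finite.
        mad = np.finfo(float).eps * max(1.0, float(np.max(np.abs(combined))))
        logger.debug("outlier sum: MAD is 0, floored at %g", mad)
    z = (combined - med) / mad
    q75, q25 = np.percentile(z, [75.0, 25.0])  # linear-interpolation quartiles
    return z, float(q75 + (q75 - q25))


def outlier_sum(case: Sequence[float], control: Sequence[float]) -> float:
    """Sum of standardized CASE values strictly above the upper fence."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0:
        raise ValueError("outlier sum needs at least one case value")
    if case.size + control.size < 2:
        raise ValueError("outlier sum needs at least two values in total")
    z, fence = _standardized_fence(np.concatenate([case, control]))
    zc = z[:case.size]
    return float(zc[zc > fence].sum())


def permutation_null(case: Sequence[float], control: Sequence[float],
                     n_perm: int = DEFAULT_N_PERM,
                     rng: np.random.Generator | int | None = None) -> OutlierSumNull:
    """Permutation null of the outlier sum and its CLT normal-tail p-value.

    Case/control labels are uniformly re-assigned preserving group sizes;
    the z-score of the observed statistic against the permutation mean/sd
    (ddof=1) is mapped to a one-sided upper-tail normal probability — the
    outlier sum only detects case-upward signal.  A null with zero spread is
    flagged degenerate and reported with p = 1.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(rng)
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    observed = outlier_sum(case, control)

    z, fence = _standardized_fence(np.concatenate([case, control]))
    contrib = np.where(z > fence, z, 0.0)
    n, n_case = z.size, case.size
    # Random relabellings = random size-n_case index subsets.
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_case]
    null = contrib[order].sum(axis=1)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0.0:
        return OutlierSumNull(observed, null_mean, 0.0, 0.0, 1.0, degenerate=True)
    os_z = (observed - null_mean) / null_sd
    return OutlierSumNull(observed, null_mean, null_sd, os_z,
                          float(sps.norm.sf(os_z)))


def mann_whitney(case: Sequence[float], control: Sequence[float],
                 alternative: str = "greater") -> float:
    """Mann-Whitney U p-value (one-sided case > control by default).

    Exact enumeration for small tie-free groups (< 8 per group); otherwise
    the tie-corrected, continuity-corrected normal approximation.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("Mann-Whitney needs non-empty groups")
    pooled = np.concatenate([case, control])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(case.size, control.size) < 8 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(case, control, alternative=alternative, method=method)
    return float(res.pvalue)


def ks_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided two-sample Kolmogorov-Smirnov p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test needs non-empty samples")
    return float(sps.ks_2samp(x, y, alternative="two-sided", method="auto").pvalue)


def hedges_g(case: Sequence[float], control: Sequence[float]) -> float:
    """Hedges' g: pooled-sd standardized mean difference with the
    small-sample correction J = 1 - 3 / (4 (n1 + n2) - 9).

    Returns NaN when the pooled sd is zero (effect size undefined).
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = case.size, control.size
    if n1 < 2 or n2 < 2:
        raise ValueError("Hedges' g needs >= 2 values per group")
    sp2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0.0:
        logger.debug("Hedges' g undefined: pooled sd is 0")
        return float("nan")
    d = (case.mean() - control.mean()) / np.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(j * d)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _protein_rng(seed: int, index: int) -> np.random.Generator:
    """Per-protein RNG stream independent of evaluation order."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(index,)))


def rank_proteome(scores: pd.DataFrame, manifest: SampleManifest,
                  n_perm: int = DEFAULT_N_PERM, seed: int = 0, *,
                  proteins: Sequence[ProteinRecord] | None = None,
                  score_threshold: float = 6.0,
                  w: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Full per-protein statistics table, ranked for antigen discovery.

    ``scores`` is the long-form (sample_id, protein_id, piwas_score,
    piwas_loc) matrix.  Per-protein permutation streams derive from
    ``(seed, rank of protein_id)`` so the output is identical under any
    reordering of proteins or manifest rows; group score vectors are sorted
    before testing for the same reason (every statistic used is
    exchangeable within a group).  When ``proteins`` is given, dominant
    epitopes of high-scoring case samples are reported per protein.

    The table is sorted by os_fdr ascending, then os_z descending.
    Proteins whose scores are all zero in both cohorts carry p = 1
    throughout rather than being dropped.
    """
    cohorts = {sid: manifest.cohort_of(sid) for sid in manifest.sample_ids}
    unknown = set(scores["sample_id"]) - set(cohorts)
    if unknown:
        raise ValueError(f"scores contain samples absent from the manifest: {sorted(unknown)}")
    missing = set(cohorts) - set(scores["sample_id"])
    if missing:
        raise ValueError(f"manifest samples missing from the scores: {sorted(missing)}")
    by_protein = {pid: g for pid, g in scores.groupby("protein_id", sort=False)}
    protein_ids = list(by_protein)
    order_index = {pid: i for i, pid in enumerate(sorted(protein_ids))}
    prot_records = {p.protein_id: p for p in proteins} if proteins is not None else {}

    rows = []
    for pid in protein_ids:
        g = by_protein[pid]
        is_case = g["sample_id"].map(cohorts) == CASE
        case_scores = g.loc[is_case, "piwas_score"].to_numpy(dtype=float)
        ctrl_scores = g.loc[~is_case, "piwas_score"].to_numpy(dtype=float)
        case_locs = g.loc[is_case, "piwas_loc"].to_numpy(dtype=int)
        ctrl_locs = g.loc[~is_case, "piwas_loc"].to_numpy(dtype=int)

        all_zero = not (np.any(case_scores) or np.any(ctrl_scores))
        if all_zero:
            null = OutlierSumNull(0.0, 0.0, 0.0, 0.0, 1.0, degenerate=True)
            mw_p = ks_p = loc_ks_p = 1.0
            g_eff = float("nan")
        else:
            rng = _protein_rng(seed, order_index[pid])
            null = permutation_null(np.sort(case_scores), np.sort(ctrl_scores),
                                    n_perm=n_perm, rng=rng)
            mw_p = mann_whitney(case_scores, ctrl_scores)
            ks_p = ks_test(case_scores, ctrl_scores)
            loc_ks_p = ks_test(case_locs, ctrl_locs)
            g_eff = hedges_g(case_scores, ctrl_scores)

        epitopes: list[tuple[str, int, int]] = []
        if pid in prot_records:
            epitopes = dominant_epitopes(prot_records[pid], case_scores,
                                         case_locs, score_threshold, w)
        rows.append({
            "protein_id": pid,
            "outlier_sum": null.observed,
            "os_null_mean": null.null_mean,
            "os_null_sd": null.null_sd,
            "os_z": null.os_z,
            "os_p": null.os_p,
            "mw_p": mw_p,
            "ks_p": ks_p,
            "hedges_g": g_eff,
            "loc_ks_p": loc_ks_p,
            "dominant_epitopes": ";".join(e for e, _, _ in epitopes),
            "dominant_locs": ";".join(str(l) for _, l, _ in epitopes),
        })
    table = pd.DataFrame(rows)
    table["os_fdr"] = fdr_adjust(table["os_p"].to_numpy())
    table = table.sort_values(
        ["os_fdr", "os_z", "protein_id"], ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return table[[
        "protein_id", "outlier_sum", "os_null_mean", "os_null_sd", "os_z",
        "os_p", "os_fdr", "mw_p", "ks_p", "hedges_g", "loc_ks_p",
        "dominant_epitopes", "dominant_locs",
    ]]


def distribution_summary(values_by_sample: Mapping[str, Sequence[float]],
                         bins: int | Sequence[float] = 50) -> pd.DataFrame:
    """Per-sample histogram of score (or log-enrichment) values.

    A shared set of bin edges covering the pooled range is used for every
    sample so the per-sample distributions are directly comparable; counts
    include both boundary values, so they sum to each sample's value count.
    """
    pooled = np.concatenate([np.asarray(v, dtype=float)
                             for v in values_by_sample.values()])
    if pooled.size == 0:
        raise ValueError("no values to summarize")
    if np.isscalar(bins):
        lo, hi = float(pooled.min()), float(pooled.max())
        if lo == hi:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    rows = []
    for sid, vals in values_by_sample.items():
        counts, _ = np.histogram(np.asarray(vals, dtype=float), bins=edges)
        for i, c in enumerate(counts):
            rows.append((sid, edges[i], edges[i + 1], int(c)))
    return pd.DataFrame(rows, columns=["sample_id", "bin_left", "bin_right", "count"])
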