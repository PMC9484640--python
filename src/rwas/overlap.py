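"""Observed-versus-expected overlap tests via blacklist-aware shuffling.

Counts how many feature elements (MPRA SNPs, ChIP-seq peaks...) overlap the
enhancer annotation, then builds the null by repeatedly relocating the
enhancers uniformly over the allowed genome (excluding e.g. the MHC and the
ENCODE blacklist) and recounting.  The empirical p-value uses the add-one
estimator, so it is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .intervals import ChromSizes, IntervalSet, merge_adjacent, shuffle_intervals

logger = logging.getLogger(__name__)


@dataclass
class OverlapTestResult:
    """Result of a permutation overlap test."""

    observed: int
    expected_mean: float
    expected_sd: float
    n_perm: int
    empirical_p: float
    enrichment: float
    direction: str
    perm_counts: np.ndarray | None = None

    def summary(self) -> str:
        return (
            f"observed {self.observed} vs expected "
            f"{self.expected_mean:.2f} +/- {self.expected_sd:.2f} "
            f"({self.n_perm} permutations); "
            f"{self.direction} p = {self.empirical_p:.4g}, "
            f"enrichment = {self.enrichment:.3f}"
        )


def observed_overlap(features: IntervalSet, enhancers: IntervalSet) -> int:
    """Number of feature elements overlapping >= 1 enhancer by >= 1 bp."""
    if len(features) == 0 or len(enhancers) == 0:
        return 0
    enh = merge_adjacent(enhancers)
    count = 0
    edf = enh.df
    for chrom, sub in features.df.groupby("chrom", sort=False):
        esub = edf[edf["chrom"] == chrom]
        if esub.empty:
            continue
        es = esub["start"].to_numpy()
        ee = esub["end"].to_numpy()
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        k = np.searchsorted(es, e, side="left") - 1
        hit = (k >= 0) & (ee[np.maximum(k, 0)] > s)
        count += int(hit.sum())
    return count


def permutation_test(features: IntervalSet, enhancers: IntervalSet,
                     sizes: ChromSizes,
                     exclusion: IntervalSet | None = None,
                     n_perm: int = 1000, rng_seed: int = 0,
                     direction: str = "enrichment",
                     shuffle_features: bool = False,
                     keep_perm_counts: bool = False) -> OverlapTestResult:
    """Permutation overlap test, shuffling the enhancer annotation.

    Per permutation the enhancers are uniformly relocated (features stay
    fixed; flip with ``shuffle_features=True``) and the overlap recount
    forms the null.  ``empirical_p = (1 + #{perm >= obs}) / (n_perm + 1)``
    for enrichment, with ``<=`` for depletion.  Fully seed-deterministic.
    """
    if direction not in ("enrichment", "depletion"):
        raise ValueError(f"unknown direction {direction!r}")
    obs = observed_overlap(features, enhancers)
    rng = np.random.default_rng(rng_seed)
    moving, fixed = ((features, enhancers) if shuffle_features
                     else (enhancers, features))
    counts = _permuted_counts(moving, fixed, sizes, exclusion, n_perm, rng,
                              count_moving=shuffle_features)
    if direction == "enrichment":
        exceed = int(np.count_nonzero(counts >= obs))
    else:
        exceed = int(np.count_nonzero(counts <= obs))
    p = (1 + exceed) / (n_perm + 1)
    mean = float(counts.mean())
    enrichment = obs / mean if mean > 0 else np.inf
    return OverlapTestResult(
        observed=obs, expected_mean=mean, expected_sd=float(counts.std(ddof=1)),
        n_perm=n_perm, empirical_p=p, enrichment=enrichment,
        direction=direction, perm_counts=counts if keep_perm_counts else None)


_MAX_ATTEMPTS = 10_000


def _merge_runs(starts: np.ndarray, ends: np.ndarray):
    """Vectorized sweep-merge of intervals into disjoint sorted runs."""
    order = np.argsort(starts, kind="stable")
    s = starts[order]
    e = np.maximum.accumulate(ends[order])
    if len(s) == 0:
        return s, e
    brk = np.flatnonzero(np.r_[True, s[1:] > e[:-1]])
    ms = s[brk]
    me = e[np.r_[brk[1:] - 1, len(s) - 1]]
    return ms, me


def _count_hits(qs: np.ndarray, qe: np.ndarray, ms: np.ndarray,
                me: np.ndarray) -> int:
    """Query elements overlapping >= 1 bp of the merged runs."""
    if len(ms) == 0 or len(qs) == 0:
        return 0
    k = np.searchsorted(ms, qe, side="left") - 1
    hit = (k >= 0) & (me[np.maximum(k, 0)] > qs)
    return int(hit.sum())


def _permuted_counts(moving: IntervalSet, fixed: IntervalSet,
                     sizes: ChromSizes, exclusion: IntervalSet | None,
                     n_perm: int, rng: np.random.Generator,
                     count_moving: bool) -> np.ndarray:
    """Null overlap counts, relocating ``moving`` uniformly per permutation.

    Same placement semantics as :func:`rwas.intervals.shuffle_intervals`
    (chromosome and length preserved, exclusion-free starts, rejection
    sampling), but the whole permutation loop runs on flat arrays.
    """
    exc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if exclusion is not None and len(exclusion):
        for chrom, sub in merge_adjacent(exclusion).df.groupby("chrom",
                                                               sort=False):
            exc[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    fixed_by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in fixed.df.groupby("chrom", sort=False)
    }
    mov_by_chrom = {
        chrom: (sub["end"] - sub["start"]).to_numpy()
        for chrom, sub in moving.df.groupby("chrom", sort=False)
    }
    counts = np.zeros(n_perm, dtype=np.int64)
    for chrom, lengths in mov_by_chrom.items():
        if chrom not in sizes:
            raise ValueError(f"no chromosome size for {chrom}")
        L = sizes[chrom]
        es, ee = exc.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        fs, fe = fixed_by_chrom.get(chrom,
                                    (np.empty(0, np.int64), np.empty(0, np.int64)))
        if len(fs):
            fms, fme = _merge_runs(fs, fe)
        n = len(lengths)
        for i in range(n_perm):
            starts = np.empty(n, dtype=np.int64)
            pending = np.arange(n)
            for _ in range(_MAX_ATTEMPTS):
                if len(pending) == 0:
                    break
                cand = rng.integers(0, L - lengths[pending] + 1)
                if len(es):
                    j = np.searchsorted(es, cand + lengths[pending],
                                        side="left") - 1
                    bad = (j >= 0) & (ee[np.maximum(j, 0)] > cand)
                else:
                    bad = np.zeros(len(pending), dtype=bool)
                starts[pending[~bad]] = cand[~bad]
                pending = pending[bad]
            if len(pending):
                raise RuntimeError(
                    f"could not place an interval on {chrom} after "
                    f"{_MAX_ATTEMPTS} attempts")
            if len(fs) == 0:
                continue
            ends = starts + lengths
            if count_moving:
                counts[i] += _count_hits(starts, ends, fms, fme)
            else:
                ms, me = _merge_runs(starts, ends)
                counts[i] += _count_hits(fs, fe, ms, me)
    return counts
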