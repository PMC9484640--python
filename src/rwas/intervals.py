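"""Genomic interval engine.

Everything downstream of the ChromHMM segmentations runs through this module:
pooling enhancer states, merging adjacent annotations, normalizing merged
regions to fixed-width centroids, removing blacklisted regions, base-pair
Jaccard similarity between annotations, nearest-feature distances, binary
overlap flags, and blacklist-aware uniform shuffles for permutation nulls.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
Positions read from 1-based sources (SNP tables, TSS tables) are converted
on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COLUMNS = ["chrom", "start", "end", "id", "label", "score"]


@dataclass(frozen=True)
class GenomeInterval:
    """A single genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    id: str
    label: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp."""

    @classmethod
    def read(cls, path) -> "ChromSizes":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                         dtype={"chrom": str, "length": np.int64})
        if (df["length"] <= 0).any():
            raise ValueError(f"non-positive chromosome length in {path}")
        return cls(zip(df["chrom"], df["length"]))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.items():
                fh.write(f"{chrom}\t{length}\n")


class IntervalSet:
    """A named collection of genomic intervals backed by a DataFrame.

    The frame always carries columns ``chrom, start, end, id, label, score``;
    ``label``/``score`` may be all-NA.  Interval ids are unique.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True,
                 sizes: ChromSizes | None = None):
        df = df.copy()
        if "id" not in df.columns or df["id"].isna().all():
            df["id"] = _auto_ids(df)
        for col in ("label", "score"):
            if col not in df.columns:
                df[col] = pd.NA if col == "label" else np.nan
        df = df[_COLUMNS].reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["id"] = df["id"].astype(str)
        if validate:
            bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
            if len(bad):
                row = df.loc[bad[0]]
                raise ValueError(
                    f"invalid interval {row['chrom']}:{row['start']}-{row['end']}"
                )
            if df["id"].duplicated().any():
                dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
                raise ValueError(f"duplicate interval id {dup!r}")
            if sizes is not None:
                for chrom, sub in df.groupby("chrom", sort=False):
                    if chrom in sizes and (sub["end"] > sizes[chrom]).any():
                        raise ValueError(f"interval beyond end of {chrom}")
        self._df = df

    # -- basic container protocol -------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[GenomeInterval]:
        for row in self._df.itertuples(index=False):
            yield GenomeInterval(
                row.chrom, int(row.start), int(row.end), row.id,
                None if pd.isna(row.label) else row.label,
                None if pd.isna(row.score) else float(row.score),
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self._df[["chrom", "start", "end", "id"]]
        b = other._df[["chrom", "start", "end", "id"]]
        return a.equals(b)

    @classmethod
    def from_records(cls, records: Iterable[tuple], **kw) -> "IntervalSet":
        """Build from (chrom, start, end[, id[, label[, score]]]) tuples."""
        rows = [tuple(r) + (None,) * (6 - len(r)) for r in records]
        df = pd.DataFrame(rows, columns=_COLUMNS)
        return cls(df, **kw)

    def sort(self) -> "IntervalSet":
        df = self._df.sort_values(["chrom", "start", "end"], kind="mergesort")
        return IntervalSet(df, validate=False)

    def total_bp(self) -> int:
        """Base pairs covered by the union of the intervals."""
        m = merge_adjacent(self)
        return int((m.df["end"] - m.df["start"]).sum())


def _auto_ids(df: pd.DataFrame) -> pd.Series:
    base = (df["chrom"].astype(str) + ":" + df["start"].astype(str)
            + "-" + df["end"].astype(str))
    if base.duplicated().any():
        suffix = base.groupby(base).cumcount()
        base = base.where(suffix == 0, base + "." + suffix.astype(str))
    return base


# ---------------------------------------------------------------------------
# BED input / output
# ---------------------------------------------------------------------------

def read_bed(path) -> IntervalSet:
    """Read a BED3/BED4/BED6 file into an IntervalSet.

    Column 4 (if present) becomes the interval id, column 5 the score and
    column 6 is ignored (strand).  Malformed lines raise with their line
    number.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid coordinates {start}-{end}"
                )
            iid = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError:
                    score = None
            records.append((chrom, start, end, iid, None, score))
    if not records:
        return IntervalSet(pd.DataFrame(columns=_COLUMNS))
    df = pd.DataFrame(records, columns=_COLUMNS)
    if df["id"].isna().any():
        df["id"] = df["id"].fillna(_auto_ids(df))
    return IntervalSet(df)


def write_bed(iset: IntervalSet, path, score: bool = False) -> None:
    """Write BED4 (or BED5 with ``score=True``); round-trips with read_bed."""
    cols = ["chrom", "start", "end", "id"] + (["score"] if score else [])
    iset.df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_segmentation(path) -> IntervalSet:
    """Read a ChromHMM segmentation (BED4, state label in column 4)."""
    iset = read_bed(path)
    df = iset.df.copy()
    df["label"] = df["id"]
    df["id"] = _auto_ids(df)
    return IntervalSet(df)


# ---------------------------------------------------------------------------
# Enhancer preprocessing
# ---------------------------------------------------------------------------

def pool_states(segmentation: IntervalSet, keep_states: set[str]) -> IntervalSet:
    """Keep segmentation intervals whose state label is in ``keep_states``.

    This pools the enhancer-like chromatin states of a segmentation into a
    single annotation; labels are dropped, input order preserved.
    """
    if not keep_states:
        raise ValueError("keep_states must be non-empty")
    df = segmentation.df
    if df["label"].isna().any():
        raise ValueError("every interval needs a state label")
    out = df[df["label"].isin(set(keep_states))].copy()
    out["label"] = pd.NA
    return IntervalSet(out, validate=False)


def merge_adjacent(iset: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Fuse overlapping or book-ended intervals (gap <= ``max_gap``) per chrom.

    With ``max_gap=0`` the union of covered bases is preserved exactly.
    Merged intervals get fresh ``chrom:start-end`` ids.
    """
    if len(iset) == 0:
        return iset
    pieces = []
    for chrom, sub in iset.df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        starts = sub["start"].to_numpy()
        ends = np.maximum.accumulate(sub["end"].to_numpy())
        new_grp = np.r_[True, starts[1:] > ends[:-1] + max_gap]
        grp = np.cumsum(new_grp)
        agg = pd.DataFrame({"start": starts, "end": sub["end"].to_numpy(),
                            "id": sub["id"].to_numpy()}) \
            .groupby(grp).agg(start=("start", "min"), end=("end", "max"),
                              id=("id", "first"), n=("id", "size"))
        agg["chrom"] = chrom
        pieces.append(agg[["chrom", "start", "end", "id", "n"]])
    df = pd.concat(pieces, ignore_index=True)
    # singletons keep their id; fused groups get fresh positional ids
    fused = df["n"] > 1
    if fused.any():
        df.loc[fused, "id"] = _auto_ids(df[fused])
    df = df.drop(columns="n")
    return IntervalSet(df, validate=False)


def centroid_normalize(iset: IntervalSet, half_width: int = 500,
                       sizes: ChromSizes | None = None) -> IntervalSet:
    """Replace each merged interval by a fixed-width window on its centre.

    ``[s, e)`` maps to ``[c - half_width, c + half_width)`` with
    ``c = (s + e) // 2``, clipped to the chromosome.  Clipped intervals are
    counted in the log; ids are preserved from the merged input.
    """
    iset = merge_adjacent(iset)
    df = iset.df.copy()
    c = (df["start"] + df["end"]) // 2
    start = c - half_width
    end = c + half_width
    lo = np.zeros(len(df), dtype=np.int64)
    hi = np.full(len(df), np.iinfo(np.int64).max)
    if sizes is not None:
        hi = df["chrom"].map(sizes).fillna(np.iinfo(np.int64).max).astype(np.int64).to_numpy()
    new_start = np.maximum(start.to_numpy(), lo)
    new_end = np.minimum(end.to_numpy(), hi)
    clipped = (new_start != start.to_numpy()) | (new_end != end.to_numpy())
    if clipped.any():
        logger.info("centroid_normalize: clipped %d/%d intervals at chromosome "
                    "edges", int(clipped.sum()), len(df))
    df["start"], df["end"] = new_start, new_end
    return IntervalSet(df, validate=False)


def exclude_regions(iset: IntervalSet, exclusion: IntervalSet,
                    mode: str = "any_overlap") -> IntervalSet:
    """Drop intervals hitting the exclusion set (MHC, ENCODE blacklist...).

    ``mode="any_overlap"`` (default) drops on >= 1 bp overlap;
    ``mode="containment"`` drops only intervals fully inside an exclusion
    interval.
    """
    if len(iset) == 0 or len(exclusion) == 0:
        return iset
    exc = merge_adjacent(exclusion)
    keep = np.ones(len(iset), dtype=bool)
    df = iset.df
    for chrom, sub in exc.df.groupby("chrom", sort=False):
        sel = df["chrom"] == chrom
        if not sel.any():
            continue
        s = df.loc[sel, "start"].to_numpy()
        e = df.loc[sel, "end"].to_numpy()
        es = sub["start"].to_numpy()
        ee = sub["end"].to_numpy()
        # runs are disjoint and sorted: the only candidate is the last run
        # starting before the query end
        k = np.searchsorted(es, e, side="left") - 1
        cand_end = ee[np.maximum(k, 0)]
        if mode == "any_overlap":
            hit = (k >= 0) & (cand_end > s)
        elif mode == "containment":
            hit = (k >= 0) & (es[np.maximum(k, 0)] <= s) & (cand_end >= e)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        keep[np.flatnonzero(sel.to_numpy())[hit]] = False
    dropped = int((~keep).sum())
    if dropped:
        logger.info("exclude_regions: dropped %d/%d intervals", dropped, len(iset))
    return IntervalSet(df[keep], validate=False)


def prepare_enhancers(segmentation: IntervalSet, keep_states: set[str],
                      sizes: ChromSizes | None = None,
                      exclusion: IntervalSet | None = None,
                      half_width: int = 500, max_gap: int = 0) -> IntervalSet:
    """Pool -> merge -> centroid-normalize -> exclude, the standard pipeline."""
    enh = pool_states(segmentation, keep_states)
    enh = merge_adjacent(enh, max_gap=max_gap)
    enh = centroid_normalize(enh, half_width=half_width, sizes=sizes)
    if exclusion is not None:
        enh = exclude_regions(enh, exclusion)
    return enh


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def _intersect_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Base pairs shared by two merged interval sets."""
    total = 0
    bd = b.df
    for chrom, sub in a.df.groupby("chrom", sort=False):
        other = bd[bd["chrom"] == chrom]
        if other.empty:
            continue
        s1, e1 = sub["start"].to_numpy(), sub["end"].to_numpy()
        s2, e2 = other["start"].to_numpy(), other["end"].to_numpy()
        i, j = 0, 0
        while i < len(s1) and j < len(s2):
            lo = max(s1[i], s2[j])
            hi = min(e1[i], e2[j])
            if hi > lo:
                total += hi - lo
            if e1[i] <= e2[j]:
                i += 1
            else:
                j += 1
    return total


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Base-pair Jaccard index |A ∩ B| / |A ∪ B| of two annotations."""
    am, bm = merge_adjacent(a), merge_adjacent(b)
    abp = int((am.df["end"] - am.df["start"]).sum())
    bbp = int((bm.df["end"] - bm.df["start"]).sum())
    inter = _intersect_bp(am, bm)
    union = abp + bbp - inter
    if union == 0:
        raise ValueError("Jaccard undefined: both interval sets are empty")
    return inter / union


def jaccard_matrix(sets: Sequence[IntervalSet],
                   names: Sequence[str] | None = None,
                   n_groups: int = 2):
    """Pairwise Jaccard matrix plus average-linkage hierarchical grouping.

    Returns ``(matrix, linkage, groups)`` where ``matrix`` is a DataFrame
    with unit diagonal, ``linkage`` the scipy linkage array computed on
    distance 1 - J, and ``groups`` the flat cluster labels when the tree is
    cut into ``n_groups`` clusters.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n = len(sets)
    if n < 2:
        raise ValueError("need at least two interval sets")
    if names is None:
        names = [f"set{i}" for i in range(n)]
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            J[i, j] = J[j, i] = jaccard(sets[i], sets[j])
    D = squareform(1.0 - J, checks=False)
    Z = linkage(D, method="average")
    groups = fcluster(Z, t=n_groups, criterion="maxclust")
    mat = pd.DataFrame(J, index=list(names), columns=list(names))
    return mat, Z, groups


# ---------------------------------------------------------------------------
# Distances and flags
# ---------------------------------------------------------------------------

def nearest_distance(iset: IntervalSet, points: IntervalSet) -> pd.Series:
    """Unsigned bp distance from each interval to its nearest feature.

    0 if they overlap; the gap (``other.start - interval.end`` or vice
    versa) otherwise.  Intervals on chromosomes without any feature get NaN.
    """
    out = pd.Series(np.nan, index=iset.df["id"], name="distance")
    pdf = points.df
    for chrom, sub in iset.df.groupby("chrom", sort=False):
        feats = pdf[pdf["chrom"] == chrom].sort_values("start")
        if feats.empty:
            continue
        fs = feats["start"].to_numpy()
        fe = np.maximum.accumulate(feats["end"].to_numpy())
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        n = len(fs)
        # last feature starting before the query end
        k = np.searchsorted(fs, e, side="left") - 1
        has_left = k >= 0
        kk = np.maximum(k, 0)
        overlap = has_left & (fe[kk] > s)
        left = np.where(has_left, s - fe[kk], np.inf)
        ridx = np.minimum(k + 1, n - 1)
        right = np.where(k + 1 < n, fs[ridx] - e, np.inf)
        d = np.where(overlap, 0.0, np.maximum(np.minimum(left, right), 0.0))
        out.loc[sub["id"].to_numpy()] = d
    return out


def points_from_positions(chroms: Sequence[str], pos_1based: Sequence[int],
                          ids: Sequence[str] | None = None) -> IntervalSet:
    """1-bp intervals from 1-based positions (SNPs, TSSs)."""
    pos = np.asarray(pos_1based, dtype=np.int64) - 1
    df = pd.DataFrame({"chrom": list(chroms), "start": pos, "end": pos + 1})
    if ids is not None:
        df["id"] = list(ids)
    return IntervalSet(df)


def overlap_flag(iset: IntervalSet, features: IntervalSet, expand: int = 0,
                 mode: str = "overlap", distance: int = 0) -> pd.Series:
    """Binary per-interval flag against a feature set.

    ``mode="overlap"``: grow features by ``expand`` bp on both sides, flag on
    >= 1 bp overlap.  ``mode="within_distance"``: flag when the nearest
    feature is at most ``distance`` bp away (boundary inclusive).
    """
    if expand < 0:
        raise ValueError("expand must be >= 0")
    if mode == "overlap":
        fdf = features.df.copy()
        fdf["start"] = np.maximum(fdf["start"] - expand, 0)
        fdf["end"] = fdf["end"] + expand
        grown = IntervalSet(fdf, validate=False)
        d = nearest_distance(iset, grown)
        flag = (d == 0)
    elif mode == "within_distance":
        d = nearest_distance(iset, features)
        flag = (d <= distance)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return flag.fillna(False).astype(int)


# ---------------------------------------------------------------------------
# Shuffling
# ---------------------------------------------------------------------------

_MAX_ATTEMPTS = 10_000


def shuffle_intervals(iset: IntervalSet, sizes: ChromSizes,
                      exclusion: IntervalSet | None = None,
                      rng_seed: int | np.random.Generator = 0) -> IntervalSet:
    """Uniformly relocate each interval on its own chromosome.

    Each interval keeps its chromosome and length; the new start is uniform
    over positions where the interval overlaps no exclusion base and stays
    within the chromosome.  Relocated intervals may overlap each other.
    Rejection sampling, capped at 10,000 attempts per interval.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    exc_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if exclusion is not None and len(exclusion):
        for chrom, sub in merge_adjacent(exclusion).df.groupby("chrom", sort=False):
            exc_by_chrom[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())

    df = iset.df.copy()
    new_starts = np.empty(len(df), dtype=np.int64)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in sizes:
            raise ValueError(f"no chromosome size for {chrom}")
        L = sizes[chrom]
        lengths = (sub["end"] - sub["start"]).to_numpy()
        if (lengths > L).any():
            bad = sub.loc[(sub["end"] - sub["start"]) > L, "id"].iloc[0]
            raise ValueError(f"interval {bad!r} longer than chromosome {chrom}")
        es, ee = exc_by_chrom.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        idx = np.flatnonzero((df["chrom"] == chrom).to_numpy())
        pending = np.arange(len(lengths))
        starts = np.empty(len(lengths), dtype=np.int64)
        for _ in range(_MAX_ATTEMPTS):
            if len(pending) == 0:
                break
            cand = rng.integers(0, L - lengths[pending] + 1)
            if len(es):
                # overlap iff an exclusion run starts before cand+len and ends after cand
                j = np.searchsorted(es, cand + lengths[pending], side="left") - 1
                bad = (j >= 0) & (ee[np.maximum(j, 0)] > cand)
            else:
                bad = np.zeros(len(pending), dtype=bool)
            starts[pending[~bad]] = cand[~bad]
            pending = pending[bad]
        if len(pending):
            iid = sub["id"].iloc[pending[0]]
            raise RuntimeError(
                f"could not place interval {iid!r} after {_MAX_ATTEMPTS} attempts"
            )
        new_starts[idx] = starts
    df["end"] = new_starts + (df["end"] - df["start"])
    df["start"] = new_starts
    return IntervalSet(df, validate=False)
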