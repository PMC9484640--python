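"""Per-enhancer covariates for property association testing.

AT richness from genome sequence, mean evolutionary-conservation score from
a sparse per-base track, distance to the nearest TSS, binary flags for
overlap with human accelerated regions (HARs) and proximity to human-gained
enhancers (HGEs), and per-motif transcription-factor footprint counts with a
total-binding-site control.  Motif AT content is computed from JASPAR-style
position frequency matrices.

Every covariate is a deterministic function of its inputs; missing values
(uncovered track, all-N sequence, no feature on the chromosome) are NaN and
are handled downstream by listwise deletion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomeInterval, IntervalSet, nearest_distance, overlap_flag

logger = logging.getLogger(__name__)

_AT = set("ATat")
_ACGT = set("ACGTacgt")


class SequenceStore:
    """Per-chromosome base access backed by a FASTA file or a dict.

    Lookups are 0-based half-open and case-insensitive; ``N`` is the only
    symbol treated as missing (soft-masked lowercase bases count normally).
    """

    def __init__(self, getter, lengths: dict[str, int]):
        self._get = getter
        self.lengths = lengths

    @classmethod
    def from_fasta(cls, path) -> "SequenceStore":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        lengths = {name: len(fa[name]) for name in fa.keys()}

        def getter(chrom, start, end):
            return str(fa[chrom][start:end])

        return cls(getter, lengths)

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "SequenceStore":
        lengths = {k: len(v) for k, v in seqs.items()}

        def getter(chrom, start, end):
            return seqs[chrom][start:end]

        return cls(getter, lengths)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.lengths[chrom]:
            raise IndexError(
                f"{chrom}:{start}-{end} outside sequence of length "
                f"{self.lengths[chrom]}"
            )
        return self._get(chrom, start, end)


def at_fraction(interval: GenomeInterval, seq: SequenceStore) -> float:
    """(#A + #T) / (#A + #C + #G + #T) over the interval; NaN if all-N."""
    s = seq.fetch(interval.chrom, interval.start, interval.end).upper()
    at = s.count("A") + s.count("T")
    acgt = at + s.count("C") + s.count("G")
    if acgt == 0:
        return float("nan")
    return at / acgt


def gc_fraction(interval: GenomeInterval, seq: SequenceStore) -> float:
    s = seq.fetch(interval.chrom, interval.start, interval.end).upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        return float("nan")
    return gc / acgt


def at_fraction_table(enhancers: IntervalSet, seq: SequenceStore,
                      name: str = "at") -> pd.DataFrame:
    vals = [at_fraction(iv, seq) for iv in enhancers]
    return pd.DataFrame({name: vals}, index=pd.Index(enhancers.df["id"], name="id"))


# ---------------------------------------------------------------------------
# Conservation track
# ---------------------------------------------------------------------------

class BaseScoreTrack:
    """Sparse per-base numeric scores stored as non-overlapping runs.

    The on-disk representations are bedGraph (``chrom start end value``,
    0-based half-open) and fixed-step WIG.
    """

    def __init__(self, runs: pd.DataFrame):
        runs = runs[["chrom", "start", "end", "value"]].copy()
        runs = runs.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, sub in runs.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping runs on {chrom}")
        self.runs = runs
        self._by_chrom = {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(),
                    sub["value"].to_numpy(float))
            for chrom, sub in runs.groupby("chrom", sort=False)
        }

    @classmethod
    def read_bedgraph(cls, path) -> "BaseScoreTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
        return cls(df)

    @classmethod
    def read_wig_fixedstep(cls, path) -> "BaseScoreTrack":
        rows = []
        chrom, pos, step, span = None, 0, 1, 1
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(f.split("=") for f in line.split()[1:])
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1  # wig is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                else:
                    rows.append((chrom, pos, pos + span, float(line)))
                    pos += step
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))

    def write_bedgraph(self, path) -> None:
        self.runs.to_csv(path, sep="\t", header=False, index=False)

    def mean_over(self, chrom: str, start: int, end: int) -> tuple[float, float]:
        """(mean over covered bases, covered fraction) for an interval."""
        if chrom not in self._by_chrom:
            return float("nan"), 0.0
        rs, re_, rv = self._by_chrom[chrom]
        lo = np.searchsorted(re_, start, side="right")
        hi = np.searchsorted(rs, end, side="left")
        if hi <= lo:
            return float("nan"), 0.0
        ov = (np.minimum(re_[lo:hi], end) - np.maximum(rs[lo:hi], start))
        ov = np.maximum(ov, 0)
        covered = int(ov.sum())
        if covered == 0:
            return float("nan"), 0.0
        return float(np.dot(ov, rv[lo:hi]) / covered), covered / (end - start)


def mean_conservation(interval: GenomeInterval, track: BaseScoreTrack,
                      min_cov: float = 0.0) -> float:
    """Arithmetic mean of the track over covered bases of the interval.

    NaN when nothing is covered or the covered fraction is below
    ``min_cov``.  Averaging over covered bases only avoids biasing sparse
    constraint tracks toward zero.
    """
    mean, frac = track.mean_over(interval.chrom, interval.start, interval.end)
    if frac == 0.0 or frac < min_cov:
        return float("nan")
    return mean


def conservation_table(enhancers: IntervalSet, track: BaseScoreTrack,
                       min_cov: float = 0.0,
                       name: str = "conservation") -> pd.DataFrame:
    vals = [mean_conservation(iv, track, min_cov) for iv in enhancers]
    return pd.DataFrame({name: vals}, index=pd.Index(enhancers.df["id"], name="id"))


# ---------------------------------------------------------------------------
# TF footprints
# ---------------------------------------------------------------------------

class FootprintSet:
    """TF footprints: intervals with a motif id and a quality score."""

    def __init__(self, df: pd.DataFrame):
        df = df[["chrom", "start", "end", "motif_id", "score"]].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["score"] = df["score"].astype(float)
        if not np.isfinite(df["score"]).all():
            raise ValueError("footprint scores must be finite")
        self.df = df.reset_index(drop=True)

    @classmethod
    def read_bed(cls, path) -> "FootprintSet":
        """BED6 with the motif id in column 4 and the score in column 5."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3, 4],
                         names=["chrom", "start", "end", "motif_id", "score"],
                         dtype={"chrom": str})
        return cls(df)

    def write_bed(self, path) -> None:
        out = self.df.copy()
        out["strand"] = "."
        out.to_csv(path, sep="\t", header=False, index=False)

    def __len__(self) -> int:
        return len(self.df)


def footprint_counts(enhancers: IntervalSet, fps: FootprintSet,
                     min_score: float = 55.0,
                     containment: bool = True) -> pd.DataFrame:
    """Count footprints per (enhancer, motif), plus a ``total`` control.

    A footprint is counted for an enhancer iff its score passes
    ``min_score`` and it lies fully inside the enhancer (containment; set
    ``containment=False`` for >= 1 bp overlap).  Enhancers with no
    footprints get all-zero rows; ``total`` is the row sum over motifs.
    """
    import pyranges as pr

    fdf = fps.df[fps.df["score"] >= min_score]
    enh_ids = pd.Index(enhancers.df["id"], name="id")
    motifs = sorted(fps.df["motif_id"].unique())
    counts = pd.DataFrame(0, index=enh_ids, columns=motifs, dtype=np.int64)
    if len(fdf) and len(enhancers):
        fp_pr = pr.PyRanges(fdf.rename(columns={
            "chrom": "Chromosome", "start": "Start", "end": "End"}))
        enh_pr = pr.PyRanges(enhancers.df.rename(columns={
            "chrom": "Chromosome", "start": "Start", "end": "End"})[
            ["Chromosome", "Start", "End", "id"]])
        joined = fp_pr.join(enh_pr).df
        if len(joined):
            if containment:
                joined = joined[(joined["Start"] >= joined["Start_b"])
                                & (joined["End"] <= joined["End_b"])]
            tab = joined.groupby(["id", "motif_id"]).size().unstack(fill_value=0)
            counts = counts.add(
                tab.reindex(index=enh_ids, columns=motifs, fill_value=0),
                fill_value=0).astype(np.int64)
    counts["total"] = counts.sum(axis=1)
    return counts


# ---------------------------------------------------------------------------
# Motif PFMs
# ---------------------------------------------------------------------------

@dataclass
class Pfm:
    """Position frequency matrix over {A, C, G, T}, rows = positions."""

    motif_id: str
    matrix: np.ndarray  # (positions, 4), each row sums to 1

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PFM must be (positions, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PFM rows of {self.motif_id} must each sum to 1")

    def reverse_complement(self) -> "Pfm":
        # A<->T, C<->G and position order reversed
        return Pfm(self.motif_id, self.matrix[::-1, [3, 2, 1, 0]])


def motif_at_fraction(pfm: Pfm) -> float:
    """Probability-weighted AT content: mean over positions of p_A + p_T."""
    return float((pfm.matrix[:, 0] + pfm.matrix[:, 3]).mean())


_JASPAR_ROW = re.compile(r"^([ACGT])\s*\[?\s*([\d.\s]+?)\s*\]?\s*$")


def read_jaspar(path) -> list[Pfm]:
    """Parse JASPAR plain-text PFMs (counts are normalized to probabilities)."""
    pfms: list[Pfm] = []
    name = None
    rows: dict[str, np.ndarray] = {}
    def flush():
        if name is not None and len(rows) == 4:
            mat = np.stack([rows[b] for b in "ACGT"], axis=1)
            total = mat.sum(axis=1, keepdims=True)
            if (total <= 0).any():
                raise ValueError(f"empty PFM column in motif {name}")
            pfms.append(Pfm(name, mat / total))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip().replace("\t", "-").replace(" ", "-")
                rows = {}
            else:
                m = _JASPAR_ROW.match(line)
                if m:
                    rows[m.group(1)] = np.array(
                        [float(x) for x in m.group(2).split()], dtype=float)
    flush()
    return pfms


# ---------------------------------------------------------------------------
# Delegating covariates and assembly
# ---------------------------------------------------------------------------

def har_hge_flags(enhancers: IntervalSet, hars: IntervalSet,
                  hges: IntervalSet, har_expand: int = 2500,
                  hge_distance: int = 5000) -> pd.DataFrame:
    """Binary HAR/HGE covariates.

    HARs are expanded by ``har_expand`` bp on both sides before
    intersection; HGE membership means the enhancer lies within
    ``hge_distance`` bp of an HGE (boundary inclusive).
    """
    har = overlap_flag(enhancers, hars, expand=har_expand, mode="overlap")
    hge = overlap_flag(enhancers, hges, mode="within_distance",
                       distance=hge_distance)
    return pd.DataFrame({"har": har.to_numpy(), "hge": hge.to_numpy()},
                        index=pd.Index(enhancers.df["id"], name="id"))


def tss_distance_covariate(enhancers: IntervalSet,
                           tss_points: IntervalSet,
                           name: str = "tss_distance") -> pd.DataFrame:
    """Distance (bp) from each enhancer to the nearest TSS."""
    d = nearest_distance(enhancers, tss_points)
    return pd.DataFrame({name: d.to_numpy()},
                        index=pd.Index(enhancers.df["id"], name="id"))


def assemble_covariates(enhancers: IntervalSet,
                        *components: pd.DataFrame) -> pd.DataFrame:
    """Outer-join covariate components on enhancer id.

    Missing cells stay missing; duplicate column names are an error.
    """
    out = pd.DataFrame(index=pd.Index(enhancers.df["id"], name="id"))
    seen: set[str] = set()
    for comp in components:
        dup = seen & set(comp.columns)
        if dup:
            raise ValueError(f"duplicate covariate columns: {sorted(dup)}")
        seen |= set(comp.columns)
        out = out.join(comp, how="outer")
        logger.info("assemble_covariates: joined %s", list(comp.columns))
    return out


def read_covariate_table(path) -> pd.DataFrame:
    """TSV with header; column 1 is the enhancer id."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0]).rename_axis("id")


def write_covariate_table(table: pd.DataFrame, path) -> None:
    table.rename_axis("id").to_csv(path, sep="\t")
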