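"""Enhancer-to-gene assignment from chromatin contact pairs.

Hi-C contacts are anchor pairs; an enhancer is assigned to a gene when the
enhancer overlaps one anchor of a contact and the gene's TSS falls in the
other anchor (anchor order is irrelevant).  Gene sets are then converted to
competitive enhancer sets: an enhancer is a member iff it contacts at least
one gene of the set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .intervals import IntervalSet

logger = logging.getLogger(__name__)


def read_bedpe(path) -> pd.DataFrame:
    """Contact pairs as BEDPE (6+ columns); extra columns beyond 7 ignored.

    Returns columns ``chrom1 start1 end1 chrom2 start2 end2 score``
    (score NaN when absent).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BEDPE needs at least 6 columns")
    df = df.iloc[:, :7] if df.shape[1] >= 7 else df.iloc[:, :6]
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    if df.shape[1] == 7:
        cols.append("score")
    df.columns = cols
    if "score" not in df.columns:
        df["score"] = np.nan
    else:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    for c in ("chrom1", "chrom2"):
        df[c] = df[c].astype(str)
    return df


def write_bedpe(contacts: pd.DataFrame, path) -> None:
    contacts[["chrom1", "start1", "end1", "chrom2", "start2", "end2",
              "score"]].to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(path) -> pd.DataFrame:
    """Genes as TSV with header: gene_id, chrom, tss (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.columns = [c.lower() for c in df.columns]
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids")
    df["tss"] = df["tss"].astype(np.int64)
    return df[["gene_id", "chrom", "tss"]]


def read_gene_sets(path) -> dict[str, set[str]]:
    """Gene sets as two-column TSV (set name, gene id), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene_id"],
                     comment="#", skiprows=_maybe_header(path))
    out: dict[str, set[str]] = {}
    for name, sub in df.groupby("set", sort=False):
        out[str(name)] = set(sub["gene_id"].astype(str))
    return out


def _maybe_header(path) -> int:
    with open(path) as fh:
        first = fh.readline().lower()
    return 1 if first.startswith(("set", "name")) else 0


def enhancer_gene_contacts(enhancers: IntervalSet, contacts: pd.DataFrame,
                           genes: pd.DataFrame,
                           min_score: float | None = None,
                           gene_mode: str = "tss") -> dict[str, set[str]]:
    """Map enhancer id -> contacted gene ids.

    Enhancer E maps to gene G iff some contact pair has E overlapping one
    anchor (>= 1 bp) and G's TSS inside the other anchor.  Symmetric in
    anchor order.  ``min_score`` filters contacts; ``gene_mode="tss"``
    places the gene at its TSS (``"body"`` would need a body interval).
    """
    if min_score is not None:
        contacts = contacts[contacts["score"] >= min_score]
    edf = enhancers.df
    enh_by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(),
                sub["id"].to_numpy())
        for chrom, sub in edf.sort_values("start").groupby("chrom", sort=False)
    }
    if gene_mode != "tss":
        raise ValueError("only gene_mode='tss' is implemented")
    gpos = genes.assign(pos0=genes["tss"] - 1)
    gene_by_chrom = {
        chrom: (sub["pos0"].to_numpy(), sub["gene_id"].to_numpy())
        for chrom, sub in gpos.sort_values("pos0").groupby("chrom", sort=False)
    }

    def enh_hits(chrom, s, e):
        if chrom not in enh_by_chrom:
            return ()
        es, ee, eid = enh_by_chrom[chrom]
        # enhancers sorted by start; overlap iff es < e and ee > s
        hi = np.searchsorted(es, e, side="left")
        sel = np.flatnonzero(ee[:hi] > s)
        return eid[sel]

    def gene_hits(chrom, s, e):
        if chrom not in gene_by_chrom:
            return ()
        pos, gid = gene_by_chrom[chrom]
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, e, side="left")
        return gid[lo:hi]

    mapping: dict[str, set[str]] = {}
    for row in contacts.itertuples(index=False):
        anchors = ((row.chrom1, row.start1, row.end1),
                   (row.chrom2, row.start2, row.end2))
        for (ea, ga) in ((anchors[0], anchors[1]), (anchors[1], anchors[0])):
            enh_ids = enh_hits(*ea)
            if len(enh_ids) == 0:
                continue
            gids = gene_hits(*ga)
            if len(gids) == 0:
                continue
            for e_id in enh_ids:
                mapping.setdefault(e_id, set()).update(gids)
    return mapping


def build_enhancer_set(geneset: set[str], mapping: dict[str, set[str]],
                       enhancers: IntervalSet | None = None,
                       name: str = "set") -> pd.Series:
    """Binary enhancer membership: 1 iff the enhancer contacts a set gene.

    Indexed over all enhancers when ``enhancers`` is given, else over the
    mapped enhancers.
    """
    if not mapping:
        raise ValueError("empty enhancer-gene mapping")
    index = (pd.Index(enhancers.df["id"], name="id") if enhancers is not None
             else pd.Index(sorted(mapping), name="id"))
    member = pd.Series(0, index=index, name=name, dtype=int)
    for enh_id, gids in mapping.items():
        if enh_id in member.index and gids & geneset:
            member.loc[enh_id] = 1
    return member


def significant_target_genes(assoc: pd.DataFrame,
                             mapping: dict[str, set[str]],
                             alpha_adjusted: float = 0.05,
                             p_col: str = "p_adj") -> set[str]:
    """Genes contacted by at least one significant enhancer.

    ``assoc`` needs ``enhancer_id`` and an adjusted p column.
    """
    if p_col not in assoc.columns:
        raise KeyError(f"association table has no {p_col!r} column")
    sig = assoc.loc[assoc[p_col] < alpha_adjusted, "enhancer_id"]
    genes: set[str] = set()
    for enh_id in sig:
        genes |= mapping.get(enh_id, set())
    return genes


def target_genes_by_annotation(assocs: dict[str, pd.DataFrame],
                               mappings: dict[str, dict[str, set[str]]],
                               alpha_adjusted: float = 0.05,
                               p_col: str = "p_adj"):
    """Per-annotation significant target genes plus their intersection."""
    per = {ann: significant_target_genes(assocs[ann], mappings[ann],
                                         alpha_adjusted, p_col)
           for ann in assocs}
    inter = set.intersection(*per.values()) if per else set()
    return per, inter
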