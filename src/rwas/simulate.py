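"""Synthetic study generator with known ground truth.

Produces every input the RWAS stack consumes — enhancer intervals, genome
sequence with planted per-enhancer AT content, an LD-block reference panel,
GWAS summary statistics with planted enhancer effects, TF footprints,
a conservation track, genes, Hi-C-like contact pairs and gene sets — so the
whole pipeline is testable end to end without downloads.

Genotypes are built from latent Gaussian AR(1) processes within LD blocks
(independent across blocks), thresholded at the MAF quantile into haploid
alleles; dosages are sums of two haplotypes.  Summary-statistic Z-scores are
drawn per block as ``Z ~ mu + sqrt(inflation) * MVN(0, R)`` with
``mu = R delta``; ``delta`` is nonzero at SNPs of causal enhancers, with the
per-SNP chi-square(1) noncentrality equal to ``beta * standardized
covariate`` (floored at zero — noncentrality is nonnegative, so planted
covariate effects are monotone, not signed).  ``inflation`` models the
genome-wide polygenic inflation of large GWAS (lambda_GC ~ 1.3-1.5 for
psychiatric traits); the default 1.0 is an exact null.

Each artifact uses its own RNG stream spawned from the master seed, so
regenerating one file never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .covariates import FootprintSet, Pfm, SequenceStore, BaseScoreTrack
from .intervals import ChromSizes, IntervalSet
from .region import ReferencePanel

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Lengths in bp; rates per kb; ``rho`` is the within-block AR(1)
    parameter of the latent genotype process.
    """

    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_enhancers: int = 2000
    enhancer_length_dist: str = "fixed"          # "fixed" | "uniform"
    enhancer_length_params: tuple = (1000,)
    snp_per_kb: float = 5.0
    ld_block_bp: int = 2000
    rho: float = 0.6
    maf_range: tuple = (0.05, 0.5)
    n_ref_samples: int = 500
    gwas_n: int = 100_000
    gwas_inflation: float = 1.0
    effects: dict = field(default_factory=dict)  # covariate -> beta on per-SNP ncp
    causal_fraction: float = 1.0
    at_range: tuple = (0.3, 0.7)
    at_background: float = 0.5
    n_motifs: int = 20
    fp_rate: float = 1.0
    fp_len: int = 15
    fp_score_range: tuple = (30.0, 100.0)
    fp_at_coupling: float = 0.0
    cons_mean: float = 1.0
    cons_sd: float = 0.5
    cons_noise: float = 0.2
    cons_run: int = 25
    cons_gap_fraction: float = 0.0
    n_genes: int = 300
    risk_gene_fraction: float = 0.1
    contact_anchor: int = 5000
    max_contacts: int = 3
    contact_risk_pref: float = 0.8
    n_blacklist: int = 5
    blacklist_len: int = 20_000
    n_hars: int = 50
    har_len: int = 300
    n_hges: int = 50
    hge_len: int = 1000

    def __post_init__(self):
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.n_enhancers <= 0 or self.chrom_length <= 0:
            raise ValueError("sizes must be positive")
        if self.snp_per_kb <= 0 or self.ld_block_bp <= 0:
            raise ValueError("rates and lengths must be positive")

    @property
    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes({f"chr{i + 1}": self.chrom_length
                           for i in range(self.n_chrom)})


@dataclass
class SimTruth:
    """Ground truth aligned with the emitted files."""

    enhancers: pd.DataFrame       # id, causal, planted covariate columns
    snp_delta: pd.Series          # per-SNP delta (sqrt noncentrality)
    risk_genes: set[str] = field(default_factory=set)

    def to_json(self, path) -> None:
        payload = {
            "enhancers": self.enhancers.reset_index().to_dict(orient="list"),
            "snp_delta": {k: float(v) for k, v in
                          self.snp_delta.items() if v != 0.0},
            "risk_genes": sorted(self.risk_genes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# streams: one per artifact, fixed offsets from the master seed
_STREAMS = {"enhancers": 0, "panel": 1, "gwas": 2, "footprints": 3,
            "contacts": 4, "conservation": 5, "genes": 6, "features": 7,
            "truth": 8, "motifs": 9, "blacklist": 10}


def _rng(seed: int, artifact: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[artifact],)))


# ---------------------------------------------------------------------------
# Enhancers and sequence
# ---------------------------------------------------------------------------

def _draw_lengths(cfg: SimConfig, n: int, rng) -> np.ndarray:
    if cfg.enhancer_length_dist == "fixed":
        return np.full(n, int(cfg.enhancer_length_params[0]), dtype=np.int64)
    if cfg.enhancer_length_dist == "uniform":
        lo, hi = cfg.enhancer_length_params
        return rng.integers(int(lo), int(hi) + 1, size=n)
    raise ValueError(f"unknown length distribution {cfg.enhancer_length_dist!r}")


def simulate_enhancers_and_sequences(cfg: SimConfig, seed: int
                                     ) -> tuple[IntervalSet, SequenceStore,
                                                pd.Series]:
    """Non-overlapping enhancers plus genome sequence with planted AT.

    Per enhancer the per-base probability of A-or-T is drawn uniformly from
    ``cfg.at_range``; the background genome sits at ``cfg.at_background``.
    Returns the intervals, the sequence store, and the planted AT values.
    """
    rng = _rng(seed, "enhancers")
    sizes = cfg.chrom_sizes
    chroms = list(sizes)
    per_chrom = np.full(len(chroms), cfg.n_enhancers // len(chroms))
    per_chrom[: cfg.n_enhancers % len(chroms)] += 1
    records = []
    seqs: dict[str, str] = {}
    at_planted: dict[str, float] = {}
    counter = 0
    for chrom, n_here in zip(chroms, per_chrom):
        L = sizes[chrom]
        lengths = _draw_lengths(cfg, n_here, rng)
        free = L - int(lengths.sum())
        if free <= n_here:
            raise ValueError(f"{chrom}: not enough room for {n_here} enhancers")
        gaps = rng.dirichlet(np.ones(n_here + 1)) * free
        starts = (np.cumsum(gaps[:-1]) +
                  np.concatenate([[0], np.cumsum(lengths[:-1])])).astype(np.int64)
        # background AT draw for the whole chromosome, then overwrite enhancers
        at = rng.random(L) < cfg.at_background
        which = rng.integers(0, 2, size=L)  # A/T or C/G choice
        codes = np.where(at, np.where(which == 0, 0, 3),
                         np.where(which == 0, 1, 2))
        for s, ln in zip(starts, lengths):
            iid = f"enh{counter:05d}"
            counter += 1
            p_at = rng.uniform(*cfg.at_range)
            at_planted[iid] = p_at
            seg_at = rng.random(ln) < p_at
            seg_which = rng.integers(0, 2, size=ln)
            codes[s:s + ln] = np.where(seg_at,
                                       np.where(seg_which == 0, 0, 3),
                                       np.where(seg_which == 0, 1, 2))
            records.append((chrom, int(s), int(s + ln), iid))
        seqs[chrom] = _BASES[codes].tobytes().decode()
    enhancers = IntervalSet.from_records(records)
    return enhancers, SequenceStore.from_dict(seqs), pd.Series(at_planted,
                                                               name="at")


def write_fasta(seq: SequenceStore, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in seq.lengths:
            fh.write(f">{chrom}\n")
            s = seq.fetch(chrom, 0, seq.lengths[chrom])
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Reference panel
# ---------------------------------------------------------------------------

def _snp_positions(cfg: SimConfig, rng) -> pd.DataFrame:
    rows = []
    for chrom, L in cfg.chrom_sizes.items():
        n = rng.poisson(cfg.snp_per_kb * L / 1000.0)
        pos = np.sort(rng.choice(L, size=min(n, L), replace=False)) + 1  # 1-based
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    df = pd.concat(rows, ignore_index=True)
    df["snp_id"] = [f"rs{i:07d}" for i in range(len(df))]
    df["block"] = (df["chrom"].astype(str) + ":" +
                   ((df["pos"] - 1) // cfg.ld_block_bp).astype(str))
    return df[["snp_id", "chrom", "pos", "block"]]


def simulate_reference_panel(cfg: SimConfig, seed: int) -> ReferencePanel:
    """LD-block genotype panel from thresholded latent AR(1) Gaussians."""
    rng = _rng(seed, "panel")
    locs = _snp_positions(cfg, rng)
    n_hap = 2 * cfg.n_ref_samples
    maf = rng.uniform(*cfg.maf_range, size=len(locs))
    thresh = norm.ppf(maf)
    dosage = np.empty((cfg.n_ref_samples, len(locs)))
    chol_cache: dict[int, np.ndarray] = {}
    for _, idx in locs.groupby("block", sort=False).indices.items():
        m = len(idx)
        if m not in chol_cache:
            C = cfg.rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
            chol_cache[m] = np.linalg.cholesky(C)
        latent = rng.standard_normal((n_hap, m)) @ chol_cache[m].T
        hap = (latent < thresh[idx]).astype(np.int8)
        dosage[:, idx] = hap[: cfg.n_ref_samples] + hap[cfg.n_ref_samples:]
    return ReferencePanel(dosage, list(locs["snp_id"]),
                          locs=locs[["snp_id", "chrom", "pos", "block"]])


# ---------------------------------------------------------------------------
# Ground-truth effects and summary statistics
# ---------------------------------------------------------------------------

def make_truth(cfg: SimConfig, enhancers: IntervalSet,
               covariates: pd.DataFrame, panel: ReferencePanel,
               seed: int) -> SimTruth:
    """Assign causal enhancers and per-SNP delta from the effect model.

    For a causal enhancer with standardized covariate value ``s`` the
    per-SNP chi-square(1) noncentrality is ``sum_c beta_c * s_c`` floored at
    zero; ``delta = sqrt(ncp)`` at every SNP inside the enhancer.
    """
    rng = _rng(seed, "truth")
    edf = enhancers.df.set_index("id")
    causal = pd.Series(
        rng.random(len(edf)) < cfg.causal_fraction, index=edf.index)
    ncp = pd.Series(0.0, index=edf.index)
    for cov, beta in cfg.effects.items():
        vals = covariates[cov].reindex(edf.index).astype(float)
        s = (vals - vals.mean()) / vals.std()
        ncp = ncp.add(beta * s, fill_value=0.0)
    ncp = ncp.clip(lower=0.0).where(causal, 0.0).fillna(0.0)

    locs = panel.locs
    delta_arr = np.zeros(len(locs))
    by_chrom = {chrom: (sub["pos"].to_numpy() - 1, sub.index.to_numpy())
                for chrom, sub in locs.groupby("chrom", sort=False)}
    for row in edf.itertuples():
        val = ncp.loc[row.Index]
        if val == 0.0 or row.chrom not in by_chrom:
            continue
        pos0, rows_idx = by_chrom[row.chrom]
        lo = np.searchsorted(pos0, row.start, side="left")
        hi = np.searchsorted(pos0, row.end, side="left")
        delta_arr[rows_idx[lo:hi]] = np.sqrt(val)
    delta = pd.Series(delta_arr, index=locs["snp_id"])

    truth_table = pd.DataFrame({"causal": causal,
                                "planted_ncp": ncp})
    for cov in cfg.effects:
        truth_table[cov] = covariates[cov].reindex(edf.index)
    return SimTruth(truth_table, delta)


def _block_ld(dosage_block: np.ndarray) -> np.ndarray:
    X = dosage_block
    sd = X.std(axis=0)
    keep = sd > 0
    R = np.eye(X.shape[1])
    if keep.sum() > 1:
        sub = np.corrcoef(X[:, keep], rowvar=False)
        R[np.ix_(keep, keep)] = sub
    R = np.clip((R + R.T) / 2, -1, 1)
    np.fill_diagonal(R, 1.0)
    return R


def simulate_summary_stats(cfg: SimConfig, panel: ReferencePanel,
                           truth: SimTruth | None, seed: int) -> pd.DataFrame:
    """GWAS summary statistics with planted effects.

    Per LD block, ``Z ~ R delta + sqrt(inflation) * MVN(0, R)`` with ``R``
    the panel LD of the block; two-sided ``p = 2 Phi(-|Z|)``.
    """
    rng = _rng(seed, "gwas")
    locs = panel.locs
    delta_all = (truth.snp_delta.reindex(locs["snp_id"]).fillna(0.0).to_numpy()
                 if truth is not None else np.zeros(len(locs)))
    z = np.empty(len(locs))
    scale = np.sqrt(cfg.gwas_inflation)
    for _, idx in locs.groupby("block", sort=False).indices.items():
        R = _block_ld(panel.dosages[:, idx])
        lam, V = np.linalg.eigh(R)
        lam = np.maximum(lam, 0.0)
        A = V * np.sqrt(lam)
        mu = R @ delta_all[idx]
        z[idx] = mu + scale * (A @ rng.standard_normal(len(idx)))
    p = 2.0 * norm.sf(np.abs(z))
    return pd.DataFrame({"snp_id": locs["snp_id"],
                         "p": np.clip(p, 1e-300, 1.0),
                         "n": cfg.gwas_n,
                         "z": z})


# ---------------------------------------------------------------------------
# Footprints, motifs, conservation, genes, contacts
# ---------------------------------------------------------------------------

def simulate_motifs(cfg: SimConfig, seed: int) -> tuple[list[Pfm], pd.Series]:
    """Simple PFMs with controlled AT content (uniform within A/T and C/G)."""
    rng = _rng(seed, "motifs")
    pfms = []
    ats = {}
    for i in range(cfg.n_motifs):
        mid = f"MOTIF{i:03d}"
        at = rng.uniform(0.2, 0.8)
        width = int(rng.integers(8, 14))
        row = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
        jitter = rng.uniform(0.9, 1.1, size=(width, 4)) * row
        mat = jitter / jitter.sum(axis=1, keepdims=True)
        pfms.append(Pfm(mid, mat))
        ats[mid] = float((mat[:, 0] + mat[:, 3]).mean())
    return pfms, pd.Series(ats, name="motif_at")


def simulate_footprints(cfg: SimConfig, enhancers: IntervalSet,
                        motif_at: pd.Series, seed: int,
                        enhancer_at: pd.Series | None = None) -> FootprintSet:
    """Poisson footprint counts per (enhancer, motif).

    Null (``fp_at_coupling=0``): constant rate ``fp_rate / n_motifs`` per
    pair.  Alternative: the log-rate increases with the product of the
    enhancer's standardized AT and the motif's centred AT, so AT-rich motifs
    concentrate in AT-rich enhancers.
    """
    rng = _rng(seed, "footprints")
    edf = enhancers.df
    base = cfg.fp_rate / max(len(motif_at), 1)
    if enhancer_at is not None and cfg.fp_at_coupling != 0.0:
        s = (enhancer_at - enhancer_at.mean()) / enhancer_at.std()
        s = s.reindex(edf["id"]).fillna(0.0).to_numpy()
    else:
        s = np.zeros(len(edf))
    m_at = motif_at.to_numpy()
    rows = []
    lo, hi = cfg.fp_score_range
    for i, row in enumerate(edf.itertuples(index=False)):
        span = row.end - row.start - cfg.fp_len
        if span <= 0:
            continue
        rates = base * np.exp(cfg.fp_at_coupling * s[i] * 2 * (m_at - 0.5))
        counts = rng.poisson(rates)
        for mid, k in zip(motif_at.index, counts):
            for _ in range(k):
                start = int(row.start + rng.integers(0, span + 1))
                rows.append((row.chrom, start, start + cfg.fp_len, mid,
                             float(rng.uniform(lo, hi))))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "motif_id",
                                     "score"])
    return FootprintSet(df)


def simulate_conservation_track(cfg: SimConfig, enhancers: IntervalSet,
                                seed: int) -> tuple[BaseScoreTrack, pd.Series]:
    """Per-base scores in runs with a planted per-enhancer mean."""
    rng = _rng(seed, "conservation")
    rows = []
    means = {}
    for row in enhancers.df.itertuples(index=False):
        mu = float(rng.normal(cfg.cons_mean, cfg.cons_sd))
        means[row.id] = mu
        for s in range(row.start, row.end, cfg.cons_run):
            e = min(s + cfg.cons_run, row.end)
            if cfg.cons_gap_fraction and rng.random() < cfg.cons_gap_fraction:
                continue
            rows.append((row.chrom, s, e, mu + float(rng.normal(0, cfg.cons_noise))))
    track = BaseScoreTrack(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "value"]))
    return track, pd.Series(means, name="planted_conservation")


def simulate_genes(cfg: SimConfig, seed: int) -> pd.DataFrame:
    rng = _rng(seed, "genes")
    sizes = cfg.chrom_sizes
    chroms = rng.choice(list(sizes), size=cfg.n_genes)
    tss = np.array([rng.integers(1, sizes[c]) for c in chroms])
    return pd.DataFrame({"gene_id": [f"gene{i:04d}" for i in range(cfg.n_genes)],
                         "chrom": chroms, "tss": tss})


def simulate_contacts(cfg: SimConfig, enhancers: IntervalSet,
                      genes: pd.DataFrame, seed: int,
                      truth: SimTruth | None = None) -> pd.DataFrame:
    """Contact pairs: each enhancer contacts 0-3 genes.

    When ground truth is given, causal enhancers preferentially contact
    risk-set genes (probability ``contact_risk_pref`` per contact).
    """
    rng = _rng(seed, "contacts")
    n_risk = max(1, int(cfg.risk_gene_fraction * len(genes)))
    risk_idx = rng.choice(len(genes), size=n_risk, replace=False)
    risk = set(genes["gene_id"].iloc[risk_idx])
    if truth is not None:
        truth.risk_genes = risk
    half = cfg.contact_anchor // 2
    sizes = cfg.chrom_sizes
    rows = []
    causal = (truth.enhancers["causal"] if truth is not None else None)
    for row in enhancers.df.itertuples(index=False):
        k = int(rng.integers(0, cfg.max_contacts + 1))
        if k == 0:
            continue
        is_causal = bool(causal.get(row.id, False)) if causal is not None else False
        for _ in range(k):
            if is_causal and rng.random() < cfg.contact_risk_pref:
                g = genes.iloc[int(rng.choice(risk_idx))]
            else:
                g = genes.iloc[int(rng.integers(0, len(genes)))]
            c = (row.start + row.end) // 2
            a1s = max(0, c - half)
            a1e = min(sizes[row.chrom], c + half)
            g0 = int(g["tss"]) - 1
            a2s = max(0, g0 - half)
            a2e = min(sizes[g["chrom"]], g0 + half + 1)
            rows.append((row.chrom, a1s, a1e, g["chrom"], a2s, a2e, 1.0))
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2",
                                       "start2", "end2", "score"])


def simulate_features(cfg: SimConfig, n_features: int, seed: int,
                      exclusion: IntervalSet | None = None,
                      length: int = 1) -> IntervalSet:
    """Uniform feature elements (e.g. MPRA SNPs) for overlap testing."""
    from .intervals import shuffle_intervals

    rng = _rng(seed, "features")
    sizes = cfg.chrom_sizes
    chroms = rng.choice(list(sizes), size=n_features)
    recs = [(c, 0, length, f"feat{i:05d}") for i, c in enumerate(chroms)]
    base = IntervalSet.from_records(recs)
    return shuffle_intervals(base, sizes, exclusion, rng_seed=rng)


def simulate_blacklist(cfg: SimConfig, seed: int) -> IntervalSet:
    rng = _rng(seed, "blacklist")
    sizes = cfg.chrom_sizes
    recs = []
    for i in range(cfg.n_blacklist):
        chrom = str(rng.choice(list(sizes)))
        start = int(rng.integers(0, sizes[chrom] - cfg.blacklist_len))
        recs.append((chrom, start, start + cfg.blacklist_len, f"bl{i}"))
    return IntervalSet.from_records(recs)


# ---------------------------------------------------------------------------
# Bundled study
# ---------------------------------------------------------------------------

@dataclass
class SimStudy:
    """All artifacts of one simulated study, with their ground truth."""

    cfg: SimConfig
    seed: int
    enhancers: IntervalSet
    sequences: SequenceStore
    at_planted: pd.Series
    panel: ReferencePanel
    gwas: pd.DataFrame
    truth: SimTruth
    footprints: FootprintSet | None
    motif_at: pd.Series | None
    pfms: list | None
    conservation: BaseScoreTrack | None
    cons_planted: pd.Series | None
    genes: pd.DataFrame | None
    contacts: pd.DataFrame | None

    @property
    def snp_locs(self) -> pd.DataFrame:
        return self.panel.locs[["snp_id", "chrom", "pos"]]

    def write(self, outdir) -> dict:
        """Emit every artifact as plain text; returns the path manifest."""
        import os

        from .hic import write_bedpe
        from .intervals import write_bed

        os.makedirs(outdir, exist_ok=True)
        paths = {k: os.path.join(outdir, v) for k, v in {
            "enhancers": "enhancers.bed", "genome": "genome.fa",
            "chrom_sizes": "chrom.sizes", "snp_locs": "snp_loc.tsv",
            "gwas": "gwas.tsv", "panel": "panel.tsv",
            "footprints": "footprints.bed", "motifs": "motifs.jaspar",
            "conservation": "conservation.bedGraph", "genes": "genes.tsv",
            "contacts": "contacts.bedpe", "truth": "truth.json",
        }.items()}
        write_bed(self.enhancers, paths["enhancers"])
        write_fasta(self.sequences, paths["genome"])
        self.cfg.chrom_sizes.write(paths["chrom_sizes"])
        self.snp_locs.to_csv(paths["snp_locs"], sep="\t", index=False)
        self.gwas[["snp_id", "p", "n"]].rename(
            columns={"snp_id": "SNP", "p": "P", "n": "N"}).to_csv(
            paths["gwas"], sep="\t", index=False)
        self.panel.write_tsv(paths["panel"])
        if self.footprints is not None:
            self.footprints.write_bed(paths["footprints"])
            with open(paths["motifs"], "w") as fh:
                for pfm in self.pfms:
                    fh.write(f">{pfm.motif_id}\n")
                    counts = np.round(pfm.matrix * 1000, 3)
                    for b, rowvals in zip("ACGT", counts.T):
                        fh.write(f"{b} [ "
                                 + " ".join(f"{v:g}" for v in rowvals)
                                 + " ]\n")
        else:
            paths.pop("footprints"), paths.pop("motifs")
        if self.conservation is not None:
            self.conservation.write_bedgraph(paths["conservation"])
        else:
            paths.pop("conservation")
        if self.contacts is not None:
            self.genes.to_csv(paths["genes"], sep="\t", index=False)
            write_bedpe(self.contacts, paths["contacts"])
        else:
            paths.pop("genes"), paths.pop("contacts")
        self.truth.to_json(paths["truth"])
        return paths


_ALL_COMPONENTS = frozenset({"footprints", "conservation", "contacts"})


def simulate_study(cfg: SimConfig | None = None, seed: int = 0,
                   components: frozenset = _ALL_COMPONENTS) -> SimStudy:
    """Generate a full coherent study from one master seed.

    ``components`` selects the optional artifacts (footprints, conservation,
    contacts); the GWAS core (enhancers, sequence, panel, summary
    statistics, truth) is always produced.  Streams are fixed per artifact,
    so the core is bit-identical whatever subset is requested.
    """
    cfg = cfg or SimConfig()
    enhancers, seqs, at_planted = simulate_enhancers_and_sequences(cfg, seed)
    panel = simulate_reference_panel(cfg, seed)
    covs = at_planted.to_frame()
    truth = make_truth(cfg, enhancers, covs, panel, seed)
    gwas = simulate_summary_stats(cfg, panel, truth, seed)
    fps = motif_at = pfms = track = cons_planted = genes = contacts = None
    if "footprints" in components:
        pfms, motif_at = simulate_motifs(cfg, seed)
        fps = simulate_footprints(cfg, enhancers, motif_at, seed,
                                  enhancer_at=at_planted)
    if "conservation" in components:
        track, cons_planted = simulate_conservation_track(cfg, enhancers, seed)
    if "contacts" in components:
        genes = simulate_genes(cfg, seed)
        contacts = simulate_contacts(cfg, enhancers, genes, seed, truth=truth)
    return SimStudy(cfg, seed, enhancers, seqs, at_planted, panel, gwas,
                    truth, fps, motif_at, pfms, track, cons_planted, genes,
                    contacts)
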