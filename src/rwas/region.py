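"""Enhancer-level association from GWAS summary statistics.

The engine behind the enhancer-based GWAS: SNPs are annotated to enhancer
intervals, per-SNP p-values are converted to 1-df chi-square statistics, and
each enhancer is scored by the mean chi-square of its SNPs.  Under the null,
SNP Z-scores are multivariate normal with correlation equal to the local LD
matrix ``R``, so the sum of chi-squares is distributed as a weighted sum of
independent chi-square(1) variables with weights equal to the eigenvalues of
``R``.  The survival function of that weighted sum gives the enhancer
p-value; its probit transform ``z = Phi^{-1}(1 - p)`` is the response used
by the downstream property regressions.

The weighted chi-square tail is computed by (in order of preference) exact
closed forms for equal weights, Ruben's mixture-of-central-chi-squares
series, Imhof's integral with oscillatory-weight tail quadrature, a
Lugannani-Rice saddlepoint in the far tail, and Liu's moment-matching
approximation as a last resort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.stats import chi2, ncx2, norm

from .intervals import IntervalSet

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16
_EIG_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_snp_locs(path) -> pd.DataFrame:
    """SNP locations: 3-column TSV (id, chrom, 1-based pos) or PLINK .bim."""
    path = str(path)
    if path.endswith(".bim"):
        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                         dtype={"chrom": str})
        df = df[["snp_id", "chrom", "pos"]]
    else:
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        df = df.rename(columns={"snp": "snp_id", "id": "snp_id",
                                "bp": "pos", "position": "pos"})
        df = df[["snp_id", "chrom", "pos"]]
        df["chrom"] = df["chrom"].astype(str)
    if df["snp_id"].duplicated().any():
        raise ValueError("duplicate SNP ids in location file")
    df["pos"] = df["pos"].astype(np.int64)
    return df.reset_index(drop=True)


def read_gwas(path, snp_col: str = "SNP", p_col: str = "P",
              n_col: str = "N") -> pd.DataFrame:
    """GWAS summary statistics: whitespace-delimited with a header.

    Returns columns ``snp_id, p, n`` (``n`` NaN when absent).  p-values are
    clamped into ``(0, 1]`` on ingest.
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.upper(): c for c in df.columns}
    try:
        out = pd.DataFrame({"snp_id": df[cols[snp_col.upper()]].astype(str),
                            "p": df[cols[p_col.upper()]].astype(float)})
    except KeyError as exc:
        raise ValueError(f"missing column in {path}: {exc}") from exc
    out["n"] = (df[cols[n_col.upper()]].astype(float)
                if n_col.upper() in cols else np.nan)
    if (out["p"] > 1).any() or (out["p"] < 0).any():
        raise ValueError("p-values outside [0, 1]")
    out["p"] = out["p"].clip(lower=_P_FLOOR)
    return out


class ReferencePanel:
    """Dosage matrix (samples x SNPs, values in [0, 2]) with SNP locations."""

    def __init__(self, dosages: np.ndarray, snp_ids: list[str],
                 locs: pd.DataFrame | None = None):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2 or dosages.shape[1] != len(snp_ids):
            raise ValueError("dosage matrix must be samples x SNPs")
        self.dosages = dosages
        self.snp_ids = list(snp_ids)
        self._col = {s: i for i, s in enumerate(self.snp_ids)}
        self.locs = locs

    @classmethod
    def read_tsv(cls, path, locs: pd.DataFrame | None = None) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(float), list(df.columns), locs=locs)

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.dosages, columns=self.snp_ids).to_csv(
            path, sep="\t", index=False, float_format="%g")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def columns(self, snp_ids) -> np.ndarray:
        try:
            idx = [self._col[s] for s in snp_ids]
        except KeyError as exc:
            raise KeyError(f"SNP {exc} not in reference panel") from exc
        return self.dosages[:, idx]


@dataclass
class LdMatrix:
    """Pearson LD for one enhancer's SNPs, with cached floored eigenvalues."""

    R: np.ndarray
    snp_ids: list[str]
    _eigs: np.ndarray | None = field(default=None, repr=False)

    @property
    def eigenvalues(self) -> np.ndarray:
        if self._eigs is None:
            lam = np.linalg.eigvalsh(self.R)
            lam = np.maximum(lam, _EIG_FLOOR * lam.max())
            self._eigs = lam
        return self._eigs

    @property
    def dim(self) -> int:
        return self.R.shape[0]


def ld_matrix(panel: ReferencePanel, snp_ids) -> LdMatrix:
    """Pearson correlation of mean-imputed dosages for the requested SNPs.

    Monomorphic SNPs are dropped with a warning; eigenvalues are floored at
    1e-8 times the largest to guard near-singular LD.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least two reference samples")
    X = panel.columns(snp_ids).copy()
    # mean imputation of missing dosages
    if np.isnan(X).any():
        mu = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(mu, idx[1])
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [s for s, k in zip(snp_ids, keep) if not k]
        if not keep.any():
            raise ValueError("all requested SNPs are monomorphic in the panel")
        warnings.warn(f"dropping monomorphic SNPs: {dropped}", stacklevel=2)
        X = X[:, keep]
    kept = [s for s, k in zip(snp_ids, keep) if k]
    if X.shape[1] == 1:
        return LdMatrix(np.ones((1, 1)), kept)
    R = np.corrcoef(X, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return LdMatrix(R, kept)


# ---------------------------------------------------------------------------
# p <-> chi-square plumbing
# ---------------------------------------------------------------------------

def snp_chisq(p) -> np.ndarray | float:
    """Upper-tail chi-square(1) quantile of a two-sided p-value."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr > 1)):
        raise ValueError("p-values must be in (0, 1]")
    q = chi2.isf(np.clip(p_arr, _P_FLOOR, 1.0), df=1)
    return float(q) if np.isscalar(p) else q


def probit_z(p) -> np.ndarray | float:
    """z = Phi^{-1}(1 - p), with p clamped to [1e-300, 1 - 1e-16]."""
    p_arr = np.clip(np.asarray(p, dtype=float), _P_FLOOR, _P_CEIL)
    z = norm.isf(p_arr)
    return float(z) if np.isscalar(p) else z


# ---------------------------------------------------------------------------
# Weighted chi-square survival function
# ---------------------------------------------------------------------------

def _ruben_sf(x: float, lam: np.ndarray, tol: float = 1e-11,
              kmax: int = 1000) -> float | None:
    """Ruben's series: P(sum lam_j chi2_1 >= x) as a chi-square mixture.

    With scale beta = min(lam) all mixture coefficients are nonnegative and
    sum to 1, so the truncation error is bounded by the missing coefficient
    mass.  Returns None when the series has not converged within ``kmax``
    terms (large eigenvalue spread).
    """
    m = lam.size
    beta = lam.min()
    r = 1.0 - beta / lam
    a = np.empty(kmax)
    g = np.empty(kmax + 1)
    a[0] = np.exp(0.5 * np.sum(np.log(beta / lam)))
    tot = a[0]
    gpow = np.ones_like(r)
    K = None
    for k in range(1, kmax):
        gpow *= r
        g[k] = gpow.sum()
        a[k] = 0.5 / k * np.dot(g[1:k + 1][::-1], a[:k])
        tot += a[k]
        if 1.0 - tot < tol:
            K = k + 1
            break
    if K is None:
        return None
    ks = np.arange(K)
    return float(np.dot(a[:K], chi2.sf(x / beta, m + 2 * ks)))


def _imhof_sf(x: float, lam: np.ndarray) -> tuple[float, float]:
    """Imhof's inversion integral with oscillatory-weight tail quadrature.

    Splits the Gil-Pelaez integral at a finite point; the slowly decaying
    oscillatory tail sin(phi(u) - xu/2) is handled by QUADPACK's QAWF rule
    after writing it as g(u)sin(phi)cos(wu) - g(u)cos(phi)sin(wu) with
    w = x/2 and phi(u) = (1/2) sum arctan(lam u) slowly varying.
    Returns (probability, error estimate).
    """
    w = 0.5 * x
    a = 2.0 / lam.max()

    def g(u):
        return 1.0 / (u * np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2))))

    def phi(u):
        return 0.5 * np.sum(np.arctan(lam * u))

    def f(u):
        return np.sin(phi(u) - w * u) * g(u)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        head, e1 = integrate.quad(f, 0, a, limit=200, epsabs=1e-13,
                                  epsrel=1e-11)
        t1, e2 = integrate.quad(lambda u: np.sin(phi(u)) * g(u), a, np.inf,
                                weight="cos", wvar=w, limit=200)
        t2, e3 = integrate.quad(lambda u: np.cos(phi(u)) * g(u), a, np.inf,
                                weight="sin", wvar=w, limit=200)
    p = 0.5 + (head + t1 - t2) / np.pi
    return p, e1 + e2 + e3


def _saddlepoint_sf(x: float, lam: np.ndarray) -> float:
    """Lugannani-Rice saddlepoint for the far upper tail."""
    m = lam.size
    mean = lam.sum()
    if x <= mean:  # saddlepoint only used in the upper tail
        return np.nan
    zeta_max = 0.5 / lam.max()

    def kprime(z):
        return np.sum(lam / (1.0 - 2.0 * z * lam)) - x

    zeta = optimize.brentq(kprime, -1e2, zeta_max * (1 - 1e-12), xtol=1e-14)
    K = -0.5 * np.sum(np.log1p(-2.0 * zeta * lam))
    K2 = 2.0 * np.sum(lam ** 2 / (1.0 - 2.0 * zeta * lam) ** 2)
    w = np.sign(zeta) * np.sqrt(2.0 * (zeta * x - K))
    v = zeta * np.sqrt(K2)
    if abs(w) < 1e-8:
        return 0.5
    return float(norm.sf(w + np.log(v / w) / w))


def _liu_sf(x: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matched noncentral chi-square approximation."""
    c1 = lam.sum()
    c2 = np.sum(lam ** 2)
    c3 = np.sum(lam ** 3)
    c4 = np.sum(lam ** 4)
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        aa = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * aa ** 3 - aa ** 2
        df = aa ** 2 - 2.0 * delta
    else:
        delta = 0.0
        df = c2 ** 3 / c3 ** 2 if c3 > 0 else 1.0
    mu_x = df + delta
    sigma_x = np.sqrt(2.0) * np.sqrt(df + 2.0 * delta)
    t = (x - c1) / np.sqrt(2.0 * c2)
    return float(ncx2.sf(t * sigma_x + mu_x, df, delta))


def weighted_chisq_sf(x: float, weights) -> float:
    """P(sum_j lam_j chi2_1,j >= x) for nonnegative weights ``lam``.

    Accuracy target: 1e-10 absolute or 1e-4 relative, whichever is looser.
    """
    if x < 0:
        raise ValueError("quadratic-form statistic must be >= 0")
    lam = np.asarray(weights, dtype=float)
    if lam.size == 0 or np.any(lam < 0) or not np.any(lam > 0):
        raise ValueError("weights must be nonnegative and not all zero")
    lam = lam[lam > 1e-12 * lam.max()]
    if x == 0:
        return 1.0
    m = lam.size
    # exact closed form for equal weights (covers m == 1 and rank-1 LD)
    if np.ptp(lam) <= 1e-12 * lam.max():
        return float(chi2.sf(x / lam.mean(), m))
    p = _ruben_sf(x, lam)
    if p is not None:
        return min(max(p, 0.0), 1.0)
    try:
        p, err = _imhof_sf(x, lam)
    except Exception:  # pragma: no cover - QUADPACK failure
        return min(max(_liu_sf(x, lam), 0.0), 1.0)
    if p < 1e-8 or err > 1e-6:
        # Imhof's absolute accuracy floor: switch to the saddlepoint
        sp = _saddlepoint_sf(x, lam)
        if np.isfinite(sp):
            return sp
        return min(max(_liu_sf(x, lam), 0.0), 1.0)
    return min(max(p, 0.0), 1.0)


# ---------------------------------------------------------------------------
# The enhancer test
# ---------------------------------------------------------------------------

def _pvalue_from_q(q: np.ndarray, R: LdMatrix) -> tuple[float, float]:
    if q.size != R.dim:
        raise ValueError(f"{q.size} p-values but LD matrix of dim {R.dim}")
    stat = float(q.mean())
    p = weighted_chisq_sf(float(q.sum()), R.eigenvalues)
    return stat, min(max(p, _P_FLOOR), 1.0)


def enhancer_pvalue(ps, R: LdMatrix) -> tuple[float, float]:
    """Mean chi-square test for one enhancer.

    ``T = mean(q_i)`` with ``q_i`` the chi-square(1) transforms of the SNP
    p-values; the p-value is the weighted chi-square survival of ``sum q_i``
    at the LD eigenvalues.  A single SNP returns its own p-value exactly.
    """
    return _pvalue_from_q(np.atleast_1d(snp_chisq(ps)), R)


def mc_pvalue_oracle(q_sum: float, R: LdMatrix, n_draws: int = 100_000,
                     rng_seed: int = 0) -> float:
    """Monte-Carlo reference for the enhancer p-value (test oracle).

    Draws Z ~ MVN(0, R) and reports the add-one-smoothed upper-tail
    frequency of sum Z^2.
    """
    if n_draws < 10_000:
        raise ValueError("use at least 1e4 draws")
    rng = np.random.default_rng(rng_seed)
    lam, V = np.linalg.eigh(R.R)
    lam = np.maximum(lam, 0.0)
    A = V * np.sqrt(lam)
    exceed = 0
    chunk = 200_000
    done = 0
    while done < n_draws:
        k = min(chunk, n_draws - done)
        Z = rng.standard_normal((k, R.dim)) @ A.T
        exceed += int(np.count_nonzero((Z ** 2).sum(axis=1) >= q_sum))
        done += k
    return (1 + exceed) / (n_draws + 1)


def annotate_snps(enhancers: IntervalSet, locs: pd.DataFrame,
                  window: int = 0) -> dict[str, list[str]]:
    """Map enhancer id -> SNP ids with (pos-1) in [start-window, end+window).

    SNPs may belong to several enhancers; enhancers with zero SNPs are
    omitted (and counted in the log).
    """
    mapping: dict[str, list[str]] = {}
    edf = enhancers.df
    for chrom, sub in locs.groupby("chrom", sort=False):
        esub = edf[edf["chrom"] == str(chrom)]
        if esub.empty:
            continue
        pos0 = sub["pos"].to_numpy(np.int64) - 1
        order = np.argsort(pos0, kind="mergesort")
        pos0 = pos0[order]
        ids = sub["snp_id"].to_numpy()[order]
        for row in esub.itertuples(index=False):
            lo = np.searchsorted(pos0, row.start - window, side="left")
            hi = np.searchsorted(pos0, row.end + window, side="left")
            if hi > lo:
                mapping.setdefault(row.id, []).extend(ids[lo:hi])
    n_empty = len(edf) - len(mapping)
    if n_empty:
        logger.info("annotate_snps: %d/%d enhancers have no SNPs",
                    n_empty, len(edf))
    return mapping


# ---------------------------------------------------------------------------
# Model / results objects
# ---------------------------------------------------------------------------

class EnhancerAssociationResults:
    """Per-enhancer association table with summary and plotting helpers."""

    def __init__(self, table: pd.DataFrame, n_dropped_snps: int = 0,
                 n_dropped_enhancers: int = 0):
        self.table = table
        self.n_dropped_snps = n_dropped_snps
        self.n_dropped_enhancers = n_dropped_enhancers

    def __len__(self) -> int:
        return len(self.table)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Enhancer association (SNP-wise mean chi-square model)",
            "=" * 56,
            f"enhancers tested      {len(t)}",
            f"enhancers dropped     {self.n_dropped_enhancers} (no usable SNPs)",
            f"SNPs dropped          {self.n_dropped_snps}",
            f"median SNPs/enhancer  {t['n_snps'].median():.1f}",
            f"min p-value           {t['p'].min():.3g}",
            f"lambda (median chi2)  "
            f"{np.median(snp_chisq(t['p'])) / chi2.ppf(0.5, 1):.3f}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EnhancerAssociationResults":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def plot_qq(self, ax=None):
        """Quantile-quantile plot of enhancer p-values against uniform."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = np.sort(self.table["p"].to_numpy())
        n = len(p)
        exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
        ax.scatter(exp, -np.log10(p), s=4)
        lim = max(exp.max(), -np.log10(p.min()))
        ax.plot([0, lim], [0, lim], color="grey", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        return ax


class EnhancerAssociationModel:
    """Mean chi-square enhancer association model.

    Parameters
    ----------
    enhancers : IntervalSet
        Regions to test (typically 1-kb centroid-normalized enhancers).
    gwas : DataFrame
        Columns ``snp_id, p`` (``n`` optional).
    snp_locs : DataFrame
        Columns ``snp_id, chrom, pos`` (1-based).
    panel : ReferencePanel
        Dosages from which LD is estimated.
    window : int
        Bp added on both sides when annotating SNPs to enhancers.
    """

    def __init__(self, enhancers: IntervalSet, gwas: pd.DataFrame,
                 snp_locs: pd.DataFrame, panel: ReferencePanel,
                 window: int = 0):
        self.enhancers = enhancers
        self.gwas = gwas
        self.snp_locs = snp_locs
        self.panel = panel
        self.window = window

    def fit(self) -> EnhancerAssociationResults:
        # p -> chi-square(1) once for the whole GWAS table
        q_all = chi2.isf(np.clip(self.gwas["p"].to_numpy(float),
                                 _P_FLOOR, 1.0), df=1)
        qmap = dict(zip(self.gwas["snp_id"], q_all))
        panel_snps = set(self.panel.snp_ids)
        mapping = annotate_snps(self.enhancers, self.snp_locs, self.window)
        rows = []
        n_dropped_snps = 0
        edf = self.enhancers.df.set_index("id")
        for enh_id, snps in mapping.items():
            usable = [s for s in dict.fromkeys(snps)
                      if s in qmap and s in panel_snps]
            n_dropped_snps += len(set(snps)) - len(usable)
            if not usable:
                continue
            try:
                R = ld_matrix(self.panel, usable)
            except ValueError:
                continue
            q = np.array([qmap[s] for s in R.snp_ids])
            stat, p = _pvalue_from_q(q, R)
            row = edf.loc[enh_id]
            rows.append((enh_id, row["chrom"], int(row["start"]),
                         int(row["end"]), R.dim, stat, p))
        if not rows:
            raise ValueError("no enhancer has usable SNPs: nothing to test")
        table = pd.DataFrame(rows, columns=["enhancer_id", "chrom", "start",
                                            "end", "n_snps", "stat", "p"])
        table["z"] = probit_z(table["p"].to_numpy())
        table = table.sort_values(["chrom", "start"]).reset_index(drop=True)
        n_dropped_enh = len(self.enhancers) - len(table)
        logger.info("region assoc: %d enhancers tested, %d dropped, "
                    "%d SNPs dropped", len(table), n_dropped_enh,
                    n_dropped_snps)
        return EnhancerAssociationResults(table, n_dropped_snps, n_dropped_enh)


def run_region_assoc(enhancers: IntervalSet, gwas: pd.DataFrame,
                     snp_locs: pd.DataFrame, panel: ReferencePanel,
                     window: int = 0) -> EnhancerAssociationResults:
    """Functional wrapper around :class:`EnhancerAssociationModel`."""
    return EnhancerAssociationModel(enhancers, gwas, snp_locs, panel,
                                    window=window).fit()
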