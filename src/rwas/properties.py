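"""Property and set association on enhancer Z-scores (the RWAS layer).

Each enhancer carries a probit Z-score from the region association step.
A quantitative property (AT richness, conservation, TSS distance, a motif's
footprint count...) is tested by regressing Z on the property plus technical
confounders; a competitive enhancer-set test uses a binary membership
covariate with a one-sided (greater) alternative, asking whether member
enhancers carry more association signal than non-members.  Cross-annotation
results are meta-analysed by taking the largest |Z| per property and
Bonferroni-adjusting for the number of annotations combined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_CONFOUNDERS = ("n_snps", "log_n_snps")


@dataclass
class PropertyModelSpec:
    """Configuration of the enhancer property regression."""

    covariates: tuple[str, ...] = ()
    confounders: tuple[str, ...] = DEFAULT_CONFOUNDERS
    sidedness: str = "two-sided"          # "two-sided" | "greater"
    correlation_mode: str = "ols"         # "ols" | "gls"
    extra_controls: tuple[str, ...] = ()  # e.g. ("total",) for footprint runs

    def __post_init__(self):
        clash = set(self.covariates) & set(self.confounders)
        if clash:
            raise ValueError(f"covariates also listed as confounders: {clash}")


def _confounder_frame(assoc: pd.DataFrame,
                      confounders: tuple[str, ...]) -> pd.DataFrame:
    """Build confounder columns from the association table.

    ``n_snps`` and ``log_n_snps`` are derived on the fly; any other name
    must already be a column of the association table.
    """
    out = pd.DataFrame(index=assoc.index)
    for name in confounders:
        if name == "log_n_snps":
            out[name] = np.log(assoc["n_snps"].astype(float))
        elif name in assoc.columns:
            out[name] = assoc[name].astype(float)
        else:
            raise KeyError(f"unknown confounder {name!r}")
    return out


def _independent_columns(base: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a maximal linearly independent subset of columns."""
    from scipy.linalg import qr

    _, r, piv = qr(base, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * diag[0]).sum()) if diag.size else 0
    return np.sort(piv[:rank])


def _fit_one(y: np.ndarray, x: np.ndarray, controls: np.ndarray,
             name: str, sidedness: str, sigma: np.ndarray | None = None):
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {name!r} has zero variance")
    # confounders redundant with the intercept (or each other) carry no
    # information; silently reduce them to an independent basis
    base = np.column_stack([np.ones_like(y), controls])
    base = base[:, _independent_columns(base)]
    # the tested covariate must add a dimension beyond the confounders
    coef, *_ = np.linalg.lstsq(base, x, rcond=None)
    resid = x - base @ coef
    if resid.var() <= 1e-12 * x.var():
        cond = np.linalg.cond(np.column_stack([base, x]))
        raise ValueError(
            f"covariate {name!r} is collinear with the confounders "
            f"(design condition number {cond:.3g})"
        )
    X = np.column_stack([base[:, :1], x, base[:, 1:]])
    model = sm.GLS(y, X, sigma=sigma) if sigma is not None else sm.OLS(y, X)
    res = model.fit()
    beta = res.params[1]
    se = res.bse[1]
    tstat = res.tvalues[1]
    if sidedness == "two-sided":
        p = res.pvalues[1]
    elif sidedness == "greater":
        p = stats.t.sf(tstat, res.df_resid)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return float(beta), float(se), float(tstat), float(p), len(y)


def fit_property(assoc: pd.DataFrame, covariates: pd.DataFrame,
                 spec: PropertyModelSpec | None = None,
                 sigma: np.ndarray | None = None) -> pd.DataFrame:
    """Marginal property regressions: z ~ intercept + covariate + confounders.

    Each covariate is tested in its own model, conditioned on the
    confounders (and on ``spec.extra_controls``, e.g. the total
    binding-site column for footprint covariates).  Missing rows are
    dropped listwise per covariate; two-sided t-test by default.

    ``assoc`` is the region-association table (needs ``enhancer_id, z,
    n_snps``); ``covariates`` is indexed by enhancer id.
    """
    if spec is None:
        spec = PropertyModelSpec(covariates=tuple(
            c for c in covariates.columns if c not in ("total",)))
    a = assoc.set_index("enhancer_id")
    conf = _confounder_frame(a, spec.confounders)
    names = spec.covariates or tuple(covariates.columns)
    rows = []
    for name in names:
        cols = [name] + [c for c in spec.extra_controls if c != name]
        data = a[["z"]].join(conf).join(covariates[cols], how="inner").dropna()
        n_par = 2 + len(spec.confounders) + len(cols) - 1
        if len(data) < n_par + 10:
            raise ValueError(
                f"covariate {name!r}: only {len(data)} complete rows for "
                f"{n_par} parameters"
            )
        controls = data[list(spec.confounders) + cols[1:]].to_numpy(float)
        sig = sigma
        if sig is not None:
            keep = a.index.get_indexer(data.index)
            sig = sigma[np.ix_(keep, keep)]
        beta, se, t, p, n = _fit_one(
            data["z"].to_numpy(float), data[name].to_numpy(float),
            controls, name, spec.sidedness, sigma=sig)
        rows.append((name, beta, se, t, p, n))
    return pd.DataFrame(rows, columns=["covariate", "beta", "se",
                                       "statistic", "p", "n_used"])


def fit_set(assoc: pd.DataFrame, membership: pd.Series,
            spec: PropertyModelSpec | None = None,
            name: str | None = None,
            sigma: np.ndarray | None = None) -> pd.Series:
    """Competitive enhancer-set test (one-sided greater).

    ``membership`` is a 0/1 series indexed by enhancer id; the test asks
    whether member enhancers have larger Z than non-members, conditional on
    the confounders.
    """
    if spec is None:
        spec = PropertyModelSpec(sidedness="greater")
    name = name or (membership.name or "set")
    mem = membership.dropna().astype(float)
    if mem.nunique() != 2 or set(mem.unique()) != {0.0, 1.0}:
        raise ValueError(f"set {name!r}: membership must contain both 0s and 1s")
    cov = mem.to_frame(name)
    res = fit_property(assoc, cov,
                       PropertyModelSpec(covariates=(name,),
                                         confounders=spec.confounders,
                                         sidedness="greater"),
                       sigma=sigma)
    row = res.iloc[0]
    n_members = int(mem.reindex(assoc["enhancer_id"]).fillna(0).sum())
    return pd.Series({"set": name, "beta": row["beta"], "se": row["se"],
                      "statistic": row["statistic"], "p": row["p"],
                      "set_size": n_members,
                      "background_size": int(row["n_used"])})


# ---------------------------------------------------------------------------
# Optional GLS correction for correlated neighbouring enhancers
# ---------------------------------------------------------------------------

def gls_correlation(snp_map: dict[str, list[str]], panel,
                    enhancer_ids: list[str] | None = None) -> pd.DataFrame:
    """Estimate the correlation of enhancer statistics induced by shared LD.

    corr(T_g, T_h) is approximated by
    ``sum_{i in g, j in h} r^2_ij / sqrt(sum_g r^2 * sum_h r^2)`` where r is
    the panel LD.  Enhancers with no SNPs in common LD get ~0.  Used to
    whiten the property regression in ``correlation_mode="gls"``.
    """
    from .region import ld_matrix

    ids = enhancer_ids or list(snp_map.keys())
    n = len(ids)
    C = np.eye(n)
    # pool all SNPs once; r^2 between enhancer SNP groups
    all_snps = sorted({s for g in ids for s in snp_map[g]
                       if s in set(panel.snp_ids)})
    if not all_snps:
        return pd.DataFrame(C, index=ids, columns=ids)
    R = ld_matrix(panel, all_snps)
    pos = {s: i for i, s in enumerate(R.snp_ids)}
    groups = [np.array([pos[s] for s in snp_map[g] if s in pos], dtype=int)
              for g in ids]
    R2 = R.R ** 2
    selfsum = np.array([R2[np.ix_(g, g)].sum() if len(g) else 0.0
                        for g in groups])
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = groups[i], groups[j]
            if len(gi) == 0 or len(gj) == 0:
                continue
            num = R2[np.ix_(gi, gj)].sum()
            if num > 0:
                C[i, j] = C[j, i] = num / np.sqrt(selfsum[i] * selfsum[j])
    return pd.DataFrame(C, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Meta-analysis and multiple testing
# ---------------------------------------------------------------------------

def meta_max_z(results: pd.DataFrame, n_annotations: int | None = None) -> pd.DataFrame:
    """Max-|Z| meta-analysis across annotations.

    ``results`` stacks per-annotation property tables (columns
    ``covariate, statistic, p`` and optionally ``annotation``).  Per
    covariate, the row with the largest |statistic| is kept and its
    two-sided p is Bonferroni-adjusted for the number of annotations
    combined; the sign of the best statistic is retained.
    """
    if n_annotations is None:
        n_annotations = (results["annotation"].nunique()
                         if "annotation" in results.columns else 1)
    rows = []
    for cov, sub in results.groupby("covariate", sort=False):
        best = sub.loc[sub["statistic"].abs().idxmax()]
        p_two = 2.0 * stats.norm.sf(abs(best["statistic"]))
        p_adj = min(1.0, n_annotations * p_two)
        rows.append({
            "covariate": cov,
            "statistic": float(best["statistic"]),
            "annotation": best.get("annotation", None),
            "p": p_two,
            "p_adj": p_adj,
            "n_annotations": n_annotations,
        })
    return pd.DataFrame(rows)


def adjust_pvalues(ps, method: str = "bonferroni") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    ps = np.asarray(ps, dtype=float)
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("p-values must be in (0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment {method!r}")
    return multipletests(ps, method=key)[1]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold controlling FWER at ``alpha``."""
    return alpha / n_tests


def attribute_group_test(values, in_group) -> dict[str, float]:
    """Wilcoxon rank-sum test of a per-TF attribute between two groups.

    Exact p for small groups (both <= 12, no ties), normal approximation
    with tie correction otherwise.  Returns two-sided and both one-sided
    p-values (``greater`` = in-group values larger).
    """
    values = np.asarray(values, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    a, b = values[in_group], values[~in_group]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(values)) < len(values)
    method = "exact" if (max(len(a), len(b)) <= 12 and not ties) else "asymptotic"
    out = {}
    for alt in ("two-sided", "greater", "less"):
        out[alt] = float(stats.mannwhitneyu(a, b, alternative=alt,
                                            method=method).pvalue)
    return out


# ---------------------------------------------------------------------------
# Model / results wrappers
# ---------------------------------------------------------------------------

class PropertyResults:
    """Property regression results with a summary table."""

    def __init__(self, table: pd.DataFrame, spec: PropertyModelSpec):
        self.table = table
        self.spec = spec

    def summary(self) -> str:
        t = self.table.copy()
        lines = ["Enhancer property association (covariate mode)",
                 "=" * 64,
                 f"confounders: {', '.join(self.spec.confounders)}  "
                 f"| test: {self.spec.sidedness}",
                 "",
                 f"{'covariate':<24}{'beta':>10}{'se':>10}{'t':>8}"
                 f"{'p':>12}{'n':>8}"]
        for row in t.itertuples(index=False):
            lines.append(f"{row.covariate:<24}{row.beta:>10.4f}{row.se:>10.4f}"
                         f"{row.statistic:>8.2f}{row.p:>12.3g}{row.n_used:>8d}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot_effects(self, ax=None):
        """Coefficient plot with ~95% intervals."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        y = np.arange(len(t))
        ax.errorbar(t["beta"], y, xerr=1.96 * t["se"], fmt="o")
        ax.axvline(0.0, color="grey", lw=1)
        ax.set_yticks(y, t["covariate"])
        ax.set_xlabel("effect on enhancer Z")
        return ax


class PropertyModel:
    """statsmodels-style front end to the property regression.

    Parameters
    ----------
    assoc : DataFrame or EnhancerAssociationResults
        Region association output (``enhancer_id, z, n_snps``).
    covariates : DataFrame indexed by enhancer id.
    spec : PropertyModelSpec, optional.
    """

    def __init__(self, assoc, covariates: pd.DataFrame,
                 spec: PropertyModelSpec | None = None,
                 sigma: np.ndarray | None = None):
        if hasattr(assoc, "table"):
            assoc = assoc.table
        self.assoc = assoc
        self.covariates = covariates
        self.spec = spec or PropertyModelSpec(covariates=tuple(
            c for c in covariates.columns if c != "total"))
        self.sigma = sigma

    def fit(self) -> PropertyResults:
        table = fit_property(self.assoc, self.covariates, self.spec,
                             sigma=self.sigma)
        return PropertyResults(table, self.spec)


class SetModel:
    """Competitive enhancer-set model over one or more memberships."""

    def __init__(self, assoc, memberships: pd.DataFrame,
                 spec: PropertyModelSpec | None = None):
        if hasattr(assoc, "table"):
            assoc = assoc.table
        self.assoc = assoc
        self.memberships = memberships
        self.spec = spec or PropertyModelSpec(sidedness="greater")

    def fit(self) -> pd.DataFrame:
        rows = [fit_set(self.assoc, self.memberships[c], self.spec, name=c)
                for c in self.memberships.columns]
        return pd.DataFrame(rows)
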