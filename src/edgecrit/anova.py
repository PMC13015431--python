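"""Mixed-design (split-plot) ANOVA with sphericity diagnostics and post-hocs.

Implements the 2 (group) x k (event type) mixed ANOVA used throughout the
pipeline: one between-subjects factor, one within-subjects factor, optional
continuous between-subject covariates (e.g. age), classical two-stratum
sums-of-squares decomposition with Type III effect coding, Mauchly's
sphericity test, the Greenhouse-Geisser epsilon correction (applied to the
within and interaction degrees of freedom when Mauchly's p < .05), Holm
step-down post-hocs for within-factor pairs and Tukey-Kramer for group
comparisons.

The modelling surface follows the statsmodels idiom: build a
:class:`MixedAnova` from a long-format DataFrame, call :meth:`MixedAnova.fit`
to obtain a :class:`MixedAnovaResults` carrying the effect table,
diagnostics and ``summary()``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.linalg import helmert
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


class DesignError(ValueError):
    """Raised for singular designs (empty group, lone subject, ...)."""


# --------------------------------------------------------------------------
# numpy core
# --------------------------------------------------------------------------

def _effect_code(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero (effect) coding; last level is the reference."""
    cats = list(pd.unique(labels))  # stable input order
    idx = {c: i for i, c in enumerate(cats)}
    codes = np.array([idx[v] for v in labels])
    n_lev = len(cats)
    X = np.zeros((labels.size, n_lev - 1))
    for j in range(n_lev - 1):
        X[codes == j, j] = 1.0
        X[codes == n_lev - 1, j] = -1.0
    return X, cats


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def mauchly_test(Y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Mauchly's W and its chi-square p-value on the pooled within-group
    covariance of the repeated measures.  k = 2 is trivially spherical
    (returns W = 1, p = 1)."""
    N, k = Y.shape
    if k == 2:
        return 1.0, 1.0
    n_e = 0
    S = np.zeros((k, k))
    for g in np.unique(groups):
        Yg = Y[groups == g]
        Yc = Yg - Yg.mean(0)
        S += Yc.T @ Yc
        n_e += Yg.shape[0] - 1
    S /= n_e
    C = helmert(k, full=False)
    St = C @ S @ C.T
    d = k - 1
    eig = np.linalg.eigvalsh(St)
    eig = np.maximum(eig, 0.0)
    denom = (eig.sum() / d) ** d
    W = float(np.prod(eig) / denom) if denom > 0 else 0.0
    if W <= 0:
        return 0.0, 0.0
    f = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * n_e)
    chi2 = -n_e * f * math.log(W)
    df = d * (d + 1) // 2 - 1
    return W, float(sstats.chi2.sf(chi2, df))


def gg_epsilon(Y: np.ndarray, groups: np.ndarray | None = None) -> float:
    """Box/Greenhouse-Geisser epsilon from the (pooled) within-subject
    covariance, clipped to [1/(k-1), 1]."""
    N, k = Y.shape
    if groups is None:
        groups = np.zeros(N, dtype=int)
    S = np.zeros((k, k))
    n_e = 0
    for g in np.unique(groups):
        Yg = Y[groups == g]
        Yc = Yg - Yg.mean(0)
        S += Yc.T @ Yc
        n_e += Yg.shape[0] - 1
    S /= max(n_e, 1)
    C = helmert(k, full=False)
    St = C @ S @ C.T
    d = k - 1
    tr = np.trace(St)
    tr2 = np.trace(St @ St)
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / (d * tr2)
    return float(min(1.0, max(1.0 / d, eps)))


def mixed_anova_arrays(Y: np.ndarray, groups: np.ndarray,
                       covariates: np.ndarray | None = None,
                       alpha: float = 0.05) -> dict:
    """Classical split-plot ANOVA on a wide (subjects x levels) matrix.

    Between stratum: Type III regression of subject means on effect-coded
    group (plus covariates); its residual is the subjects-within-groups
    error.  Within stratum: Type III regression of within-subject deviations
    on level and level-by-group terms; residual = subject-by-level error with
    (N - G)(k - 1) degrees of freedom.  GG-corrected p-values are reported
    for the within and interaction effects and adopted (column ``p``) when
    Mauchly's test rejects at ``alpha``.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    N, k = Y.shape
    glabels = pd.unique(groups)
    G = len(glabels)
    if G < 2:
        raise DesignError("need at least two groups")
    counts = [np.sum(groups == g) for g in glabels]
    if min(counts) < 2:
        raise DesignError("need >= 2 subjects per group")
    m = 0 if covariates is None else np.atleast_2d(covariates).shape[1]

    # ---- between-subjects stratum (on subject means)
    ybar = Y.mean(axis=1)
    Xg, _ = _effect_code(groups)
    ones = np.ones((N, 1))
    blocks = [ones, Xg]
    if m:
        cov = np.asarray(covariates, dtype=float).reshape(N, m)
        blocks.append(cov - cov.mean(0))
    Xfull = np.hstack(blocks)
    rss_full = _rss(Xfull, ybar)
    rss_nog = _rss(np.hstack([b for i, b in enumerate(blocks) if i != 1]), ybar)
    df_g = G - 1
    df_e_between = N - 1 - df_g - m
    ss_group = k * (rss_nog - rss_full)
    ss_err_b = k * rss_full
    F_group = (ss_group / df_g) / (ss_err_b / df_e_between)
    p_group = float(sstats.f.sf(F_group, df_g, df_e_between))

    cov_rows = []
    if m:
        for j in range(m):
            keep = np.delete(np.arange(Xfull.shape[1]), 1 + df_g + j, axis=0)
            rss_noc = _rss(Xfull[:, keep], ybar)
            ss_c = k * (rss_noc - rss_full)
            F_c = (ss_c / 1) / (ss_err_b / df_e_between)
            cov_rows.append(dict(source=f"covariate_{j}", ss=ss_c, df1=1,
                                 df2=df_e_between, F=F_c,
                                 p_unc=float(sstats.f.sf(F_c, 1, df_e_between)),
                                 p_gg=np.nan,
                                 p=float(sstats.f.sf(F_c, 1, df_e_between))))

    # ---- within-subjects stratum (on deviations from subject means)
    Z = (Y - ybar[:, None]).ravel()  # subject-major order
    lev = np.tile(np.arange(k), N)
    grp_rep = np.repeat(groups, k)
    Xl, _ = _effect_code(lev)
    Xgr, _ = _effect_code(grp_rep)
    inter = np.einsum("ij,il->ijl", Xl, Xgr).reshape(N * k, -1)
    onesw = np.ones((N * k, 1))
    Xw_full = np.hstack([onesw, Xgr, Xl, inter])
    rss_w_full = _rss(Xw_full, Z)
    rss_no_l = _rss(np.hstack([onesw, Xgr, inter]), Z)
    rss_no_i = _rss(np.hstack([onesw, Xgr, Xl]), Z)
    df_l = k - 1
    df_i = (k - 1) * (G - 1)
    df_e_w = (N - G) * (k - 1)
    ss_level = rss_no_l - rss_w_full
    ss_inter = rss_no_i - rss_w_full
    ss_err_w = rss_w_full
    ms_err_w = ss_err_w / df_e_w
    F_level = (ss_level / df_l) / ms_err_w
    F_inter = (ss_inter / df_i) / ms_err_w

    W, p_mauchly = mauchly_test(Y, groups)
    eps = gg_epsilon(Y, groups)
    use_gg = (k > 2) and (p_mauchly < alpha)

    def within_row(source, ss, df1, F):
        p_unc = float(sstats.f.sf(F, df1, df_e_w))
        # clamped: df shrinkage is a conservative correction, so the
        # corrected p never undercuts the uncorrected one (only matters F<1)
        p_gg = max(float(sstats.f.sf(F, eps * df1, eps * df_e_w)), p_unc)
        return dict(source=source, ss=ss, df1=(eps * df1 if use_gg else df1),
                    df2=(eps * df_e_w if use_gg else df_e_w), F=F,
                    p_unc=p_unc, p_gg=p_gg, p=(p_gg if use_gg else p_unc))

    rows = [dict(source="group", ss=ss_group, df1=df_g, df2=df_e_between,
                 F=F_group, p_unc=p_group, p_gg=np.nan, p=p_group)]
    rows += cov_rows
    rows.append(within_row("within", ss_level, df_l, F_level))
    rows.append(within_row("interaction", ss_inter, df_i, F_inter))
    table = pd.DataFrame(rows)
    return dict(table=table, mauchly_w=W, mauchly_p=p_mauchly,
                gg_epsilon=eps, sphericity_corrected=use_gg,
                ss_error_between=ss_err_b, df_error_between=df_e_between,
                ss_error_within=ss_err_w, df_error_within=df_e_w)


# --------------------------------------------------------------------------
# Model / Results surface
# --------------------------------------------------------------------------

class MixedAnova:
    """Mixed-design ANOVA model for a long-format table.

    Parameters
    ----------
    data : DataFrame with one row per (subject, within-level) observation.
    dv, within, between, subject : column names.
    covariates : optional list of numeric subject-level column names.

    Subjects missing any within-factor level are dropped listwise.
    """

    def __init__(self, data: pd.DataFrame, dv: str, within: str,
                 between: str, subject: str,
                 covariates: list[str] | None = None):
        self.dv, self.within, self.between = dv, within, between
        self.subject, self.covariates = subject, covariates or []
        wide = data.pivot_table(index=subject, columns=within, values=dv,
                                aggfunc="mean")
        self.levels = list(wide.columns)
        complete = wide.dropna()
        self.n_dropped = wide.shape[0] - complete.shape[0]
        meta_cols = [between] + self.covariates
        meta = data.drop_duplicates(subject).set_index(subject)[meta_cols]
        meta = meta.loc[complete.index]
        per_subj_groups = data.groupby(subject)[between].nunique()
        if (per_subj_groups > 1).any():
            raise DesignError("each subject must appear in exactly one group")
        self.wide = complete
        self.groups = meta[between].to_numpy()
        self.cov_values = (meta[self.covariates].to_numpy(dtype=float)
                           if self.covariates else None)
        self.data = data

    @classmethod
    def from_dataframe(cls, data, **kwargs) -> "MixedAnova":
        return cls(data, **kwargs)

    def fit(self, alpha: float = 0.05,
            posthocs: bool = True) -> "MixedAnovaResults":
        out = mixed_anova_arrays(self.wide.to_numpy(), self.groups,
                                 covariates=self.cov_values, alpha=alpha)
        res = MixedAnovaResults(model=self, alpha=alpha, **out)
        if posthocs:
            res.posthoc_within = posthoc_within(self.wide, method="holm")
            res.posthoc_between = posthoc_between(self.wide, self.groups)
        return res


@dataclass
class MixedAnovaResults:
    """Effect table, sphericity diagnostics and post-hoc comparisons."""

    model: MixedAnova
    table: pd.DataFrame
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    sphericity_corrected: bool
    ss_error_between: float
    df_error_between: int
    ss_error_within: float
    df_error_within: int
    alpha: float = 0.05
    posthoc_within: pd.DataFrame | None = None
    posthoc_between: pd.DataFrame | None = None

    def effect(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]

    def significant(self, source: str) -> bool:
        return bool(self.effect(source)["p"] < self.alpha)

    def to_json(self) -> str:
        import json

        out = dict(effects=self.table.to_dict(orient="records"),
                   mauchly_w=self.mauchly_w, mauchly_p=self.mauchly_p,
                   gg_epsilon=self.gg_epsilon,
                   sphericity_corrected=self.sphericity_corrected)
        for name, ph in (("posthoc_within", self.posthoc_within),
                         ("posthoc_between", self.posthoc_between)):
            if ph is not None:
                out[name] = ph.to_dict(orient="records")
        return json.dumps(out)

    def summary(self) -> str:
        lines = [
            f"Mixed ANOVA: {self.model.dv} ~ {self.model.between} x "
            f"{self.model.within} (N={self.model.wide.shape[0]}, "
            f"k={len(self.model.levels)})",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            f"Mauchly W={self.mauchly_w:.4f} p={self.mauchly_p:.4f}; "
            f"GG epsilon={self.gg_epsilon:.4f}"
            + (" (correction applied)" if self.sphericity_corrected else ""),
        ]
        if self.posthoc_within is not None and len(self.posthoc_within):
            lines += ["Post-hoc (within, Holm):",
                      self.posthoc_within.to_string(index=False,
                                                    float_format=lambda v: f"{v:.4f}")]
        if self.posthoc_between is not None and len(self.posthoc_between):
            lines += ["Post-hoc (between, Tukey-Kramer):",
                      self.posthoc_between.to_string(index=False,
                                                     float_format=lambda v: f"{v:.4f}")]
        return "\n".join(lines)

    def plot_means(self, ax=None):
        """Group x level mean plot with SE bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        wide, groups = self.model.wide, self.model.groups
        for g in pd.unique(groups):
            sub = wide[groups == g]
            ax.errorbar(range(sub.shape[1]), sub.mean(0),
                        yerr=sub.std(0) / np.sqrt(sub.shape[0]),
                        label=str(g), marker="o", capsize=3)
        ax.set_xticks(range(wide.shape[1]), [str(c) for c in wide.columns])
        ax.set(ylabel=self.model.dv, xlabel=self.model.within)
        ax.legend(title=self.model.between)
        return ax


def mixed_anova(data: pd.DataFrame, dv: str, within: str, between: str,
                subject: str, covariates: list[str] | None = None,
                alpha: float = 0.05) -> MixedAnovaResults:
    """Convenience wrapper: build and fit a :class:`MixedAnova`."""
    return MixedAnova(data, dv=dv, within=within, between=between,
                      subject=subject, covariates=covariates).fit(alpha=alpha)


# --------------------------------------------------------------------------
# Post-hoc comparisons
# --------------------------------------------------------------------------

def holm_correct(pvals: list[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(pvals, method="holm")[1]


def posthoc_within(wide: pd.DataFrame, method: str = "holm") -> pd.DataFrame:
    """All pairwise within-level paired t-tests, Holm-corrected."""
    pairs = list(itertools.combinations(wide.columns, 2))
    if len(wide.columns) < 2:
        return pd.DataFrame(columns=["pair", "t", "p_raw", "p_corrected",
                                     "method"])
    rows = []
    for a, b in pairs:
        t, p = sstats.ttest_rel(wide[a], wide[b])
        rows.append(dict(pair=f"{a} vs {b}", t=float(t), p_raw=float(p)))
    df = pd.DataFrame(rows)
    df["p_corrected"] = (holm_correct(df["p_raw"].tolist())
                         if method == "holm" else df["p_raw"])
    df["method"] = method
    return df


def posthoc_between(wide: pd.DataFrame, groups: np.ndarray,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer (studentized range, unequal n) on subject means."""
    glabels = pd.unique(groups)
    if len(glabels) < 2:
        return pd.DataFrame(columns=["pair", "t", "p_raw", "p_corrected",
                                     "method"])
    ybar = wide.to_numpy().mean(axis=1)
    res = pairwise_tukeyhsd(ybar, np.asarray(groups, dtype=str), alpha=alpha)
    pairs = [f"{a} vs {b}" for a, b in
             zip(np.asarray(res.groupsunique)[
                 np.triu_indices(len(res.groupsunique), 1)[0]],
                 np.asarray(res.groupsunique)[
                 np.triu_indices(len(res.groupsunique), 1)[1]])]
    return pd.DataFrame({
        "pair": pairs,
        "t": np.asarray(res.meandiffs, dtype=float),
        "p_raw": np.asarray(res.pvalues, dtype=float),
        "p_corrected": np.asarray(res.pvalues, dtype=float),
        "method": "tukey_kramer",
    })


def posthoc(data: pd.DataFrame, dv: str, within: str, between: str,
            subject: str, effect: str = "within",
            method: str = "holm") -> pd.DataFrame:
    """Post-hoc table for a long-format dataset.

    ``effect='within'`` with Holm on paired t-tests; ``effect='between'``
    with Tukey-Kramer (reduces to Tukey HSD at equal n).
    """
    model = MixedAnova(data, dv=dv, within=within, between=between,
                       subject=subject)
    if effect == "within":
        return posthoc_within(model.wide, method=method)
    if effect == "between":
        return posthoc_between(model.wide, model.groups)
    raise ValueError("effect must be 'within' or 'between'")
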