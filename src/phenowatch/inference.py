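"""Statistical stage: control-standardization, demographic screens,
covariate-adjusted group contrasts and NPI associations.

Every outcome is log-transformed (with a small offset when the outcome
contains zeros) and standardized to the control group: z = (log(x + d) -
mu_CN) / sd_CN, so effects are in control-SD units.  Group differences and
NPI associations come from ordinary least squares with age, sex and years
of education as covariates; the three pairwise group contrasts are read off
one model refit with a re-leveled reference (CN reference gives SCD-CN and
CI-CN, SCD reference gives CI-SCD).  Because the outcomes fall into three
highly correlated families (calls, app use, location), p-values are
Bonferroni-corrected by the fixed factor 3, not by the number of outcomes.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .catalog import FEATURE_NAMES, cluster_of

logger = logging.getLogger(__name__)

CONTRASTS = (("SCD", "CN"), ("CI", "CN"), ("CI", "SCD"))
DEFAULT_COVARIATES = ("age", "sex", "education_years")
BONFERRONI_FACTOR = 3  # the three outcome families

RESULT_COLUMNS = ["outcome", "cluster", "contrast", "beta", "se", "p_raw", "p_adj",
                  "n", "flag"]


def _cluster(name: str) -> str:
    try:
        return cluster_of(name)
    except KeyError:
        return "other"


# ---------------------------------------------------------------------------
# standardization

class ControlStandardizer(TransformerMixin, BaseEstimator):
    """Log-transform outcomes and z-score them against the control group.

    ``fit(X, y)`` takes the raw outcome table and a boolean control-group
    mask aligned with its rows (``y=None`` treats every row as control).
    The log offset is chosen per outcome by ``offset_policy`` and applied
    only to outcomes that contain zeros:

    - ``"min_positive"`` (default): the smallest positive observed value,
    - ``"half_min"``: half of it,
    - ``"one"``: 1.

    Outcomes whose control values are all missing, fewer than 2, or have
    zero variance on the log scale are dropped (recorded in ``dropped_``).

    Attributes
    ----------
    offset_, center_, scale_ : pd.Series per retained outcome
    dropped_ : dict outcome -> reason
    """

    def __init__(self, offset_policy: str = "min_positive"):
        self.offset_policy = offset_policy

    def fit(self, X: pd.DataFrame, y=None):
        if self.offset_policy not in ("min_positive", "half_min", "one"):
            raise ValueError(f"unknown offset policy: {self.offset_policy!r}")
        control = pd.Series(True, index=X.index) if y is None else pd.Series(
            np.asarray(y, dtype=bool), index=X.index)
        if not control.any():
            raise ValueError("control group is empty")
        offsets, centers, scales = {}, {}, {}
        self.dropped_: dict[str, str] = {}
        for col in X.columns:
            x = pd.to_numeric(X[col], errors="coerce")
            if (x < 0).any():
                raise ValueError(f"negative values in outcome {col!r}")
            has_zero = (x == 0).any()
            if has_zero:
                positive = x[x > 0]
                if self.offset_policy == "one":
                    delta = 1.0
                elif not len(positive):
                    delta = 1.0  # all-zero outcome; dropped below for zero SD
                elif self.offset_policy == "min_positive":
                    delta = float(positive.min())
                else:
                    delta = float(positive.min()) / 2.0
            else:
                delta = 0.0
            logx = np.log(x + delta)
            ctrl = logx[control.reindex(X.index, fill_value=False)].dropna()
            if len(ctrl) == 0:
                self.dropped_[col] = "all_missing_in_controls"
            elif len(ctrl) < 2:
                self.dropped_[col] = "insufficient_controls"
            elif float(ctrl.std(ddof=1)) == 0.0:
                self.dropped_[col] = "zero_control_sd"
            else:
                offsets[col] = delta
                centers[col] = float(ctrl.mean())
                scales[col] = float(ctrl.std(ddof=1))
        for col, why in self.dropped_.items():
            logger.info("outcome %s dropped from standardization: %s", col, why)
        self.offset_ = pd.Series(offsets, dtype=float)
        self.center_ = pd.Series(centers, dtype=float)
        self.scale_ = pd.Series(scales, dtype=float)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = list(self.center_.index)
        z = pd.DataFrame(index=X.index, columns=cols, dtype=float)
        for col in cols:
            x = pd.to_numeric(X[col], errors="coerce")
            z[col] = (np.log(x + self.offset_[col]) - self.center_[col]) / self.scale_[col]
        return z


def standardize(features: pd.DataFrame, control_ids,
                offset_policy: str = "min_positive") -> tuple[pd.DataFrame, ControlStandardizer]:
    """Standardize every catalogue outcome in ``features`` to the controls."""
    outcome_cols = [c for c in FEATURE_NAMES if c in features.columns]
    mask = features.index.isin(control_ids)
    est = ControlStandardizer(offset_policy=offset_policy)
    est.fit(features[outcome_cols], mask)
    return est.transform(features[outcome_cols]), est


# ---------------------------------------------------------------------------
# demographic screen (controls)

def demographic_screen(features: pd.DataFrame, outcomes=None) -> pd.DataFrame:
    """Nonparametric screens of outcomes against demographics in controls.

    Sex uses a two-sided Mann-Whitney U on raw values; age and education use
    Spearman rho; a Shapiro-Wilk normality check is reported per outcome.
    If a ``group`` column is present only CN rows are used.  Outcomes with
    fewer than 3 non-missing control values are skipped.
    """
    df = features[features["group"] == "CN"] if "group" in features.columns else features
    outcomes = outcomes or [c for c in FEATURE_NAMES if c in df.columns]
    rows = []
    for col in outcomes:
        x = pd.to_numeric(df[col], errors="coerce")
        ok = x.notna()
        if int(ok.sum()) < 3:
            logger.info("outcome %s skipped in demographic screen: <3 control values", col)
            continue
        with warnings.catch_warnings():
            # constant outcomes are reported with an undefined normality stat
            warnings.simplefilter("ignore", UserWarning)
            sw = stats.shapiro(x[ok].to_numpy()[:5000])
        rows.append({"outcome": col, "variable": "normality", "test": "shapiro",
                     "statistic": float(sw.statistic), "p": float(sw.pvalue),
                     "n": int(ok.sum())})
        if "sex" in df.columns:
            f = x[ok & (df["sex"] == "female")]
            m = x[ok & (df["sex"] == "male")]
            if len(f) and len(m):
                u = stats.mannwhitneyu(f, m, alternative="two-sided")
                rows.append({"outcome": col, "variable": "sex", "test": "mannwhitneyu",
                             "statistic": float(u.statistic), "p": float(u.pvalue),
                             "n": int(len(f) + len(m))})
        for var, source in (("age", "age"), ("education", "education_years")):
            if source not in df.columns:
                continue
            v = pd.to_numeric(df[source], errors="coerce")
            both = ok & v.notna()
            if int(both.sum()) < 3:
                continue
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                # a constant feature legitimately yields an undefined rho
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                rho, p = stats.spearmanr(x[both], v[both])
            rows.append({"outcome": col, "variable": var, "test": "spearman",
                         "statistic": float(rho) if np.isfinite(rho) else np.nan,
                         "p": float(p) if np.isfinite(p) else np.nan,
                         "n": int(both.sum())})
    return pd.DataFrame(rows, columns=["outcome", "variable", "test", "statistic",
                                       "p", "n"])


# ---------------------------------------------------------------------------
# group contrasts

def _adjust(p: float, factor: int) -> float:
    return float(min(1.0, factor * p)) if np.isfinite(p) else np.nan


def _fit_ols(df: pd.DataFrame, reference: str, covariates) -> tuple:
    terms = []
    for c in covariates:
        terms.append(f"C({c})" if df[c].dtype == object else c)
    formula = f"z ~ C(group, Treatment(reference='{reference}'))"
    if terms:
        formula += " + " + " + ".join(terms)
    model = smf.ols(formula, data=df)
    rank_deficient = np.linalg.matrix_rank(model.exog) < model.exog.shape[1]
    return model.fit(), rank_deficient


class GroupContrastModel(BaseEstimator):
    """Pairwise diagnostic-group contrasts on standardized outcomes.

    ``fit(Z, meta)`` takes the standardized outcome table and an aligned
    participant table with ``group`` and the covariate columns.  For each
    outcome one OLS model ``z ~ group + covariates`` is fit with the CN
    reference (yielding SCD-CN and CI-CN) and refit with the SCD reference
    (yielding CI-SCD); p-values are coefficient t-tests, adjusted by the
    fixed Bonferroni factor.  Results land in ``results_``.
    """

    def __init__(self, covariates=DEFAULT_COVARIATES, bonferroni: int = BONFERRONI_FACTOR,
                 min_group_n: int = 3):
        self.covariates = covariates
        self.bonferroni = bonferroni
        self.min_group_n = min_group_n

    def fit(self, Z: pd.DataFrame, meta: pd.DataFrame):
        rows = []
        covs = list(self.covariates)
        for outcome in Z.columns:
            df = meta[["group", *covs]].copy()
            df["z"] = pd.to_numeric(Z[outcome], errors="coerce")
            df = df.dropna()
            sizes = df["group"].value_counts()
            usable = set(sizes.index[sizes >= self.min_group_n])
            base_flag = ""
            if len(usable) < 2:
                for a, b in CONTRASTS:
                    rows.append({"outcome": outcome, "cluster": _cluster(outcome),
                                 "contrast": f"{a}-{b}", "beta": np.nan, "se": np.nan,
                                 "p_raw": np.nan, "p_adj": np.nan, "n": len(df),
                                 "flag": "insufficient_groups"})
                continue
            sub = df[df["group"].isin(usable)]
            fits = {}
            for ref in ("CN", "SCD"):
                if ref in usable:
                    fits[ref], deficient = _fit_ols(sub, ref, covs)
                    if deficient:
                        base_flag = "rank_deficient"
            for a, b in CONTRASTS:
                flag = base_flag
                beta = se = p = np.nan
                if a in usable and b in usable and b in fits:
                    name = f"C(group, Treatment(reference='{b}'))[T.{a}]"
                    res = fits[b]
                    beta = float(res.params[name])
                    se = float(res.bse[name])
                    p = float(res.pvalues[name])
                elif a not in usable or b not in usable:
                    flag = "insufficient_n"
                rows.append({"outcome": outcome, "cluster": _cluster(outcome),
                             "contrast": f"{a}-{b}", "beta": beta, "se": se,
                             "p_raw": p, "p_adj": _adjust(p, self.bonferroni),
                             "n": int(len(sub)), "flag": flag})
        self.results_ = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        return self


def group_contrasts(Z: pd.DataFrame, meta: pd.DataFrame,
                    covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    return GroupContrastModel(covariates=covariates).fit(Z, meta).results_


# ---------------------------------------------------------------------------
# NPI associations

class NpiAssociationModel(BaseEstimator):
    """Per-outcome OLS slope of a standardized outcome on an NPI score.

    Only participants with the score present enter; the same covariates and
    Bonferroni factor as the group contrasts apply.  ``adjust_group=True``
    adds diagnostic group as an extra covariate.  Results with fewer than
    ``low_n`` complete cases are flagged; a constant score is flagged and
    yields no estimate.
    """

    def __init__(self, score_col: str = "npi_total", covariates=DEFAULT_COVARIATES,
                 adjust_group: bool = False, bonferroni: int = BONFERRONI_FACTOR,
                 low_n: int = 10):
        self.score_col = score_col
        self.covariates = covariates
        self.adjust_group = adjust_group
        self.bonferroni = bonferroni
        self.low_n = low_n

    def fit(self, Z: pd.DataFrame, meta: pd.DataFrame):
        rows = []
        covs = list(self.covariates)
        extra = ["group"] if self.adjust_group else []
        for outcome in Z.columns:
            df = meta[[self.score_col, *covs, *extra]].copy()
            df["z"] = pd.to_numeric(Z[outcome], errors="coerce")
            df = df.dropna()
            flag = ""
            beta = se = p = np.nan
            n_min_fit = len(covs) + len(extra) + 3
            if df[self.score_col].nunique() <= 1:
                flag = "constant_predictor"
            elif len(df) < n_min_fit:
                flag = "insufficient_n"
            else:
                terms = [f"C({c})" if df[c].dtype == object else c
                         for c in covs + extra]
                formula = f"z ~ {self.score_col}" + ("" if not terms
                                                     else " + " + " + ".join(terms))
                res = smf.ols(formula, data=df).fit()
                beta = float(res.params[self.score_col])
                se = float(res.bse[self.score_col])
                p = float(res.pvalues[self.score_col])
                if len(df) < self.low_n:
                    flag = "low_n"
            rows.append({"outcome": outcome, "cluster": _cluster(outcome),
                         "contrast": self.score_col, "beta": beta, "se": se,
                         "p_raw": p, "p_adj": _adjust(p, self.bonferroni),
                         "n": int(len(df)), "flag": flag})
        self.results_ = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        return self


def npi_association(Z: pd.DataFrame, meta: pd.DataFrame, score_col: str = "npi_total",
                    covariates=DEFAULT_COVARIATES,
                    adjust_group: bool = False) -> pd.DataFrame:
    return NpiAssociationModel(score_col=score_col, covariates=covariates,
                               adjust_group=adjust_group).fit(Z, meta).results_


# ---------------------------------------------------------------------------
# reporting

def significance_tier(p_adj: float) -> str:
    """Marker tiers on adjusted p: '**' < .01, '*' < .05, '.' < .10, else ''."""
    if not np.isfinite(p_adj):
        return ""
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    if p_adj < 0.10:
        return "."
    return ""


def _wide_contrast_table(results: pd.DataFrame) -> pd.DataFrame:
    out = None
    for contrast, sub in results.groupby("contrast", sort=False):
        sub = sub.set_index("outcome")
        block = pd.DataFrame({
            f"{contrast} beta (SE)": [
                "" if not np.isfinite(b) else f"{b:.2f} ({s:.2f})"
                for b, s in zip(sub["beta"], sub["se"])],
            f"{contrast} p_adj": sub["p_adj"].round(3).values,
            f"{contrast} sig": [significance_tier(p) for p in sub["p_adj"]],
        }, index=sub.index)
        out = block if out is None else out.join(block)
    ordered = [o for o in FEATURE_NAMES if o in out.index]
    return out.reindex(ordered + [o for o in out.index if o not in ordered])


def plot_heatmap(results: pd.DataFrame, path) -> None:
    """Outcome x contrast heat map of betas with significance-tier labels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    beta = results.pivot_table(index="outcome", columns="contrast", values="beta",
                               sort=False, dropna=False)
    padj = results.pivot_table(index="outcome", columns="contrast", values="p_adj",
                               sort=False, dropna=False)
    if beta.size == 0 or beta.isna().all().all():
        return
    order = [o for o in FEATURE_NAMES if o in beta.index]
    beta, padj = beta.reindex(order), padj.reindex(order)
    fig, ax = plt.subplots(figsize=(2 + 1.4 * beta.shape[1], 1 + 0.28 * beta.shape[0]))
    lim = max(1.0, float(np.nanmax(np.abs(beta.to_numpy()))) if beta.size else 1.0)
    im = ax.imshow(beta.to_numpy(dtype=float), cmap="RdYlGn", vmin=-lim, vmax=lim,
                   aspect="auto")
    ax.set_xticks(range(beta.shape[1]), beta.columns)
    ax.set_yticks(range(beta.shape[0]), beta.index, fontsize=7)
    for i in range(beta.shape[0]):
        for j in range(beta.shape[1]):
            tier = significance_tier(float(padj.iloc[i, j]))
            if tier:
                ax.text(j, i, tier, ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="standardized effect (control SD)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def summarize(contrasts: pd.DataFrame, out_dir, *, npi: pd.DataFrame | None = None,
              screen: pd.DataFrame | None = None, plots: bool = True) -> None:
    """Write the deterministic report set: tidy + wide contrast tables,
    optional NPI and demographic-screen tables, and effect heat maps."""
    if not len(contrasts):
        raise ValueError("no contrast results to summarize")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tidy = contrasts.copy()
    tidy["sig"] = [significance_tier(p) for p in tidy["p_adj"]]
    tidy.to_csv(out_dir / "contrasts_tidy.csv", index=False)
    _wide_contrast_table(contrasts).to_csv(out_dir / "contrasts.csv")
    if plots:
        plot_heatmap(contrasts, out_dir / "contrasts_heatmap.png")
        plot_heatmap(contrasts, out_dir / "contrasts_heatmap.svg")
    if npi is not None and len(npi):
        npi = npi.copy()
        npi["sig"] = [significance_tier(p) for p in npi["p_adj"]]
        npi.to_csv(out_dir / "npi.csv", index=False)
        if plots:
            plot_heatmap(npi, out_dir / "npi_heatmap.png")
    if screen is not None and len(screen):
        screen.to_csv(out_dir / "demographic_screen.csv", index=False)
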