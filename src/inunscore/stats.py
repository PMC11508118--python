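"""Field-trial and soil-survey statistics.

Simple regressions of yield and water conditions on the inundation
score, Spearman rank correlations among soil physicochemical
properties, group comparisons (Welch t, one-way ANOVA with Tukey HSD
and a compact letter display), PCA of standardized site variables, and
the two soil-chemistry saturation indices (base saturation and
effective base saturation).

All tests are two-sided with alpha = 0.05 unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .util import round_half_up

TREATMENTS = ("CT", "NK", "NK+PR", "NK+TSP")


# ---------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One field site of the fertilization trial.

    ``yield_by_treatment`` maps each of CT, NK, NK+PR, NK+TSP to a
    ``(mean, sd)`` pair of grain yields in Mg/ha (site means over the
    trial years); submergence and cumulative water depth are site-level
    seasonal means.
    """

    site_name: str
    soil_group: str
    submergence_days: float
    submergence_days_sd: float
    cumulative_water_depth: float
    cumulative_water_depth_sd: float
    yield_by_treatment: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        missing = [t for t in TREATMENTS if t not in self.yield_by_treatment]
        if missing:
            raise ValueError(f"{self.site_name}: missing treatments {missing}")
        for t, (m, _sd) in self.yield_by_treatment.items():
            if m < 0:
                raise ValueError(f"{self.site_name}: negative yield for {t}")

    def yield_mean(self, treatment: str) -> float:
        return self.yield_by_treatment[treatment][0]


@dataclass
class HorizonRecord:
    """One soil horizon of a profile pit.

    Texture fractions are percent (sand+silt+clay ≈ 100 when present);
    carbon/nitrogen in g/kg, Bray phosphorus in mg P/kg, exchangeable
    cations and CEC in cmolc/kg, BS/EBS in percent.  Fields may be None
    for horizons sampled for texture only (or not sampled at all).
    """

    site_name: str
    soil_group: str
    horizon_name: str
    depth_top: float | None = None
    depth_bottom: float | None = None
    texture_class: str | None = None
    sand: float | None = None
    silt: float | None = None
    clay: float | None = None
    total_c: float | None = None
    total_n: float | None = None
    ph_h2o: float | None = None
    ph_kcl: float | None = None
    ec: float | None = None
    bray1_p: float | None = None
    bray2_p: float | None = None
    exch_al: float | None = None
    exch_na: float | None = None
    exch_k: float | None = None
    exch_ca: float | None = None
    exch_mg: float | None = None
    cec: float | None = None
    bs: float | None = None
    ebs: float | None = None

    def __post_init__(self):
        if self.has_texture():
            total = self.sand + self.silt + self.clay
            if not (99.0 <= total <= 101.0):
                raise ValueError(
                    f"{self.site_name} {self.horizon_name}: sand+silt+clay = {total:.1f} not ~100"
                )

    def has_texture(self) -> bool:
        return None not in (self.sand, self.silt, self.clay)

    def has_complete_chemistry(self) -> bool:
        keys = ("total_c", "total_n", "ph_h2o", "ph_kcl", "ec", "bray1_p", "bray2_p",
                "exch_al", "exch_na", "exch_k", "exch_ca", "exch_mg", "cec")
        return all(getattr(self, k) is not None for k in keys)


@dataclass
class RegressionFit:
    """Simple (one-predictor) OLS fit summary."""

    slope: float
    intercept: float
    r2: float
    r2_adj: float
    p_value: float
    n: int


@dataclass
class PcaFit:
    """PCA of standardized variables (correlation-matrix PCA)."""

    loadings: np.ndarray        # variables x components, unit-norm columns
    sdev: np.ndarray            # per-component standard deviations
    proportion: np.ndarray      # variance fractions, sum to 1
    cumulative: np.ndarray
    variables: list[str] | None = None


# ---------------------------------------------------------------------
# Regression and correlation
# ---------------------------------------------------------------------

def ols_fit(x, y) -> RegressionFit:
    """Ordinary least squares of y on x with intercept.

    Adjusted R² uses 1 − (1−R²)(n−1)/(n−2); the p-value is the
    two-sided t-test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: degenerate design")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    return RegressionFit(
        slope=float(slope),
        intercept=float(intercept),
        r2=float(model.rsquared),
        r2_adj=float(model.rsquared_adj),
        p_value=float(model.pvalues[1]),
        n=n,
    )


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D sequences with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def correlation_matrix(df, rows: list[str], cols: list[str], method: str = "pearson"):
    """Pairwise correlation (and p) between two variable lists.

    ``method`` is ``"pearson"`` (product-moment; the published
    texture-vs-chemistry matrix reproduces under this one) or
    ``"spearman"`` (rank).  Returns two DataFrames (coefficient, p)
    indexed by ``rows`` x ``cols``.
    """
    import pandas as pd

    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    rho = pd.DataFrame(index=rows, columns=cols, dtype=float)
    pval = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for a in rows:
        for b in cols:
            res = fn(df[a], df[b])
            rho.loc[a, b] = res.statistic
            pval.loc[a, b] = res.pvalue
    return rho, pval


def spearman_matrix(df, rows: list[str], cols: list[str]):
    """Pairwise Spearman rho (and p); see :func:`correlation_matrix`."""
    return correlation_matrix(df, rows, cols, method="spearman")


# ---------------------------------------------------------------------
# Treatment effects
# ---------------------------------------------------------------------

def yield_increase(trial: TrialRecord, treatment: str) -> float:
    """Yield gain of a fertilized treatment over the unfertilized control."""
    if treatment == "CT":
        raise KeyError("increase is relative to CT; pick a fertilized treatment")
    if treatment not in trial.yield_by_treatment:
        raise KeyError(f"{trial.site_name}: no treatment {treatment!r}")
    return trial.yield_mean(treatment) - trial.yield_mean("CT")


def relative_yield(trial: TrialRecord) -> float:
    """Phosphate-rock yield relative to TSP: mean(NK+PR) / mean(NK+TSP)."""
    tsp = trial.yield_mean("NK+TSP")
    if tsp <= 0:
        raise ZeroDivisionError(f"{trial.site_name}: NK+TSP mean yield must be > 0")
    return trial.yield_mean("NK+PR") / tsp


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _compact_letter_display(labels: list[str], not_different: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different.  Letters
    are assigned greedily: start with one column of all groups, split
    it for every significant pair, absorb duplicate columns.
    """
    columns: list[set[str]] = [set(labels)]
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            if frozenset((gi, gj)) in not_different:
                continue
            new_cols = []
            for col in columns:
                if gi in col and gj in col:
                    new_cols.append(col - {gi})
                    new_cols.append(col - {gj})
                else:
                    new_cols.append(col)
            # absorb columns that are subsets of another
            columns = [c for c in new_cols if not any(c < d for d in new_cols)]
            # drop exact duplicates, keep order
            seen, uniq = [], []
            for c in columns:
                if c not in seen:
                    seen.append(c)
                    uniq.append(c)
            columns = uniq
    letters = {g: "" for g in labels}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in labels:
            if g in col:
                letters[g] += letter
    return letters


def anova_tukey(groups: dict[str, list[float]], alpha: float = 0.05):
    """One-way ANOVA with all-pairs Tukey HSD and a letter display.

    Returns ``(F, p, letters, tukey_frame)``; ``letters`` maps each
    group label to its compact-letter-display string (groups sharing a
    letter are not significantly different at ``alpha``).  Unbalanced
    groups use the Tukey–Kramer adjustment.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has n < 2")
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    f_stat, p = sps.f_oneway(*arrays)
    flat = np.concatenate(arrays)
    tags = np.concatenate([[g] * len(groups[g]) for g in labels])
    if np.ptp(flat) == 0:
        # all observations identical: nothing distinguishable
        letters = {g: "a" for g in labels}
        return float("nan"), 1.0, letters, None
    tk = pairwise_tukeyhsd(flat, tags, alpha=alpha)
    not_diff = set()
    uniq = [str(g) for g in tk.groupsunique]
    pairs = [(uniq[i], uniq[j]) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]
    for (g1, g2), reject in zip(pairs, np.asarray(tk.reject)):
        if not reject:
            not_diff.add(frozenset((g1, g2)))
    letters = _compact_letter_display(labels, not_diff)
    return float(f_stat), float(p), letters, tk


# ---------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------

def pca_standardized(data, variables: list[str] | None = None) -> PcaFit:
    """PCA of z-scored columns (PCA of the correlation structure).

    Columns are standardized to zero mean and unit (ddof=1) variance;
    component standard deviations are the square roots of the
    eigenvalues of the sample correlation matrix, and variance
    proportions are eigenvalues over their total.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 observations and >= 2 variables")
    if np.isnan(X).any():
        raise ValueError("missing values are not allowed; complete the matrix first")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        idx = int(np.argmax(sd == 0))
        name = variables[idx] if variables else f"column {idx}"
        raise ValueError(f"zero-variance column cannot be standardized: {name}")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]))
    pca.fit(Z)
    eigvals = pca.explained_variance_
    loadings = pca.components_.T  # variables x components, unit columns
    sdev = np.sqrt(eigvals)
    proportion = eigvals / eigvals.sum()
    return PcaFit(
        loadings=loadings,
        sdev=sdev,
        proportion=proportion,
        cumulative=np.cumsum(proportion),
        variables=list(variables) if variables else None,
    )


# ---------------------------------------------------------------------
# Soil chemistry indices
# ---------------------------------------------------------------------

def base_saturation(horizon: HorizonRecord, ndigits: int | None = None) -> float:
    """Base saturation: 100 × (Na + K + Ca + Mg) / CEC, in percent.

    May exceed 100 when the ammonium-acetate bases overshoot the
    measured CEC.
    """
    for k in ("exch_na", "exch_k", "exch_ca", "exch_mg", "cec"):
        if getattr(horizon, k) is None:
            raise ValueError(f"{horizon.site_name} {horizon.horizon_name}: {k} missing")
    if horizon.cec <= 0:
        raise ValueError(f"{horizon.site_name} {horizon.horizon_name}: CEC must be > 0")
    bases = horizon.exch_na + horizon.exch_k + horizon.exch_ca + horizon.exch_mg
    bs = 100.0 * bases / horizon.cec
    return round_half_up(bs, ndigits) if ndigits is not None else bs


def effective_base_saturation(horizon: HorizonRecord, ndigits: int | None = None) -> float:
    """Effective base saturation: 100 × bases / (bases + exchangeable Al)."""
    for k in ("exch_na", "exch_k", "exch_ca", "exch_mg", "exch_al"):
        if getattr(horizon, k) is None:
            raise ValueError(f"{horizon.site_name} {horizon.horizon_name}: {k} missing")
    bases = horizon.exch_na + horizon.exch_k + horizon.exch_ca + horizon.exch_mg
    denom = bases + horizon.exch_al
    if denom <= 0:
        raise ValueError(
            f"{horizon.site_name} {horizon.horizon_name}: bases + Al must be > 0"
        )
    ebs = 100.0 * bases / denom
    return round_half_up(ebs, ndigits) if ndigits is not None else ebs
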