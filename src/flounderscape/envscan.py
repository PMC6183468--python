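"""Locus-environment association scans.

Two complementary detectors of spatially divergent selection:

* A univariate Bayesian scan in the Coop et al. standardized-allele-
  frequency model: populations share a background covariance matrix
  (estimated here by a closed-form moment estimator with a ridge), and
  each locus x environmental variable pair receives a Bayes factor
  comparing an environmental-association model against the null,
  computed in whitened space with a Zellner g-prior closed form.
  Significance of the exceedance counts (BF > 3) is calibrated with
  permutations of the environmental data, a two-sample
  Kolmogorov-Smirnov test on the BF distributions and a binomial exact
  test on the exceedance counts.

* A multivariate redundancy analysis (RDA): individual allele
  frequencies are regressed on the standardized environmental matrix,
  the fitted values decomposed into constrained axes, and loci scoring
  beyond +/- 3 SD on any of the first three axes flagged as outliers,
  then confirmed by per-locus ordinary regression (p < 0.001) with a
  full permutation null over both counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (EmptyResultError, InvalidParameterError)
from .genotypes import GenotypeMatrix, impute_mean

logger = logging.getLogger(__name__)

ENV_VARIABLES = ("distance_km", "depth_m", "bottom_temp", "salinity_psu")


# ---------------------------------------------------------------------------
# grouping and standardization

@dataclass
class PopulationGrouping:
    """Assignment of individuals to coastwise groups split at breaks."""

    breaks: np.ndarray            # ordered break latitudes (south to north)
    group_index: np.ndarray       # per individual, 0 = southernmost group

    @property
    def n_groups(self) -> int:
        return int(self.group_index.max()) + 1

    def sizes(self) -> np.ndarray:
        return np.bincount(self.group_index, minlength=self.n_groups)


def assign_groups(latitudes, breaks) -> PopulationGrouping:
    """Group individuals by latitude between ordered break positions.

    Group index counts the breaks at or south of the individual, so an
    individual exactly on a break joins the northern side.  Empty
    groups are dropped with a warning and indices re-packed.
    """
    lat = np.asarray(latitudes, float)
    brk = np.sort(np.asarray(breaks, float))
    if len(np.unique(brk)) != len(brk):
        raise InvalidParameterError("breaks must be distinct")
    idx = np.searchsorted(brk, lat, side="right")
    present = np.unique(idx)
    if len(present) < len(brk) + 1:
        logger.warning("dropping %d empty group(s)",
                       len(brk) + 1 - len(present))
    remap = {g: i for i, g in enumerate(present)}
    idx = np.array([remap[g] for g in idx])
    return PopulationGrouping(breaks=brk, group_index=idx)


@dataclass
class EnvTable:
    """Individual, group-averaged and group-standardized environments."""

    individual: pd.DataFrame
    group_means: pd.DataFrame
    standardized: pd.DataFrame

    @property
    def variables(self) -> list[str]:
        return list(self.standardized.columns)


def standardize_env(env: pd.DataFrame,
                    grouping: PopulationGrouping) -> EnvTable:
    """Average each variable within groups, then z-score across groups.

    The denominator is the population SD over the group means, so the
    standardized columns have mean 0 and SD 1 across groups exactly.
    """
    if grouping.n_groups < 2:
        raise InvalidParameterError("need >= 2 groups to standardize")
    if len(env) != len(grouping.group_index):
        raise InvalidParameterError("env rows must match individuals")
    num = env.select_dtypes("number")
    means = num.groupby(grouping.group_index).mean()
    std = means.std(axis=0, ddof=0)
    for v, s in std.items():
        if s == 0:
            raise InvalidParameterError(
                f"environmental variable {v!r} has zero variance across "
                "groups")
    standardized = (means - means.mean(axis=0)) / std
    return EnvTable(individual=env.copy(), group_means=means,
                    standardized=standardized)


# ---------------------------------------------------------------------------
# covariance model and Bayes factors

@dataclass
class CovarianceModel:
    """Among-group covariance of standardized allele frequencies."""

    omega: np.ndarray
    ridge: float
    n_loci: int
    _whitener: np.ndarray | None = field(default=None, repr=False)

    def whitener(self) -> np.ndarray:
        """Symmetric inverse square root of omega."""
        if self._whitener is None:
            w, v = np.linalg.eigh(self.omega)
            if w.min() <= 0:
                raise InvalidParameterError("covariance not positive definite")
            self._whitener = (v / np.sqrt(w)) @ v.T
        return self._whitener


def group_allele_freqs(matrix: GenotypeMatrix,
                       grouping: PopulationGrouping) -> np.ndarray:
    """(n_groups, n_loci) alternate-allele frequencies over called
    genotypes."""
    out = np.empty((grouping.n_groups, matrix.n_loci))
    for g in range(grouping.n_groups):
        sub = matrix.take_individuals(
            np.flatnonzero(grouping.group_index == g))
        out[g] = sub.alt_allele_freq()
    return out


def estimate_covariance(freqs: np.ndarray, ridge: float = 1e-3
                        ) -> CovarianceModel:
    """Moment estimator of the among-group frequency covariance.

    Each locus contributes the outer product of its standardized
    deviation vector x = (p - pbar) / sqrt(pbar (1 - pbar)); the
    average over loci plus a ridge gives a symmetric positive-definite
    background model.  Loci fixed across all groups carry no signal and
    are excluded.
    """
    freqs = np.asarray(freqs, float)
    P, L = freqs.shape
    if P < 2:
        raise InvalidParameterError("need >= 2 groups")
    if L < 50:
        logger.warning("covariance estimated from only %d loci", L)
    pbar = np.nanmean(freqs, axis=0)
    usable = (pbar > 0) & (pbar < 1) & np.isfinite(pbar)
    if not usable.any():
        raise EmptyResultError("no polymorphic loci for covariance")
    x = (freqs[:, usable] - pbar[usable]) / np.sqrt(
        pbar[usable] * (1 - pbar[usable]))
    omega = (x @ x.T) / x.shape[1] + ridge * np.eye(P)
    return CovarianceModel(omega=omega, ridge=ridge,
                           n_loci=int(usable.sum()))


#: Default g-prior scale of the environmental effect.  In whitened units
#: the null residuals have unit variance by construction (the background
#: covariance IS the null model), so g is the prior variance of the
#: association amplitude in background-SD units: g = 100 says a selected
#: locus may plausibly shift by ~10 background SDs per environmental SD,
#: the order seen for strong clines over a near-panmictic background.
DEFAULT_BF_G = 100.0


def env_bayes_factor(x_std: np.ndarray, e_std: np.ndarray,
                     cov: CovarianceModel,
                     g: float = DEFAULT_BF_G) -> float:
    """Closed-form Bayes factor for one locus-environment pair.

    The locus's standardized group frequencies and the design
    (intercept, environment) are whitened by the inverse square root of
    the background covariance, in which the null model is standard
    normal (the covariance model fixes the residual scale).  With a
    Gaussian g-prior on the environmental slope the marginal-likelihood
    ratio is

        BF = (1 + g)^(-1/2) * exp( g / (1 + g) * z^2 / 2 ),

    where z is the amplitude of the environmental signal beyond the
    intercept, in whitened (background-SD) units.  A locus with no
    association (z = 0) has BF = (1+g)^(-1/2) < 1.
    """
    x_std = np.asarray(x_std, float)
    e_std = np.asarray(e_std, float)
    P = len(x_std)
    if P <= 2:
        raise InvalidParameterError("Bayes factor needs > 2 groups")
    if len(e_std) != P:
        raise InvalidParameterError("length mismatch")
    W = cov.whitener()
    z2 = _whitened_signal_ss(W @ x_std,
                             W @ np.column_stack([np.ones(P), e_std]))
    return float((1 + g) ** -0.5 * np.exp(0.5 * z2 * g / (1 + g)))


def _whitened_signal_ss(y: np.ndarray, X: np.ndarray) -> float:
    """Squared signal amplitude of X's second column beyond its first."""
    _, res0 = _ols_rss(y, X[:, :1])
    _, res1 = _ols_rss(y, X)
    return max(0.0, res0 - res1)


def _ols_rss(y, X):
    beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _standardized_freq_matrix(freqs: np.ndarray) -> np.ndarray:
    """Per-locus standardized deviation vectors; NaN where fixed."""
    pbar = freqs.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (freqs - pbar) / np.sqrt(pbar * (1 - pbar))


def bf_scan(matrix: GenotypeMatrix, grouping: PopulationGrouping,
            env: EnvTable, cov: CovarianceModel,
            threshold: float = 3.0, g: float = DEFAULT_BF_G) -> pd.DataFrame:
    """Bayes factors for every locus x environmental variable.

    Vectorized version of :func:`env_bayes_factor` over all loci.
    Returns a frame with one ``bf_<variable>`` column per variable plus
    ``<variable>_hit`` flags where BF exceeds ``threshold``.
    """
    freqs = group_allele_freqs(matrix, grouping)
    P = grouping.n_groups
    W = cov.whitener()
    X0 = W @ np.ones((P, 1))
    x_all = _standardized_freq_matrix(freqs)
    out = pd.DataFrame({"contig": matrix.loci["contig"],
                        "position": matrix.loci["position"]})
    Y = W @ np.nan_to_num(x_all)
    fixed = ~np.isfinite(x_all).all(axis=0)
    # residuals after intercept, shared across variables
    q0, _ = np.linalg.qr(X0)
    R0 = Y - q0 @ (q0.T @ Y)
    rss0 = (R0 ** 2).sum(axis=0)
    for v in env.variables:
        e = env.standardized[v].to_numpy()
        X = W @ np.column_stack([np.ones(P), e])
        q, _ = np.linalg.qr(X)
        R1 = Y - q @ (q.T @ Y)
        rss1 = (R1 ** 2).sum(axis=0)
        z2 = np.maximum(0.0, rss0 - rss1)
        bf = (1 + g) ** -0.5 * np.exp(0.5 * z2 * g / (1 + g))
        bf[fixed] = (1 + g) ** -0.5        # no signal at fixed loci
        out[f"bf_{v}"] = bf
        out[f"{v}_hit"] = bf > threshold
    return out


def bf_permutation_null(matrix: GenotypeMatrix,
                        grouping: PopulationGrouping,
                        env_individual: pd.DataFrame,
                        cov: CovarianceModel,
                        n_perm: int = 10,
                        threshold: float = 3.0,
                        rng: np.random.Generator | None = None,
                        observed_scan: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Permutation null for the Bayes-factor scan.

    Environmental values are permuted across individuals, re-averaged
    and re-standardized over the original groups, and the scan re-run.
    Per variable this yields the expected count of BF > threshold under
    no association, a two-sample Kolmogorov-Smirnov comparison of the
    observed BF distribution against the pooled permuted one, and a
    binomial exact test (one-sided, 'greater') of the observed
    exceedance count against the permuted exceedance proportion.
    """
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    env_obs = standardize_env(env_individual, grouping)
    if observed_scan is None:
        observed_scan = bf_scan(matrix, grouping, env_obs, cov, threshold)
    perm_bfs = {v: [] for v in env_obs.variables}
    for _ in range(n_perm):
        perm = rng.permutation(len(env_individual))
        env_p = env_individual.iloc[perm].reset_index(drop=True)
        scan_p = bf_scan(matrix, grouping,
                         standardize_env(env_p, grouping), cov, threshold)
        for v in env_obs.variables:
            perm_bfs[v].append(scan_p[f"bf_{v}"].to_numpy())
    rows = []
    n_loci = matrix.n_loci
    for v in env_obs.variables:
        obs_bf = observed_scan[f"bf_{v}"].to_numpy()
        obs_count = int((obs_bf > threshold).sum())
        pooled = np.concatenate(perm_bfs[v])
        expected = float((pooled > threshold).mean() * n_loci)
        ks_stat, ks_p = stats.ks_2samp(obs_bf, pooled)
        p0 = min(1.0, max((pooled > threshold).mean(), 1e-12))
        binom_p = stats.binomtest(obs_count, n_loci, p0,
                                  alternative="greater").pvalue
        rows.append((v, obs_count, expected, float(ks_stat), float(ks_p),
                     float(binom_p)))
    return pd.DataFrame(rows, columns=["variable", "observed_count",
                                       "expected_count", "ks_stat", "ks_p",
                                       "binom_p"])


# ---------------------------------------------------------------------------
# redundancy analysis

@dataclass
class RdaResult:
    """Constrained ordination of allele frequencies on environments."""

    locus_scores: np.ndarray          # loci x axes (V * singular values)
    individual_scores: np.ndarray     # individuals x axes
    singular_values: np.ndarray
    prop_constrained: float           # share of total variance constrained
    env_axis_corr: pd.DataFrame       # variables x axes correlations


def rda_fit(Y: np.ndarray, X: np.ndarray,
            env_names: list[str] | None = None) -> RdaResult:
    """Redundancy analysis of a centered response matrix on predictors.

    Fitted values ``Yhat = X (X'X)^-1 X' Y`` are decomposed by SVD;
    locus scores are the right singular vectors scaled by their
    singular values.  Raises on collinear predictors, naming the
    dependent column.
    """
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    n, L = Y.shape
    if X.shape[0] != n:
        raise InvalidParameterError("Y and X row mismatch")
    if n < X.shape[1] + 1:
        raise InvalidParameterError("need more individuals than predictors")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))
    if bad.size:
        name = (env_names[bad[0]] if env_names is not None
                else f"column {bad[0]}")
        raise InvalidParameterError(f"collinear predictor: {name}")
    proj = q.T @ Y                      # (p, L): Yhat = q @ proj
    U_small, S, Vt = np.linalg.svd(proj, full_matrices=False)
    total_var = float((Y ** 2).sum())
    constrained = float((S ** 2).sum())
    locus_scores = (Vt.T * S)
    individual_scores = (q @ U_small) * S
    names = env_names or [f"x{i}" for i in range(X.shape[1])]
    corr = np.zeros((X.shape[1], len(S)))
    for i in range(X.shape[1]):
        for a in range(len(S)):
            axis = individual_scores[:, a]
            if axis.std() > 0 and X[:, i].std() > 0:
                corr[i, a] = np.corrcoef(X[:, i], axis)[0, 1]
    return RdaResult(
        locus_scores=locus_scores,
        individual_scores=individual_scores,
        singular_values=S,
        prop_constrained=constrained / total_var if total_var else 0.0,
        env_axis_corr=pd.DataFrame(
            corr, index=names,
            columns=[f"axis{a + 1}" for a in range(len(S))]))


def rda_outliers(locus_scores: np.ndarray, k_axes: int = 3,
                 z: float = 3.0) -> np.ndarray:
    """Flag loci beyond +/- z SD of the mean score on the first axes."""
    n_axes = locus_scores.shape[1]
    if n_axes < k_axes:
        logger.warning("only %d constrained axes available; using all",
                       n_axes)
        k_axes = n_axes
    flags = np.zeros(locus_scores.shape[0], bool)
    for a in range(k_axes):
        s = locus_scores[:, a]
        sd = s.std()
        if sd == 0:
            continue
        flags |= np.abs(s - s.mean()) > z * sd
    return flags


def individual_freq_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Individual allele frequencies (dosage/2), mean-interpolated."""
    return impute_mean(matrix) / 2.0


def outlier_env_regression(matrix: GenotypeMatrix, env_individual:
                           pd.DataFrame, outliers: np.ndarray,
                           alpha: float = 0.001) -> pd.DataFrame:
    """OLS of each outlier locus's allele frequency on each variable.

    Returns r^2, the two-sided slope p-value, and a significance flag
    at ``alpha`` for every outlier locus x variable pair.
    """
    variables = list(env_individual.select_dtypes("number").columns)
    for v in variables:
        if env_individual[v].std() == 0:
            raise InvalidParameterError(f"variable {v!r} has zero variance")
    idx = np.flatnonzero(outliers)
    F = individual_freq_matrix(matrix)
    rows = []
    for j in idx:
        y = F[:, j]
        for v in variables:
            x = env_individual[v].to_numpy(float)
            if y.std() == 0:
                r2, p = 0.0, 1.0
            else:
                res = stats.linregress(x, y)
                r2, p = res.rvalue ** 2, res.pvalue
            rows.append((matrix.loci["contig"].iloc[j], j, v, r2, p,
                         p < alpha))
    return pd.DataFrame(rows, columns=["contig", "locus_index", "variable",
                                       "r2", "p", "significant"])


def _rda_counts(F_centered: np.ndarray, X: np.ndarray, F_raw: np.ndarray,
                env_arr: np.ndarray, k_axes: int, z: float,
                alpha: float) -> tuple[int, int]:
    """Outlier count and significant-association count for one design."""
    q, _ = np.linalg.qr(X)
    proj = q.T @ F_centered
    _, S, Vt = np.linalg.svd(proj, full_matrices=False)
    flags = rda_outliers(Vt.T * S, k_axes, z)
    idx = np.flatnonzero(flags)
    n_sig = 0
    n = F_raw.shape[0]
    for j in idx:
        y = F_raw[:, j]
        sy = y.std()
        if sy == 0:
            continue
        for vcol in env_arr.T:
            r = np.corrcoef(vcol, y)[0, 1]
            if abs(r) >= 1.0:
                n_sig += 1
                continue
            t = r * np.sqrt((n - 2) / (1 - r ** 2))
            p = 2 * stats.t.sf(abs(t), n - 2)
            if p < alpha:
                n_sig += 1
    return int(flags.sum()), n_sig


def rda_permutation_null(matrix: GenotypeMatrix,
                         env_individual: pd.DataFrame,
                         n_perm: int = 10_000,
                         k_axes: int = 3, z: float = 3.0,
                         alpha: float = 0.001,
                         rng: np.random.Generator | None = None
                         ) -> dict:
    """Permutation null for the RDA outlier/association pipeline.

    Environmental rows are permuted jointly across individuals; for
    each permutation the outlier count (+/- z SD on the first k axes)
    and the count of significant locus-variable regressions among those
    outliers are recorded.  Empirical p-values are
    ``(1 + exceedances) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    num = env_individual.select_dtypes("number")
    env_arr = (num - num.mean()) / num.std(ddof=0)
    env_arr = env_arr.to_numpy(float)
    F_raw = individual_freq_matrix(matrix)
    F_centered = F_raw - F_raw.mean(axis=0)
    obs_out, obs_sig = _rda_counts(F_centered, env_arr, F_raw, env_arr,
                                   k_axes, z, alpha)
    c_out = 0
    c_sig = 0
    perm_out = np.empty(n_perm, int)
    perm_sig = np.empty(n_perm, int)
    for b in range(n_perm):
        perm = rng.permutation(env_arr.shape[0])
        Xp = env_arr[perm]
        o, s = _rda_counts(F_centered, Xp, F_raw, Xp, k_axes, z, alpha)
        perm_out[b] = o
        perm_sig[b] = s
        c_out += o >= obs_out
        c_sig += s >= obs_sig
    return {
        "observed_outliers": obs_out,
        "observed_significant": obs_sig,
        "p_outlier_count": (1 + c_out) / (n_perm + 1),
        "p_significant_count": (1 + c_sig) / (n_perm + 1),
        "perm_outliers": perm_out,
        "perm_significant": perm_sig,
    }
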