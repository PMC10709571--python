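"""Negative-binomial log-linear GLMs for stacked multi-aligner count data.

The model for gene g and stacked column i (sample x mapper) is

    y_gi ~ NB(mu_gi, phi_g),        Var(y_gi) = mu_gi + phi_g * mu_gi^2
    log(mu_gi) = x_i' beta_g + log(N_i)

with an additive (no-interaction) design over the experimental group factor
and the mapper factor, and offset log effective library size N_i.  This
module provides

* :func:`build_design` — treatment-coded additive design matrix;
* :func:`fit_nbglm` / :func:`fit_nbglm_many` — IRLS maximum-likelihood fits
  at fixed dispersion (vectorized across genes);
* :func:`estimate_dispersion` — Cox–Reid adjusted-profile-likelihood
  dispersion estimation with shrinkage toward the common value;
* :func:`lrt_factor` — per-gene likelihood-ratio tests for one factor,
  chi-square reference, Benjamini–Hochberg adjustment;
* :func:`nb_exact_test` — the two-group negative-binomial exact test
  (conditional enumeration over partitions of the total).

All fits are deterministic given their inputs; nothing here consumes a
random number generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io_design import StackedCounts

__all__ = [
    "DesignMatrix",
    "GeneFit",
    "FactorTestResult",
    "build_design",
    "build_oneway_design",
    "fit_nbglm",
    "fit_nbglm_many",
    "estimate_dispersion",
    "lrt_factor",
    "nb_exact_test",
    "nb_loglik",
    "bh_adjust",
]

MAX_IRLS_ITER = 100
IRLS_TOL = 1e-8  # relative deviance change
IRLS_BETA_TOL = 1e-9  # max coefficient change, tightens the final iterate
BETA_CLAMP = 50.0  # |beta| bound guarding all-zero degeneracies
DISPERSION_BOUNDS = (1e-6, 10.0)
MU_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _treatment_code(labels: np.ndarray, prefix: str):
    """Treatment (reference-level) coding; the lexicographically smallest
    level is the reference.  Returns (columns, names, levels)."""
    levels = sorted(set(labels.tolist()))
    cols = []
    names = []
    for lev in levels[1:]:
        cols.append((labels == lev).astype(float))
        names.append(f"{prefix}[{lev}]")
    return cols, names, levels


@dataclass
class DesignMatrix:
    """Additive intercept + group + mapper design, treatment coded."""

    matrix: np.ndarray  # (n_obs, p)
    names: list[str]
    group_levels: list[str] = field(default_factory=list)
    mapper_levels: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def drop_factor(self, prefix: str) -> "DesignMatrix":
        """Reduced design with every ``prefix[...]`` contrast removed."""
        keep = [i for i, nm in enumerate(self.names)
                if not nm.startswith(f"{prefix}[")]
        if len(keep) == len(self.names):
            raise ValueError(f"no columns for factor {prefix!r}")
        return DesignMatrix(self.matrix[:, keep],
                            [self.names[i] for i in keep],
                            self.group_levels, self.mapper_levels)


def build_design(stacked: StackedCounts) -> DesignMatrix:
    """Design matrix for the two-factor additive model on a stacked table.

    Rank is ``1 + (G_levels - 1) + (K_levels - 1)``.
    """
    groups = stacked.group_labels
    mappers = stacked.mapper_labels
    g_cols, g_names, g_levels = _treatment_code(groups, "group")
    m_cols, m_names, m_levels = _treatment_code(mappers, "mapper")
    if not g_cols:
        raise ValueError("group factor has a single level")
    if not m_cols:
        raise ValueError("mapper factor has a single level")
    n = len(stacked.columns)
    X = np.column_stack([np.ones(n)] + g_cols + m_cols)
    return DesignMatrix(X, ["intercept"] + g_names + m_names,
                        g_levels, m_levels)


def build_oneway_design(groups) -> DesignMatrix:
    """Intercept + group design for a single-mapper (one-way) analysis."""
    groups = np.asarray([str(g) for g in groups])
    g_cols, g_names, g_levels = _treatment_code(groups, "group")
    if not g_cols:
        raise ValueError("group factor has a single level")
    X = np.column_stack([np.ones(len(groups))] + g_cols)
    return DesignMatrix(X, ["intercept"] + g_names, g_levels, [])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, dispersion) -> np.ndarray:
    """NB log-likelihood, summed over the last axis.

    ``dispersion`` may be a scalar or broadcastable array; 0 selects the
    Poisson limit.  ``y`` and ``mu`` broadcast together; the last axis is the
    observation axis.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), MU_FLOOR)
    phi = np.asarray(dispersion, dtype=float)
    if phi.ndim:
        phi = phi[..., None]
    pois = y * np.log(mu) - mu - gammaln(y + 1.0)
    if np.all(phi == 0):
        return pois.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(phi > 0, 1.0 / np.where(phi > 0, phi, 1.0), np.inf)
        nb = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
              + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    ll = np.where(phi > 0, nb, pois)
    return ll.sum(axis=-1)


def _nb_deviance(y, mu, phi):
    """Unit deviance summed over observations (broadcast over genes)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, MU_FLOOR)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim:
        phi = phi[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        r = np.where(phi > 0, 1.0 / np.where(phi > 0, phi, 1.0), np.inf)
        nb_t2 = (y + r) * np.log((y + r) / (mu + r))
        pois_t2 = y - mu
    t2 = np.where(phi > 0, nb_t2, pois_t2)
    return 2.0 * (t1 - t2).sum(axis=-1)


# ---------------------------------------------------------------------------
# IRLS fitting
# ---------------------------------------------------------------------------

@dataclass
class GeneFit:
    """Maximum-likelihood fit of the NB log-linear model for one gene."""

    beta: np.ndarray
    dispersion: float
    fitted_mu: np.ndarray
    log_lik: float
    converged: bool
    n_iter: int
    degenerate: bool = False


def fit_nbglm_many(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                   dispersion, max_iter: int = MAX_IRLS_ITER,
                   tol: float = IRLS_TOL):
    """Vectorized IRLS over genes at fixed per-gene dispersion.

    Parameters
    ----------
    y : (G, m) counts; X : (m, p) design; offset : (m,) log effective sizes;
    dispersion : scalar or (G,) array (0 = Poisson).

    Returns
    -------
    beta : (G, p); mu : (G, m); ll : (G,); converged : (G,) bool;
    n_iter : (G,) int
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    G, m = y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (G,)).copy()
    phi_col = phi[:, None]

    # initialization: mu halfway between data and gene mean, floored
    gene_mean = np.maximum(y.mean(axis=1, keepdims=True), 1e-2)
    mu = np.maximum((y + gene_mean) / 2.0, 1e-2)
    eta = np.log(mu)

    converged = np.zeros(G, dtype=bool)
    n_iter = np.zeros(G, dtype=int)
    dev = _nb_deviance(y, mu, phi)
    beta = np.zeros((G, p))
    active = np.ones(G, dtype=bool)
    ridge = 1e-10 * np.eye(p)

    for it in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        mu_a = mu[idx]
        w = mu_a / (1.0 + phi_col[idx] * mu_a)  # IRLS working weights
        w = np.maximum(w, 1e-12)
        z = (eta[idx] - offset) + (y[idx] - mu_a) / mu_a
        XtWX = np.einsum("mp,gm,mq->gpq", X, w, X, optimize=True)
        XtWz = np.einsum("mp,gm,gm->gp", X, w, z, optimize=True)
        try:
            b = np.linalg.solve(XtWX + ridge, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            b = np.stack([np.linalg.lstsq(XtWX[g], XtWz[g], rcond=None)[0]
                          for g in range(len(idx))])
        b = np.clip(b, -BETA_CLAMP, BETA_CLAMP)
        beta_step = np.abs(b - beta[idx]).max(axis=1)
        beta[idx] = b
        eta_new = offset + b @ X.T
        mu_new = np.exp(np.clip(eta_new, -700, 700))
        dev_new = _nb_deviance(y[idx], mu_new, phi[idx])
        rel = np.abs(dev_new - dev[idx]) / (np.abs(dev_new) + 0.1)
        done = (rel < tol) & (beta_step < IRLS_BETA_TOL)
        mu[idx] = mu_new
        eta[idx] = eta_new
        dev[idx] = dev_new
        n_iter[idx] += 1
        converged[idx[done]] = True
        active[idx[done]] = False

    mu = np.maximum(mu, MU_FLOOR)
    ll = nb_loglik(y, mu, phi)
    return beta, mu, ll, converged, n_iter


def fit_nbglm(y, X, offset=None, dispersion: float = 0.0,
              max_iter: int = MAX_IRLS_ITER, tol: float = IRLS_TOL) -> GeneFit:
    """Fit the NB log-linear model for a single gene.

    ``X`` may be a :class:`DesignMatrix` or a plain 2-D array; ``offset``
    defaults to zeros (effective size 1).  ``dispersion`` is held fixed
    (0 selects the Poisson limit).
    """
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if offset is None:
        offset = np.zeros(len(y))
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if len(y) != Xm.shape[0]:
        raise ValueError("length of y does not match design rows")
    beta, mu, ll, conv, n_iter = fit_nbglm_many(
        y[None, :], Xm, np.asarray(offset, dtype=float), dispersion,
        max_iter=max_iter, tol=tol)
    degenerate = bool(np.all(y == 0)) or bool(np.any(np.abs(beta) >= BETA_CLAMP))
    return GeneFit(beta[0], float(dispersion), mu[0], float(ll[0]),
                   bool(conv[0]), int(n_iter[0]), degenerate)


# ---------------------------------------------------------------------------
# dispersion estimation (Cox-Reid adjusted profile likelihood)
# ---------------------------------------------------------------------------

def _apl_grid(y, X, offset, grid):
    """Cox-Reid adjusted profile log-likelihood on a dispersion grid.

    Returns an array (n_grid, G): for each candidate dispersion the model is
    refit and APL = loglik - 0.5 * logdet(X'WX) evaluated per gene.
    """
    G = y.shape[0]
    out = np.empty((len(grid), G))
    for i, phi in enumerate(grid):
        beta, mu, ll, _, _ = fit_nbglm_many(y, X, offset, phi)
        w = np.maximum(mu / (1.0 + phi * mu), 1e-12)
        XtWX = np.einsum("mp,gm,mq->gpq", X, w, X, optimize=True)
        sign, logdet = np.linalg.slogdet(XtWX)
        logdet = np.where(sign > 0, logdet, np.inf)
        out[i] = ll - 0.5 * logdet
    return out


def _interp_max(log_grid: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Per-gene quadratic interpolation of the grid maximum (in log space)."""
    k = np.argmax(scores, axis=0)
    G = scores.shape[1]
    est = log_grid[k]
    inner = (k > 0) & (k < len(log_grid) - 1)
    gi = np.flatnonzero(inner)
    if len(gi):
        km = k[gi]
        y0 = scores[km - 1, gi]
        y1 = scores[km, gi]
        y2 = scores[km + 1, gi]
        x0, x1, x2 = log_grid[km - 1], log_grid[km], log_grid[km + 1]
        denom = (y0 - 2 * y1 + y2)
        with np.errstate(divide="ignore", invalid="ignore"):
            shift = 0.5 * (y0 - y2) / denom * (x1 - x0)
        shift = np.where(np.abs(denom) > 1e-12, shift, 0.0)
        shift = np.clip(shift, -(x1 - x0), (x2 - x1))
        est[gi] = x1 + shift
    return est


def estimate_dispersion(counts, X, offsets, prior_df: float = 10.0,
                        n_grid: int = 25, bounds=DISPERSION_BOUNDS):
    """Per-gene NB dispersions via Cox-Reid APL with common-value shrinkage.

    The APL of every gene is evaluated on a fixed grid of ``n_grid``
    log-spaced dispersions in ``bounds``.  The common dispersion maximizes
    the summed APL; gene-wise estimates maximize the weighted score

        df_res * APL_g(phi) + prior_df * mean_g APL_g(phi)

    so that ``prior_df -> inf`` collapses every gene onto the common value.
    Genes with all-zero counts receive the common dispersion.

    Returns ``(dispersions, common_dispersion)``.
    """
    y = counts.counts if isinstance(counts, StackedCounts) else np.asarray(counts)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    m, p = Xm.shape
    if p >= m:
        raise ValueError("design rank must be below the number of columns")
    df_res = m - p
    log_grid = np.linspace(np.log(bounds[0]), np.log(bounds[1]), n_grid)
    grid = np.exp(log_grid)
    apl = _apl_grid(y, Xm, offsets, grid)  # (n_grid, G)
    nonzero = y.sum(axis=1) > 0
    if not nonzero.any():
        common = bounds[0]
        return np.full(y.shape[0], common), common
    apl_mean = apl[:, nonzero].mean(axis=1)  # common profile
    common = float(np.exp(_interp_max(log_grid, apl_mean[:, None])[0]))
    if not np.isfinite(prior_df):
        disp = np.full(y.shape[0], common)
        return disp, common
    score = df_res * apl + prior_df * apl_mean[:, None]
    disp = np.exp(_interp_max(log_grid, score))
    disp = np.clip(disp, bounds[0], bounds[1])
    disp[~nonzero] = common
    return disp, common


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class FactorTestResult:
    """Per-gene likelihood-ratio test results for one factor."""

    gene_ids: list[str]
    factor: str
    lr_stat: np.ndarray
    df: int
    p_value: np.ndarray
    p_adjusted: np.ndarray
    converged: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "factor": self.factor,
            "lr_stat": self.lr_stat,
            "df": self.df,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
        })


def lrt_factor(counts, X_full, X_reduced, offsets, dispersions,
               gene_ids=None, factor: str = "factor") -> FactorTestResult:
    """Likelihood-ratio test of the columns dropped from the full design.

    Both fits of a gene use the same dispersion.  The statistic
    ``2 (ll_full - ll_reduced)`` is clipped at 0 and referred to a chi-square
    with df = rank difference; p-values are BH-adjusted across genes.
    Genes whose either fit failed to converge get p = 1.
    """
    y = counts.counts if isinstance(counts, StackedCounts) else np.asarray(counts)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    Xf = X_full.matrix if isinstance(X_full, DesignMatrix) else np.asarray(X_full)
    Xr = (X_reduced.matrix if isinstance(X_reduced, DesignMatrix)
          else np.asarray(X_reduced))
    if Xr.shape[1] >= Xf.shape[1]:
        raise ValueError("reduced design must have fewer columns than full")
    if gene_ids is None:
        gene_ids = (counts.gene_ids if isinstance(counts, StackedCounts)
                    else [f"g{i}" for i in range(y.shape[0])])
    offsets = np.asarray(offsets, dtype=float)
    _, _, ll_full, conv_f, _ = fit_nbglm_many(y, Xf, offsets, dispersions)
    _, _, ll_red, conv_r, _ = fit_nbglm_many(y, Xr, offsets, dispersions)
    lr = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    df = int(np.linalg.matrix_rank(Xf) - np.linalg.matrix_rank(Xr))
    p = chi2.sf(lr, df)
    converged = conv_f & conv_r
    p = np.where(converged, p, 1.0)
    return FactorTestResult(list(gene_ids), factor, lr, df, p, bh_adjust(p),
                            converged)


# ---------------------------------------------------------------------------
# two-group NB exact test
# ---------------------------------------------------------------------------

def _exact_conditional_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int,
                              dispersion: float) -> float:
    """Two-sided exact p-value conditional on ``sum_a + sum_b``.

    Group sums of i.i.d. NB counts with common mean and dispersion phi are
    NB with size n/phi; conditional on the total the partition law is a
    negative-binomial analogue of the hypergeometric that does not depend on
    the mean.  Two-sidedness by the minimum-likelihood rule: sum the
    probabilities of all partitions no more likely than the observed one.
    phi = 0 gives the Poisson limit (a binomial partition law).
    """
    s = int(sum_a) + int(sum_b)
    if s == 0:
        return 1.0
    a = np.arange(s + 1, dtype=float)
    if dispersion > 0:
        ra = n_a / dispersion
        rb = n_b / dispersion
        logw = (gammaln(a + ra) - gammaln(a + 1.0)
                + gammaln(s - a + rb) - gammaln(s - a + 1.0))
    else:
        logw = (a * np.log(n_a) + (s - a) * np.log(n_b)
                - gammaln(a + 1.0) - gammaln(s - a + 1.0))
    logp = logw - logsumexp(logw)
    obs = logp[int(sum_a)]
    keep = logp <= obs + 1e-10  # tolerance keeps exact ties in
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def _moment_match_to_common_size(y: np.ndarray, eff_sizes: np.ndarray,
                                 dispersion: np.ndarray) -> np.ndarray:
    """Map counts to a common effective library size, matching NB moments.

    The common size is the geometric mean of the effective sizes.  Each
    observation is shifted/scaled so that its first two NB moments under the
    gene's pooled expression proportion match the common-size moments
    (identity when all effective sizes are equal), then clipped at zero.
    """
    eff = np.asarray(eff_sizes, dtype=float)
    common = float(np.exp(np.mean(np.log(eff))))
    if np.allclose(eff, common):
        return y.astype(float)
    phi = np.asarray(dispersion, dtype=float).reshape(-1, 1)
    lam = (y.sum(axis=1, keepdims=True) / eff.sum())  # pooled proportion
    mu_in = lam * eff
    mu_out = lam * common
    v_in = np.maximum(mu_in + phi * mu_in**2, 1e-8)
    v_out = np.maximum(mu_out + phi * mu_out**2, 1e-8)
    adj = mu_out + np.sqrt(v_out / v_in) * (y - mu_in)
    return np.maximum(adj, 0.0)


def nb_exact_test(counts_a: np.ndarray, counts_b: np.ndarray,
                  dispersion, effective_sizes_a=None,
                  effective_sizes_b=None) -> np.ndarray:
    """Exact NB test for a difference between two groups, per gene.

    ``counts_a``/``counts_b``: (G, n_a) and (G, n_b) matrices.  Counts are
    first adjusted to a common effective library size, group sums rounded to
    integers, then the conditional partition enumeration gives the two-sided
    p-value.  ``dispersion`` is a scalar or per-gene vector (0 = Poisson).
    """
    ya = np.atleast_2d(np.asarray(counts_a, dtype=float))
    yb = np.atleast_2d(np.asarray(counts_b, dtype=float))
    G = ya.shape[0]
    if yb.shape[0] != G:
        raise ValueError("group matrices disagree on the number of genes")
    n_a, n_b = ya.shape[1], yb.shape[1]
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (G,))
    if (phi < 0).any():
        raise ValueError("dispersion must be >= 0")
    if effective_sizes_a is not None or effective_sizes_b is not None:
        eff = np.concatenate([np.asarray(effective_sizes_a, dtype=float),
                              np.asarray(effective_sizes_b, dtype=float)])
        adj = _moment_match_to_common_size(np.hstack([ya, yb]), eff, phi)
        ya, yb = adj[:, :n_a], adj[:, n_a:]
    sum_a = np.rint(ya.sum(axis=1)).astype(np.int64)
    sum_b = np.rint(yb.sum(axis=1)).astype(np.int64)
    return np.array([
        _exact_conditional_pvalue(sum_a[g], sum_b[g], n_a, n_b, float(phi[g]))
        for g in range(G)
    ])
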