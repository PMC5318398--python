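"""Bayesian fit of the full genetic model and permutation-based significance.

The model is a hierarchical linear mixed model: per-environment intercepts
(absorbing the population mean and the environment effect e_h), one
coefficient per genetic term, and a residual.  Each term class (a, d, aa, ...,
dde) carries its own variance component with a scaled-inverse-chi-square
prior; coefficients are conditionally normal.  Estimation is by Gibbs
sampling with a blocked coefficient update: term columns are strongly
collinear in line/hybrid designs (an environment-specific pair of columns
sums exactly to its general column), and drawing the whole coefficient
vector from its joint conditional normal lets the chain traverse those
ridges that single-site updates cannot.  Posterior means and standard errors
come from post-burn-in thinned draws; the shrinkage prior keeps the fit
proper when terms outnumber observations.

Experiment-wise significance uses the permutation distribution of the maximum
per-term statistic.  Refitting a full chain per permutation is needlessly
expensive; instead permutations (and the observed data, identically) are
scored with a fast marginal statistic — the absolute within-environment
correlation between a term column and the response — whose max-null
quantile gives the critical value, and empirical tail probabilities (with the
+1 correction) give -log10 P_EW.  Responses are permuted across subjects
within each environment so the environment structure survives permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .design import TERM_CLASSES, DesignMatrix, Term


@dataclass
class McmcSpec:
    """Gibbs sampler settings and variance-component priors.

    ``prior_df`` and ``prior_scale_frac`` define the scaled-inverse-chi-square
    prior for every variance component: df nu0 = prior_df, scale
    s0^2 = prior_scale_frac * var(y).  Weakly informative at the default
    (nu0=4); the data dominate for any reasonably sized design.
    """

    n_iterations: int = 20000
    burn_in: int = 4000
    thin: int = 10
    seed: int = 0
    prior_df: float = 4.0
    prior_scale_frac: float = 0.5

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class MappingResult:
    """Posterior summaries of one fitted trait model."""

    terms: list  # list[Term]
    post_mean: np.ndarray  # per-term posterior mean effect
    post_se: np.ndarray  # per-term posterior sd
    mc_se: np.ndarray  # Monte Carlo se of the posterior mean (batch means)
    var_components: dict  # term class -> posterior mean variance component
    sigma2_resid: float  # V_eps posterior mean
    env_means: dict  # env -> posterior mean intercept (mu + e_h)
    trait: str = ""
    col_var: np.ndarray = None  # empirical variance of each design column
    stats: np.ndarray = None  # per-term observed permutation statistic
    neglog_pew: np.ndarray = None  # -log10 P_EW per term (after significance)
    p_floor: np.ndarray = None  # True where P_EW hit the empirical floor

    @property
    def mu(self) -> float:
        return float(np.mean(list(self.env_means.values())))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "term": [t.label() for t in self.terms],
            "class": [t.cls for t in self.terms],
            "effect": self.post_mean,
            "se": self.post_se,
        })
        if self.stats is not None:
            df["stat"] = self.stats
        if self.neglog_pew is not None:
            df["neglog_pew"] = self.neglog_pew
        return df


@dataclass
class QTSTable:
    """Experiment-wise significant terms of one trait, plus the population
    mean per environment (the per-environment intercepts)."""

    trait: str
    entries: pd.DataFrame  # term, class, loci, environment, effect, se, neglog_pew
    env_means: dict

    COLUMNS = ("term", "class", "loci", "environment", "effect", "se",
               "neglog_pew", "p_floor")

    def term_effects(self) -> dict:
        """Retained terms as a ``Term -> effect`` mapping."""
        out = {}
        for _, row in self.entries.iterrows():
            out[Term.from_label(row["term"])] = float(row["effect"])
        return out

    def loci(self) -> list:
        seen = []
        for term in self.term_effects():
            for l in term.loci:
                if l not in seen:
                    seen.append(l)
        return seen

    def write(self, path, sep: str = "\t") -> None:
        with open(path, "w") as fh:
            for env, m in sorted(self.env_means.items()):
                fh.write(f"# env_mean {env}={m!r}\n")
            fh.write(f"# trait {self.trait}\n")
            self.entries.to_csv(fh, sep=sep, index=False)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "QTSTable":
        env_means, trait = {}, ""
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("# env_mean "):
                k, v = line[len("# env_mean "):].strip().split("=")
                env_means[k] = float(v)
            elif line.startswith("# trait "):
                trait = line[len("# trait "):].strip()
            else:
                body.append(line)
        from io import StringIO
        entries = pd.read_csv(StringIO("".join(body)), sep=sep)
        entries["environment"] = entries["environment"].where(
            entries["environment"].notna(), None)
        return cls(trait=trait, entries=entries, env_means=env_means)


# ---------------------------------------------------------------------------
# Gibbs core


@njit(cache=True)
def _gibbs_chain(y, X, class_of, n_class, env_of, n_env, n_iter, burn, thin,
                 nu0, s0, nu0e, s0e, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    n, p = X.shape
    G = X.T @ X  # fixed Gram matrix; term columns are highly collinear in
    # line/hybrid designs, so coefficients are drawn as one block
    n_h = np.zeros(n_env)
    for i in range(n):
        n_h[env_of[i]] += 1.0

    p_c = np.zeros(n_class)
    for j in range(p):
        p_c[class_of[j]] += 1.0

    beta = np.zeros(p)
    mu_env = np.zeros(n_env)
    sig2c = np.full(n_class, s0)
    sig2e = s0e

    n_keep = (n_iter - burn + thin - 1) // thin
    beta_draws = np.zeros((n_keep, p))
    mu_draws = np.zeros((n_keep, n_env))
    sig2c_draws = np.zeros((n_keep, n_class))
    sig2e_draws = np.zeros(n_keep)

    kept = 0
    for it in range(n_iter):
        # per-environment intercepts (flat prior), given beta
        fit = X @ beta
        for h in range(n_env):
            s = 0.0
            for i in range(n):
                if env_of[i] == h:
                    s += y[i] - fit[i]
            mu_env[h] = (s / n_h[h]
                         + np.sqrt(sig2e / n_h[h]) * np.random.standard_normal())
        # coefficient block: beta | rest ~ N(A^-1 b, A^-1),
        # A = X'X / sig2e + diag(1 / sig2_class), b = X'r / sig2e
        r = y - mu_env[env_of]
        A = G / sig2e
        for j in range(p):
            A[j, j] += 1.0 / sig2c[class_of[j]]
        b = (X.T @ r) / sig2e
        L = np.linalg.cholesky(A)
        z = np.linalg.solve(L, b)
        m = np.linalg.solve(L.T, z)
        eta = np.random.standard_normal(p)
        beta = m + np.linalg.solve(L.T, eta)
        # class variance components
        for c in range(n_class):
            ssb = 0.0
            for j in range(p):
                if class_of[j] == c:
                    ssb += beta[j] * beta[j]
            sig2c[c] = (nu0 * s0 + ssb) / np.random.chisquare(nu0 + p_c[c])
        # residual variance
        resid = r - X @ beta
        sse = 0.0
        for i in range(n):
            sse += resid[i] * resid[i]
        sig2e = (nu0e * s0e + sse) / np.random.chisquare(nu0e + n)

        if it >= burn and (it - burn) % thin == 0:
            beta_draws[kept] = beta
            mu_draws[kept] = mu_env
            sig2c_draws[kept] = sig2c
            sig2e_draws[kept] = sig2e
            kept += 1
    return beta_draws, mu_draws, sig2c_draws, sig2e_draws


def _batch_mc_se(draws: np.ndarray) -> np.ndarray:
    """Monte Carlo standard error of the mean by non-overlapping batch means."""
    n = draws.shape[0]
    n_batch = max(int(np.floor(np.sqrt(n))), 2)
    m = n // n_batch
    trimmed = draws[:n_batch * m]
    batches = trimmed.reshape(n_batch, m, -1).mean(axis=1)
    return batches.std(axis=0, ddof=1) / np.sqrt(n_batch)


def fit_gibbs(x: DesignMatrix, spec: McmcSpec = None) -> MappingResult:
    """Fit the full genetic model on a design matrix by Gibbs sampling."""
    spec = spec or McmcSpec()
    y = np.asarray(x.y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    X = np.asarray(x.X, dtype=float)
    if X.shape[1] < 1:
        raise ValueError("design has no term columns")

    classes_present = sorted({t.cls for t in x.terms},
                             key=TERM_CLASSES.index)
    class_lut = {c: k for k, c in enumerate(classes_present)}
    class_of = np.array([class_lut[t.cls] for t in x.terms], dtype=np.int64)
    env_of = x.env_index()

    vy = float(np.var(y))
    s0 = max(spec.prior_scale_frac * vy, 1e-12)
    beta_d, mu_d, sig2c_d, sig2e_d = _gibbs_chain(
        y, X, class_of, len(classes_present), env_of, len(x.env_levels),
        int(spec.n_iterations), int(spec.burn_in), int(spec.thin),
        float(spec.prior_df), s0, float(spec.prior_df), s0,
        int(spec.seed) % (2 ** 31))

    if not (np.all(np.isfinite(beta_d)) and np.all(np.isfinite(sig2e_d))):
        raise RuntimeError("Gibbs chain diverged: non-finite draws")

    post_mean = beta_d.mean(axis=0)
    post_se = beta_d.std(axis=0, ddof=1)
    mc_se = _batch_mc_se(beta_d)
    var_components = {c: float(sig2c_d[:, k].mean())
                      for c, k in class_lut.items()}
    env_means = {e: float(mu_d[:, k].mean())
                 for k, e in enumerate(x.env_levels)}
    return MappingResult(
        terms=list(x.terms), post_mean=post_mean, post_se=post_se,
        mc_se=mc_se, var_components=var_components,
        sigma2_resid=float(sig2e_d.mean()), env_means=env_means,
        trait=x.trait, col_var=X.var(axis=0),
        stats=term_statistics(x))


# ---------------------------------------------------------------------------
# Permutation significance


def _within_env_center(v: np.ndarray, env_of: np.ndarray, n_env: int
                       ) -> np.ndarray:
    out = np.asarray(v, dtype=float).copy()
    for h in range(n_env):
        m = env_of == h
        out[m] -= out[m].mean()
    return out


def term_statistics(x: DesignMatrix) -> np.ndarray:
    """Per-term statistic: |within-environment correlation| of column and
    response.  Zero-variance columns score 0."""
    env_of = x.env_index()
    n_env = len(x.env_levels)
    yc = _within_env_center(x.y, env_of, n_env)
    Xc = np.column_stack([_within_env_center(x.X[:, j], env_of, n_env)
                          for j in range(x.X.shape[1])])
    ynorm = np.linalg.norm(yc)
    xnorm = np.linalg.norm(Xc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stats = np.abs(Xc.T @ yc) / (xnorm * ynorm)
    stats[~np.isfinite(stats)] = 0.0
    return stats


@dataclass
class PermutationNull:
    """Null distribution of the maximum per-term statistic."""

    maxima: np.ndarray
    alpha: float
    critical: float

    def __float__(self):
        return float(self.critical)


def permutation_threshold(x: DesignMatrix, n_perm: int = 2000,
                          alpha: float = 0.05, spec: McmcSpec = None
                          ) -> PermutationNull:
    """Critical value of the max-term statistic controlling the
    experiment-wise type I error at ``alpha``.

    Responses are permuted across subjects within each environment.  Returns
    the (1 - alpha) upper quantile (method "higher": at n_perm = 20 and
    alpha = 0.05 the threshold is the largest null maximum).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    spec = spec or McmcSpec()
    rng = np.random.default_rng(int(spec.seed) % (2 ** 31))
    env_of = x.env_index()
    n_env = len(x.env_levels)
    yc = _within_env_center(x.y, env_of, n_env)
    Xc = np.column_stack([_within_env_center(x.X[:, j], env_of, n_env)
                          for j in range(x.X.shape[1])])
    ynorm = np.linalg.norm(yc)
    xnorm = np.linalg.norm(Xc, axis=0)
    if ynorm == 0:
        return PermutationNull(maxima=np.zeros(n_perm), alpha=alpha,
                               critical=0.0)

    # permuting within environment preserves within-env means and the norm
    perms = np.empty((len(yc), n_perm))
    idx = np.arange(len(yc))
    groups = [idx[env_of == h] for h in range(n_env)]
    for b in range(n_perm):
        col = yc.copy()
        for gidx in groups:
            col[gidx] = col[rng.permutation(gidx)]
        perms[:, b] = col
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.abs(Xc.T @ perms) / (xnorm[:, None] * ynorm)
    S[~np.isfinite(S)] = 0.0
    maxima = S.max(axis=0)
    critical = float(np.quantile(maxima, 1.0 - alpha, method="higher"))
    return PermutationNull(maxima=maxima, alpha=alpha, critical=critical)


def significance(m: MappingResult, crit) -> QTSTable:
    """Filter a mapping result to experiment-wise significant terms.

    ``crit`` is the ``PermutationNull`` from ``permutation_threshold`` (a bare
    critical value is accepted, but then -log10 P_EW is only bounded, not
    estimated).  P_EW of a term is the empirical tail probability of its
    observed statistic under the max-null with the +1 correction:
    (1 + #{null maxima >= stat}) / (n_perm + 1).  A statistic exceeding every
    null maximum is reported at the floor -log10((n_perm + 1)) and flagged.
    """
    stats = m.stats
    if stats is None:
        raise ValueError("mapping result carries no term statistics")
    if isinstance(crit, PermutationNull):
        maxima = np.asarray(crit.maxima, dtype=float)
        n_perm = len(maxima)
        exceed = (maxima[None, :] >= stats[:, None]).sum(axis=1)
        pew = (1.0 + exceed) / (n_perm + 1.0)
        floor = exceed == 0
        threshold = crit.critical
    else:
        threshold = float(crit)
        pew = np.where(stats > threshold, np.nan, 1.0)
        floor = np.zeros(len(stats), dtype=bool)
    if not np.isfinite(threshold):
        raise ValueError("critical value must be finite")
    m.neglog_pew = -np.log10(pew)
    m.p_floor = floor

    keep = stats > threshold
    rows = []
    for j in np.nonzero(keep)[0]:
        t = m.terms[j]
        rows.append({
            "term": t.label(), "class": t.cls,
            "loci": "|".join(t.loci), "environment": t.env,
            "effect": float(m.post_mean[j]), "se": float(m.post_se[j]),
            "neglog_pew": float(m.neglog_pew[j]),
            "p_floor": bool(floor[j]),
        })
    entries = pd.DataFrame(rows, columns=list(QTSTable.COLUMNS))
    return QTSTable(trait=m.trait, entries=entries, env_means=dict(m.env_means))


def prediction_correlation(m: MappingResult, x: DesignMatrix) -> dict:
    """Correlation between fitted genotypic value and observed response.

    The fitted value of an observation is its environment intercept plus the
    sum of all fitted terms.  Returns the pooled Pearson correlation R_Yhat
    plus per-environment correlations; a zero-variance side yields NaN.
    """
    env_int = np.array([m.env_means[e] for e in x.environments])
    yhat = env_int + x.X @ m.post_mean
    y = np.asarray(x.y, dtype=float)

    def _corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    out = {"pooled": _corr(yhat, y)}
    for e in x.env_levels:
        mask = x.environments == e
        out[e] = _corr(yhat[mask], y[mask])
    return out
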