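"""Diversity statistics for the habitat comparison.

Implements, from their defining formulas:

* Hill numbers (q0 richness, q1 = exp(Shannon entropy) as an evenness
  summary, general q >= 0);
* exact sample-based rarefaction
  ``E[S(t)] = sum_i [1 - C(T - Y_i, t) / C(T, t)]`` over incidence
  frequencies ``Y_i`` in ``T`` sampling units;
* nonlinear accumulation-model fitting (asymptotic regression, Lomolino,
  logistic) with AIC selection;
* the Jaccard beta-diversity partition into turnover (beta_jtu) and
  nestedness (beta_jnes);
* PERMANOVA with sequential (type-I) sums of squares and free row
  permutations;
* principal coordinates analysis (PCoA) by Gower double-centering;
* power/sample-size for a balanced one-way ANOVA via the noncentral F
  distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "hill_number",
    "rarefy_exact",
    "rarefaction_curve",
    "AccumulationFit",
    "fit_accumulation",
    "select_best_model",
    "BetaPair",
    "beta_pair",
    "beta_pair_matrices",
    "PermanovaResult",
    "permanova",
    "PcoaResult",
    "pcoa",
    "anova_power",
    "anova_power_n",
    "anova_power_n_continuous",
    "ACCUMULATION_MODELS",
]


# ---------------------------------------------------------------------------
# Hill numbers

def hill_number(counts: Sequence[float], q: float) -> float:
    """Hill number of order ``q``: the effective number of equally
    abundant taxa.

    q=0 is richness; q=1 is exp(Shannon entropy) (the continuous limit);
    general q uses ``(sum p_i^q)^(1/(1-q))``.  Zero counts are dropped.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all counts are zero")
    if q < 0:
        raise ValueError("q must be >= 0")
    p = c / c.sum()
    if q == 0:
        return float(p.size)
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


# ---------------------------------------------------------------------------
# exact sample-based rarefaction

def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_exact(incidence: Sequence[int], T: int, t: int) -> float:
    """Expected richness in ``t`` of ``T`` sampling units.

    ``incidence`` holds the per-taxon incidence frequencies Y_i (number of
    units in which taxon i occurred); the expectation over all C(T, t)
    equally likely subsets is ``sum_i [1 - C(T - Y_i, t) / C(T, t)]``.
    """
    if not (1 <= t <= T):
        raise ValueError(f"t must be in [1, {T}], got {t}")
    y = np.asarray(incidence, dtype=int)
    if np.any(y < 0) or np.any(y > T):
        raise ValueError("incidence frequencies must satisfy 0 <= Y_i <= T")
    y = y[y > 0]
    total = 0.0
    for yi in y:
        if T - yi < t:
            total += 1.0  # taxon present in every subset of size t
        else:
            total += 1.0 - math.exp(_log_comb(T - yi, t) - _log_comb(T, t))
    return total


def rarefaction_curve(incidence: Sequence[int], T: int) -> np.ndarray:
    """E[S(t)] for t = 1..T."""
    return np.array([rarefy_exact(incidence, T, t) for t in range(1, T + 1)])


# ---------------------------------------------------------------------------
# accumulation models

def _asymp(t, Asym, R0, lrc):
    return Asym + (R0 - Asym) * np.exp(-np.exp(lrc) * t)


def _lomolino(t, Asym, xmid, slope):
    with np.errstate(invalid="ignore", over="ignore"):
        return Asym / (1.0 + slope ** np.log(xmid / t))


def _logistic(t, Asym, xmid, scal):
    return Asym / (1.0 + np.exp((xmid - t) / scal))


ACCUMULATION_MODELS = {
    "asymptotic": _asymp,
    "lomolino": _lomolino,
    "logistic": _logistic,
}


@dataclass
class AccumulationFit:
    model: str
    params: dict[str, float]
    rss: float
    aic: float
    fitted: np.ndarray
    converged: bool
    message: str = ""

    @property
    def asymptote(self) -> float:
        return self.params["Asym"]


def _start_values(model: str, t: np.ndarray, s: np.ndarray) -> list[float]:
    """Self-start heuristics: Asym a little above the observed maximum,
    R0 at the first point, unit rate; midpoint at the median sample count,
    slope/scale from a crude two-point slope."""
    asym0 = 1.05 * float(s.max())
    if model == "asymptotic":
        return [asym0, float(s[0]), 0.0]
    xmid0 = float(np.median(t))
    span = float(t[-1] - t[0]) or 1.0
    rise = float(s[-1] - s[0])
    scal0 = max(span / 4.0, 0.5) if rise > 0 else 1.0
    if model == "logistic":
        return [asym0, xmid0, scal0]
    return [asym0, xmid0, max(1.0 + rise / span / 10.0, 1.5)]  # lomolino slope > 1


def fit_accumulation(
    t: Sequence[float], s: Sequence[float], model: str = "asymptotic"
) -> AccumulationFit:
    """Nonlinear least-squares fit of an accumulation model to curve
    points (t, S).

    AIC follows the Gaussian-likelihood convention
    ``n*ln(2*pi*RSS/n) + n + 2*(p+1)`` with p model parameters (+1 for
    the error variance), so AIC differences between models fitted to the
    same points are free of additive constants.  Non-convergence yields a
    flagged fit (``converged=False``) rather than an exception.
    """
    if model not in ACCUMULATION_MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(ACCUMULATION_MODELS)}")
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 curve points")
    func = ACCUMULATION_MODELS[model]
    names = {"asymptotic": ["Asym", "R0", "lrc"],
             "lomolino": ["Asym", "xmid", "slope"],
             "logistic": ["Asym", "xmid", "scal"]}[model]
    p0 = _start_values(model, t, s)
    # the Lomolino slope must stay positive for slope**log(...) to be real
    kwargs: dict = (
        {"bounds": ([0.0, 0.0, 1.0 + 1e-9], [np.inf, np.inf, np.inf]), "max_nfev": 20000}
        if model == "lomolino"
        else {"maxfev": 20000}
    )
    try:
        popt, _ = optimize.curve_fit(func, t, s, p0=p0, **kwargs)
        fitted = func(t, *popt)
        if not np.all(np.isfinite(fitted)):
            raise RuntimeError("non-finite fitted values")
        converged, message = True, ""
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        popt = np.asarray(p0)
        fitted = func(t, *popt)
        converged, message = False, str(exc)
    rss = float(np.sum((s - fitted) ** 2))
    n = t.size
    p = len(popt)
    aic = n * math.log(2 * math.pi * max(rss, 1e-300) / n) + n + 2 * (p + 1)
    return AccumulationFit(
        model=model,
        params=dict(zip(names, map(float, popt))),
        rss=rss,
        aic=float(aic),
        fitted=np.asarray(fitted, dtype=float),
        converged=converged,
        message=message,
    )


def select_best_model(fits: Iterable[AccumulationFit]) -> AccumulationFit:
    """Lowest-AIC fit among converged fits; ties broken by fewer
    parameters, then model name."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged accumulation fit to select from")
    return min(converged, key=lambda f: (f.aic, len(f.params), f.model))


# ---------------------------------------------------------------------------
# Jaccard beta-diversity partition

@dataclass(frozen=True)
class BetaPair:
    beta_jac: float
    beta_jtu: float
    beta_jnes: float


def beta_pair(site1: Iterable, site2: Iterable) -> BetaPair:
    """Pairwise Jaccard dissimilarity partitioned into turnover and
    nestedness.

    With a shared taxa, b and c unique to either site:
    beta_jac = (b+c)/(a+b+c); beta_jtu = 2*min(b,c)/(a + 2*min(b,c));
    beta_jnes = beta_jac - beta_jtu.
    """
    s1, s2 = set(site1), set(site2)
    if not s1 and not s2:
        raise ValueError("both sites are empty")
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    beta_jac = (b + c) / (a + b + c)
    m = min(b, c)
    beta_jtu = 2 * m / (a + 2 * m) if (a + 2 * m) > 0 else 0.0
    return BetaPair(beta_jac, beta_jtu, beta_jac - beta_jtu)


def beta_pair_matrices(presence: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Square beta_jac, beta_jtu and beta_jnes matrices over the rows
    (samples) of a presence/absence table."""
    samples = list(presence.index)
    n = len(samples)
    jac = np.zeros((n, n))
    jtu = np.zeros((n, n))
    jnes = np.zeros((n, n))
    sets = [set(presence.columns[presence.iloc[i].to_numpy() > 0]) for i in range(n)]
    for i, j in combinations(range(n), 2):
        bp = beta_pair(sets[i], sets[j])
        jac[i, j] = jac[j, i] = bp.beta_jac
        jtu[i, j] = jtu[j, i] = bp.beta_jtu
        jnes[i, j] = jnes[j, i] = bp.beta_jnes
    return tuple(
        pd.DataFrame(m, index=samples, columns=samples) for m in (jac, jtu, jnes)
    )


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    terms: list[str]
    df: dict[str, int]
    ss: dict[str, float]
    r2: dict[str, float]
    pseudo_f: dict[str, float]
    p: dict[str, float]
    residual_df: int
    residual_ss: float
    residual_r2: float
    total_ss: float
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "df": self.df[t],
                "ss": self.ss[t],
                "r2": self.r2[t],
                "pseudo_f": self.pseudo_f[t],
                "p": self.p[t],
            }
            for t in self.terms
        ]
        rows.append(
            {
                "term": "Residual",
                "df": self.residual_df,
                "ss": self.residual_ss,
                "r2": self.residual_r2,
                "pseudo_f": np.nan,
                "p": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # pseudo-inverse hat matrix; tolerant of rank-deficient dummy codings
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _check_distance_matrix(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")


def permanova(
    distances: pd.DataFrame | np.ndarray,
    factors: pd.DataFrame,
    terms: Sequence[str] = ("habitat", "replicate", "time_of_day"),
    n_perm: int = 999,
    seed: int = 1,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The total sum of squared distances is partitioned sequentially
    (type-I) over ``terms`` via hat matrices on the Gower-centered
    inner-product matrix; each term's pseudo-F is tested by freely
    permuting the rows of the factor table (equivalently the rows/columns
    of the centered matrix), with the add-one convention
    ``p = (1 + #{F* >= F}) / (1 + n_perm)``.
    """
    d = np.asarray(distances, dtype=float)
    _check_distance_matrix(d)
    n = d.shape[0]
    if isinstance(distances, pd.DataFrame):
        factors = factors.loc[list(distances.index)]
    if len(factors) != n:
        raise ValueError("factor table does not match the distance matrix")
    terms = list(terms)
    for term in terms:
        if factors[term].nunique() < 2:
            raise ValueError(f"term {term!r} has fewer than 2 levels")

    g = _gower_center(d)
    total_ss = float(np.trace(g))

    # cumulative hat matrices for the sequential decomposition
    ones = np.ones((n, 1))
    designs: list[np.ndarray] = []
    dfs: list[int] = []
    x = ones
    rank_prev = 1
    for term in terms:
        dummies = pd.get_dummies(factors[term].astype(str), drop_first=False).to_numpy(float)
        x = np.hstack([x, dummies])
        rank = np.linalg.matrix_rank(x)
        dfs.append(rank - rank_prev)
        rank_prev = rank
        designs.append(x)
    hats = [_hat(x) for x in designs]
    h0 = _hat(ones)
    residual_df = n - rank_prev
    if residual_df <= 0:
        raise ValueError("model saturates the data; no residual degrees of freedom")

    def decompose(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        prev = h0
        ss_terms = np.empty(len(terms))
        for i, h in enumerate(hats):
            ss_terms[i] = np.trace((h - prev) @ gmat)
            prev = h
        ss_res = float(np.trace((np.eye(n) - hats[-1]) @ gmat))
        return ss_terms, ss_res

    ss_obs, ss_res = decompose(g)
    f_obs = (ss_obs / np.array(dfs)) / (ss_res / residual_df)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_rp = decompose(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_rp / residual_df)
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    return PermanovaResult(
        terms=terms,
        df=dict(zip(terms, dfs)),
        ss=dict(zip(terms, map(float, ss_obs))),
        r2=dict(zip(terms, (float(s / total_ss) for s in ss_obs))),
        pseudo_f=dict(zip(terms, map(float, f_obs))),
        p=dict(zip(terms, map(float, pvals))),
        residual_df=residual_df,
        residual_ss=ss_res,
        residual_r2=float(ss_res / total_ss),
        total_ss=total_ss,
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PCoA

@dataclass
class PcoaResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(
    distances: pd.DataFrame | np.ndarray, n_axes: int | None = None
) -> PcoaResult:
    """Principal coordinates analysis.

    The distance matrix is Gower double-centered (B = -1/2 J D^2 J) and
    eigendecomposed; axes are eigenvectors scaled by the square root of
    their (positive) eigenvalues, sorted descending.  Negative
    eigenvalues — possible for non-Euclidean dissimilarities such as the
    Jaccard turnover component — are reported and their axes dropped;
    proportions explained are relative to the sum of positive eigenvalues.
    """
    d = np.asarray(distances, dtype=float)
    _check_distance_matrix(d)
    index = (
        list(distances.index)
        if isinstance(distances, pd.DataFrame)
        else list(range(d.shape[0]))
    )
    b = _gower_center(d)
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    pos_sum = eigval[pos].sum()
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=index, columns=axes),
        eigenvalues=eigval[pos],
        proportion_explained=(eigval[pos] / pos_sum if pos_sum > 0 else eigval[pos]),
        negative_eigenvalues=eigval[eigval < -tol],
    )


# ---------------------------------------------------------------------------
# balanced one-way ANOVA power

def anova_power(k: int, n: int, f: float, alpha: float = 0.05) -> float:
    """Power of a balanced one-way ANOVA with ``k`` groups of ``n``
    samples and Cohen effect size ``f`` at level ``alpha``.

    Under the alternative the F statistic is noncentral F with
    df (k-1, k(n-1)) and noncentrality lambda = k*n*f^2.
    """
    if k < 2 or n < 2:
        raise ValueError("need k >= 2 groups and n >= 2 per group")
    df1, df2 = k - 1, k * (n - 1)
    fcrit = stats.f.isf(alpha, df1, df2)
    lam = k * n * f**2
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def anova_power_n(
    k: int,
    f: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
    n_max: int = 10_000,
) -> int:
    """Smallest integer group size n >= 2 reaching ``target_power``."""
    if f <= 0:
        raise ValueError("effect size f must be > 0")
    if not (0 < alpha < 1 and 0 < target_power < 1):
        raise ValueError("alpha and target_power must be in (0, 1)")
    for n in range(2, n_max + 1):
        if anova_power(k, n, f, alpha) >= target_power:
            return n
    raise ValueError(f"target power not reached for any n <= {n_max}")


def anova_power_n_continuous(
    k: int, f: float, alpha: float = 0.05, target_power: float = 0.8
) -> float:
    """Fractional group size n solving power(n) = target_power.

    This is the quantity R-style power solvers print (they root-find a
    continuous n, evaluating the error df ``k*(n-1)`` at non-integer n);
    published sample sizes are typically this value rounded.  The
    guaranteed-power integer answer is :func:`anova_power_n`.
    """
    if f <= 0:
        raise ValueError("effect size f must be > 0")

    def _power(n: float) -> float:
        df1, df2 = k - 1, k * (n - 1)
        fcrit = stats.f.isf(alpha, df1, df2)
        return float(stats.ncf.sf(fcrit, df1, df2, k * n * f**2))

    lo, hi = 1.0 + 1e-9, 2.0
    while _power(hi) < target_power:
        hi *= 2
        if hi > 1e7:
            raise ValueError("target power not reachable")
    return float(optimize.brentq(lambda n: _power(n) - target_power, lo, hi))
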