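"""Factor-analysis integration of multiplatform feature tables.

The sequential dimensionality-reduction cascade:

1. Pearson-correlation decorrelation (intra-matrix, then inter-matrix) to
   eliminate multicollinearity before any factor model is fitted.
2. Per matrix: PCA with varimax rotation; the number of components is chosen
   by the Kaiser-Guttman rule (eigenvalue > 1) raised until cumulative
   explained variance exceeds 60%, with the scree elbow reported as a
   diagnostic.  Variables are retained only when their top absolute loading
   exceeds 0.5 and is at least 0.1 clear of the second ("double saturation"
   rule).
3. Per matrix: maximum-likelihood factor analysis (varimax rotated) on the
   PCA-retained variables, with the same selection and retention rules.
4. All surviving variables are pooled and a combined maximum-likelihood
   factor analysis with varimax rotation yields the final factors; the
   Kaiser-Meyer-Olkin statistic reports sampling adequacy.
5. Thurstone regression factor scores (Z S^-1 Lambda) turn the factors into
   per-sample variables for clustering.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class IntegrateError(ValueError):
    pass


class ConvergenceError(IntegrateError):
    def __init__(self, message: str, iterations: int):
        super().__init__(f"{message} (after {iterations} iterations)")
        self.iterations = iterations


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, sd 1, ddof=1); constant columns -> 0."""
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    sd = sd.replace(0.0, 1.0)
    return (table - mean) / sd


# ---------------------------------------------------------------------------
# multicollinearity elimination
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CorrelationFilterResult:
    stage: str                       # "intra" or "inter"
    platform_id: str
    retained_features: list[str]
    dropped_features: list[tuple[str, str, float]]  # (dropped, partner, r)


def _screen_correlations(corr: pd.DataFrame, threshold: float,
                         scope: dict[str, str] | None = None
                         ) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Iteratively drop one member of the worst |r| >= threshold pair.

    The member with the larger mean absolute correlation to all other
    surviving variables is dropped ("drop the hub").  Ties break to the
    variable from the larger matrix (inter stage, via ``scope``), then to the
    lexicographically later id.  ``scope`` maps variable -> platform; when
    given, only cross-platform pairs are eligible.
    """
    vars_ = list(corr.columns)
    dropped: list[tuple[str, str, float]] = []
    A = corr.abs().to_numpy(copy=True)
    np.fill_diagonal(A, 0.0)
    if scope is not None:
        plats = np.array([scope[v] for v in vars_])
        eligible = plats[:, None] != plats[None, :]
    else:
        eligible = np.ones_like(A, dtype=bool)
    sizes = None
    if scope is not None:
        from collections import Counter
        counts = Counter(scope.values())
        sizes = np.array([counts[scope[v]] for v in vars_], dtype=float)
    alive = np.ones(len(vars_), dtype=bool)
    while True:
        M = np.where(eligible & alive[:, None] & alive[None, :], A, 0.0)
        mx = M.max()
        if mx < threshold:
            break
        # worst pair: largest |r|; ties -> lexicographically smallest pair
        cand = np.argwhere(np.isclose(M, mx))
        pairs = sorted({tuple(sorted((vars_[i], vars_[j]))) for i, j in cand})
        vi, vj = pairs[0]
        i, j = vars_.index(vi), vars_.index(vj)
        # mean |r| to all other surviving variables
        others = alive.copy()
        others[[i, j]] = False
        mi = A[i, others].mean() if others.any() else 0.0
        mj = A[j, others].mean() if others.any() else 0.0
        if not np.isclose(mi, mj):
            drop = i if mi > mj else j
        elif sizes is not None and sizes[i] != sizes[j]:
            drop = i if sizes[i] > sizes[j] else j
        else:
            drop = max(i, j, key=lambda t: vars_[t])
        keep = j if drop == i else i
        alive[drop] = False
        dropped.append((vars_[drop], vars_[keep], float(corr.iat[drop, keep])))
    retained = [v for v, a in zip(vars_, alive) if a]
    return retained, dropped


def decorrelate(tables: dict[str, pd.DataFrame], threshold: float = 0.9
                ) -> tuple[dict[str, pd.DataFrame], list[CorrelationFilterResult]]:
    """Two-stage Pearson decorrelation: within each matrix, then across matrices.

    ``tables`` maps platform id -> standardized samples x variables table
    (shared sample order).  Returns the filtered tables and per-stage results.
    """
    if not 0 < threshold <= 1:
        raise IntegrateError("threshold must be in (0, 1]")
    for t in tables.values():
        if len(t) < 3:
            raise IntegrateError("need >= 3 samples")
    results: list[CorrelationFilterResult] = []
    intra: dict[str, pd.DataFrame] = {}
    for pid, table in tables.items():
        corr = table.corr()
        retained, dropped = _screen_correlations(corr, threshold)
        results.append(CorrelationFilterResult("intra", pid, retained, dropped))
        intra[pid] = table[retained]

    pooled = pd.concat(intra.values(), axis=1)
    scope = {v: pid for pid, t in intra.items() for v in t.columns}
    retained, dropped = _screen_correlations(pooled.corr(), threshold, scope)
    retained_set = set(retained)
    out: dict[str, pd.DataFrame] = {}
    for pid, table in intra.items():
        keep = [v for v in table.columns if v in retained_set]
        drop = [(v, p, r) for v, p, r in dropped if scope[v] == pid]
        results.append(CorrelationFilterResult("inter", pid, keep, drop))
        out[pid] = table[keep]
    return out, results


# ---------------------------------------------------------------------------
# KMO sampling adequacy
# ---------------------------------------------------------------------------

def compute_kmo(corr: np.ndarray | pd.DataFrame) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum p_ij^2) over i != j, where p_ij are
    the partial correlations obtained from the inverse correlation matrix.
    """
    R = np.asarray(corr, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise IntegrateError("correlation matrix must be square")
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = float(np.sum(R[off] ** 2))
    if r2 == 0:
        raise IntegrateError("no correlations: KMO undefined")
    try:
        A = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        log.warning("correlation matrix singular; adding ridge 1e-8")
        A = np.linalg.inv(R + 1e-8 * np.eye(R.shape[0]))
    d = np.sqrt(np.abs(np.diag(A)))
    P = -A / np.outer(d, d)
    p2 = float(np.sum(P[off] ** 2))
    return r2 / (r2 + p2)


# ---------------------------------------------------------------------------
# component-number selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SelectionDiagnostics:
    kaiser_n: int
    scree_elbow: int
    cumulative_variance: float
    n: int


def select_n_components(eigenvalues: Sequence[float],
                        n_variables: int | None = None,
                        min_cum_var: float = 0.60
                        ) -> tuple[int, SelectionDiagnostics]:
    """Choose the component count from three rules.

    Base count = Kaiser-Guttman (eigenvalues > 1 of the correlation matrix,
    floor 1); raised until the cumulative explained variance share exceeds
    ``min_cum_var`` (capped at the number of eigenvalues supplied).  The
    scree elbow (argmax of the second difference of the eigenvalue curve) is
    reported as a diagnostic and a warning is logged when it disagrees.
    """
    ev = np.asarray(list(eigenvalues), dtype=float)
    if ev.size == 0:
        raise IntegrateError("empty eigenvalue list")
    if np.any(np.diff(ev) > 1e-9):
        raise IntegrateError("eigenvalues must be sorted descending")
    total = float(n_variables) if n_variables is not None else float(ev.sum())
    if total <= 0:
        raise IntegrateError("total variance must be positive")
    n = max(int(np.sum(ev > 1.0)), 1)
    cum = np.cumsum(ev) / total
    while cum[n - 1] <= min_cum_var and n < ev.size:
        n += 1
    if ev.size >= 3:
        second_diff = ev[:-2] - 2 * ev[1:-1] + ev[2:]
        elbow = int(np.argmax(second_diff)) + 1
    else:
        elbow = 1
    diag = SelectionDiagnostics(kaiser_n=int(np.sum(ev > 1.0)),
                                scree_elbow=elbow,
                                cumulative_variance=float(cum[n - 1]), n=n)
    if elbow != n:
        log.debug("scree elbow (%d) disagrees with selected n (%d)", elbow, n)
    return n, diag


# ---------------------------------------------------------------------------
# varimax rotation
# ---------------------------------------------------------------------------

def _fix_sign_and_order(L: np.ndarray) -> np.ndarray:
    """Largest-|loading| entry of each column positive; columns by SS desc."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    ss = (L ** 2).sum(axis=0)
    order = np.argsort(-ss, kind="stable")
    return L[:, order]


def varimax_rotate(loadings: np.ndarray, tol: float = 1e-6,
                   max_iter: int = 100) -> np.ndarray:
    """Orthogonal varimax rotation with Kaiser row normalization.

    Converges when the criterion gain falls below ``tol`` or after
    ``max_iter`` sweeps.  Output convention: each column's largest-magnitude
    loading is positive and columns are ordered by descending sum of squared
    loadings.  A single column is returned unchanged (up to the convention).
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2:
        raise IntegrateError("loadings must be 2-D")
    p, k = L.shape
    if k < 2:
        return _fix_sign_and_order(L.copy())
    h = np.sqrt((L ** 2).sum(axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    B = (L / h_safe[:, None]).copy()

    def criterion(M: np.ndarray) -> float:
        return float(np.sum(M ** 4) - np.sum((M ** 2).sum(axis=0) ** 2) / p)

    # classical pairwise (Kaiser) sweeps: closed-form optimal planar angle
    # per column pair, monotone in the varimax criterion
    crit = criterion(B)
    for _ in range(max_iter):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = B[:, i], B[:, j]
                u = x ** 2 - y ** 2
                v = 2.0 * x * y
                num = 2.0 * (u @ v - u.sum() * v.sum() / p)
                den = (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                B[:, i], B[:, j] = c * x + s * y, -s * x + c * y
        crit_new = criterion(B)
        if crit_new - crit < tol * max(abs(crit), 1.0):
            break
        crit = crit_new
    rotated = B * h_safe[:, None]
    return _fix_sign_and_order(rotated)


# ---------------------------------------------------------------------------
# component models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ComponentModel:
    """One fitted PCA or maximum-likelihood factor model."""

    method: str                      # "pca" | "mlfa"
    rotation: str                    # "none" | "varimax"
    variable_ids: list[str]
    loadings: pd.DataFrame           # variables x components
    variance_share: np.ndarray       # per retained component
    cumulative_variance: float
    kmo: float
    eigenvalues: np.ndarray | None = None    # pca: full spectrum
    uniquenesses: pd.Series | None = None    # mlfa
    n_iter: int | None = None
    selection: SelectionDiagnostics | None = None

    def validate(self) -> None:
        if self.method == "mlfa" and self.uniquenesses is not None:
            comm = (self.loadings ** 2).sum(axis=1)
            if not np.allclose(comm + self.uniquenesses, 1.0, atol=1e-6):
                raise IntegrateError("communality + uniqueness != 1")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _component_columns(k: int) -> list[str]:
    return [f"F{j + 1}" for j in range(k)]


def fit_pca(table: pd.DataFrame, n: int) -> ComponentModel:
    """PCA of the correlation matrix; loadings = eigenvectors * sqrt(eigenvalue).

    The first ``n`` loading columns are varimax-rotated.  Variance shares are
    eigenvalue / number of variables.
    """
    Z = standardize(table)
    p = Z.shape[1]
    if np.isnan(Z.to_numpy()).any():
        raise IntegrateError("PCA requires complete data")
    if n > min(Z.shape[0] - 1, p):
        raise IntegrateError(f"n={n} too large for {Z.shape[0]} samples x {p} variables")
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    if p == 1:
        corr = np.array([[1.0]])
    ev, vec = np.linalg.eigh(corr)
    order = np.argsort(-ev)
    ev, vec = np.maximum(ev[order], 0.0), vec[:, order]
    load = vec[:, :n] * np.sqrt(ev[:n])
    rotated = varimax_rotate(load) if n >= 2 else _fix_sign_and_order(load)
    loadings = pd.DataFrame(rotated, index=table.columns,
                            columns=_component_columns(n))
    share = (rotated ** 2).sum(axis=0) / p
    model = ComponentModel(
        method="pca", rotation="varimax" if n >= 2 else "none",
        variable_ids=list(table.columns), loadings=loadings,
        variance_share=share, cumulative_variance=float(ev[:n].sum() / p),
        kmo=_kmo_or_nan(corr), eigenvalues=ev)
    model.validate()
    return model


def _kmo_or_nan(corr: np.ndarray) -> float:
    try:
        return compute_kmo(corr)
    except IntegrateError:
        return float("nan")


def _principal_axis_start(S: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-axis loadings from SMC-reduced correlation matrix."""
    p = S.shape[0]
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(S))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    smc = np.clip(smc, 0.05, 0.995)
    R = S.copy()
    np.fill_diagonal(R, smc)
    ev, vec = np.linalg.eigh(R)
    order = np.argsort(-ev)
    ev, vec = ev[order], vec[:, order]
    lam = vec[:, :k] * np.sqrt(np.maximum(ev[:k], 1e-8))
    psi = np.clip(1.0 - (lam ** 2).sum(axis=1), 0.005, 1.0)
    return lam, psi


def _ml_discrepancy(S: np.ndarray, lam: np.ndarray, psi: np.ndarray) -> float:
    """ML fitting function: ln|Sigma| + tr(S Sigma^-1) - ln|S| - p."""
    p = S.shape[0]
    sigma = lam @ lam.T + np.diag(psi)
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign <= 0 or sign_s <= 0:
        return np.inf
    return float(logdet_sigma + np.trace(S @ np.linalg.inv(sigma))
                 - logdet_s - p)


def ledermann_bound(p: int) -> int:
    """Largest factor count identifiable from p variables."""
    return int(np.floor((2 * p + 1 - np.sqrt(8 * p + 1)) / 2))


def _psi_objective(psi: np.ndarray, S: np.ndarray, k: int
                   ) -> tuple[float, np.ndarray]:
    """Profile ML discrepancy over uniquenesses, with analytic gradient.

    For fixed Psi the optimal loadings are closed-form in the eigensystem of
    Psi^-1/2 S Psi^-1/2; the concentrated discrepancy is
    ``sum_{j>k} (lambda_j - ln lambda_j - 1)``.
    """
    sc = 1.0 / np.sqrt(psi)
    Sstar = S * np.outer(sc, sc)
    ev, vec = np.linalg.eigh(Sstar)
    ev, vec = ev[::-1], vec[:, ::-1]
    tail = np.maximum(ev[k:], 1e-12)
    f = float(np.sum(tail - np.log(tail) - 1.0))
    lam = _optimal_loadings(psi, ev, vec, k)
    resid = lam @ lam.T + np.diag(psi) - S
    grad = np.diag(resid) / psi ** 2
    return f, grad


def _optimal_loadings(psi: np.ndarray, ev: np.ndarray, vec: np.ndarray,
                      k: int) -> np.ndarray:
    """Conditional ML loadings Lambda = Psi^1/2 V_k (E_k - I)^1/2."""
    top = np.maximum(ev[:k] - 1.0, 0.0)
    return np.sqrt(psi)[:, None] * vec[:, :k] * np.sqrt(top)[None, :]


def fit_mlfa(table: pd.DataFrame, n: int, tol: float = 1e-6,
             max_iter: int = 1000) -> ComponentModel:
    """Maximum-likelihood factor analysis, varimax-rotated.

    Fits Sigma = Lambda Lambda' + Psi by minimizing the ML discrepancy
    ``ln|Sigma| + tr(S Sigma^-1) - ln|S| - p``.  The likelihood is profiled
    over the loadings (closed form given the uniquenesses) and the
    uniquenesses are optimized by L-BFGS-B with analytic gradients, bounded
    in [0.005, 1] (Heywood protection), starting deterministically from
    principal-axis estimates.  Raises :class:`ConvergenceError` when the
    optimizer does not reach tolerance ``tol`` within ``max_iter``
    iterations.
    """
    from scipy.optimize import minimize

    if n < 1:
        raise IntegrateError("n must be >= 1")
    Z = standardize(table)
    p = Z.shape[1]
    if n >= p:
        raise IntegrateError(f"n={n} must be < {p} variables")
    X = Z.to_numpy()
    if np.isnan(X).any():
        raise IntegrateError("ML-FA requires complete data")
    S = np.corrcoef(X, rowvar=False)
    lam0, psi0 = _principal_axis_start(S, n)
    f_start = _ml_discrepancy(S, lam0, psi0)
    res = minimize(_psi_objective, psi0, args=(S, n), jac=True,
                   method="L-BFGS-B", bounds=[(0.005, 1.0)] * p,
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7})
    it = int(res.nit)
    if not res.success:
        raise ConvergenceError(f"ML-FA did not converge: {res.message}", it)
    psi = np.clip(res.x, 0.005, 1.0)
    sc = 1.0 / np.sqrt(psi)
    ev, vec = np.linalg.eigh(S * np.outer(sc, sc))
    ev, vec = ev[::-1], vec[:, ::-1]
    lam = _optimal_loadings(psi, ev, vec, n)
    f_prev = _ml_discrepancy(S, lam, psi)
    if not np.isfinite(f_prev) or f_prev > f_start + 1e-8:
        raise ConvergenceError(
            "optimizer failed to improve on principal-axis start", it)

    rotated = varimax_rotate(lam) if n >= 2 else _fix_sign_and_order(lam)
    # enforce communality + uniqueness = 1 exactly (Heywood rows rescaled)
    comm = (rotated ** 2).sum(axis=1)
    over = comm > 0.995
    if over.any():
        rotated[over] *= np.sqrt(0.995 / comm[over])[:, None]
        comm = (rotated ** 2).sum(axis=1)
    uniq = 1.0 - comm
    loadings = pd.DataFrame(rotated, index=table.columns,
                            columns=_component_columns(n))
    share = (rotated ** 2).sum(axis=0) / p
    model = ComponentModel(
        method="mlfa", rotation="varimax" if n >= 2 else "none",
        variable_ids=list(table.columns), loadings=loadings,
        variance_share=share, cumulative_variance=float(share.sum()),
        kmo=_kmo_or_nan(S),
        uniquenesses=pd.Series(uniq, index=table.columns), n_iter=it)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# variable retention (double-saturation rule)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RetentionDecision:
    variable: str
    top_loading_abs: float
    second_loading_abs: float
    assigned_component: int | None   # 0-based column index, when retained
    retained: bool
    reason: str                      # kept | below_threshold | double_saturation


def apply_retention(model: ComponentModel, threshold: float = 0.5,
                    gap: float = 0.1) -> list[RetentionDecision]:
    """Keep variables loading cleanly on a single component.

    A variable is retained iff its top absolute loading is strictly greater
    than ``threshold`` and exceeds the second-largest absolute loading by at
    least ``gap`` (otherwise it shows "double saturation").  With a single
    component the gap rule passes vacuously.
    """
    L = model.loadings.to_numpy()
    decisions = []
    for i, var in enumerate(model.loadings.index):
        absl = np.abs(L[i])
        order = np.argsort(-absl, kind="stable")
        top = float(absl[order[0]])
        second = float(absl[order[1]]) if absl.size > 1 else 0.0
        if top <= threshold:
            decisions.append(RetentionDecision(var, top, second, None, False,
                                               "below_threshold"))
        elif absl.size > 1 and (top - second) < gap:
            decisions.append(RetentionDecision(var, top, second, None, False,
                                               "double_saturation"))
        else:
            decisions.append(RetentionDecision(var, top, second,
                                               int(order[0]), True, "kept"))
    return decisions


def retained_variables(decisions: list[RetentionDecision]) -> list[str]:
    return [d.variable for d in decisions if d.retained]


def enforce_min_indicators(decisions: list[RetentionDecision],
                           min_vars: int = 2) -> list[RetentionDecision]:
    """Invalidate factors with fewer than ``min_vars`` saturating variables.

    A common factor needs at least two indicators to be identified; a factor
    saturated by a single variable (typically a Heywood case of an
    over-factored fit) is no factor at all, so its variables are released.
    """
    counts: dict[int, int] = {}
    for d in decisions:
        if d.retained:
            counts[d.assigned_component] = counts.get(d.assigned_component, 0) + 1
    out = []
    for d in decisions:
        if d.retained and counts[d.assigned_component] < min_vars:
            out.append(RetentionDecision(
                d.variable, d.top_loading_abs, d.second_loading_abs, None,
                False, "singleton_factor"))
        else:
            out.append(d)
    return out


# ---------------------------------------------------------------------------
# per-matrix cascade and combined factor analysis
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CascadeResult:
    platform_id: str
    retained_table: pd.DataFrame
    pca_model: ComponentModel | None
    fa_model: ComponentModel | None
    pca_decisions: list[RetentionDecision]
    fa_decisions: list[RetentionDecision]


def cascade_reduce(table: pd.DataFrame, platform_id: str = "",
                   threshold: float = 0.5, gap: float = 0.1,
                   min_cum_var: float = 0.60) -> CascadeResult:
    """PCA -> retention -> ML-FA -> retention for one platform's table.

    A matrix with fewer than 4 variables, or whose ML-FA step fails to
    extract any cleanly-saturating variable, contributes zero variables.
    """
    empty = CascadeResult(platform_id, table.iloc[:, :0], None, None, [], [])
    if table.shape[1] < 4:
        log.warning("%s: fewer than 4 variables; contributes nothing", platform_id)
        return empty
    Z = standardize(table)
    n_samples, p = Z.shape
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
    n_pc, _ = select_n_components(np.maximum(ev, 0.0), n_variables=p,
                                  min_cum_var=min_cum_var)
    n_pc = min(n_pc, n_samples - 1, p)
    pca_model = fit_pca(Z, n_pc)
    pca_dec = enforce_min_indicators(apply_retention(pca_model, threshold, gap))
    keep1 = retained_variables(pca_dec)
    if len(keep1) < 2:
        log.warning("%s: PCA retention left %d variables; contributes nothing",
                    platform_id, len(keep1))
        return CascadeResult(platform_id, table.iloc[:, :0], pca_model, None,
                             pca_dec, [])
    sub = Z[keep1]
    p2 = sub.shape[1]
    corr2 = np.corrcoef(sub.to_numpy(), rowvar=False)
    ev2 = np.sort(np.linalg.eigvalsh(corr2))[::-1]
    n_fa, _ = select_n_components(np.maximum(ev2, 0.0), n_variables=p2,
                                  min_cum_var=min_cum_var)
    n_fa = min(n_fa, p2 - 1, max(ledermann_bound(p2), 1))
    try:
        fa_model = fit_mlfa(sub, n_fa)
    except IntegrateError as e:
        log.warning("%s: ML-FA failed (%s); contributes nothing", platform_id, e)
        return CascadeResult(platform_id, table.iloc[:, :0], pca_model, None,
                             pca_dec, [])
    fa_dec = enforce_min_indicators(apply_retention(fa_model, threshold, gap))
    keep2 = retained_variables(fa_dec)
    return CascadeResult(platform_id, table[keep2], pca_model, fa_model,
                         pca_dec, fa_dec)


def combined_fa(tables: Sequence[pd.DataFrame], threshold: float = 0.5,
                gap: float = 0.1, min_cum_var: float = 0.60
                ) -> tuple[ComponentModel, list[RetentionDecision]]:
    """Pooled maximum-likelihood factor analysis over all retained variables."""
    tables = [t for t in tables if t.shape[1] > 0]
    if not tables:
        raise IntegrateError("no variables to pool")
    pooled = pd.concat(tables, axis=1)
    if pooled.columns.duplicated().any():
        raise IntegrateError("duplicate variable ids across platforms")
    Z = standardize(pooled)
    p = Z.shape[1]
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
    n, _ = select_n_components(np.maximum(ev, 0.0), n_variables=p,
                               min_cum_var=min_cum_var)
    n = min(n, p - 1, max(ledermann_bound(p), 1))
    if p < 2 * n:
        raise IntegrateError(f"pooled variables ({p}) < 2 x factors ({n})")
    model = fit_mlfa(Z, n)
    if model.kmo < 0.5:
        log.warning("combined FA: KMO %.2f < 0.5, sampling inadequate", model.kmo)
    decisions = enforce_min_indicators(apply_retention(model, threshold, gap))
    return model, decisions


# ---------------------------------------------------------------------------
# regression factor scores
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FactorScores:
    scores: pd.DataFrame       # samples x factors
    method: str = "regression"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def regression_scores(model: ComponentModel, table: pd.DataFrame
                      ) -> FactorScores:
    """Thurstone regression factor scores: scores = Z S^-1 Lambda."""
    missing = [v for v in model.loadings.index if v not in table.columns]
    if missing:
        raise IntegrateError(f"table lacks model variables: {missing[:5]}")
    Z = standardize(table[list(model.loadings.index)])
    X = Z.to_numpy()
    S = np.corrcoef(X, rowvar=False)
    lam = model.loadings.to_numpy()
    try:
        sol = np.linalg.solve(S, lam)
    except np.linalg.LinAlgError:
        try:
            sol = np.linalg.solve(S + 1e-8 * np.eye(S.shape[0]), lam)
        except np.linalg.LinAlgError as e:
            raise IntegrateError(f"correlation matrix singular beyond ridge: {e}")
    scores = pd.DataFrame(X @ sol, index=table.index,
                          columns=model.loadings.columns)
    return FactorScores(scores=scores)
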