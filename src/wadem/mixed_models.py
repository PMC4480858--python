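"""Gaussian linear mixed models with random intercepts and a low-rank
radial smoother, plus spatial-autocorrelation diagnostics.

The model is

    y = X beta + sum_b Z_b u_b + e,
    u_b ~ N(0, sigma^2 gamma_b I),  e ~ N(0, sigma^2 I),

with one variance ratio ``gamma_b`` per random block (a grouping-factor
random intercept and/or a penalized radial-basis smoother). The likelihood is
profiled over ``beta`` and ``sigma^2`` and maximized over ``log gamma`` with a
bounded quasi-Newton search, so fits are deterministic. The marginal
covariance is never assembled: with q total random-effect columns, all
quantities come from q x q Woodbury algebra, making n ~ 10^3 problems cheap.

ML is the default criterion because models with different fixed effects are
compared by AICc; REML is available for variance-component estimation within
a fixed mean structure.

The smoother is the classical low-rank thin-plate construction: basis entries
``r^2 log r`` to K space-filling knots, post-multiplied by the inverse square
root of the knot-penalty matrix so the coefficients act as an exchangeable
random effect with a single variance component.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .formula import design_matrix

_GAMMA_LOG_BOUNDS = (np.log(1e-10), np.log(1e8))


class FitError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class SmootherSpec:
    """Low-rank thin-plate radial smoother: K distinct knots in meters."""

    knots: np.ndarray  # (K, 2)

    def __post_init__(self):
        knots = np.atleast_2d(np.asarray(self.knots, dtype=float))
        object.__setattr__(self, "knots", knots)
        if knots.shape[0] < 3:
            raise ValueError("need at least 3 knots")
        d = _pairwise_dist(knots, knots)
        if np.any(d[~np.eye(len(knots), dtype=bool)] == 0):
            raise ValueError("duplicate knots")


@dataclasses.dataclass
class LmmSpec:
    """Model specification: response, fixed terms, random structure, criterion."""

    response: str
    fixed_terms: tuple[str, ...] = ()
    random_intercept: str | None = None  # grouping column, e.g. "month", "region"
    smoother: SmootherSpec | None = None
    smoother_coords: tuple[str, str] = ("x_m", "y_m")
    criterion: str = "ML"

    def __post_init__(self):
        self.fixed_terms = tuple(self.fixed_terms)
        if self.criterion not in {"ML", "REML"}:
            raise ValueError("criterion must be 'ML' or 'REML'")


@dataclasses.dataclass
class LmmFit:
    spec: LmmSpec
    coef: pd.Series
    se: pd.Series
    varcomp: dict[str, float]  # sigma^2-scaled variance per block + "residual"
    loglik: float
    n: int
    k_params: int
    fitted: np.ndarray
    residuals: np.ndarray
    blups: dict[str, pd.Series | np.ndarray]
    case_index: pd.Index
    converged: bool = True

    def predict(self, table: pd.DataFrame, include_random: bool = True) -> np.ndarray:
        """Predict for new rows. Random intercept levels unseen in training
        (and the population level for new data) contribute zero; the smoother
        contributes its BLUP surface evaluated at the row coordinates."""
        X, names = design_matrix(table, self.spec.fixed_terms)
        eta = X @ self.coef.reindex(names).to_numpy()
        if include_random:
            if self.spec.random_intercept is not None:
                levels = self.blups.get(self.spec.random_intercept)
                if levels is not None:
                    eta = eta + (
                        table[self.spec.random_intercept]
                        .map(levels)
                        .fillna(0.0)
                        .to_numpy(float)
                    )
            if self.spec.smoother is not None:
                coords = table[list(self.spec.smoother_coords)].to_numpy(float)
                Z = radial_basis(coords, self.spec.smoother.knots)
                eta = eta + Z @ np.asarray(self.blups["smoother"])
        return eta


def _pairwise_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def tps_kernel(r: np.ndarray) -> np.ndarray:
    """Thin-plate radial kernel r^2 log r, continuously 0 at r = 0."""
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


def radial_basis(coords: np.ndarray, knots: np.ndarray, raw: bool = False) -> np.ndarray:
    """Radial-basis design matrix for a low-rank thin-plate smoother.

    ``entry(i, k) = r^2 log r`` with r the distance from point i to knot k.
    Unless ``raw``, columns are post-multiplied by the inverse square root of
    the knot-penalty matrix ``Omega[k, l] = tps(|knot_k - knot_l|)`` so the
    coefficients are exchangeable random effects. Distances are scaled by the
    median inter-knot distance for conditioning; the scaling is part of the
    basis definition and applied identically at fit and prediction time.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    knots = np.atleast_2d(np.asarray(knots, dtype=float))
    dkk = _pairwise_dist(knots, knots)
    off = dkk[~np.eye(len(knots), dtype=bool)]
    if np.any(off == 0):
        raise ValueError("duplicate knots")
    scale = np.median(off) if off.size else 1.0
    C = tps_kernel(_pairwise_dist(coords, knots) / scale)
    if raw:
        return C
    omega = tps_kernel(dkk / scale)
    # symmetric inverse square root via eigendecomposition; Omega is only
    # conditionally positive definite, so eigenvalue magnitudes are used
    w, V = np.linalg.eigh(omega)
    mag = np.maximum(np.abs(w), 1e-10 * np.max(np.abs(w)))
    return C @ (V / np.sqrt(mag)) @ V.T


def select_knots(coords: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Space-filling knot subset via farthest-point traversal.

    The first knot is the point farthest from a seeded random start (the
    start itself is discarded), then points maximizing the minimum distance
    to the chosen set are added greedily; ties break on the lowest index.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    if k > n:
        raise ValueError(f"requested {k} knots from {n} candidate cells")
    rng = np.random.default_rng(seed)
    start = coords[rng.integers(n)]
    d = np.sqrt(((coords - start) ** 2).sum(axis=1))
    chosen = [int(np.argmax(d))]
    mind = np.sqrt(((coords - coords[chosen[0]]) ** 2).sum(axis=1))
    while len(chosen) < k:
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, np.sqrt(((coords - coords[nxt]) ** 2).sum(axis=1)))
    return coords[chosen]


def default_knot_count(n_cells: int) -> int:
    return max(3, min(50, n_cells // 10))


# ---------------------------------------------------------------------------
# Fitting


def _random_blocks(table: pd.DataFrame, spec: LmmSpec):
    """Assemble (name, Z, metadata) for each random block, in spec order."""
    blocks = []
    if spec.random_intercept is not None:
        g = table[spec.random_intercept]
        levels = pd.Index(sorted(g.unique()))
        Z = (g.to_numpy()[:, None] == levels.to_numpy()[None, :]).astype(float)
        blocks.append((spec.random_intercept, Z, levels))
    if spec.smoother is not None:
        coords = table[list(spec.smoother_coords)].to_numpy(float)
        Z = radial_basis(coords, spec.smoother.knots)
        blocks.append(("smoother", Z, None))
    return blocks


def _profiled_criterion(theta, XtX, Xty, yty, ZtX, Zty, ZtZ, n, p, sizes, criterion):
    """Negative profiled log-likelihood at log variance ratios ``theta``.

    Returns (value, beta, sigma2, M_cholesky, sqrt_gamma_per_column).
    """
    gam = np.exp(theta)
    sg = np.concatenate([np.full(q, np.sqrt(g)) for g, q in zip(gam, sizes)]) if sizes else np.zeros(0)
    q = len(sg)
    if q:
        M = np.eye(q) + (sg[:, None] * ZtZ * sg[None, :])
        cf = linalg.cho_factor(M, lower=True)
        logdetV0 = 2.0 * np.sum(np.log(np.diag(cf[0])))
        WtX = sg[:, None] * ZtX
        Wty = sg * Zty
        XtVX = XtX - WtX.T @ linalg.cho_solve(cf, WtX)
        XtVy = Xty - WtX.T @ linalg.cho_solve(cf, Wty)
        ytVy = yty - Wty @ linalg.cho_solve(cf, Wty)
    else:
        cf = None
        logdetV0 = 0.0
        XtVX, XtVy, ytVy = XtX, Xty, yty
    try:
        beta = linalg.solve(XtVX, XtVy, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise FitError("singular generalized-least-squares system") from exc
    rss = float(ytVy - 2 * beta @ XtVy + beta @ XtVX @ beta)
    rss = max(rss, 1e-300)
    if criterion == "ML":
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV0 + n)
    else:
        sigma2 = rss / (n - p)
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + logdetV0 + logdetXtVX + (n - p))
    return -ll, beta, sigma2, cf, sg, XtVX


def fit_lmm(table: pd.DataFrame, spec: LmmSpec) -> LmmFit:
    """Fit a Gaussian LMM by profiled ML or REML.

    Complete cases of the referenced columns are used. Raises
    :class:`FitError` on a singular fixed-effect design (naming the collinear
    columns) or non-convergence.
    """
    used = [spec.response]
    X_full, names = design_matrix(table, spec.fixed_terms)
    if spec.random_intercept is not None:
        used.append(spec.random_intercept)
    if spec.smoother is not None:
        used.extend(spec.smoother_coords)
    finite = np.isfinite(table[spec.response].to_numpy(float)) & np.isfinite(X_full).all(axis=1)
    for col in used[1:]:
        v = table[col]
        finite &= v.notna().to_numpy()
    data = table.loc[finite]
    X = X_full[finite]
    y = data[spec.response].to_numpy(float)
    n, p = X.shape

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the dependent columns via QR pivoting
        _, _, piv = linalg.qr(X, pivoting=True, mode="economic")
        bad = [names[j] for j in piv[rank:]]
        raise FitError(f"singular fixed-effect design; collinear terms: {bad}")

    # internal column scaling (exact reparameterization) keeps the normal
    # equations well-conditioned for raw-scale polynomial terms
    col_scale = np.sqrt((X**2).mean(axis=0))
    col_scale[col_scale == 0] = 1.0
    X = X / col_scale

    blocks = _random_blocks(data, spec)
    sizes = [Z.shape[1] for _, Z, _ in blocks]
    nblocks = len(blocks)
    k_params = p + nblocks + 1
    if n <= k_params + 1:
        raise FitError(f"too few complete cases (n={n}) for {k_params} parameters")

    Z = np.hstack([b[1] for b in blocks]) if blocks else np.zeros((n, 0))
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)
    ZtX, Zty, ZtZ = Z.T @ X, Z.T @ y, Z.T @ Z

    args = (XtX, Xty, yty, ZtX, Zty, ZtZ, n, p, sizes, spec.criterion)

    if nblocks:
        # method-of-moments-flavoured deterministic starts
        starts = [np.full(nblocks, np.log(0.1)), np.full(nblocks, np.log(1.0)),
                  np.full(nblocks, np.log(1e-4))]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                lambda th: _profiled_criterion(th, *args)[0],
                x0,
                method="L-BFGS-B",
                bounds=[_GAMMA_LOG_BOUNDS] * nblocks,
                options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if not best.success and not np.isfinite(best.fun):
            raise FitError(f"variance optimization failed: {best.message}")
        theta = best.x
        converged = bool(best.success)
    else:
        theta = np.zeros(0)
        converged = True

    negll, beta, sigma2, cf, sg, XtVX = _profiled_criterion(theta, *args)
    cov_beta = sigma2 * linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    beta_out = beta / col_scale
    se_out = se / col_scale

    varcomp = {"residual": sigma2}
    gam = np.exp(theta)
    for (name, _, _), g in zip(blocks, gam):
        varcomp[name] = float(g * sigma2)

    # BLUPs: u_hat = gamma_b Z_b' V0^{-1} (y - X beta)
    blups: dict = {}
    fitted = X @ beta
    if sizes:
        Ztr = Zty - ZtX @ beta
        proj = linalg.cho_solve(cf, sg * Ztr)
        u = sg**2 * (Ztr - ZtZ @ (sg * proj))
        offset = 0
        for (name, Zb, levels), qb in zip(blocks, sizes):
            ub = u[offset : offset + qb]
            offset += qb
            fitted = fitted + Zb @ ub
            if levels is not None:
                blups[name] = pd.Series(ub, index=levels)
            else:
                blups[name] = ub
    residuals = y - fitted

    return LmmFit(
        spec=spec,
        coef=pd.Series(beta_out, index=names),
        se=pd.Series(se_out, index=names),
        varcomp=varcomp,
        loglik=-negll,
        n=n,
        k_params=k_params,
        fitted=fitted,
        residuals=residuals,
        blups=blups,
        case_index=data.index,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Moran's I


def moran_i(
    surface: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Moran's I of a 2-D surface under rook adjacency, with permutation p.

    NaN cells are excluded. Weights are row-standardized, so
    ``I = z' W z / z' z`` with z the centered values. The p-value is
    one-sided for positive autocorrelation,
    ``(1 + #{I_perm >= I_obs}) / (n_perm + 1)``, from seeded shuffles.
    """
    surface = np.asarray(surface, dtype=float)
    mask = np.isfinite(surface)
    n = int(mask.sum())
    if n < 10:
        raise ValueError("need >= 10 non-missing cells")
    vals = surface[mask]
    if np.ptp(vals) == 0:
        raise ValueError("Moran's I undefined for constant residuals")
    idx = -np.ones(surface.shape, dtype=int)
    idx[mask] = np.arange(n)
    pairs_i, pairs_j = [], []
    for dr, dc in ((0, 1), (1, 0)):
        a = idx[: surface.shape[0] - dr, : surface.shape[1] - dc]
        b = idx[dr:, dc:]
        ok = (a >= 0) & (b >= 0)
        pairs_i.extend(a[ok]); pairs_j.extend(b[ok])
        pairs_i.extend(b[ok]); pairs_j.extend(a[ok])
    pairs_i = np.asarray(pairs_i); pairs_j = np.asarray(pairs_j)
    deg = np.bincount(pairs_i, minlength=n).astype(float)
    w = 1.0 / deg[pairs_i]  # row-standardized

    def stat(z):
        z = z - z.mean()
        return float(np.sum(w * z[pairs_i] * z[pairs_j]) / np.sum(z * z))

    i_obs = stat(vals)
    rng = np.random.default_rng(seed)
    count = 0
    z = vals.copy()
    for _ in range(n_perm):
        rng.shuffle(z)
        if stat(z) >= i_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return i_obs, p
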