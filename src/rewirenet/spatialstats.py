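"""Additive-model decomposition of rewiring potential.

Per trophic level, rewiring potential is regressed on a penalized-spline
smooth of species richness (cubic B-splines, basis size k = 10,
second-order difference penalty) plus a bivariate spatial smooth of the
cell centroid coordinates (low-rank Gaussian radial basis around 30
k-means knots, ridge penalty, with unpenalized linear lon/lat terms in
its null space).  Gaussian family, identity link; smoothing parameters
chosen by generalized cross-validation on a two-dimensional log grid.

The fit decomposes exactly as ``fitted = intercept + f(richness) +
f(lon, lat)`` with both smooths centered over the training cells, so the
richness partial effect is directly the object that exhibits (or fails
to exhibit) saturation of potential with richness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from sklearn.cluster import KMeans

from .dataio import LEVELS

DEFAULT_LAMBDA_GRID = np.logspace(-6, 12, 13)


class FitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# bases
# ---------------------------------------------------------------------------

@dataclass
class _RichnessBasis:
    """Cubic B-spline basis with sum-to-zero constraint absorbed."""

    knots: np.ndarray
    z: np.ndarray  # k x (k-1) constraint-null-space reparameterisation
    xmin: float
    xmax: float
    k: int

    @classmethod
    def build(cls, x: np.ndarray, k: int) -> "_RichnessBasis":
        xmin, xmax = float(x.min()), float(x.max())
        n_interior = k - 4  # cubic: basis dim = interior + degree + 1
        # interior knots at quantiles so resolution follows the data
        interior = np.quantile(np.unique(x), np.linspace(0, 1, n_interior + 2)[1:-1])
        knots = np.r_[[xmin] * 4, interior, [xmax] * 4]
        raw = BSpline.design_matrix(x, knots, 3).toarray()
        c = raw.mean(axis=0)  # sum-to-zero constraint over training cells
        z = null_space(c[None, :])
        return cls(knots, z, xmin, xmax, k)

    def design(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self.xmin, self.xmax)
        return BSpline.design_matrix(xc, self.knots, 3).toarray() @ self.z

    def penalty(self) -> np.ndarray:
        """Integrated squared second derivative, S_ij = int b_i'' b_j'' dx.

        Exact via 3-point Gauss-Legendre per knot interval (the integrand
        is piecewise quadratic for cubic splines); the null space is the
        linear functions, so an infinitely smoothed fit is a straight line.
        """
        breaks = np.unique(self.knots)
        nodes, weights = np.polynomial.legendre.leggauss(3)
        xs, ws = [], []
        for a, b in zip(breaks[:-1], breaks[1:]):
            xs.append((b - a) / 2 * nodes + (a + b) / 2)
            ws.append((b - a) / 2 * weights)
        xs, ws = np.concatenate(xs), np.concatenate(ws)
        d2 = np.column_stack(
            [
                BSpline(self.knots, np.eye(self.k)[i], 3).derivative(2)(xs)
                for i in range(self.k)
            ]
        )
        s = (d2 * ws[:, None]).T @ d2
        return self.z.T @ s @ self.z


@dataclass
class _SpatialBasis:
    """Linear terms + Gaussian radial basis at k-means knots, centered."""

    knots: np.ndarray  # n_knots x 2
    lengthscale: float
    col_means: np.ndarray | None = None

    @classmethod
    def build(cls, coords: np.ndarray, n_knots: int) -> "_SpatialBasis":
        n_knots = min(n_knots, np.unique(coords, axis=0).shape[0])
        km = KMeans(n_clusters=n_knots, n_init=10, random_state=0).fit(coords)
        knots = km.cluster_centers_
        d = np.sqrt(((knots[:, None, :] - knots[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        # kernel width tied to knot spacing so the basis resolves structure
        # down to the knot grid; the ridge penalty handles oversmoothing
        ls = 1.5 * float(np.median(nn[np.isfinite(nn)])) if np.isfinite(nn).any() else 1.0
        basis = cls(knots, float(ls))
        basis.col_means = basis._raw(coords).mean(axis=0)
        return basis

    def _raw(self, coords: np.ndarray) -> np.ndarray:
        d2 = ((coords[:, None, :] - self.knots[None, :, :]) ** 2).sum(-1)
        rad = np.exp(-d2 / (2.0 * self.lengthscale**2))
        return np.column_stack([coords, rad])

    def design(self, coords: np.ndarray) -> np.ndarray:
        return self._raw(coords) - self.col_means

    def penalty(self) -> np.ndarray:
        p = self.knots.shape[0] + 2
        s = np.eye(p)
        s[0, 0] = s[1, 1] = 0.0  # linear null space unpenalized
        return s


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

@dataclass
class GamFit:
    level: str
    coef: np.ndarray
    blocks: dict  # name -> slice into coef
    basis_richness: _RichnessBasis | None
    basis_spatial: _SpatialBasis | None
    lambdas: dict
    edf: dict
    edf_total: float
    deviance_explained: float
    sigma2: float
    cov: np.ndarray
    intercept: float
    fitted: np.ndarray
    f_richness: np.ndarray
    f_spatial: np.ndarray
    richness: np.ndarray
    p_values: dict
    degenerate: bool
    n_dropped_na: int

    def summary(self) -> dict:
        return {
            "trophic_level": self.level,
            "deviance_explained": self.deviance_explained,
            "edf": dict(self.edf),
            "lambdas": dict(self.lambdas),
            "p_values": dict(self.p_values),
            "degenerate": self.degenerate,
            "n_dropped_na": self.n_dropped_na,
        }


def _solve(xtx, xty, s_list, lambdas):
    pen = sum(l * s for l, s in zip(lambdas, s_list))
    a = np.linalg.inv(xtx + pen)
    return a, a @ xty


def fit_gam(
    map_df: pd.DataFrame,
    level: str,
    response: str = "potential",
    k: int = 10,
    n_spatial_knots: int = 30,
    spatial: bool = True,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
) -> GamFit:
    """Fit the potential ~ s(richness) + s(lon, lat) additive model.

    ``map_df`` is the per-cell table from :func:`rewirenet.rewiring.potential_map`
    (or any frame with ``trophic_level, richness, lon_min, lat_min`` and the
    response column).  NA-response cells are dropped with their count
    recorded.  A constant response returns a degenerate fit with deviance
    explained 0 and a flat richness effect.
    """
    if level not in LEVELS:
        raise FitError(f"unknown trophic level {level!r}")
    sub = map_df[map_df.trophic_level == level] if "trophic_level" in map_df.columns else map_df
    n_na = int(sub[response].isna().sum())
    sub = sub.dropna(subset=[response])
    if len(sub) < 50:
        raise FitError(f"need >= 50 non-NA cells, got {len(sub)}")
    y = sub[response].to_numpy(dtype=float)
    r = sub["richness"].to_numpy(dtype=float)
    if r.var() == 0:
        raise FitError("richness has zero variance")
    coords = sub[["lon_min", "lat_min"]].to_numpy(dtype=float)
    n = len(y)

    rich_basis = _RichnessBasis.build(r, k)
    br = rich_basis.design(r)
    cols = [np.ones((n, 1)), br]
    blocks = {"intercept": slice(0, 1), "richness": slice(1, 1 + br.shape[1])}
    s_list = []
    p_total = 1 + br.shape[1]
    s_rich = np.zeros((p_total, p_total))
    sp_basis = None
    if spatial:
        sp_basis = _SpatialBasis.build(coords, n_spatial_knots)
        bs = sp_basis.design(coords)
        blocks["spatial"] = slice(p_total, p_total + bs.shape[1])
        cols.append(bs)
        p_total += bs.shape[1]
    x = np.column_stack(cols)

    def _embed(block: str, s: np.ndarray) -> np.ndarray:
        full = np.zeros((p_total, p_total))
        sl = blocks[block]
        full[sl, sl] = s
        return full

    s_list = [_embed("richness", rich_basis.penalty())]
    if spatial:
        s_list.append(_embed("spatial", sp_basis.penalty()))

    xtx, xty = x.T @ x, x.T @ y
    grids = [lambda_grid] * len(s_list)
    trials = []
    for lams in np.stack(np.meshgrid(*grids, indexing="ij"), -1).reshape(-1, len(s_list)):
        a, beta = _solve(xtx, xty, s_list, lams)
        fitted = x @ beta
        rss = float(((y - fitted) ** 2).sum())
        tr_h = float(np.trace(a @ xtx))
        gcv = n * rss / max(n - tr_h, 1e-8) ** 2
        trials.append((gcv, tr_h, lams, a, beta))
    # GCV can tie across the grid (e.g. a noiseless response representable
    # in every penalty's null space); take the smoothest fit within a
    # relative tolerance of the minimum
    gmin = min(t[0] for t in trials)
    tol = gmin * (1 + 1e-6) + 1e-12
    _, _, lams, a, beta = min((t for t in trials if t[0] <= tol), key=lambda t: t[1])

    fitted = x @ beta
    rss = float(((y - fitted) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = tss <= 1e-12 * max(float((y**2).sum()), 1.0)
    dev_expl = 0.0 if degenerate else max(1.0 - rss / tss, 0.0)
    f_mat = a @ xtx  # maps unpenalized df onto effective df per coefficient
    edf_diag = np.diag(f_mat)
    edf = {name: float(edf_diag[sl].sum()) for name, sl in blocks.items() if name != "intercept"}
    edf_total = float(np.trace(f_mat))
    sigma2 = rss / max(n - edf_total, 1.0)
    cov = sigma2 * (a @ xtx @ a)

    f_rich = x[:, blocks["richness"]] @ beta[blocks["richness"]]
    f_spat = (
        x[:, blocks["spatial"]] @ beta[blocks["spatial"]] if spatial else np.zeros(n)
    )
    p_values = {}
    for name in ("richness", "spatial") if spatial else ("richness",):
        sl = blocks[name]
        b = beta[sl]
        v = cov[sl, sl]
        try:
            w = float(b @ np.linalg.pinv(v) @ b)
            df = max(edf[name], 1.0)
            p_values[name] = float(stats.chi2.sf(w, df))
        except np.linalg.LinAlgError:
            p_values[name] = float("nan")

    lam = {"richness": float(lams[0])}
    if spatial:
        lam["spatial"] = float(lams[1])
    return GamFit(
        level=level, coef=beta, blocks=blocks, basis_richness=rich_basis,
        basis_spatial=sp_basis, lambdas=lam, edf=edf, edf_total=edf_total,
        deviance_explained=dev_expl, sigma2=sigma2, cov=cov,
        intercept=float(beta[0]), fitted=fitted, f_richness=f_rich,
        f_spatial=f_spat, richness=r, p_values=p_values,
        degenerate=degenerate, n_dropped_na=n_na,
    )


def partial_effect(fit: GamFit, richness_grid: np.ndarray) -> pd.DataFrame:
    """Centered partial effect of richness with pointwise standard errors.

    Points outside the training richness range are evaluated at the
    clamped boundary and flagged ``extrapolated``.
    """
    grid = np.asarray(richness_grid, dtype=float)
    b = fit.basis_richness.design(grid)
    sl = fit.blocks["richness"]
    effect = b @ fit.coef[sl]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", b, fit.cov[sl, sl], b), 0.0))
    extrap = (grid < fit.basis_richness.xmin) | (grid > fit.basis_richness.xmax)
    return pd.DataFrame({"richness": grid, "effect": effect, "se": se, "extrapolated": extrap})


def saturation_richness(fit: GamFit, n_grid: int = 400, frac: float = 0.05) -> float:
    """Richness at which potential saturates.

    Returns the first grid point where the mean potential curve
    (intercept + richness partial effect over the training range) comes
    within ``frac`` of its plateau, measured relative to the curve's
    total rise: ``curve >= max - frac * (max - min)``.
    """
    grid = np.linspace(fit.basis_richness.xmin, fit.basis_richness.xmax, n_grid)
    curve = fit.intercept + partial_effect(fit, grid)["effect"].to_numpy()
    target = curve.max() - frac * (curve.max() - curve.min())
    idx = np.argmax(curve >= target)
    return float(grid[idx])
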