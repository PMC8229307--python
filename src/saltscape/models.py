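"""Nested covariate models by OLS and geographically weighted regression.

Three nested specifications per intake outcome (na_k_ratio, na_intake,
k_intake), all adjusted for total energy intake and survey year:

* model 1 — neighborhood food-environment densities (supermarket, grocery,
  convenience);
* model 2 — individual socio-demographics (age, sex, civil status,
  occupation, education, nationality) plus zone median household income;
* model 3 — union of models 1 and 2.

GWR fits a weighted least-squares regression at every observation location
with a fixed Gaussian kernel ``exp(-0.5 (d/b)^2)``; the bandwidth ``b`` is
chosen by golden-section search on the corrected Akaike criterion

    AICc = 2 n ln(sigma_hat) + n ln(2 pi) + n (n + tr(S)) / (n - 2 - tr(S))

where ``S`` is the hat matrix mapping y to fitted values and
``sigma_hat^2 = RSS / n``. For OLS we report
``AICc = AIC + 2 k (k + 1) / (n - k - 1)`` with the Gaussian log-likelihood
and ``k`` = number of design columns (intercept included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .autocorr import MoranResult, global_moran
from .weights import SpatialWeights

__all__ = [
    "ModelSpec",
    "OlsFit",
    "GwrFit",
    "build_design",
    "fit_ols",
    "gwr_kernel",
    "fit_gwr",
    "optimize_bandwidth",
    "residual_autocorrelation",
]

OUTCOMES = ("na_k_ratio", "na_intake", "k_intake")

FOOD_ENV_COLUMNS = ["supermarket", "grocery", "convenience"]

# dummy codes against documented reference levels:
# male; not married/cohabiting; low occupation; primary education; non-Swiss
SOCIO_DEMO_COLUMNS = [
    "age",
    "sex_female",
    "civil_married_cohabiting",
    "occupation_medium",
    "occupation_high",
    "occupation_not_working",
    "education_secondary",
    "education_tertiary",
    "nationality_swiss",
    "zone_income",
]

ADJUSTMENT_COLUMNS = ["energy", "year"]


@dataclass
class ModelSpec:
    outcome: str
    model_id: int

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")

    @property
    def covariates(self) -> list:
        cols = []
        if self.model_id in (1, 3):
            cols += FOOD_ENV_COLUMNS
        if self.model_id in (2, 3):
            cols += SOCIO_DEMO_COLUMNS
        return cols + ADJUSTMENT_COLUMNS

    @property
    def tag(self) -> str:
        return f"{self.outcome}_model{self.model_id}"


@dataclass
class OlsFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    residuals: np.ndarray = field(repr=False)
    aicc: float
    n: int
    k: int
    rss: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.values,
                "se": self.bse.values,
                "t": self.tvalues.values,
                "aicc": self.aicc,
            }
        )


@dataclass
class GwrFit:
    bandwidth: float
    params: pd.DataFrame = field(repr=False)  # n x k local coefficients
    tvalues: pd.DataFrame = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    trace_S: float
    effective_params: float
    aicc: float
    n: int
    k: int
    rss: float

    def surfaces_frame(self, ids, coords) -> pd.DataFrame:
        coords = np.asarray(coords, dtype=float)
        frames = []
        for term in self.params.columns:
            frames.append(
                pd.DataFrame(
                    {
                        "id": ids,
                        "x": coords[:, 0],
                        "y": coords[:, 1],
                        "term": term,
                        "estimate": self.params[term].values,
                        "t": self.tvalues[term].values,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def build_design(
    participants: pd.DataFrame,
    densities: pd.DataFrame | None,
    income: pd.Series | None,
    spec: ModelSpec,
):
    """Assemble (y, X) for one model specification.

    Categorical covariates are dummy-coded against the reference levels
    documented in :data:`SOCIO_DEMO_COLUMNS`; an intercept column leads and
    the column order is fixed by the spec's covariate list.
    """
    df = participants.reset_index(drop=True)
    y = df[spec.outcome].to_numpy(dtype=float)

    cols = {"intercept": np.ones(len(df))}
    needed = spec.covariates
    if any(c in FOOD_ENV_COLUMNS for c in needed):
        if densities is None:
            raise ValueError("missing covariate source: densities")
        dens = densities.loc[df["id"].values]
        for c in FOOD_ENV_COLUMNS:
            if c not in dens.columns:
                raise ValueError(f"missing covariate: {c}")
            cols[c] = dens[c].to_numpy(dtype=float)
    if any(c in SOCIO_DEMO_COLUMNS for c in needed):
        cols["age"] = df["age"].to_numpy(dtype=float)
        cols["sex_female"] = (df["sex"] == "female").to_numpy(dtype=float)
        cols["civil_married_cohabiting"] = (
            df["civil_status"] == "married_cohabiting"
        ).to_numpy(dtype=float)
        for lvl in ("medium", "high", "not_working"):
            cols[f"occupation_{lvl}"] = (df["occupation"] == lvl).to_numpy(float)
        for lvl in ("secondary", "tertiary"):
            cols[f"education_{lvl}"] = (df["education"] == lvl).to_numpy(float)
        cols["nationality_swiss"] = (df["nationality"] == "swiss").to_numpy(float)
        if income is None:
            raise ValueError("missing covariate source: zone_income")
        cols["zone_income"] = np.asarray(
            income.loc[df["id"].values], dtype=float
        )
    for c in ADJUSTMENT_COLUMNS:
        if c not in df.columns:
            raise ValueError(f"missing covariate: {c}")
        cols[c] = df[c].to_numpy(dtype=float)

    order = ["intercept"] + needed
    X = pd.DataFrame({c: cols[c] for c in order})
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in covariates: {bad}")
    return y, X


def fit_ols(y: np.ndarray, X: pd.DataFrame) -> OlsFit:
    """Ordinary least squares with classical standard errors and AICc."""
    import statsmodels.api as sm

    Xv = np.asarray(X, dtype=float)
    n, k = Xv.shape
    rank = np.linalg.matrix_rank(Xv)
    if rank < k:
        # flag columns whose removal restores full rank
        names = list(X.columns) if hasattr(X, "columns") else list(range(k))
        suspects = [
            names[j]
            for j in range(k)
            if np.linalg.matrix_rank(np.delete(Xv, j, axis=1)) == rank
        ]
        raise np.linalg.LinAlgError(
            f"design matrix rank deficient (rank {rank} < {k} columns); "
            f"collinear candidates: {suspects}"
        )
    res = sm.OLS(y, Xv).fit()
    aicc = res.aic + 2 * k * (k + 1) / (n - k - 1)
    names = list(X.columns) if hasattr(X, "columns") else list(range(k))
    return OlsFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        residuals=np.asarray(res.resid),
        aicc=float(aicc),
        n=n,
        k=k,
        rss=float(res.ssr),
    )


def gwr_kernel(d, bandwidth: float):
    """Fixed Gaussian distance kernel ``exp(-0.5 (d/bandwidth)^2)``."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distance must be non-negative")
    w = np.exp(-0.5 * (d_arr / bandwidth) ** 2)
    return float(w) if np.isscalar(d) else w


def _pairwise_dist(coords: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import cdist

    return cdist(coords, coords)


def _gwr_core(y, Xv, D, bandwidth, want_inference):
    """Local WLS at every location; returns fit pieces.

    With ``want_inference`` False only residuals and tr(S) are computed,
    which is all the AICc bandwidth search needs.
    """
    n, k = Xv.shape
    W = gwr_kernel(D, bandwidth)
    fitted = np.empty(n)
    trace_S = 0.0
    betas = np.empty((n, k)) if want_inference else None
    ses = np.empty((n, k)) if want_inference else None
    for i in range(n):
        w = W[i]
        Xw = Xv * w[:, None]
        XtWX = Xw.T @ Xv
        XtWy = Xw.T @ y
        try:
            C = np.linalg.solve(XtWX, Xw.T)  # k x n, maps y -> beta_i
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular local design at observation {i} "
                f"(bandwidth {bandwidth:.1f} m too small)"
            ) from err
        beta_i = C @ y
        fitted[i] = Xv[i] @ beta_i
        trace_S += float(Xv[i] @ C[:, i])
        if want_inference:
            betas[i] = beta_i
            ses[i] = np.sqrt(np.sum(C * C, axis=1))  # sqrt(diag(C C^T))
    resid = y - fitted
    rss = float(resid @ resid)
    return betas, ses, resid, rss, trace_S


def _gwr_aicc(n, rss, trace_S):
    sigma = np.sqrt(rss / n)
    denom = n - 2.0 - trace_S
    if denom <= 0:
        return np.inf
    return 2 * n * np.log(sigma) + n * np.log(2 * np.pi) + n * (n + trace_S) / denom


def fit_gwr(
    y: np.ndarray,
    X: pd.DataFrame,
    coords: np.ndarray,
    bandwidth: float,
    dist_matrix: np.ndarray | None = None,
) -> GwrFit:
    """Geographically weighted regression at a fixed Gaussian bandwidth.

    Local t-values use the weighted variance estimator
    ``var(beta_i) = sigma_hat^2 diag(C_i C_i^T)`` with the global
    ``sigma_hat^2 = RSS / (n - tr(S))``, reported unadjusted for dependent
    hypotheses.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n, k = Xv.shape
    D = dist_matrix if dist_matrix is not None else _pairwise_dist(coords)

    betas, se_unit, resid, rss, trace_S = _gwr_core(y, Xv, D, bandwidth, True)
    sigma2 = rss / max(n - trace_S, 1e-12)
    se = np.sqrt(sigma2) * se_unit
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = betas / se

    names = list(X.columns) if hasattr(X, "columns") else list(range(k))
    return GwrFit(
        bandwidth=float(bandwidth),
        params=pd.DataFrame(betas, columns=names),
        tvalues=pd.DataFrame(tvals, columns=names),
        residuals=resid,
        trace_S=float(trace_S),
        effective_params=float(trace_S),
        aicc=float(_gwr_aicc(n, rss, trace_S)),
        n=n,
        k=k,
        rss=rss,
    )


_GOLDEN = (np.sqrt(5) - 1) / 2


def optimize_bandwidth(
    y: np.ndarray,
    X: pd.DataFrame,
    coords: np.ndarray,
    search_range: tuple | None = None,
    tol: float = 1.0,
    dist_matrix: np.ndarray | None = None,
):
    """Golden-section search for the AICc-minimizing GWR bandwidth.

    Default search range is [2 x mean nearest-neighbor distance, region
    diagonal], which keeps the smallest candidate bandwidths nonsingular.
    Returns ``(bandwidth, trace)`` where trace is the list of
    ``(bandwidth, AICc)`` evaluations; if the evaluations are detectably
    non-unimodal a warning is recorded and the global minimum over all
    evaluations is returned.
    """
    coords = np.asarray(coords, dtype=float)
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    D = dist_matrix if dist_matrix is not None else _pairwise_dist(coords)

    if search_range is None:
        D_off = D + np.diag(np.full(len(D), np.inf))
        mean_nn = float(np.mean(D_off.min(axis=1)))
        lo = 2.0 * mean_nn
        hi = float(
            np.hypot(np.ptp(coords[:, 0]), np.ptp(coords[:, 1]))
        )
    else:
        lo, hi = search_range
    if not (0 < lo < hi):
        raise ValueError("search range must be positive and ordered")

    cache = {}

    def f(b):
        if b not in cache:
            _, _, _, rss, trS = _gwr_core(y, Xv, D, b, False)
            cache[b] = _gwr_aicc(len(y), rss, trS)
        return cache[b]

    a, d = lo, hi
    b = d - _GOLDEN * (d - a)
    c = a + _GOLDEN * (d - a)
    fb, fc = f(b), f(c)
    while d - a > tol:
        if fb <= fc:
            d, c, fc = c, b, fb
            b = d - _GOLDEN * (d - a)
            fb = f(b)
        else:
            a, b, fb = b, c, fc
            c = a + _GOLDEN * (d - a)
            fc = f(c)

    trace = sorted(cache.items())
    best = min(cache, key=cache.get)
    aiccs = [v for _, v in trace]
    diffs = np.sign(np.diff(aiccs))
    # rises-then-falls anywhere after a fall signals non-unimodality
    nz = diffs[diffs != 0]
    if np.any((nz[:-1] > 0) & (nz[1:] < 0)):
        warnings.warn(
            "AICc trace not unimodal over evaluated bandwidths; "
            "returning global minimum over evaluations",
            stacklevel=2,
        )
    return float(best), trace


def residual_autocorrelation(
    fit, weights: SpatialWeights, n_perm: int = 999, seed: int = 0
) -> MoranResult:
    """Global Moran's I of a model's residuals at the outcome's band."""
    return global_moran(fit.residuals, weights, n_perm=n_perm, seed=seed)
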