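"""Global and Local Moran's I with Monte-Carlo permutation inference.

Implemented from the definitions (not delegated to a spatial-statistics
package):

* Global Moran's I
  ``I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2``
  with one-sided pseudo p-values from value permutations.
* Scale selection over incremental distance bands: the band whose
  statistically significant permutation z-score is largest.
* Local Moran's I ``I_i = z_i * sum_j w_ij z_j`` where ``z`` is standardized
  with the population (divide-by-n) standard deviation, so that
  ``sum_i I_i * S0 / n`` (row-standardized: mean of I_i) recovers the global
  statistic. Inference is by conditional permutation: observation i is held
  fixed and the remaining n-1 values are permuted over its neighbor slots.
  Cluster classes follow the Moran-scatterplot quadrants: HH, LH, LL, HL,
  with non-significant observations (and islands) labeled not_significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

from .weights import SpatialWeights, distance_band_weights

__all__ = [
    "MoranResult",
    "ScaleProfile",
    "LisaResult",
    "global_moran",
    "scale_selection",
    "local_moran",
    "lisa_on_residuals",
    "write_lisa_csv",
    "write_lisa_geojson",
]

#: Integer map-legend coding for cluster classes.
CLASS_CODES = {"not_significant": 0, "HH": 1, "LH": 2, "LL": 3, "HL": 4}


@dataclass
class MoranResult:
    I: float
    expected_I: float
    z_score: float
    pseudo_p: float
    n_permutations: int
    seed: int
    threshold: float
    perm_mean: float = field(repr=False, default=np.nan)
    perm_sd: float = field(repr=False, default=np.nan)

    @property
    def significant(self) -> bool:
        return self.pseudo_p < 0.05


@dataclass
class ScaleProfile:
    bands: list
    results: dict  # band -> MoranResult
    selected_band: float
    selection_rule_applied: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "band_m": b,
                "I": r.I,
                "z_score": r.z_score,
                "pseudo_p": r.pseudo_p,
                "selected": b == self.selected_band,
            }
            for b, r in self.results.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class LisaResult:
    local_I: np.ndarray
    quadrant: np.ndarray  # strings HH/LH/LL/HL for every obs (islands too)
    pseudo_p: np.ndarray
    classes: np.ndarray  # quadrant if significant else not_significant
    alpha: float
    n_permutations: int
    seed: int
    model_tag: str = ""

    @property
    def n(self) -> int:
        return len(self.local_I)

    def class_counts(self) -> pd.Series:
        return pd.Series(self.classes).value_counts()

    def members(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.classes == cls)


def _moran_stat(z: np.ndarray, w: SpatialWeights) -> float:
    # z must be mean-centered; works for raw deviations or standardized values
    lag = w.lag(z)
    return float(len(z) / w.s0 * (z @ lag) / (z @ z))


def global_moran(
    values: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with a Monte-Carlo permutation test.

    The pseudo p-value counts permuted statistics whose deviation from the
    permutation mean is at least as large in magnitude as the observed one,
    with the standard +1 correction:
    ``p = (exceedances + 1) / (n_perm + 1)``. Counting |deviations| keeps
    the null distribution of p super-uniform (P(p <= t) <= t + 1/(R+1))
    while still responding to departures in either direction.
    """
    x = np.asarray(values, dtype=float)
    if len(x) != weights.n:
        raise ValueError(f"values length {len(x)} != weights.n {weights.n}")
    if np.ptp(x) == 0:
        raise ValueError("constant values: Moran's I undefined")

    z = x - x.mean()
    n = len(x)
    I_obs = _moran_stat(z, weights)
    e_I = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    sims = np.empty(n_perm)
    for k in range(n_perm):
        sims[k] = _moran_stat(rng.permutation(z), weights)

    perm_mean = sims.mean()
    perm_sd = sims.std(ddof=0)
    z_score = (I_obs - perm_mean) / perm_sd if perm_sd > 0 else np.nan
    exceed = int(np.sum(np.abs(sims - perm_mean) >= abs(I_obs - perm_mean)))
    pseudo_p = (exceed + 1) / (n_perm + 1)

    return MoranResult(
        I=I_obs,
        expected_I=e_I,
        z_score=float(z_score),
        pseudo_p=float(pseudo_p),
        n_permutations=n_perm,
        seed=seed,
        threshold=weights.threshold,
        perm_mean=float(perm_mean),
        perm_sd=float(perm_sd),
    )


DEFAULT_BANDS = (200.0, 400.0, 600.0, 800.0, 1000.0)


def scale_selection(
    values: np.ndarray,
    coords: np.ndarray,
    bands=DEFAULT_BANDS,
    alpha: float = 0.05,
    fallback_band: float | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> ScaleProfile:
    """Pick the spatial scale where the significant Moran z-score peaks.

    Global Moran's I is evaluated at each incremental distance band; the
    selected band maximizes the permutation z-score among bands significant
    at ``alpha``. If no band is significant the ``fallback_band`` is used
    (defaulting to the largest evaluated band) and the applied rule recorded.
    """
    bands = list(bands)
    if len(bands) < 2:
        raise ValueError("need at least 2 bands")
    results = {}
    for b in bands:
        w = distance_band_weights(coords, b, standardize=True)
        results[b] = global_moran(values, w, n_perm=n_perm, seed=seed)

    sig = [b for b in bands if results[b].pseudo_p < alpha]
    if sig:
        selected = max(sig, key=lambda b: results[b].z_score)
        rule = f"max significant z-score at alpha={alpha}"
    else:
        selected = fallback_band if fallback_band is not None else bands[-1]
        rule = f"no band significant at alpha={alpha}; fallback to {selected} m"
    return ScaleProfile(
        bands=bands, results=results, selected_band=selected,
        selection_rule_applied=rule,
    )


def local_moran(
    values: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    fdr: bool = False,
    model_tag: str = "",
) -> LisaResult:
    """Univariate Local Moran's I with conditional permutation inference.

    For each observation i the remaining n-1 standardized values are permuted
    and the first k_i of each permutation fill i's neighbor slots; the pseudo
    p counts conditional-permutation statistics deviating from their mean by
    at least the observed deviation in magnitude. Quadrants use the signs of
    z_i and its spatial lag, with >= 0 counted as "high". No multiplicity
    correction is applied by default; ``fdr=True`` switches the significance
    cut to a Benjamini-Hochberg threshold.
    """
    x = np.asarray(values, dtype=float)
    n = weights.n
    if len(x) != n:
        raise ValueError(f"values length {len(x)} != weights.n {weights.n}")
    if np.ptp(x) == 0:
        raise ValueError("constant values: local Moran undefined")

    z = (x - x.mean()) / x.std(ddof=0)
    lag = weights.lag(z)
    local_I = z * lag

    quadrant = np.where(
        z >= 0,
        np.where(lag >= 0, "HH", "HL"),
        np.where(lag >= 0, "LH", "LL"),
    ).astype(object)

    rng = np.random.default_rng(seed)
    cards = weights.cardinalities()
    kmax = int(cards.max()) if n else 0
    # one shared bank of permutations of size kmax, indexed per-observation
    # into its own "others" array (standard conditional-permutation scheme)
    perm_bank = np.empty((n_perm, kmax), dtype=int)
    for r in range(n_perm):
        perm_bank[r] = rng.permutation(n - 1)[:kmax]

    pseudo_p = np.ones(n)
    idx_all = np.arange(n)
    for i in range(n):
        k = cards[i]
        if k == 0:
            continue  # island: not significant by definition
        others = z[idx_all != i]
        draws = others[perm_bank[:, :k]]  # (n_perm, k)
        lag_sims = draws @ weights.weights[i]
        sims = z[i] * lag_sims
        mean_sim = sims.mean()
        exceed = int(
            np.sum(np.abs(sims - mean_sim) >= abs(local_I[i] - mean_sim))
        )
        pseudo_p[i] = (exceed + 1) / (n_perm + 1)

    cut = np.full(n, alpha)
    if fdr:
        order = np.argsort(pseudo_p)
        m = n
        bh = np.zeros(n)
        thresh = 0.0
        for rank, idx in enumerate(order, start=1):
            if pseudo_p[idx] <= alpha * rank / m:
                thresh = pseudo_p[idx]
        cut = np.full(n, thresh if thresh > 0 else 0.0)
        cut = np.nextafter(cut, np.inf)  # p <= thresh significant

    significant = pseudo_p < cut
    significant[cards == 0] = False
    classes = np.where(significant, quadrant, "not_significant").astype(object)

    return LisaResult(
        local_I=local_I,
        quadrant=quadrant.astype(str),
        pseudo_p=pseudo_p,
        classes=classes.astype(str),
        alpha=alpha,
        n_permutations=n_perm,
        seed=seed,
        model_tag=model_tag,
    )


def lisa_on_residuals(
    model_residuals: np.ndarray,
    weights: SpatialWeights,
    model_tag: str = "",
    **kwargs,
) -> LisaResult:
    """Local Moran's I on regression residuals, tagged with the model name."""
    res = np.asarray(model_residuals, dtype=float)
    if len(res) != weights.n:
        raise ValueError(
            f"residual length {len(res)} != weights.n {weights.n}"
        )
    return local_moran(res, weights, model_tag=model_tag, **kwargs)


def write_lisa_csv(lisa: LisaResult, ids, path) -> None:
    pd.DataFrame(
        {
            "id": ids,
            "local_I": lisa.local_I,
            "p": lisa.pseudo_p,
            "class": lisa.classes,
        }
    ).to_csv(path, index=False)


def write_lisa_geojson(lisa: LisaResult, ids, coords, path) -> None:
    """GeoJSON points with integer class codes 1=HH 2=LH 3=LL 4=HL 0=n.s."""
    coords = np.asarray(coords, dtype=float)
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(xy[0]), float(xy[1])]},
            "properties": {
                "id": str(i),
                "local_I": float(li),
                "p": float(p),
                "class": CLASS_CODES[c],
            },
        }
        for i, xy, li, p, c in zip(
            ids, coords, lisa.local_I, lisa.pseudo_p, lisa.classes
        )
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
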