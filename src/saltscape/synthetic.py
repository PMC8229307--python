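"""Synthetic georeferenced cohort generator.

Emulates the data structure of an urban population-based nutrition survey:
an urban core with dense streets and food outlets inside a rural periphery,
participants placed with higher density in the core, socio-demographic
composition that drifts along the urban-rural axis, and intake outcomes
built as

    outcome = baseline + covariate effects + latent spatial field + noise.

The latent field is a zero-mean Gaussian process with a J-Bessel
(hole-effect) correlation,

    corr(d) = J0(1.8412 * d / correlation_range),

the classical "wave" covariance of a 2-D random field whose spectral mass
sits on a ring of wavenumbers. The range is parametrized as the
*detectability peak* of an incremental-distance-band Moran analysis: for a
band of radius d the idealized z-score profile is proportional to
``(1/d) * int_0^d u corr(u) du = J1(kappa d) / (kappa d) * d`` up to
constants, i.e. to ``J1(kappa d)``, which attains its maximum where
``kappa d = 1.8412`` (the first maximum of J1). Setting
``kappa = 1.8412 / correlation_range`` therefore makes a surface with range
800 m one whose spatial clustering is *strongest*, not merely present, at
the 800 m band. Correlation at the range itself is J0(1.8412) = 0.315; the
first zero crossing sits at 1.306x the range, beyond which the hole-effect
kernel turns weakly negative (alternating patches).

All randomness flows from ``RegionSpec.seed`` through per-stage child seeds,
so identical specs give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import math

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .cohort import _CAL, SALT_PER_NA
from .food_env import OUTLET_LISTING_YEARS, StreetNetwork

__all__ = [
    "RegionSpec",
    "SyntheticCohort",
    "make_street_network",
    "simulate_spatial_field",
    "simulate_cohort",
    "plant_cluster",
    "simulate_varying_slope",
    "J1_PEAK",
]

#: first maximum of the Bessel function J1; argmax of the band-z profile
J1_PEAK = 1.8412


def _default_effects():
    # slopes on the outcome scale (g/day); signs follow the usual
    # socio-demographic gradients in intake surveys: older age and women
    # eat more K (lower Na:K), Swiss nationality the opposite, tertiary
    # education more K, supermarket access slightly more K
    return {
        "age": {"na_intake": 0.004, "k_intake": 0.012},
        "sex_female": {"na_intake": 0.10, "k_intake": 0.35},
        "nationality_swiss": {"na_intake": -0.10, "k_intake": -0.30},
        "education_tertiary": {"na_intake": -0.10, "k_intake": 0.35},
        "civil_married_cohabiting": {"k_intake": -0.05},
        "supermarket": {"k_intake": 0.05},
    }


def _default_missing():
    # per-field missingness probabilities of a well-run survey
    return {
        "civil_status": 0.001,
        "occupation": 0.007,
        "education": 0.011,
        "nationality": 0.004,
        "intake": 0.0001,
        "zone_income": 0.014,
    }


@dataclass
class RegionSpec:
    """Parameters of the synthetic study region and cohort."""

    extent: tuple = (9800.0, 9800.0)  # meters
    street_grid_spacing: float = 70.0
    urban_center: tuple = (4900.0, 4900.0)
    urban_radius: float = 2500.0
    n_participants: int = 1000
    n_outlets_per_category: dict = field(
        default_factory=lambda: {"supermarket": 20, "grocery": 55, "convenience": 140}
    )
    correlation_range: float = 800.0
    field_sd: float = 0.3  # g/day, sd of the latent spatial field
    field_loadings: dict = field(
        default_factory=lambda: {"na_intake": 0.6, "k_intake": -0.15}
    )
    composition_range: float = 1200.0  # meters, neighborhood-composition scale
    effect_sizes: dict = field(default_factory=_default_effects)
    noise_sd: float = 0.5  # g/day, independent outcome noise (Na scale)
    urban_fraction: float = 0.6  # share of participants in the urban core
    missing_rates: dict = field(default_factory=_default_missing)
    zone_size: float = 500.0  # meters, analysis-zone grid for income join
    seed: int = 0

    def __post_init__(self):
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("extent must be strictly positive in both dimensions")
        if self.street_grid_spacing <= 0:
            raise ValueError("street_grid_spacing must be positive")
        if self.correlation_range <= 0:
            raise ValueError("correlation_range must be positive")
        for k, p in self.missing_rates.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missing rate for {k} outside [0, 1]")
        if not 0 <= self.urban_fraction <= 1:
            raise ValueError("urban_fraction outside [0, 1]")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["extent"] = list(d["extent"])
        d["urban_center"] = list(d["urban_center"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RegionSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["extent"] = tuple(d["extent"])
        d["urban_center"] = tuple(d["urban_center"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame
    outlets: pd.DataFrame
    network: StreetNetwork
    income_by_zone_year: pd.DataFrame
    truth: pd.DataFrame
    spec: RegionSpec

    def write(self, outdir) -> None:
        """Write all tables as plain-text files under ``outdir``."""
        import os

        os.makedirs(outdir, exist_ok=True)
        self.participants.to_csv(os.path.join(outdir, "participants.csv"), index=False)
        self.outlets.to_csv(os.path.join(outdir, "outlets.csv"), index=False)
        self.network.write_csv(
            os.path.join(outdir, "network_nodes.csv"),
            os.path.join(outdir, "network_edges.csv"),
        )
        self.network.write_geojson(os.path.join(outdir, "network.geojson"))
        self.income_by_zone_year.to_csv(os.path.join(outdir, "income.csv"), index=False)
        self.truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)
        self.spec.to_yaml(os.path.join(outdir, "region.yaml"))


def make_street_network(spec: RegionSpec) -> StreetNetwork:
    """Planar grid street network spanning the region extent.

    Nodes sit at integer multiples of the grid spacing; every edge length is
    the Euclidean distance between its endpoints (one spacing). The graph is
    connected by construction.
    """
    s = spec.street_grid_spacing
    ncx = int(math.floor(spec.extent[0] / s))
    ncy = int(math.floor(spec.extent[1] / s))
    if ncx < 2 or ncy < 2:
        raise ValueError(
            "degenerate extent: grid spacing must divide the extent into "
            "at least 2 cells per axis"
        )
    g = nx.Graph()
    nxn, nyn = ncx + 1, ncy + 1
    for iy in range(nyn):
        for ix in range(nxn):
            g.add_node(iy * nxn + ix, pos=(ix * s, iy * s))
    for iy in range(nyn):
        for ix in range(nxn):
            nid = iy * nxn + ix
            if ix + 1 < nxn:
                g.add_edge(nid, nid + 1, length=s)
            if iy + 1 < nyn:
                g.add_edge(nid, nid + nxn, length=s)
    return StreetNetwork(g)


def field_correlation(d, correlation_range: float):
    """Closed-form correlation of the latent field at distance ``d``."""
    from scipy.special import j0

    return j0(J1_PEAK * np.asarray(d, dtype=float) / correlation_range)


def simulate_spatial_field(
    coords: np.ndarray,
    correlation_range: float,
    sd: float,
    seed: int = 0,
    jitter: float = 1e-8,
) -> np.ndarray:
    """Zero-mean Gaussian-process realization at fixed coordinates.

    Dense Cholesky simulation; the O(n^3) factorization is comfortable to a
    few thousand points, which covers the generator's cohort sizes. ``sd=0``
    returns exact zeros. Coincident points receive (numerically) identical
    field values through the jitter-stabilized factorization.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 2:
        raise ValueError("need at least 2 coordinates")
    if len(np.unique(coords, axis=0)) < 2:
        raise ValueError("need at least 2 distinct coordinates")
    if correlation_range <= 0:
        raise ValueError("correlation_range must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    n = len(coords)
    if sd == 0:
        return np.zeros(n)

    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(coords))
    C = sd**2 * field_correlation(D, correlation_range)
    C[np.diag_indices(n)] += jitter * sd**2
    L = np.linalg.cholesky(C)
    rng = np.random.default_rng(seed)
    return L @ rng.standard_normal(n)


def _sample_positions(rng, n, spec: RegionSpec):
    """Urban-core-weighted point placement clipped to the grid hull."""
    w, h = spec.extent
    cx, cy = spec.urban_center
    s = spec.street_grid_spacing
    # keep points on the street-grid hull so everything snaps within 50 m
    xmax = math.floor(w / s) * s
    ymax = math.floor(h / s) * s
    urban = rng.random(n) < spec.urban_fraction
    xy = np.empty((n, 2))
    n_urban = int(urban.sum())
    r = spec.urban_radius * np.sqrt(rng.random(n_urban))
    theta = rng.random(n_urban) * 2 * np.pi
    xy[urban, 0] = cx + r * np.cos(theta)
    xy[urban, 1] = cy + r * np.sin(theta)
    n_rural = n - n_urban
    xy[~urban, 0] = rng.random(n_rural) * xmax
    xy[~urban, 1] = rng.random(n_rural) * ymax
    xy[:, 0] = np.clip(xy[:, 0], 0, xmax)
    xy[:, 1] = np.clip(xy[:, 1], 0, ymax)
    return xy, urban


def _composition_field(xy, spec: RegionSpec, seed: int) -> np.ndarray:
    """Latent neighborhood-composition score driving covariate gradients.

    Urban-core offset (advantaged-composition proxy peaks downtown, turns
    negative toward the periphery) plus a smooth Gaussian-process wiggle
    simulated on a coarse 500 m lattice and interpolated — cheap at any
    cohort size and adequately smooth at the 1.2 km composition scale.
    """
    d = np.hypot(xy[:, 0] - spec.urban_center[0], xy[:, 1] - spec.urban_center[1])
    offset = 1.6 * np.exp(-((d / spec.urban_radius) ** 2)) - 0.6

    step = 500.0
    gx = np.arange(0.0, spec.extent[0] + step, step)
    gy = np.arange(0.0, spec.extent[1] + step, step)
    gxx, gyy = np.meshgrid(gx, gy, indexing="ij")
    grid = np.c_[gxx.ravel(), gyy.ravel()]
    g_grid = simulate_spatial_field(
        grid, spec.composition_range, 1.0, seed=seed
    )
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (gx, gy), g_grid.reshape(len(gx), len(gy)), method="linear",
        bounds_error=False, fill_value=0.0,
    )
    return offset + interp(xy)


def _zone_id(xy, zone_size):
    gx = np.floor(xy[:, 0] / zone_size).astype(int)
    gy = np.floor(xy[:, 1] / zone_size).astype(int)
    return [f"z{a}_{b}" for a, b in zip(gx, gy)]


def simulate_cohort(spec: RegionSpec) -> SyntheticCohort:
    """Generate the full synthetic study package.

    Builds the street grid, places participants (urban-weighted) and outlets
    (urban-concentrated), draws socio-demographics with urban/rural
    composition differences, simulates the latent spatial field, assembles
    outcomes, derives the raw FFQ sodium by inverting the calibration
    equations, attaches zone incomes, and finally knocks out fields at the
    configured missingness rates. The ``truth`` table carries the latent
    field value, urban membership and planted-cluster flags per participant.
    """
    if spec.n_participants < 10:
        raise ValueError("n_participants must be at least 10")
    network = make_street_network(spec)
    root = np.random.default_rng(spec.seed)
    seeds = root.integers(0, 2**31 - 1, size=8)

    n = spec.n_participants
    rng_pos = np.random.default_rng(seeds[0])
    xy, urban = _sample_positions(rng_pos, n, spec)

    # socio-demographic composition varies smoothly in space: the tanh of a
    # latent neighborhood score shifts education, nationality, age and civil
    # status together, producing the urban-rural compositional divide that
    # carries most of the explainable spatial signal in the outcomes
    comp = _composition_field(xy, spec, seed=int(seeds[7]))
    t = np.tanh(comp)

    rng_cov = np.random.default_rng(seeds[1])
    sex = np.where(rng_cov.random(n) < 0.5, "female", "male")
    age = np.clip(rng_cov.normal(50.1 - 2.0 * t, 11.5), 18, 90).round(0)
    civil = np.where(
        rng_cov.random(n) < 0.72 - 0.10 * t, "married_cohabiting", "other"
    )
    occ_p = np.array([0.42, 0.34, 0.20, 0.04])
    occ_levels = np.array(["low", "medium", "high", "not_working"])
    u = rng_cov.random(n)
    occupation = occ_levels[(u[:, None] > occ_p.cumsum()[None, :]).sum(axis=1)]
    p_tert = 0.40 + 0.25 * t
    p_sec = 0.45 - 0.10 * t
    edu_levels = np.array(["primary", "secondary", "tertiary"])
    edu_p = np.stack([1.0 - p_sec - p_tert, p_sec, p_tert], axis=1)
    u = rng_cov.random(n)
    education = edu_levels[(u[:, None] > edu_p.cumsum(axis=1)).sum(axis=1)]
    nationality = np.where(
        rng_cov.random(n) < 0.70 - 0.20 * t, "swiss", "other"
    )
    year = rng_cov.integers(1993, 2019, size=n)
    energy = np.maximum(rng_cov.normal(2300.0, 700.0, n), 300.0).round(0)

    # outlets before outcomes: the supermarket effect needs densities; the
    # generator uses the *euclidean* decayed density as the true covariate
    # (cheap, monotone in the network one)
    rng_out = np.random.default_rng(seeds[2])
    outlet_rows = []
    oid = 0
    for cat, count in spec.n_outlets_per_category.items():
        o_xy, _ = _sample_positions(
            rng_out, count,
            RegionSpec(
                extent=spec.extent,
                street_grid_spacing=spec.street_grid_spacing,
                urban_center=spec.urban_center,
                urban_radius=spec.urban_radius,
                urban_fraction=0.75,
                seed=0,
            ),
        )
        for k in range(count):
            for yr in OUTLET_LISTING_YEARS:
                outlet_rows.append(
                    {
                        "id": f"o{oid}_{yr}",
                        "x": o_xy[k, 0],
                        "y": o_xy[k, 1],
                        "category": cat,
                        "year": yr,
                    }
                )
            oid += 1
    outlets = pd.DataFrame(outlet_rows)

    sup = outlets[
        (outlets["category"] == "supermarket")
        & (outlets["year"] == OUTLET_LISTING_YEARS[0])
    ][["x", "y"]].to_numpy()
    if len(sup):
        from scipy.spatial.distance import cdist

        dsup = cdist(xy, sup)
        sup_density = np.maximum(0.0, 1.0 - dsup / 800.0).sum(axis=1)
    else:
        sup_density = np.zeros(n)

    covariate_values = {
        "age": age - 50.0,
        "sex_female": (sex == "female").astype(float),
        "nationality_swiss": (nationality == "swiss").astype(float),
        "education_tertiary": (education == "tertiary").astype(float),
        "civil_married_cohabiting": (civil == "married_cohabiting").astype(float),
        "supermarket": sup_density,
    }

    fld = (
        simulate_spatial_field(
            xy, spec.correlation_range, spec.field_sd, seed=int(seeds[3])
        )
        if spec.field_sd > 0
        else np.zeros(n)
    )

    rng_noise = np.random.default_rng(seeds[4])
    base = {"na_intake": 3.7, "k_intake": 2.7}
    noise_scale = {"na_intake": 1.0, "k_intake": 0.8}
    outcomes = {}
    for out in ("na_intake", "k_intake"):
        y = np.full(n, base[out])
        for cov, slopes in spec.effect_sizes.items():
            if out in slopes and cov in covariate_values:
                y = y + slopes[out] * covariate_values[cov]
        y = y + spec.field_loadings.get(out, 0.0) * fld
        y = y + rng_noise.normal(0.0, spec.noise_sd * noise_scale[out], n)
        outcomes[out] = y

    # respect the hard floors the calibration equations impose on Na and
    # keep K physiologically positive
    na_floor = np.where(
        sex == "male",
        _CAL["male"][0] / SALT_PER_NA + 0.05,
        _CAL["female"][0] / SALT_PER_NA + 0.05,
    )
    na = np.maximum(outcomes["na_intake"], na_floor)
    k = np.maximum(outcomes["k_intake"], 0.5)
    a = np.where(sex == "male", _CAL["male"][0], _CAL["female"][0])
    b = np.where(sex == "male", _CAL["male"][1], _CAL["female"][1])
    ffq_na = (SALT_PER_NA * na - a) / b

    zone = _zone_id(xy, spec.zone_size)

    participants = pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(n)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "year": year,
            "age": age,
            "sex": sex,
            "civil_status": civil,
            "occupation": occupation,
            "education": education,
            "nationality": nationality,
            "ffq_na": ffq_na,
            "k_intake": k,
            "energy": energy,
            "zone_id": zone,
        }
    )

    # zone income table: rural zones richer, mild year drift
    rng_inc = np.random.default_rng(seeds[5])
    w, h = spec.extent
    dmax = math.hypot(w, h) / 2
    zones = sorted(set(zone))
    zone_xy = {
        z: (
            (int(z[1:].split("_")[0]) + 0.5) * spec.zone_size,
            (int(z.split("_")[1]) + 0.5) * spec.zone_size,
        )
        for z in zones
    }
    inc_rows = []
    for z in zones:
        zx, zy_ = zone_xy[z]
        d = math.hypot(zx - spec.urban_center[0], zy_ - spec.urban_center[1])
        base_inc = 110_000 + 40_000 * (d / dmax) + rng_inc.normal(0, 10_000)
        for yr in range(2005, 2017):
            inc_rows.append(
                {
                    "zone_id": z,
                    "year": yr,
                    "income": round(base_inc + 800 * (yr - 2005), 1),
                }
            )
    income = pd.DataFrame(inc_rows)

    # missingness knockout
    rng_miss = np.random.default_rng(seeds[6])
    for fld_name, rate in spec.missing_rates.items():
        if rate <= 0:
            continue
        mask = rng_miss.random(n) < rate
        if fld_name == "intake":
            participants.loc[mask, "ffq_na"] = np.nan
        elif fld_name == "zone_income":
            participants.loc[mask, "zone_id"] = np.nan
        elif fld_name in participants.columns:
            participants.loc[mask, fld_name] = np.nan

    truth = pd.DataFrame(
        {
            "id": participants["id"],
            "field": fld,
            "composition": comp,
            "urban": urban,
            "na_intake_true": na,
            "k_intake_true": k,
            "cluster_member": False,
        }
    )

    return SyntheticCohort(
        participants=participants,
        outlets=outlets,
        network=network,
        income_by_zone_year=income,
        truth=truth,
        spec=spec,
    )


def plant_cluster(
    cohort: SyntheticCohort,
    center: tuple,
    radius: float,
    delta: float,
    outcome: str = "na_intake",
) -> SyntheticCohort:
    """Shift an outcome by ``delta`` for participants within ``radius`` of
    ``center`` and record the membership in ``truth``.

    Sodium shifts are applied on the calibrated scale by adjusting the raw
    FFQ value through the inverse calibration, so the downstream pipeline
    sees the planted effect after calibration.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    parts = cohort.participants.copy()
    truth = cohort.truth.copy()
    d = np.hypot(parts["x"] - center[0], parts["y"] - center[1])
    members = (d <= radius).to_numpy()
    if not members.any():
        raise ValueError("no participants inside the planted-cluster radius")
    if delta != 0:
        if outcome == "na_intake":
            b = np.where(parts["sex"] == "male", _CAL["male"][1], _CAL["female"][1])
            parts.loc[members, "ffq_na"] = (
                parts.loc[members, "ffq_na"]
                + SALT_PER_NA * delta / b[members]
            )
        elif outcome == "k_intake":
            parts.loc[members, "k_intake"] = parts.loc[members, "k_intake"] + delta
        else:
            raise ValueError(f"cannot plant on outcome {outcome!r}")
    truth.loc[members, "cluster_member"] = True
    return SyntheticCohort(
        participants=parts,
        outlets=cohort.outlets,
        network=cohort.network,
        income_by_zone_year=cohort.income_by_zone_year,
        truth=truth,
        spec=cohort.spec,
    )


def simulate_varying_slope(
    n: int = 1000,
    extent: tuple = (9800.0, 9800.0),
    slope_scale: float | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
):
    """Regression testbed with smoothly varying local coefficient surfaces.

    ``y = beta0(x, y) + beta1(x, y) * x1 + noise`` where both coefficient
    surfaces ramp across the region as phase-shifted cosines with period
    ``2 * slope_scale`` (default: one full regime swing corner to corner).
    The varying intercept leaves spatially clustered residuals in any
    global (stationary-coefficient) fit, which a local fit absorbs.
    Returns ``(coords, X, y, truth)`` with truth columns beta0 and beta1.
    """
    rng = np.random.default_rng(seed)
    coords = rng.random((n, 2)) * np.asarray(extent)
    if slope_scale is None:
        slope_scale = extent[0] / 2
    x1 = rng.standard_normal(n)
    u = np.pi * coords[:, 0] / slope_scale
    v = np.pi * coords[:, 1] / slope_scale
    beta1 = 1.0 + np.cos(u) * np.cos(v)
    beta0 = 1.0 + np.cos(u + 1.2) * np.cos(v + 1.2)
    y = beta0 + beta1 * x1 + rng.normal(0, noise_sd, n)
    X = pd.DataFrame({"intercept": np.ones(n), "x1": x1})
    truth = pd.DataFrame({"beta0": beta0, "beta1": beta1})
    return coords, X, y, truth
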