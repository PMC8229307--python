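"""End-to-end study pipeline on synthetic or user-supplied data.

Stages: simulate (or load) -> outcome construction and exclusions ->
street-network accessibility -> per-outcome spatial-scale selection ->
raw LISA -> OLS and GWR fits of the three nested models -> residual LISA
per model -> HH/LL cluster characterization. Every stage is a pure function
of (inputs, config, seed); a run manifest records all parameters, stage
counts and library versions, and identical configs reproduce byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import os

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autocorr import (
    DEFAULT_BANDS,
    lisa_on_residuals,
    local_moran,
    scale_selection,
    write_lisa_csv,
    write_lisa_geojson,
)
from .characterize import compare_clusters, radar_table
from .cohort import add_outcomes, apply_exclusions
from .food_env import assign_income_year, outlet_density
from .models import (
    ModelSpec,
    build_design,
    fit_gwr,
    fit_ols,
    optimize_bandwidth,
    residual_autocorrelation,
    _pairwise_dist,
)
from .synthetic import RegionSpec, SyntheticCohort, simulate_cohort
from .weights import distance_band_weights

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run"]

OUTCOMES = ("na_k_ratio", "na_intake", "k_intake")


@dataclass
class PipelineConfig:
    region: RegionSpec = field(default_factory=RegionSpec)
    bands: tuple = DEFAULT_BANDS
    n_permutations: int = 999
    alpha: float = 0.05
    kernel_bandwidth: float = 800.0  # accessibility decay, meters
    gwr_bandwidth: float | None = None  # None -> AICc-optimized per model
    bandwidth_search: tuple | None = None
    residual_fits: tuple = ("ols", "gwr")
    outcomes: tuple = OUTCOMES
    seed: int = 0
    outdir: str = "saltscape_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region"]["extent"] = list(d["region"]["extent"])
        d["region"]["urban_center"] = list(d["region"]["urban_center"])
        d["bands"] = list(self.bands)
        d["residual_fits"] = list(self.residual_fits)
        d["outcomes"] = list(self.outcomes)
        if self.bandwidth_search is not None:
            d["bandwidth_search"] = list(self.bandwidth_search)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "region" in d:
            r = d["region"]
            r["extent"] = tuple(r["extent"])
            r["urban_center"] = tuple(r["urban_center"])
            d["region"] = RegionSpec(**r)
        for k in ("bands", "residual_fits", "outcomes"):
            if k in d:
                d[k] = tuple(d[k])
        if d.get("bandwidth_search") is not None:
            d["bandwidth_search"] = tuple(d["bandwidth_search"])
        return cls(**d)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    retained: pd.DataFrame
    report: object
    densities: pd.DataFrame
    scale_profiles: dict
    raw_lisa: dict
    ols_fits: dict
    gwr_fits: dict
    residual_lisa: dict
    residual_moran: dict
    comparisons: dict
    manifest: dict


def _child_seed(root: int, tag: str) -> int:
    import zlib

    h = np.random.default_rng(
        [root, zlib.crc32(tag.encode())]
    ).integers(0, 2**31 - 1)
    return int(h)


def run(config: PipelineConfig, cohort: SyntheticCohort | None = None) -> PipelineResult:
    """Execute the full pipeline and write all outputs under config.outdir."""
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    stale_flag = os.path.join(outdir, "STALE")
    with open(stale_flag, "w") as fh:
        fh.write("run in progress or aborted\n")

    config_record = config.to_dict()
    config_record.pop("outdir")  # path, not an analysis parameter
    manifest = {
        "saltscape_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config_record,
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as err:  # noqa: BLE001 - annotate and rethrow
                manifest["stages"][name] = {"status": "failed", "error": str(err)}
                _write_manifest(manifest, outdir)
                raise PipelineError(name, err) from err
        return deco

    @stage("simulate")
    def cohort_data():
        c = cohort if cohort is not None else simulate_cohort(config.region)
        manifest["stages"]["simulate"] = {
            "status": "ok",
            "n_participants": len(c.participants),
            "n_outlet_rows": len(c.outlets),
        }
        return c

    @stage("exclusions")
    def filtered():
        parts = add_outcomes(cohort_data.participants)
        region = ((0.0, 0.0), tuple(cohort_data.spec.extent))
        retained, report = apply_exclusions(
            parts, region=region, zone_income=cohort_data.income_by_zone_year
        )
        report.to_frame().to_csv(os.path.join(outdir, "exclusions.csv"), index=False)
        manifest["stages"]["exclusions"] = {
            "status": "ok",
            "retained": report.retained,
            "excluded": report.counts,
        }
        return retained, report

    retained, report = filtered

    @stage("accessibility")
    def access():
        acc = outlet_density(
            retained,
            cohort_data.outlets,
            cohort_data.network,
            bandwidth=config.kernel_bandwidth,
        )
        manifest["stages"]["accessibility"] = {
            "status": "ok",
            "unsnapped": len(acc.unsnapped),
        }
        return acc

    # participants the network cannot serve get missing densities; drop them
    snapped_mask = ~retained["id"].isin(access.unsnapped)
    retained = retained[snapped_mask].reset_index(drop=True)
    densities = access.densities.loc[retained["id"].values]
    densities.to_csv(os.path.join(outdir, "densities.csv"))

    # zone income lookup on the retained cohort
    inc = cohort_data.income_by_zone_year.set_index(["zone_id", "year"])["income"]
    income = pd.Series(
        [
            inc.loc[(z, assign_income_year(int(y)))]
            for z, y in zip(retained["zone_id"], retained["year"])
        ],
        index=retained["id"].values,
        name="zone_income",
    )
    analysis = retained.copy()
    analysis["zone_income"] = income.values
    for c in densities.columns:
        analysis[c] = densities[c].values
    analysis.to_csv(os.path.join(outdir, "retained.csv"), index=False)

    coords = analysis[["x", "y"]].to_numpy(dtype=float)
    ids = analysis["id"].values
    dist_matrix = _pairwise_dist(coords)

    scale_profiles, raw_lisa = {}, {}
    ols_fits, gwr_fits = {}, {}
    residual_lisa, residual_moran, comparisons = {}, {}, {}

    for outcome in config.outcomes:
        values = analysis[outcome].to_numpy(dtype=float)

        @stage(f"scale_{outcome}")
        def profile(outcome=outcome, values=values):
            p = scale_selection(
                values,
                coords,
                bands=config.bands,
                alpha=config.alpha,
                fallback_band=config.kernel_bandwidth,
                n_perm=config.n_permutations,
                seed=_child_seed(config.seed, f"scale_{outcome}"),
            )
            p.to_frame().to_csv(
                os.path.join(outdir, f"scale_{outcome}.csv"), index=False
            )
            manifest["stages"][f"scale_{outcome}"] = {
                "status": "ok",
                "selected_band": p.selected_band,
                "rule": p.selection_rule_applied,
            }
            return p

        scale_profiles[outcome] = profile
        w = distance_band_weights(coords, profile.selected_band, standardize=True)

        @stage(f"lisa_{outcome}_raw")
        def raw(outcome=outcome, values=values, w=w):
            lisa = local_moran(
                values,
                w,
                n_perm=config.n_permutations,
                alpha=config.alpha,
                seed=_child_seed(config.seed, f"lisa_{outcome}_raw"),
                model_tag=f"{outcome}_raw",
            )
            write_lisa_csv(lisa, ids, os.path.join(outdir, f"lisa_{outcome}_raw.csv"))
            write_lisa_geojson(
                lisa, ids, coords, os.path.join(outdir, f"lisa_{outcome}_raw.geojson")
            )
            manifest["stages"][f"lisa_{outcome}_raw"] = {
                "status": "ok",
                "n_permutations": config.n_permutations,
                "pseudo_p_resolution": 1.0 / (config.n_permutations + 1),
                "class_counts": {
                    k: int(v) for k, v in lisa.class_counts().items()
                },
            }
            return lisa

        raw_lisa[outcome] = raw

        for model_id in (1, 2, 3):
            mspec = ModelSpec(outcome=outcome, model_id=model_id)

            @stage(f"models_{mspec.tag}")
            def fits(mspec=mspec, values=values):
                y, X = build_design(analysis, densities, income, mspec)
                ols = fit_ols(y, X)
                ols.to_frame().to_csv(
                    os.path.join(outdir, f"ols_{mspec.tag}.csv"), index=False
                )
                if config.gwr_bandwidth is not None:
                    bw = config.gwr_bandwidth
                else:
                    bw, _ = optimize_bandwidth(
                        y, X, coords,
                        search_range=config.bandwidth_search,
                        dist_matrix=dist_matrix,
                    )
                gwr = fit_gwr(y, X, coords, bw, dist_matrix=dist_matrix)
                gwr.surfaces_frame(ids, coords).to_csv(
                    os.path.join(outdir, f"gwr_{mspec.tag}.csv"), index=False
                )
                manifest["stages"][f"models_{mspec.tag}"] = {
                    "status": "ok",
                    "ols_aicc": ols.aicc,
                    "gwr_aicc": gwr.aicc,
                    "gwr_bandwidth": bw,
                }
                return ols, gwr

            ols, gwr = fits
            ols_fits[mspec.tag] = ols
            gwr_fits[mspec.tag] = gwr

            for kind, f in (("ols", ols), ("gwr", gwr)):
                if kind not in config.residual_fits:
                    continue

                @stage(f"lisa_{mspec.tag}_{kind}")
                def rlisa(mspec=mspec, f=f, kind=kind, w=w):
                    lisa = lisa_on_residuals(
                        f.residuals,
                        w,
                        model_tag=f"{mspec.tag}_{kind}",
                        n_perm=config.n_permutations,
                        alpha=config.alpha,
                        seed=_child_seed(config.seed, f"lisa_{mspec.tag}_{kind}"),
                    )
                    write_lisa_csv(
                        lisa, ids,
                        os.path.join(outdir, f"lisa_{mspec.tag}_{kind}.csv"),
                    )
                    gmi = residual_autocorrelation(
                        f, w,
                        n_perm=config.n_permutations,
                        seed=_child_seed(config.seed, f"gmi_{mspec.tag}_{kind}"),
                    )
                    manifest["stages"][f"lisa_{mspec.tag}_{kind}"] = {
                        "status": "ok",
                        "significant": int(
                            (lisa.classes != "not_significant").sum()
                        ),
                        "residual_moran_I": gmi.I,
                        "residual_moran_z": gmi.z_score,
                    }
                    residual_moran[f"{mspec.tag}_{kind}"] = gmi
                    return lisa

                residual_lisa[f"{mspec.tag}_{kind}"] = rlisa

        @stage(f"characterize_{outcome}")
        def comparison(outcome=outcome):
            lisa = raw_lisa[outcome]
            counts = lisa.class_counts()
            if counts.get("HH", 0) == 0 or counts.get("LL", 0) == 0:
                manifest["stages"][f"characterize_{outcome}"] = {
                    "status": "skipped",
                    "reason": "empty HH or LL class",
                }
                return None
            comp = compare_clusters(analysis, lisa)
            comp.table.to_csv(
                os.path.join(outdir, f"comparison_{outcome}.csv"), index=False
            )
            radar_table(comp).to_csv(
                os.path.join(outdir, f"radar_{outcome}.csv"), index=False
            )
            manifest["stages"][f"characterize_{outcome}"] = {
                "status": "ok",
                "n_hh": comp.n_hh,
                "n_ll": comp.n_ll,
            }
            return comp

        if comparison is not None:
            comparisons[outcome] = comparison

    _write_manifest(manifest, outdir)
    os.remove(stale_flag)
    return PipelineResult(
        retained=analysis,
        report=report,
        densities=densities,
        scale_profiles=scale_profiles,
        raw_lisa=raw_lisa,
        ols_fits=ols_fits,
        gwr_fits=gwr_fits,
        residual_lisa=residual_lisa,
        residual_moran=residual_moran,
        comparisons=comparisons,
        manifest=manifest,
    )


def _write_manifest(manifest: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
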