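"""Pipeline orchestration: simulate -> methane -> flux -> compare -> community.

Each stage reads/writes the shared CSV/TSV schemas so simulated and real data
are interchangeable.  Stage failures are re-raised with the stage name;
every output carries a provenance header (config digest, seed, version).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import aggregate_to_rank, bray_curtis, pcoa, permanova
from .compare import fold_change, fold_change_summary, seasonal_summary, welch_t_test
from .config import PipelineConfig
from .flux import PorewaterProfile, bay_season_flux_summary, core_flux
from .headspace import total_porewater_methane
from .io import (
    read_count_table,
    read_headspace_csv,
    read_porewater_csv,
    read_temperature_csv,
    write_count_table,
    write_distance_matrix,
    write_flux_results,
    write_headspace_csv,
    write_porewater_csv,
    write_temperature_csv,
)
from .synthetic import (
    TemperatureScenario,
    default_community_scenario,
    default_profile_truths,
    generate_count_table,
    generate_headspace_samples,
    generate_porewater_profiles,
    generate_temperature_series,
    implied_flux,
)

__all__ = ["run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "methane", "flux", "compare", "community")

SUMMER_DEPTHS = np.arange(1.0, 40.0, 2.0)  # every 2 cm
WINTER_DEPTHS = np.arange(2.0, 40.0, 4.0)  # every 4 cm
JAR_INTERVALS = [(2.0, 6.0), (9.0, 13.0), (16.0, 20.0), (23.0, 27.0)]
COMMUNITY_DEPTHS = (0.5, 1.5, 8.5, 15.5, 22.5)


class StageError(RuntimeError):
    pass


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("[%s] starting", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def _provenance(config: PipelineConfig) -> dict[str, object]:
    return {"config": config.digest(), "seed": config.seed, "version": __version__}


@_stage("simulate")
def _simulate(config: PipelineConfig, out_dir: Path) -> None:
    prov = _provenance(config)
    truths = default_profile_truths()
    rng_seed = config.seed
    profiles = []
    truth_rows = []
    for season, depths in (("summer", SUMMER_DEPTHS), ("winter", WINTER_DEPTHS)):
        season_truths = [t for t in truths if t.season == season]
        generated, echoed = generate_porewater_profiles(season_truths, depths, seed=rng_seed)
        rng_seed += 1
        profiles.extend(generated)
        for t in echoed:
            truth_rows.append(
                {
                    "site": t.site, "bay": t.bay, "season": t.season,
                    "sulfate_surface_mM": t.sulfate_surface, "dns_true_cm": t.dns_true,
                    "methane_deep_mM": t.methane_deep,
                    "implied_flux_mmol_m2_d": implied_flux(
                        t, config.temperature_for(t.bay, t.season),
                        m0=config.d0_m0, m1=config.d0_m1,
                    ),
                }
            )
    write_porewater_csv(profiles, out_dir / "porewater.csv", provenance=prov)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth_sidecar.csv", index=False)

    heated, control = generate_temperature_series(
        TemperatureScenario(),
        start="2021-04-01", end="2022-03-31", seed=config.seed,
    )
    write_temperature_csv(
        {"heated": heated, "control": control}, out_dir / "temperature.csv", provenance=prov
    )

    # headspace jars: true concentration = generated methane at the interval midpoint
    geometry, lab = config.jar_geometry(), config.lab_conditions()
    jars = []
    for profile in profiles:
        truth = next(
            t for t in truths
            if (t.site, t.bay, t.season) == (profile.site, profile.bay, profile.season)
        )
        for interval in JAR_INTERVALS:
            mid = 0.5 * (interval[0] + interval[1])
            true_c = float(truth.expected_methane(np.array([mid]))[0])
            jars.append(
                generate_headspace_samples(
                    true_c, geometry=geometry, lab=lab,
                    site=profile.site, bay=profile.bay, season=profile.season,
                    depth_interval=interval,
                )
            )
    write_headspace_csv(jars, out_dir / "headspace.csv", provenance=prov)

    scenario = default_community_scenario()
    samples = [
        (bay, season, depth)
        for bay in ("heated", "control")
        for season in ("summer", "winter")
        for depth in COMMUNITY_DEPTHS
        for _core in range(3)
    ]
    table = generate_count_table(scenario, samples, seed=config.seed)
    write_count_table(
        table,
        out_dir / "asv_counts.tsv",
        out_dir / "asv_taxonomy.tsv",
        out_dir / "sample_metadata.csv",
        provenance=prov,
    )


@_stage("methane")
def _methane(config: PipelineConfig, out_dir: Path) -> None:
    samples = read_headspace_csv(
        out_dir / "headspace.csv", geometry=config.jar_geometry(), lab=config.lab_conditions()
    )
    ch4 = [total_porewater_methane(s, include_dissolved=config.include_dissolved) for s in samples]
    write_headspace_csv(
        samples, out_dir / "methane_mM.csv", ch4_mm=ch4, provenance=_provenance(config)
    )


@_stage("flux")
def _flux(config: PipelineConfig, out_dir: Path) -> None:
    profiles = read_porewater_csv(out_dir / "porewater.csv", porosity=config.porosity)
    results = [
        core_flux(
            p,
            temperature_c=config.temperature_for(p.bay, p.season),
            m0=config.d0_m0, m1=config.d0_m1,
            r2_threshold=config.r2_threshold,
            include_porosity_factor=config.include_porosity_factor,
        )
        for p in profiles
    ]
    prov = _provenance(config)
    write_flux_results(results, out_dir / "flux_per_core.csv", provenance=prov)
    summary = bay_season_flux_summary(results)
    (out_dir / "flux_summary.csv").write_text(
        "".join(f"# {k}: {v}\n" for k, v in prov.items()) + summary.to_csv(index=False)
    )


@_stage("compare")
def _compare(config: PipelineConfig, out_dir: Path) -> None:
    series = read_temperature_csv(out_dir / "temperature.csv")
    windows = config.season_windows()
    rows = []
    for bay, temps in series.items():
        for label, window in windows.items():
            s = seasonal_summary(temps, window)
            rows.append(
                {
                    "bay": bay, "season": label, "mean_c": s.mean, "sd_c": s.sd,
                    "min_c": s.min, "max_c": s.max, "n": s.n,
                }
            )
    temp_summary = pd.DataFrame(rows)

    t_rows = []
    for label, window in windows.items():
        a = series["heated"].loc[window.start : window.end].to_numpy()
        b = series["control"].loc[window.start : window.end].to_numpy()
        t, df, p = welch_t_test(a, b)
        t_rows.append({"season": label, "t": t, "df": df, "p_value": p})
    ttests = pd.DataFrame(t_rows)

    # methane fold changes use the jar-derived table: jar interval midpoints
    # (4, 11, 18, 25 cm) are shared by both seasons' sampling grids
    methane = pd.read_csv(out_dir / "methane_mM.csv", comment="#")
    profiles = []
    for (site, bay, season), group in methane.groupby(["site", "bay", "season"]):
        group = group.sort_values("depth_cm")
        profiles.append(
            PorewaterProfile(
                site=str(site), bay=str(bay), season=str(season),
                depths=group["depth_cm"].to_numpy(dtype=float),
                analytes={"methane": group["ch4_mM"].to_numpy(dtype=float)},
                porosity=config.porosity,
            )
        )
    fc_rows = []
    for contrast, num, den, match_sites in (
        ("season", "summer", "winter", True),
        ("bay", "heated", "control", False),  # bays have disjoint site labels
    ):
        records = fold_change(
            profiles, contrast=contrast, depth=config.fold_change_depth_cm,
            floor=config.detection_floor_mm, numerator=num, denominator=den,
            match_sites=match_sites,
        )
        if not records:
            continue
        summary = fold_change_summary(records)
        for r in records:
            fc_rows.append(
                {
                    "contrast": contrast, "site": r.site, "depth_cm": r.depth,
                    "numerator_bay": r.numerator_context[0],
                    "numerator_season": r.numerator_context[1],
                    "denominator_bay": r.denominator_context[0],
                    "denominator_season": r.denominator_context[1],
                    "ratio": r.ratio, "floor_applied": r.floor_applied,
                    "contrast_max_fold": summary["max_fold"],
                    "contrast_mean_fold": summary["mean_fold"],
                }
            )
    prov_text = "".join(f"# {k}: {v}\n" for k, v in _provenance(config).items())
    (out_dir / "temperature_summary.csv").write_text(prov_text + temp_summary.to_csv(index=False))
    (out_dir / "temperature_ttests.csv").write_text(prov_text + ttests.to_csv(index=False))
    (out_dir / "fold_changes.csv").write_text(
        prov_text + pd.DataFrame(fc_rows).to_csv(index=False)
    )


@_stage("community")
def _community(config: PipelineConfig, out_dir: Path) -> None:
    table = read_count_table(
        out_dir / "asv_counts.tsv", out_dir / "asv_taxonomy.tsv", out_dir / "sample_metadata.csv"
    )
    prov = _provenance(config)
    prov_text = "".join(f"# {k}: {v}\n" for k, v in prov.items())
    families = aggregate_to_rank(table, "family")
    d = bray_curtis(families)
    write_distance_matrix(d.sample_ids, d.values, out_dir / "bray_curtis.tsv", provenance=prov)
    ordination = pcoa(d)
    coords = ordination.coordinates.copy()
    coords.index.name = "sample_id"
    (out_dir / "pcoa_coordinates.csv").write_text(prov_text + coords.to_csv())
    result = permanova(
        d, table.metadata,
        terms=["bay", "depth", "season", "bay:depth", "bay:season"],
        n_permutations=config.n_permutations, seed=config.seed,
    )
    (out_dir / "permanova.csv").write_text(prov_text + result.to_dataframe().to_csv(index=False))


_STAGE_FUNCS = {
    "simulate": _simulate,
    "methane": _methane,
    "flux": _flux,
    "compare": _compare,
    "community": _community,
}


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> Path:
    """Run the requested stages in canonical order, writing into out_dir.

    Analysis stages read the files a previous ``simulate`` (or the user)
    placed in out_dir, so simulated and real inputs are interchangeable.
    Returns out_dir.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid stages: {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage in stages:
            _STAGE_FUNCS[stage](config, out_dir)
    return out_dir
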