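"""Readers and writers for the pipeline's CSV/TSV schemas.

CSV carries geochemistry and metadata; TSV carries count and taxonomy tables
(amplicon-pipeline convention).  Writers prepend '#'-prefixed provenance
lines (config digest, seed, package version) that the paired readers skip,
so written files round-trip to equal in-memory objects.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .community import CountTable
from .flux import FluxResult, PorewaterProfile
from .headspace import HeadspaceSample, JarGeometry, LabConditions

__all__ = [
    "read_porewater_csv",
    "write_porewater_csv",
    "read_headspace_csv",
    "write_headspace_csv",
    "read_temperature_csv",
    "write_temperature_csv",
    "read_count_table",
    "write_count_table",
    "write_flux_results",
    "write_distance_matrix",
    "read_distance_matrix",
]

logger = logging.getLogger(__name__)

POREWATER_COLUMNS = ["site", "bay", "season", "depth_cm", "analyte", "concentration_mM"]
HEADSPACE_COLUMNS = ["site", "bay", "season", "depth_top_cm", "depth_bottom_cm", "ppm"]


def _provenance_header(meta: dict[str, object] | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def _read_table(path: str | Path, sep: str, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    return frame


def read_porewater_csv(path: str | Path, porosity: float = 0.8) -> list[PorewaterProfile]:
    """Parse long-format porewater CSV into one profile per (site, bay, season).

    Rows may appear in any order; depths are sorted ascending per profile.
    Duplicate (site, bay, season, depth, analyte) rows and non-numeric
    concentrations are errors.
    """
    frame = _read_table(path, ",", POREWATER_COLUMNS)
    for col in ("depth_cm", "concentration_mM"):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[converted.isna() & frame[col].notna()]
        if len(bad):
            raise ValueError(
                f"{Path(path).name}: non-numeric {col} at data row {int(bad[0]) + 1}"
            )
        frame[col] = converted
    dup_keys = ["site", "bay", "season", "depth_cm", "analyte"]
    dups = frame[frame.duplicated(dup_keys, keep=False)]
    if len(dups):
        first = dups.iloc[0]
        raise ValueError(
            f"duplicate porewater rows for {tuple(first[k] for k in dup_keys)}"
        )
    profiles = []
    for (site, bay, season), group in frame.groupby(["site", "bay", "season"], sort=True):
        wide = group.pivot(index="depth_cm", columns="analyte", values="concentration_mM")
        wide = wide.sort_index()
        depths = wide.index.to_numpy(dtype=float)
        analytes = {
            str(a): wide[a].to_numpy(dtype=float)
            for a in wide.columns
            if not wide[a].isna().any()
        }
        dropped = [a for a in wide.columns if wide[a].isna().any()]
        if dropped:
            logger.warning(
                "profile (%s, %s, %s): analytes %s not measured at every depth; dropped",
                site, bay, season, dropped,
            )
        profiles.append(
            PorewaterProfile(
                site=str(site), bay=str(bay), season=str(season),
                depths=depths, analytes=analytes, porosity=porosity,
            )
        )
    return profiles


def write_porewater_csv(
    profiles: list[PorewaterProfile],
    path: str | Path,
    provenance: dict[str, object] | None = None,
) -> None:
    rows = []
    for p in profiles:
        for analyte, values in sorted(p.analytes.items()):
            for depth, conc in zip(p.depths, values):
                rows.append(
                    {
                        "site": p.site, "bay": p.bay, "season": p.season,
                        "depth_cm": depth, "analyte": analyte, "concentration_mM": conc,
                    }
                )
    frame = pd.DataFrame(rows, columns=POREWATER_COLUMNS)
    Path(path).write_text(_provenance_header(provenance) + frame.to_csv(index=False))


def read_headspace_csv(
    path: str | Path,
    geometry: JarGeometry | None = None,
    lab: LabConditions | None = None,
) -> list[HeadspaceSample]:
    """Parse headspace GC readings; jar geometry and lab conditions come from config."""
    frame = _read_table(path, ",", HEADSPACE_COLUMNS)
    geometry = geometry or JarGeometry()
    lab = lab or LabConditions()
    samples = []
    for _, row in frame.iterrows():
        samples.append(
            HeadspaceSample(
                site=str(row["site"]), bay=str(row["bay"]), season=str(row["season"]),
                depth_interval=(float(row["depth_top_cm"]), float(row["depth_bottom_cm"])),
                ppm=float(row["ppm"]), geometry=geometry, lab=lab,
            )
        )
    return samples


def write_headspace_csv(
    samples: list[HeadspaceSample],
    path: str | Path,
    ch4_mm: list[float] | None = None,
    provenance: dict[str, object] | None = None,
) -> None:
    """Write headspace samples; with ch4_mm, adds the converted concentration
    column with depth assigned to the interval midpoint."""
    rows = []
    for i, s in enumerate(samples):
        row = {
            "site": s.site, "bay": s.bay, "season": s.season,
            "depth_top_cm": s.depth_interval[0], "depth_bottom_cm": s.depth_interval[1],
            "ppm": s.ppm,
        }
        if ch4_mm is not None:
            row["depth_cm"] = s.depth_midpoint
            row["ch4_mM"] = ch4_mm[i]
        rows.append(row)
    frame = pd.DataFrame(rows)
    Path(path).write_text(_provenance_header(provenance) + frame.to_csv(index=False))


def read_temperature_csv(path: str | Path) -> dict[str, pd.Series]:
    """Logger CSV (timestamp, bay, temperature_c) -> per-bay series."""
    frame = _read_table(path, ",", ["timestamp", "bay", "temperature_c"])
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    out = {}
    for bay, group in frame.groupby("bay"):
        index = pd.DatetimeIndex(group["timestamp"])
        index.name = None
        out[str(bay)] = pd.Series(
            group["temperature_c"].to_numpy(dtype=float), index=index, name=str(bay)
        ).sort_index()
    return out


def write_temperature_csv(
    series_by_bay: dict[str, pd.Series],
    path: str | Path,
    provenance: dict[str, object] | None = None,
) -> None:
    frames = []
    for bay, series in series_by_bay.items():
        frames.append(
            pd.DataFrame(
                {"timestamp": series.index, "bay": bay, "temperature_c": series.to_numpy()}
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    Path(path).write_text(_provenance_header(provenance) + frame.to_csv(index=False))


def read_count_table(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
) -> CountTable:
    """Assemble a CountTable from count TSV (rows=ASVs, columns=samples),
    taxonomy TSV (asv_id, lineage), and metadata CSV (sample_id, bay, season,
    depth_cm, site)."""
    if not Path(counts_path).exists():
        raise FileNotFoundError(counts_path)
    counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    tax = _read_table(taxonomy_path, "\t", ["asv_id", "lineage"])
    meta = _read_table(metadata_path, ",", ["sample_id", "bay", "season", "depth_cm", "site"])
    metadata = meta.set_index("sample_id").rename(columns={"depth_cm": "depth"})
    metadata["depth"] = metadata["depth"].astype(float)
    taxonomy = dict(zip(tax["asv_id"].astype(str), tax["lineage"].astype(str)))
    return CountTable(
        sample_ids=[str(c) for c in counts.columns],
        asv_ids=[str(i) for i in counts.index],
        counts=counts.to_numpy(dtype=np.int64).T,
        taxonomy=taxonomy,
        metadata=metadata,
    )


def write_count_table(
    table: CountTable,
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
    provenance: dict[str, object] | None = None,
) -> None:
    header = _provenance_header(provenance)
    counts = pd.DataFrame(
        table.counts.T, index=pd.Index(table.asv_ids, name="asv_id"), columns=table.sample_ids
    )
    Path(counts_path).write_text(header + counts.to_csv(sep="\t"))
    tax = pd.DataFrame(
        {"asv_id": table.asv_ids, "lineage": [table.taxonomy[a] for a in table.asv_ids]}
    )
    Path(taxonomy_path).write_text(header + tax.to_csv(sep="\t", index=False))
    meta = table.metadata.rename(columns={"depth": "depth_cm"}).copy()
    meta.index.name = "sample_id"
    Path(metadata_path).write_text(header + meta.to_csv())


def write_flux_results(
    results: list[FluxResult],
    path: str | Path,
    provenance: dict[str, object] | None = None,
) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "site": r.site, "bay": r.bay, "season": r.season,
                "slope_mM_per_cm": r.fit.slope, "intercept_mM": r.fit.intercept,
                "r_squared": r.fit.r_squared, "n_points": r.fit.n_points,
                "dns_cm": r.dns, "d0_cm2_s": r.d0, "ds_cm2_s": r.ds,
                "flux_mmol_m2_d": r.flux, "included": r.included,
                "exclusion_reason": r.exclusion_reason or "",
            }
        )
    frame = pd.DataFrame(rows)
    Path(path).write_text(_provenance_header(provenance) + frame.to_csv(index=False))


def write_distance_matrix(
    sample_ids: list[str],
    values: np.ndarray,
    path: str | Path,
    provenance: dict[str, object] | None = None,
) -> None:
    frame = pd.DataFrame(values, index=sample_ids, columns=sample_ids)
    frame.index.name = "sample_id"
    Path(path).write_text(_provenance_header(provenance) + frame.to_csv(sep="\t"))


def read_distance_matrix(path: str | Path):
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return [str(i) for i in frame.index], frame.to_numpy(dtype=float)
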