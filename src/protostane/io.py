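"""Readers, writers and the packaged fixtures.

Formats are deliberately plain: MGF (via pyteomics) or CSV for spectra and
feature tables, CSV for every tabular fixture and result, JSON for run
summaries and simulation ground truth.  All CSV output uses UTF-8 with a
period decimal separator regardless of locale (pandas defaults).

The packaged fixtures transcribe the study's printed tables: the MRM
transition registry (14 analytes + internal standard), the 25-compound
reference library, the 14 calibration curves with LOD/LOQ, and the 43-batch
content matrix labelled by origin.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd
from pyteomics import mgf

from .annotate import (
    AnnotationReport,
    FeatureRecord,
    FragmentPeak,
    LibraryEntry,
)
from .chem import parse_formula
from .quant import AreaMeasurement, CalibrationCurve, ContentMatrix, MRMTransition

__all__ = [
    "load_fixtures",
    "load_library",
    "load_transitions",
    "load_curves",
    "load_lods",
    "load_contents",
    "fixture_hash",
    "library_features",
    "read_features_mgf",
    "write_features_mgf",
    "read_features_csv",
    "write_features_csv",
    "read_areas_csv",
    "write_areas_csv",
    "read_contents_csv",
    "write_contents_csv",
    "write_annotation_report",
]

_FIXTURES = {"library", "transitions", "curves", "contents"}


def _fixture_path(name: str):
    return resources.files("protostane.data").joinpath(f"{name}.csv")


def fixture_hash(name: str) -> str:
    """SHA-256 of a packaged fixture's bytes, for provenance logging."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}")
    return hashlib.sha256(_fixture_path(name).read_bytes()).hexdigest()[:12]


def load_library() -> tuple[LibraryEntry, ...]:
    """The 25-entry reference library (21 standard-confirmed, 14 quantified)."""
    df = pd.read_csv(_fixture_path("library"))
    entries = []
    for row in df.itertuples(index=False):
        frag_mzs, chains = [], []
        for item in str(row.fragments).split(";"):
            mz_txt, chain_txt = item.split(":")
            frag_mzs.append(float(mz_txt))
            chains.append(tuple(chain_txt.split("+")))
        lam = None if pd.isna(row.lambda_max) else float(row.lambda_max)
        entries.append(
            LibraryEntry(
                peak=int(row.peak),
                name=row.name,
                formula=parse_formula(row.formula),
                retention_time=float(row.rt_min),
                type_id=row.type_id,
                standard_confirmed=bool(row.standard_confirmed),
                quantified=bool(row.quantified),
                expected_fragments=tuple(frag_mzs),
                expected_losses=tuple(chains),
                reported_precursor_mz=float(row.precursor_mz),
                reported_error_ppm=float(row.error_ppm),
                uv_lambda_max=lam,
                mz_anomalous=bool(row.mz_anomalous),
            )
        )
    lib = tuple(entries)
    if len(lib) != 25:
        raise ValueError(f"library fixture corrupt: {len(lib)} entries, expected 25")
    if sum(e.standard_confirmed for e in lib) != 21:
        raise ValueError("library fixture corrupt: expected 21 standard-confirmed entries")
    if sum(e.quantified for e in lib) != 14:
        raise ValueError("library fixture corrupt: expected 14 quantified entries")
    return lib


def load_transitions() -> tuple[MRMTransition, ...]:
    """The MRM transition registry: 14 analytes plus the internal standard."""
    df = pd.read_csv(_fixture_path("transitions"))
    out = tuple(
        MRMTransition(
            analyte=row.analyte,
            precursor_mz=float(row.precursor_mz),
            product_mz=float(row.product_mz),
            cone_voltage=float(row.cone_voltage),
            collision_energy=float(row.collision_energy),
            is_internal_standard=bool(row.is_internal_standard),
        )
        for row in df.itertuples(index=False)
    )
    if len(out) != 15 or sum(t.is_internal_standard for t in out) != 1:
        raise ValueError("transition fixture corrupt: expected 14 analytes + 1 IS")
    return out


def load_curves() -> dict[str, CalibrationCurve]:
    """The 14 packaged calibration curves, keyed by analyte."""
    df = pd.read_csv(_fixture_path("curves"))
    curves = {
        row.analyte: CalibrationCurve(
            analyte=row.analyte,
            slope=float(row.slope),
            intercept=float(row.intercept),
            r=float(row.r),
            linear_range=(float(row.linear_low), float(row.linear_high)),
        )
        for row in df.itertuples(index=False)
    }
    if len(curves) != 14:
        raise ValueError("curve fixture corrupt: expected 14 analytes")
    return curves


def load_lods() -> dict[str, float]:
    """Packaged limits of detection (ng/mL in the injected solution)."""
    df = pd.read_csv(_fixture_path("curves"))
    return {row.analyte: float(row.lod_ng_ml) for row in df.itertuples(index=False)}


def load_contents() -> ContentMatrix:
    """The 43-sample × 14-analyte content matrix with origin labels."""
    df = pd.read_csv(_fixture_path("contents"), index_col="sample_id")
    matrix = ContentMatrix.from_frame(df)
    if matrix.values.shape != (43, 14):
        raise ValueError(f"content fixture corrupt: shape {matrix.values.shape}")
    if (matrix.origins == "Fujian").sum() != 21 or (matrix.origins == "Sichuan").sum() != 22:
        raise ValueError("content fixture corrupt: expected 21 Fujian + 22 Sichuan samples")
    return matrix


def load_fixtures(name: str):
    """Load one packaged fixture by name, validated against its invariants."""
    loaders = {
        "library": load_library,
        "transitions": load_transitions,
        "curves": load_curves,
        "contents": load_contents,
    }
    try:
        return loaders[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}") from None


def library_features(library: tuple[LibraryEntry, ...] | None = None) -> list[FeatureRecord]:
    """The packaged library rendered as noise-free features (as printed).

    Precursor m/z and fragments are the values as reported, so this is the
    natural input for reproducing the annotation of the original run.
    """
    if library is None:
        library = load_library()
    return [
        FeatureRecord(
            retention_time=e.retention_time,
            precursor_mz=e.reported_precursor_mz,
            fragments=tuple(FragmentPeak(mz) for mz in e.expected_fragments),
            uv_lambda_max=e.uv_lambda_max,
            feature_id=f"peak-{e.peak}",
        )
        for e in library
    ]


# -- spectra -----------------------------------------------------------------


def write_features_mgf(features: list[FeatureRecord], path) -> None:
    """Write features as MGF; the UV maximum rides in a UV_LAMBDA_MAX key."""
    spectra = []
    for i, f in enumerate(features):
        params = {
            "title": f.feature_id or f"feature-{i + 1}",
            "pepmass": f.precursor_mz,
            "rtinseconds": f.retention_time * 60.0,
        }
        if f.uv_lambda_max is not None:
            params["uv_lambda_max"] = f.uv_lambda_max
        spectra.append(
            {
                "params": params,
                "m/z array": [p.mz for p in sorted(f.fragments, key=lambda p: p.mz)],
                "intensity array": [
                    p.intensity for p in sorted(f.fragments, key=lambda p: p.mz)
                ],
            }
        )
    mgf.write(spectra, str(path), file_mode="w")


def read_features_mgf(path) -> list[FeatureRecord]:
    out = []
    with mgf.read(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            pepmass = params["pepmass"]
            mz0 = pepmass[0] if isinstance(pepmass, (tuple, list)) else float(pepmass)
            lam = params.get("uv_lambda_max")
            out.append(
                FeatureRecord(
                    retention_time=float(params.get("rtinseconds", 0.0)) / 60.0,
                    precursor_mz=float(mz0),
                    fragments=tuple(
                        FragmentPeak(float(mz), float(inten))
                        for mz, inten in zip(spec["m/z array"], spec["intensity array"])
                    ),
                    uv_lambda_max=float(lam) if lam is not None else None,
                    feature_id=params.get("title"),
                )
            )
    return out


def write_features_csv(features: list[FeatureRecord], path) -> None:
    """One row per feature; fragments as semicolon-joined mz:intensity pairs."""
    rows = []
    for i, f in enumerate(features):
        rows.append(
            {
                "feature_id": f.feature_id or f"feature-{i + 1}",
                "rt_min": f.retention_time,
                "precursor_mz": f.precursor_mz,
                "uv_lambda_max": f.uv_lambda_max,
                "fragments": ";".join(f"{p.mz:.4f}:{p.intensity:g}" for p in f.fragments),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_features_csv(path) -> list[FeatureRecord]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        frags = []
        if isinstance(row.fragments, str) and row.fragments:
            for item in row.fragments.split(";"):
                mz_txt, inten_txt = item.split(":")
                frags.append(FragmentPeak(float(mz_txt), float(inten_txt)))
        lam = None if pd.isna(row.uv_lambda_max) else float(row.uv_lambda_max)
        out.append(
            FeatureRecord(
                retention_time=float(row.rt_min),
                precursor_mz=float(row.precursor_mz),
                fragments=tuple(frags),
                uv_lambda_max=lam,
                feature_id=str(row.feature_id),
            )
        )
    return out


# -- areas and contents ------------------------------------------------------


def write_areas_csv(areas: list[AreaMeasurement], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "analyte": a.analyte,
                "replicate": a.replicate,
                "area": a.peak_area,
                "is_area": a.is_area,
            }
            for a in areas
        ]
    ).to_csv(path, index=False)


def read_areas_csv(path) -> list[AreaMeasurement]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        AreaMeasurement(
            sample_id=str(row.sample_id),
            analyte=str(row.analyte),
            peak_area=float(row.area),
            is_area=float(row.is_area),
            replicate=int(row.replicate),
        )
        for row in df.itertuples(index=False)
    ]


def write_contents_csv(matrix: ContentMatrix, path) -> None:
    """Wide CSV shaped like the content table, with the literal ND sentinel."""
    frame = matrix.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path)


def read_contents_csv(path) -> ContentMatrix:
    return ContentMatrix.from_frame(pd.read_csv(path, index_col="sample_id"))


# -- annotation report -------------------------------------------------------


def write_annotation_report(report: AnnotationReport, csv_path, json_path=None) -> None:
    """CSV mirroring the identification table, plus an optional JSON summary."""
    rows = []
    for r in report.results:
        rows.append(
            {
                "feature_id": r.feature.feature_id,
                "rt_min": r.feature.retention_time,
                "precursor_mz": r.feature.precursor_mz,
                "uv_lambda_max": r.feature.uv_lambda_max,
                "mode": r.mode,
                "compound": r.matched_entry.name if r.matched_entry else "",
                "formula": str(r.assigned_formula) if r.assigned_formula else "",
                "type": r.assigned_type or "",
                "precursor_ppm": r.precursor_ppm,
                "fragment_hits": r.fragment_hits,
                "diagnostics": "; ".join(r.diagnostics),
            }
        )
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report.summary(), indent=2) + "\n")
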