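"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text or PNG: BMD rasters as CSV grids (exact) or 16-bit
PNG with a JSON sidecar carrying {pixel_spacing_mm, bmd_scale, bmd_offset}
(quantised to 1/65535 of the dynamic range); ROIs as GeoJSON polygons with a
"level" property and explicit mm units; meshes and strain fields in a small
OFF-style text format; cohorts and morphometry as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BoneStrainError
from .fem import StrainField
from .mesh import BMDImage, TriMesh, VertebraROI

# ---------------------------------------------------------------------------
# BMD rasters
# ---------------------------------------------------------------------------

def write_bmd_csv(image: BMDImage, path) -> None:
    path = Path(path)
    np.savetxt(path, image.values, delimiter=",", fmt="%.8g")
    sidecar = {"pixel_spacing_mm": image.pixel_spacing_mm, "units": "g/cm^2"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_bmd_csv(path) -> BMDImage:
    path = Path(path)
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    spacing = 1.0
    if sidecar_path.exists():
        spacing = float(json.loads(sidecar_path.read_text())["pixel_spacing_mm"])
    return BMDImage(values=values, pixel_spacing_mm=spacing)


def write_bmd_png(image: BMDImage, path) -> None:
    from PIL import Image

    path = Path(path)
    vmax = float(image.values.max())
    scale = vmax / 65535.0 if vmax > 0 else 1.0
    raw = np.round(image.values / scale).astype(np.uint16) if vmax > 0 \
        else np.zeros_like(image.values, dtype=np.uint16)
    Image.fromarray(raw).save(path)   # uint16 array -> 16-bit greyscale PNG
    sidecar = {"pixel_spacing_mm": image.pixel_spacing_mm,
               "bmd_scale": scale, "bmd_offset": 0.0, "units": "g/cm^2"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_bmd_png(path) -> BMDImage:
    from PIL import Image

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    raw = np.asarray(Image.open(path), dtype=float)
    values = raw * float(sidecar["bmd_scale"]) + float(sidecar.get("bmd_offset", 0.0))
    return BMDImage(values=values, pixel_spacing_mm=float(sidecar["pixel_spacing_mm"]))


def read_bmd_image(path) -> BMDImage:
    """Dispatch on extension: .csv grid or 16-bit .png with sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        return read_bmd_png(path)
    return read_bmd_csv(path)


# ---------------------------------------------------------------------------
# ROIs (GeoJSON)
# ---------------------------------------------------------------------------

def write_rois_geojson(rois, path) -> None:
    features = []
    for roi in rois:
        ring = np.vstack([roi.contour, roi.contour[:1]])
        features.append({
            "type": "Feature",
            "properties": {"level": roi.level, "units": "mm"},
            "geometry": {"type": "Polygon",
                         "coordinates": [[[float(x), float(y)] for x, y in ring]]},
        })
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, indent=2))


def read_rois_geojson(path) -> list:
    doc = json.loads(Path(path).read_text())
    rois = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise BoneStrainError("ROI features must be Polygons")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        rois.append(VertebraROI(level=str(feat["properties"]["level"]),
                                contour=ring))
    return rois


# ---------------------------------------------------------------------------
# Mesh / strain field (OFF-style text)
# ---------------------------------------------------------------------------

def write_mesh_off(mesh: TriMesh, path, field: StrainField | None = None) -> None:
    """OFF-style dump: node/triangle tables plus named per-element columns."""
    lines = ["BSMESH 1", f"level {mesh.level or '-'}",
             f"{len(mesh.nodes)} {len(mesh.triangles)}"]
    for x, y in mesh.nodes:
        lines.append(f"{float(x)!r} {float(y)!r}")
    scalars = []
    if mesh.element_bmd is not None:
        scalars.append(("bmd", mesh.element_bmd))
    if mesh.element_modulus is not None:
        scalars.append(("modulus", mesh.element_modulus))
    if field is not None:
        scalars += [("exx", field.exx), ("eyy", field.eyy),
                    ("gxy", field.gxy), ("eq", field.eq)]
    names = " ".join(n for n, _ in scalars)
    lines.append(names if names else "-")
    for k, tri in enumerate(mesh.triangles):
        row = f"{tri[0]} {tri[1]} {tri[2]}"
        for _, arr in scalars:
            row += f" {float(arr[k])!r}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh_off(path):
    """Read a BSMESH file; returns (TriMesh, StrainField | None)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("BSMESH"):
        raise BoneStrainError("not a BSMESH file")
    level = lines[1].split(None, 1)[1]
    level = "" if level == "-" else level
    n_nodes, n_tris = map(int, lines[2].split())
    nodes = np.array([[float(v) for v in lines[3 + i].split()]
                      for i in range(n_nodes)])
    header = lines[3 + n_nodes]
    names = [] if header == "-" else header.split()
    tris = np.empty((n_tris, 3), dtype=np.int64)
    cols = {n: np.empty(n_tris) for n in names}
    for k in range(n_tris):
        parts = lines[4 + n_nodes + k].split()
        tris[k] = [int(v) for v in parts[:3]]
        for j, n_ in enumerate(names):
            cols[n_][k] = float(parts[3 + j])
    mesh = TriMesh(nodes=nodes, triangles=tris,
                   element_bmd=cols.get("bmd"),
                   element_modulus=cols.get("modulus"), level=level)
    field = None
    if all(n in cols for n in ("exx", "eyy", "gxy", "eq")):
        field = StrainField(exx=cols["exx"], eyy=cols["eyy"], gxy=cols["gxy"],
                            eq=cols["eq"], area_mm2=mesh.areas())
    return mesh, field


# ---------------------------------------------------------------------------
# Cohorts, morphometry, reports
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["id", "sex", "age", "weight_kg", "height_cm",
                  "bsi", "bmd", "tbs", "time_days", "event"]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format="%.10g")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("time_days", "event") if c not in df.columns]
    if missing:
        raise BoneStrainError(f"cohort CSV lacks required columns: {missing}")
    if df["id"].duplicated().any():
        raise BoneStrainError("cohort CSV contains duplicated patient ids")
    if (df["time_days"] <= 0).any():
        raise BoneStrainError("cohort times must be positive")
    return df


def write_morphometry_csv(rows, path) -> None:
    """rows: iterable of (id, date_days, VertebralHeights)."""
    recs = [{"id": pid, "date": date, "level": h.level,
             "anterior_mm": h.anterior_mm, "middle_mm": h.middle_mm,
             "posterior_mm": h.posterior_mm, "reference_mm": h.reference_mm}
            for pid, date, h in rows]
    pd.DataFrame(recs).to_csv(path, index=False)


def read_morphometry_csv(path):
    from .sdi import VertebralHeights

    df = pd.read_csv(path)
    rows = []
    for _, r in df.iterrows():
        rows.append((r["id"], float(r["date"]),
                     VertebralHeights(level=r["level"],
                                      anterior_mm=float(r["anterior_mm"]),
                                      middle_mm=float(r["middle_mm"]),
                                      posterior_mm=float(r["posterior_mm"]),
                                      reference_mm=float(r["reference_mm"]))))
    return rows


def write_event_table_csv(events, path) -> None:
    """events: iterable of (id, time_days, event_bool)."""
    pd.DataFrame(events, columns=["id", "time_days", "event"]) \
        .assign(event=lambda d: d["event"].astype(int)) \
        .to_csv(path, index=False)


def write_json_report(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_km_table_csv(km, path) -> None:
    pd.DataFrame({
        "time_days": km.times, "at_risk": km.at_risk, "events": km.n_events,
        "survival": km.survival, "std_err": km.std_err,
        "ci_low": km.ci_low, "ci_high": km.ci_high,
        "reliable": km.reliable.astype(int),
    }).to_csv(path, index=False, float_format="%.6g")


def plot_km(km, path, title: str = "Probability of no refracture") -> None:
    """Step plot with the 95% CI band; the unreliable tail (at-risk < 20% of
    the starting sample) is shaded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    t = np.concatenate([[0.0], km.times])
    s = np.concatenate([[1.0], km.survival])
    lo = np.concatenate([[1.0], km.ci_low])
    hi = np.concatenate([[1.0], km.ci_high])
    ax.step(t, s, where="post", color="#1040c0", label="Kaplan-Meier")
    ax.fill_between(t, lo, hi, step="post", alpha=0.2, color="#1040c0",
                    label="95% CI")
    if not km.reliable.all():
        t_unrel = km.times[~km.reliable]
        ax.axvspan(t_unrel.min(), max(t.max(), t_unrel.max()), alpha=0.15,
                   color="grey", label="at-risk < 20%")
    ax.set_xlabel("days from baseline")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0.0, 1.02)
    ax.set_title(title)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)
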