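"""Bone Strain Index: scalar strain scores and the diagnostic strain map.

The per-vertebra BSI is the area-weighted mean of the element equivalent
strains, multiplied by a fixed dimensionless scale ``k_BSI``; the lumbar BSI
aggregates the vertebral scores by area weighting, mirroring how lumbar BMD
averages L1-L4.  Because the underlying model is linear, the score is
proportional to the applied load and, for a uniform modulus change by a
factor k, scales by 1/k.  Higher scores mean higher strain at the patient's
own physiological load, i.e. a mechanically weaker vertebra.

``K_BSI_DEFAULT`` fixes the score scale so that the default phantom
population (mean areal BMD 0.76 g/cm^2, default material and load models)
lands near the clinically reported lumbar mean of about 5; the commercial
score's normalisation is unpublished, so only relative comparisons are
meaningful across configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoneStrainError
from .fem import (DEFAULT_MATERIAL, DEFAULT_THICKNESS_MM, MaterialModel,
                  assemble_and_solve, compute_strains,
                  make_boundary_conditions, StrainField)
from .load import LoadModel, Patient, vertebral_load
from .mesh import BMDImage, TriMesh, assign_materials, extract_contour, triangulate

__all__ = ["BSIResult", "vertebra_bsi", "lumbar_bsi", "render_strain_map",
           "compute_patient_bsi", "K_BSI_DEFAULT"]

#: Score scale calibrated once against the default phantom population
#: (see docs/methods.md): the population mean equivalent strain of 7.7e-5
#: maps to the reported lumbar mean score of ~5.
K_BSI_DEFAULT = 65000.0


@dataclass
class BSIResult:
    """Per-vertebra and lumbar strain scores for one scan."""

    per_vertebra_bsi: dict                    # level -> score
    lumbar_bsi: float
    per_vertebra_area_mm2: dict
    k_bsi: float
    meshes: dict = field(default_factory=dict)        # level -> TriMesh
    strain_fields: dict = field(default_factory=dict)  # level -> StrainField

    def to_dict(self) -> dict:
        return {
            "per_vertebra_bsi": {k: float(v) for k, v in self.per_vertebra_bsi.items()},
            "lumbar_bsi": float(self.lumbar_bsi),
            "per_vertebra_area_mm2": {k: float(v)
                                      for k, v in self.per_vertebra_area_mm2.items()},
            "k_bsi": float(self.k_bsi),
        }


def vertebra_bsi(field_: StrainField, k_bsi: float = K_BSI_DEFAULT) -> float:
    """Area-weighted mean equivalent strain of one vertebra, scaled by k_BSI."""
    if len(field_.eq) == 0:
        raise BoneStrainError("empty strain field")
    a = field_.area_mm2
    return float(k_bsi * np.sum(field_.eq * a) / np.sum(a))


def lumbar_bsi(per_vertebra_scores: dict, per_vertebra_areas: dict) -> float:
    """Area-weighted mean of the per-vertebra scores."""
    if not per_vertebra_scores:
        raise BoneStrainError("at least one vertebra is required")
    levels = list(per_vertebra_scores)
    s = np.array([per_vertebra_scores[lv] for lv in levels], dtype=float)
    a = np.array([per_vertebra_areas[lv] for lv in levels], dtype=float)
    return float(np.sum(s * a) / np.sum(a))


def compute_patient_bsi(image: BMDImage, rois=None, patient: Patient | None = None,
                        *,
                        material: MaterialModel = DEFAULT_MATERIAL,
                        load_model: LoadModel | None = None,
                        target_edge_mm: float | None = None,
                        segmentation_threshold: float = 0.30,
                        band_fraction: float = 0.08,
                        thickness_mm: float = DEFAULT_THICKNESS_MM,
                        constraint: str = "fixed",
                        k_bsi: float = K_BSI_DEFAULT,
                        load_scale: float = 1.0,
                        keep_fields: bool = True) -> BSIResult:
    """Run the full scan-to-score pipeline for one patient.

    Segments the scan (unless ``rois`` are given), meshes each vertebra at
    ``target_edge_mm`` (default 3x the pixel spacing), maps local BMD to
    elastic modulus, applies the patient-specific compressive load to the
    upper surface with the lower surface supported, solves the plane-stress
    problem and aggregates the equivalent strains into scores.
    """
    if patient is None:
        raise BoneStrainError("patient anthropometrics are required: the "
                              "vertebral load is patient-specific")
    if target_edge_mm is None:
        target_edge_mm = 3.0 * image.pixel_spacing_mm
    if rois is None:
        rois = extract_contour(image, threshold=segmentation_threshold)
    if load_model is None:
        load_model = LoadModel()

    scores: dict = {}
    areas: dict = {}
    meshes: dict = {}
    fields: dict = {}
    for roi in rois:
        mesh = triangulate(roi, target_edge_mm)
        mesh = assign_materials(mesh, image, material)
        force = load_scale * vertebral_load(patient, roi.level, load_model)
        bcs = make_boundary_conditions(mesh, force, band_fraction=band_fraction,
                                       thickness_mm=thickness_mm,
                                       constraint=constraint)
        u = assemble_and_solve(mesh, bcs, poisson=material.poisson)
        field_ = compute_strains(mesh, u, poisson=material.poisson)
        scores[roi.level] = vertebra_bsi(field_, k_bsi)
        areas[roi.level] = float(field_.area_mm2.sum())
        if keep_fields:
            meshes[roi.level] = mesh
            fields[roi.level] = field_

    return BSIResult(per_vertebra_bsi=scores,
                     lumbar_bsi=lumbar_bsi(scores, areas),
                     per_vertebra_area_mm2=areas,
                     k_bsi=k_bsi, meshes=meshes, strain_fields=fields)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def strain_colormap():
    """4-stop ramp blue -> green -> yellow -> red (low to high strain)."""
    from matplotlib.colors import LinearSegmentedColormap
    return LinearSegmentedColormap.from_list(
        "strain", ["#1040c0", "#10a010", "#f0e010", "#d01010"])


def render_strain_map(mesh: TriMesh, field_: StrainField, path,
                      value_range: tuple | None = None,
                      title: str | None = None) -> None:
    """Write a PNG of the mesh with triangles coloured by equivalent strain.

    The colour ramp spans [min, max] of the field (or a fixed user range);
    a uniform field degenerates to the midpoint colour.  Output bytes are
    deterministic for identical inputs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(field_.eq) != len(mesh.triangles):
        raise BoneStrainError("mesh and strain field are inconsistent")
    if value_range is None:
        vmin, vmax = float(field_.eq.min()), float(field_.eq.max())
    else:
        vmin, vmax = value_range
    if vmax - vmin < 1e-15:                    # uniform field: midpoint colour
        span = max(abs(vmax), 1.0)
        vmin, vmax = vmin - span, vmax + span

    fig, ax = plt.subplots(figsize=(4, 6))
    tpc = ax.tripcolor(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles,
                       facecolors=field_.eq, cmap=strain_colormap(),
                       vmin=vmin, vmax=vmax, edgecolors="k", linewidth=0.2)
    ax.set_aspect("equal")
    ax.invert_yaxis()                          # image convention: y downward
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    fig.colorbar(tpc, ax=ax, label="equivalent strain")
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)
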