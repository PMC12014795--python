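"""Standard-format readers/writers and run configuration.

Volumes are written as NIfTI (internal RAS world convention mapped directly
to the NIfTI affine) or NRRD via SimpleITK (LPS on disk, converted on
read/write); the SUV unit travels in a sidecar JSON because neither format
has a unit field.  Annotations use the QuPath GeoJSON dialect
(FeatureCollection with per-feature ``classification.name``), cell tables
are CSV, transform chains are JSON manifests with inline 4x4 matrices or
references to whitespace-separated text files and NIfTI displacement fields.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

from .histology import HistoArea, validate_cell_table
from .transforms import Affine, DisplacementField, TransformChain
from .volumes import ScalarVolume

logger = logging.getLogger("histopet")
if not logger.handlers:
    logging.basicConfig(level=logging.WARNING, format="%(name)s %(levelname)s: %(message)s")

__all__ = [
    "read_volume",
    "write_volume",
    "read_annotations",
    "write_annotations",
    "read_cell_table",
    "write_cell_table",
    "read_transform_chain",
    "write_transform_chain",
    "RunConfig",
    "load_config",
]


def _sidecar(path: Path) -> Path:
    return path.parent / (path.name + ".json")


def write_volume(vol: ScalarVolume, path) -> None:
    """Write NIfTI (.nii/.nii.gz) or NRRD (.nrrd) plus a unit sidecar JSON."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.values.astype(np.float64), affine), str(path))
    elif path.suffix == ".nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        # internal RAS -> ITK LPS
        img.SetOrigin((-vol.origin[0], -vol.origin[1], vol.origin[2]))
        img.SetDirection((-1.0, 0, 0, 0, -1.0, 0, 0, 0, 1.0))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    _sidecar(path).write_text(json.dumps({"unit": vol.unit}, indent=1))


def read_volume(path, expected_unit: str | None = None) -> ScalarVolume:
    """Read a NIfTI/NRRD volume; axis-aligned orientation is required.

    A missing or non-axis-aligned orientation is a hard error — the reader
    never guesses axes.  A sidecar unit that contradicts ``expected_unit``
    logs a warning.
    """
    path = Path(path)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        affine = img.affine
        if affine is None:
            raise ValueError(f"{path.name}: missing orientation information")
        rot = affine[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise ValueError(f"{path.name}: only axis-aligned volumes are supported")
        spacing = np.diag(rot)
        if np.any(spacing <= 0):
            raise ValueError(f"{path.name}: unsupported negative/zero axis scaling")
        values = np.asarray(img.dataobj, dtype=float)
        origin = affine[:3, 3]
    elif path.suffix == ".nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        if not np.allclose(np.abs(direction), np.eye(3), atol=1e-6):
            raise ValueError(f"{path.name}: only axis-aligned volumes are supported")
        values = sitk.GetArrayFromImage(img).T
        spacing = np.asarray(img.GetSpacing())
        o = np.asarray(img.GetOrigin())
        d = np.diag(direction)
        # ITK LPS -> internal RAS: negate x and y of origin and axis directions
        origin = np.array([-o[0], -o[1], o[2]])
        d_ras = np.array([-d[0], -d[1], d[2]])
        for ax in range(3):
            if d_ras[ax] < 0:  # voxel axis runs against RAS: flip into +direction
                values = np.flip(values, axis=ax)
                origin[ax] = origin[ax] - (values.shape[ax] - 1) * spacing[ax]
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    unit = "g/ml"
    sidecar = _sidecar(path)
    if sidecar.exists():
        unit = json.loads(sidecar.read_text()).get("unit", unit)
    if expected_unit is not None and unit != expected_unit:
        logger.warning(
            "%s: sidecar unit %r differs from expected %r", path.name, unit, expected_unit
        )
    return ScalarVolume(values, tuple(spacing), tuple(origin), unit)


def write_annotations(areas: list[HistoArea], path) -> None:
    """Write histo-areas as a QuPath-dialect GeoJSON FeatureCollection."""
    features = []
    for a in areas:
        features.append(
            {
                "type": "Feature",
                "id": a.area_id,
                "geometry": mapping(a.polygon),
                "properties": {
                    "objectType": "annotation",
                    "classification": {"name": a.label},
                    "patient": a.patient_id,
                    "section": a.section,
                    "area_id": a.area_id,
                    "hscore": None if np.isnan(a.hscore) else a.hscore,
                    "area_unit": a.area_unit,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_annotations(path) -> list[HistoArea]:
    """Read a GeoJSON FeatureCollection of annotated PCa areas.

    Coordinates default to micrometres.  Features missing the section
    property raise a per-feature error naming the feature.
    """
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    out: list[HistoArea] = []
    for i, feat in enumerate(data.get("features", [])):
        fid = feat.get("id", f"feature_{i}")
        props = feat.get("properties", {})
        if "section" not in props:
            raise ValueError(f"feature {fid!r}: missing required 'section' property")
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise ValueError(f"feature {fid!r}: invalid geometry ({exc})") from exc
        if not isinstance(geom, (Polygon, MultiPolygon)):
            raise ValueError(f"feature {fid!r}: geometry must be a (Multi)Polygon")
        for g in getattr(geom, "geoms", [geom]):
            if len(g.exterior.coords) < 4:
                raise ValueError(f"feature {fid!r}: ring with fewer than 3 vertices")
        label = (props.get("classification") or {}).get("name", "")
        h = props.get("hscore")
        out.append(
            HistoArea(
                patient_id=str(props.get("patient", "")),
                section=int(props["section"]),
                area_id=str(props.get("area_id", fid)),
                polygon=geom,
                label=label,
                hscore=float("nan") if h is None else float(h),
                area_unit=str(props.get("area_unit", "um^2")),
            )
        )
    return out


def write_cell_table(cells: pd.DataFrame, path) -> None:
    validate_cell_table(cells)
    cells.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_cell_table(df)


def write_transform_chain(chain: TransformChain, path) -> None:
    """Serialize a chain to a JSON manifest with inline 4x4 matrices."""

    def encode(t):
        if isinstance(t, Affine):
            return {"type": "affine", "matrix": t.matrix.tolist()}
        if isinstance(t, DisplacementField):
            raise ValueError("inline displacement fields are not serialized; reference a NIfTI file")
        raise TypeError(f"cannot serialize transform {t!r}")

    doc = {
        "global": [encode(t) for t in chain.global_transforms],
        "sections": (
            None
            if chain.section_transforms is None
            else {str(k): encode(v) for k, v in chain.section_transforms.items()}
        ),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _decode_transform(entry: dict, base: Path):
    kind = entry.get("type")
    if kind == "affine":
        if "matrix" in entry:
            return Affine(np.asarray(entry["matrix"], dtype=float))
        mat = np.loadtxt(base / entry["path"])
        return Affine(mat)
    if kind == "displacement_field":
        vol = nib.load(str(base / entry["path"]))
        arr = np.asarray(vol.dataobj, dtype=float)
        if arr.ndim == 5:  # NIfTI vector convention (x, y, z, 1, 3)
            arr = arr[:, :, :, 0, :]
        affine = vol.affine
        return DisplacementField(arr, np.diag(affine[:3, :3]), affine[:3, 3])
    raise ValueError(f"unknown transform type {kind!r}")


def read_transform_chain(path) -> TransformChain:
    path = Path(path)
    doc = json.loads(path.read_text())
    glob = [_decode_transform(e, path.parent) for e in doc.get("global", [])]
    sections = doc.get("sections")
    sec = (
        None
        if sections is None
        else {int(k): _decode_transform(v, path.parent) for k, v in sections.items()}
    )
    return TransformChain(glob, sec)


class _SpecConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    prostate_half_axes: tuple[float, float, float] = (22.0, 18.0, 20.0)
    n_lesions: int = 3
    lesion_radius_range: tuple[float, float] = (4.0, 9.0)
    section_thickness: float = 4.0
    staining_alpha: list = Field(default_factory=lambda: [1.0, 1.0, 1.0, 1.0])
    n_cells_per_area: int = 400
    uptake_slope: float = 0.09
    uptake_background: float = 0.5
    noise_sd: float = 0.3
    psf_fwhm: float = 4.8
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    misregistration_range: tuple[float, float] = (1.0, 16.0)
    gtv_threshold: float = 4.0


class _ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cohort_i: int = 2
    n_cohort_ii: int = 2
    base: _SpecConfig = Field(default_factory=_SpecConfig)
    cohort_i_overrides: dict = Field(
        default_factory=lambda: {"uptake_slope": 0.09, "psf_fwhm": 4.8, "gtv_threshold": 4.0}
    )
    cohort_ii_overrides: dict = Field(
        default_factory=lambda: {"uptake_slope": 0.18, "psf_fwhm": 4.2, "gtv_threshold": 8.0}
    )


class _AnalysisConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sub_factor: int = 4
    refine: bool = True
    ci_method: str = "bootstrap"
    n_boot: int = 10_000
    dunn_adjustment: str = "none"
    min_volume_ml: float = 1.0
    min_area_um2: float = 400.0
    min_gtv_ml: float = 5.0


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "results"
    verbosity: str = "warning"
    scenario: _ScenarioConfig = Field(default_factory=_ScenarioConfig)
    analysis: _AnalysisConfigModel = Field(default_factory=_AnalysisConfigModel)

    def phantom_scenario(self):
        from .synthetic import CohortScenario, PhantomSpec

        base = PhantomSpec(
            **{
                **self.scenario.base.model_dump(),
                "staining_alpha": tuple(
                    tuple(row) if isinstance(row, (list, tuple)) else row
                    for row in self.scenario.base.staining_alpha
                )
                if isinstance(self.scenario.base.staining_alpha[0], (list, tuple))
                else tuple(self.scenario.base.staining_alpha),
            }
        )
        return CohortScenario(
            n_cohort_i=self.scenario.n_cohort_i,
            n_cohort_ii=self.scenario.n_cohort_ii,
            base_spec=base,
            cohort_i_overrides=self.scenario.cohort_i_overrides,
            cohort_ii_overrides=self.scenario.cohort_ii_overrides,
        )

    def analysis_config(self, seed: int | None = None):
        from .stats import AnalysisConfig

        return AnalysisConfig(
            seed=self.seed if seed is None else seed,
            **self.analysis.model_dump(),
        )


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)
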