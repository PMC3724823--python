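"""File formats: NIfTI volumes, FSL bvec/bval tables, TCK streamlines,
TIFF rotation stacks, CSV profiles, and JSON boundary/truth sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .axis import BoundarySet, RadialityProfile
from .core import DWIVolume, GradientScheme
from .pli import PLIProtocol, PLIStack


class FormatError(ValueError):
    pass


# -- gradient tables (FSL dialect: bvec = 3 rows, bval = 1 row) --------------

def read_gradient_table(bvec_path, bval_path) -> GradientScheme:
    def parse(path, what):
        rows = []
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            row = []
            for col, tok in enumerate(line.split(), 1):
                try:
                    row.append(float(tok))
                except ValueError:
                    raise FormatError(
                        f"{what} {path}: non-numeric token {tok!r} at "
                        f"line {ln}, column {col}") from None
            rows.append(row)
        return rows

    bvec_rows = parse(bvec_path, "bvec")
    bval_rows = parse(bval_path, "bval")
    if len(bvec_rows) != 3:
        raise FormatError(f"bvec must have 3 rows, got {len(bvec_rows)}")
    if len(bval_rows) != 1:
        raise FormatError(f"bval must have 1 row, got {len(bval_rows)}")
    ncols = {len(r) for r in bvec_rows} | {len(bval_rows[0])}
    if len(ncols) != 1:
        raise FormatError(f"bvec/bval column counts differ: {sorted(ncols)}")

    dirs = np.asarray(bvec_rows, dtype=float).T
    bvals = np.asarray(bval_rows[0], dtype=float)
    norms = np.linalg.norm(dirs, axis=1)
    # normalize non-canonical vectors only, so canonical tables round-trip
    # bit-identically
    fix = norms > 0
    fix &= np.abs(norms - 1.0) > 1e-12
    dirs[fix] /= norms[fix, None]
    return GradientScheme(dirs, bvals)


def write_gradient_table(scheme: GradientScheme, bvec_path, bval_path) -> None:
    fmt = "%.17g"
    with open(bvec_path, "w") as f:
        for row in scheme.directions.T:
            f.write(" ".join(fmt % v for v in row) + "\n")
    with open(bval_path, "w") as f:
        f.write(" ".join(fmt % v for v in scheme.bvalues) + "\n")


# -- NIfTI volumes ------------------------------------------------------------

def save_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def load_volume(path):
    """Returns (data, affine). Accepts 3D or 4D images."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume: {p}")
    img = nib.load(str(p))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim not in (3, 4):
        raise FormatError(f"{p}: expected a 3D or 4D image, got {data.ndim}D")
    return data, img.affine


def load_mask(path, any_nonzero: bool = False):
    """Strict binary mask loader: values other than 0/1 are rejected
    unless ``any_nonzero`` is set."""
    data, affine = load_volume(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: mask must be 3D")
    if not any_nonzero:
        vals = np.unique(data)
        bad = vals[~np.isin(vals, (0.0, 1.0))]
        if bad.size:
            raise FormatError(
                f"{path}: mask contains non-binary values {bad[:5]}; "
                "pass any_nonzero to coerce")
    return data != 0, affine


def save_dwi(dwi: DWIVolume, nifti_path, bvec_path, bval_path) -> None:
    save_volume(nifti_path, dwi.signal, dwi.affine)
    write_gradient_table(dwi.scheme, bvec_path, bval_path)


def load_dwi(nifti_path, bvec_path, bval_path) -> DWIVolume:
    data, affine = load_volume(nifti_path)
    if data.ndim != 4:
        raise FormatError(f"{nifti_path}: DWI must be 4D")
    scheme = read_gradient_table(bvec_path, bval_path)
    return DWIVolume(signal=data, scheme=scheme, affine=affine)


# -- streamlines (MRtrix TCK) -------------------------------------------------

def save_streamlines(sset, path) -> None:
    from nibabel.streamlines import Tractogram
    from nibabel.streamlines.tck import TckFile
    t = Tractogram(streamlines=list(sset.streamlines),
                   affine_to_rasmm=np.eye(4))
    TckFile(t).save(str(path))


def load_streamlines(path) -> list:
    from nibabel.streamlines import load as nib_load
    return [np.asarray(s) for s in nib_load(str(path)).streamlines]


# -- PLI stacks ---------------------------------------------------------------

def save_pli_stack(stack: PLIStack, tiff_path, protocol_path) -> None:
    import tifffile
    tifffile.imwrite(str(tiff_path), stack.images.astype(np.float32),
                     photometric="minisblack")
    proto = dict(mode=stack.protocol.mode,
                 rotation_angles=list(stack.protocol.rotation_angles),
                 pixel_size=list(stack.protocol.pixel_size),
                 section_thickness=stack.protocol.section_thickness,
                 delta_max=stack.protocol.delta_max)
    Path(protocol_path).write_text(json.dumps(proto, indent=2))


def load_pli_stack(tiff_path, protocol_path) -> PLIStack:
    import tifffile
    images = np.asarray(tifffile.imread(str(tiff_path)), dtype=float)
    proto = json.loads(Path(protocol_path).read_text())
    protocol = PLIProtocol(mode=proto["mode"],
                           rotation_angles=tuple(proto["rotation_angles"]),
                           pixel_size=tuple(proto["pixel_size"]),
                           section_thickness=proto["section_thickness"],
                           delta_max=proto["delta_max"])
    return PLIStack(images=images, protocol=protocol)


# -- profiles / boundaries / truth sidecars ----------------------------------

def save_profile_csv(profile: RadialityProfile, path) -> None:
    df = pd.DataFrame({
        "sample": np.arange(profile.n_samples),
        "arc_length_mm": profile.arc_length,
        "mean_angle_deg": profile.mean_angle,
        "n_voxels": profile.voxel_count,
    })
    df.to_csv(path, index=False, float_format="%.10g")


def load_profile_csv(path, subject_id: str = "", hemisphere: str = ""
                     ) -> RadialityProfile:
    df = pd.read_csv(path)
    return RadialityProfile(mean_angle=df["mean_angle_deg"].to_numpy(),
                            voxel_count=df["n_voxels"].to_numpy(),
                            arc_length=df["arc_length_mm"].to_numpy(),
                            subject_id=subject_id, hemisphere=hemisphere)


def save_boundaries_json(boundaries: BoundarySet, path) -> None:
    Path(path).write_text(json.dumps(dict(
        b_45_mm=boundaries.b_45, b_min_mm=boundaries.b_min,
        level=boundaries.level, search_radius_mm=boundaries.search_radius,
    ), indent=2))


def load_boundaries_json(path) -> BoundarySet:
    d = json.loads(Path(path).read_text())
    return BoundarySet(b_45=d["b_45_mm"], b_min=d["b_min_mm"],
                       level=d["level"],
                       search_radius=d.get("search_radius_mm", 0.0))


def save_truth_sidecar(truth, labels_path, json_path) -> None:
    save_volume(labels_path, truth.segment_labels.astype(np.int16),
                truth.affine)
    Path(json_path).write_text(json.dumps(dict(
        planted_boundaries_mm=list(truth.planted_boundaries),
        total_arc_length_mm=truth.total_arc_length,
        ac_point_mm=list(truth.ac_point),
        arc_points_mm=[list(p) for p in truth.arc],
    ), indent=2))
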