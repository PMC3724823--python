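"""End-to-end pipeline driver: phantom/real input -> tensors -> axis ->
boundaries -> segmentation -> tracking -> bundles -> endpoint maps."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import axis as axmod
from . import io as iomod
from . import phantom as phmod
from . import tensor as tmod
from . import tracking as trmod
from .core import default_scheme

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the published values where
    stated (45 axis samples, 45-degree criterion, 10 mm refinement radius,
    500 seeds, 2 mm curvature radius, 30 mm minimum length, 0.05 amplitude
    cutoff, 60 directions at b = 1000 s/mm^2)."""

    # input: phantom block (used when dwi_path is None)
    phantom: dict = field(default_factory=dict)
    # input: real-data paths
    dwi_path: str | None = None
    bvec_path: str | None = None
    bval_path: str | None = None
    mask_path: str | None = None
    ac_point: tuple | None = None

    # stage parameters
    n_samples: int = 45
    central_window: tuple = (0.25, 0.65)
    head_window: tuple = (0.60, 0.90)
    refine_radius_mm: float = 10.0
    n_seeds: int = 500
    step_mm: float = 0.5
    curvature_radius_mm: float = 2.0
    min_length_mm: float = 30.0
    amplitude_cutoff: float = 0.05
    cutoff_mode: str = "absolute"
    n_directions: int = 60
    bvalue: float = 1000.0
    snr: float = 25.0
    s0: float = 1.0
    rule_file: str | None = None

    rng_seed: int = 0
    out_dir: str = "cnparcel_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("central_window", "head_window", "ac_point"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a dict of artifact paths and results.

    Two runs with the same config and seed produce identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    stage = "input"
    try:
        if config.dwi_path is None:
            truth = phmod.make_cn_phantom(**config.phantom)
            scheme = default_scheme(config.n_directions, config.bvalue)
            sigma = config.s0 / config.snr if config.snr else 0.0
            dwi = phmod.simulate_dwi(truth, scheme, s0=config.s0,
                                     noise_sigma=sigma,
                                     rng_seed=config.rng_seed)
            mask = truth.mask
            ac_point = truth.ac_point
            posterior_hint = truth.arc[0]
            iomod.save_dwi(dwi, out / "dwi.nii", out / "dwi.bvec",
                           out / "dwi.bval")
            iomod.save_volume(out / "mask.nii", mask.astype(np.int16),
                              truth.affine)
            iomod.save_truth_sidecar(truth, out / "truth_labels.nii",
                                     out / "truth.json")
            artifacts["truth"] = str(out / "truth.json")
        else:
            truth = None
            dwi = iomod.load_dwi(config.dwi_path, config.bvec_path,
                                 config.bval_path)
            mask, _ = iomod.load_mask(config.mask_path)
            if config.ac_point is None:
                raise ValueError("ac_point is required for real data")
            ac_point = np.asarray(config.ac_point, dtype=float)
            posterior_hint = None

        stage = "tensor"
        field_ = tmod.fit_tensors(dwi, mask)
        iomod.save_volume(out / "fa.nii", field_.fa, field_.affine)
        iomod.save_volume(out / "principal_dir.nii", field_.principal_dir,
                          field_.affine)
        iomod.save_volume(out / "rgb.nii", tmod.direction_color_map(field_),
                          field_.affine)
        artifacts["fa"] = str(out / "fa.nii")

        stage = "axis"
        spline = axmod.fit_longitudinal_spline(
            mask, dwi.affine, ac_point, n_samples=config.n_samples,
            posterior_hint=posterior_hint)
        profile = axmod.radiality_profile(field_, spline, mask)
        iomod.save_profile_csv(profile, out / "profile.csv")
        artifacts["profile"] = str(out / "profile.csv")

        stage = "boundaries"
        group = axmod.detect_group_boundaries(
            [profile], central_window=config.central_window,
            head_window=config.head_window)
        subject = axmod.refine_subject_boundaries(
            profile, group, radius=config.refine_radius_mm)
        iomod.save_boundaries_json(group, out / "boundaries_group.json")
        iomod.save_boundaries_json(subject, out / "boundaries_subject.json")
        artifacts["boundaries"] = str(out / "boundaries_subject.json")

        stage = "segment"
        labels = axmod.segment_cn(mask, dwi.affine, spline, subject)
        iomod.save_volume(out / "labels.nii", labels, dwi.affine)
        artifacts["labels"] = str(out / "labels.nii")

        stage = "track"
        dfield = trmod.DirectionField.from_tensor_field(field_)
        sset = trmod.track_streamlines(
            dfield, mask, n_seeds=config.n_seeds, step=config.step_mm,
            curvature_radius=config.curvature_radius_mm,
            min_length=config.min_length_mm,
            amplitude_cutoff=config.amplitude_cutoff,
            cutoff_mode=config.cutoff_mode, rng_seed=config.rng_seed)
        iomod.save_streamlines(sset, out / "streamlines.tck")
        artifacts["streamlines"] = str(out / "streamlines.tck")

        stage = "bundles"
        if config.rule_file:
            rules = load_rule_file(config.rule_file)
            assignment = trmod.classify_bundles(sset, rules)
        else:
            assignment = {"unassigned": list(range(len(sset)))}
        rows = ["streamline,label"]
        for label, idxs in sorted(assignment.items()):
            rows.extend(f"{i},{label}" for i in idxs)
        (out / "bundles.csv").write_text("\n".join(rows) + "\n")
        artifacts["bundles"] = str(out / "bundles.csv")

        stage = "endpoints"
        volumes = trmod.endpoint_density(sset, labels, dwi.affine)
        for lab, vol in sorted(volumes.items()):
            p = out / f"endpoints_segment{lab}.nii"
            iomod.save_volume(p, vol.astype(np.int32), dwi.affine)
            artifacts[f"endpoints_{lab}"] = str(p)

        logged = asdict(config)
        logged.pop("out_dir")  # keeps the log byte-identical across reruns
        runlog = dict(parameters=logged,
                      n_streamlines=len(sset),
                      boundaries=dict(group=dict(b_45=group.b_45,
                                                 b_min=group.b_min),
                                      subject=dict(b_45=subject.b_45,
                                                   b_min=subject.b_min)))
        (out / "run_log.json").write_text(json.dumps(runlog, indent=2,
                                                     default=str))
        artifacts["run_log"] = str(out / "run_log.json")
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}; completed artifacts: "
            f"{artifacts}") from err

    return dict(artifacts=artifacts, group=group, subject=subject,
                n_streamlines=len(sset))


def load_rule_file(path) -> "trmod.BundleRuleSet":
    """YAML bundle rules: a list of {label, include, exclude} entries plus
    a masks mapping of name -> NIfTI path."""
    raw = yaml.safe_load(Path(path).read_text())
    masks = {}
    affine = None
    for name, mpath in raw.get("masks", {}).items():
        m, aff = iomod.load_mask(mpath, any_nonzero=True)
        masks[name] = m
        affine = aff
    rules = [trmod.BundleRule(label=r["label"],
                              include=[list(g) for g in r.get("include", [])],
                              exclude=list(r.get("exclude", [])))
             for r in raw.get("rules", [])]
    return trmod.BundleRuleSet(rules=rules, masks=masks, affine=affine)
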