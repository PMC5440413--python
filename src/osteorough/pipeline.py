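"""Study orchestration: baseline calibration and study scoring from one config.

Two workflows mirror how a longitudinal arthritis study is analysed:

1. :func:`calibrate_baseline` pools normal-angle fields of all baseline
   (pre-immunization / control) surfaces into one composite histogram per
   (surface kind, radius) and derives the threshold angle ``T``.
2. :func:`run_study` scores every stack (VOI volume, roughness at all radii
   and surfaces, optional SUV) against those calibrations and, when group
   labels are present, runs the arthritic-vs-control comparison.

Stacks may be given as file paths or as in-memory :class:`ImageStack`
objects (e.g. phantoms); set ``stacks_are_vois`` when they are already
cut-out VOIs rather than whole scan scenes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .image_io import ImageStack, load_stack
from .quantify import suv as suv_op
from .quantify import voi_volume
from .roughness import (
    DEFAULT_RADII,
    RoughnessCalibration,
    calibrate,
    mean_neighbor_angle,
    multi_radius_profile,
)
from .surface import SURFACE_KINDS, otsu_threshold, split_surfaces
from .groupstats import compare_groups
from .voi import extract_vois

log = logging.getLogger(__name__)


@dataclass
class StackEntry:
    """One scan (or ready-made VOI) with its study metadata."""

    id: str
    stack: ImageStack | None = None
    path: str | None = None
    group: str = ""
    timepoint: str = ""
    role: str = "study"  # "baseline" | "study" | "both"
    activity: ImageStack | None = None
    pet_path: str | None = None
    injected_bq: float | None = None
    body_weight_g: float | None = None

    def load(self) -> ImageStack:
        if self.stack is None:
            if self.path is None:
                raise ValueError(f"stack {self.id}: neither data nor path given")
            self.stack = load_stack(self.path)
        return self.stack

    def load_activity(self) -> ImageStack | None:
        if self.activity is None and self.pet_path is not None:
            self.activity = load_stack(self.pet_path)
        return self.activity


@dataclass
class StudyConfig:
    """All parameters of one calibration + scoring run."""

    stacks: list[StackEntry]
    stacks_are_vois: bool = False
    voi_params: dict = field(default_factory=dict)
    radii: tuple[float, ...] = DEFAULT_RADII
    surfaces: tuple[str, ...] = SURFACE_KINDS
    bin_width_deg: float = 0.5
    suv_threshold_frac: float = 0.40
    out_dir: Path | None = None
    seed: int = 0
    n_boot: int = 10000

    def __post_init__(self) -> None:
        if not self.radii:
            raise ValueError("radii must be non-empty")
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        stacks = [StackEntry(**s) for s in raw.pop("stacks")]
        for s in stacks:
            if s.path is not None and not Path(s.path).exists():
                raise FileNotFoundError(f"stack {s.id}: {s.path}")
        if "radii" in raw:
            raw["radii"] = tuple(raw["radii"])
        if "surfaces" in raw:
            raw["surfaces"] = tuple(raw["surfaces"])
        return cls(stacks=stacks, **raw)


def _stage(name: str, entry_id: str):
    """Context decorator: re-raise stage failures naming stage and input."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed for input {entry_id!r}: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def _vois_of(entry: StackEntry, config: StudyConfig):
    """Yield (voi_id, ImageStack VOI) pairs for one stack entry."""
    stack = entry.load()
    if config.stacks_are_vois:
        yield entry.id, stack
        return
    with _stage("voi_extraction", entry.id):
        results = extract_vois(stack, **config.voi_params)
    for side, res in results.items():
        yield f"{entry.id}/{side}", res.voi


def calibrate_baseline(
    config: StudyConfig,
) -> dict[tuple[str, float], RoughnessCalibration]:
    """Pool baseline angle fields and fit one calibration per (surface, radius).

    Writes one JSON per pair into ``config.out_dir`` when set.  Any stage
    failure aborts with the stage name and the offending input id.
    """
    baseline = [e for e in config.stacks if e.role in ("baseline", "both")]
    if not baseline:
        raise ValueError("config lists no baseline stacks")
    fields: dict[tuple[str, float], list] = {
        (s, r): [] for s in config.surfaces for r in config.radii
    }
    for entry in baseline:
        for voi_id, voi in _vois_of(entry, config):
            with _stage("surface_reconstruction", voi_id):
                surfaces = split_surfaces(voi, provenance=voi_id)
            for kind in config.surfaces:
                mesh = surfaces.get(kind)
                if mesh.n_triangles < 2:
                    log.warning("%s: surface %s empty; skipped in calibration", voi_id, kind)
                    continue
                for r in config.radii:
                    with _stage("angle_field", voi_id):
                        fields[(kind, r)].append(
                            mean_neighbor_angle(mesh, r, voi.pitch_um,
                                                mesh_id=f"{voi_id}:{kind}")
                        )
    calibrations = {}
    for (kind, r), flist in fields.items():
        if not flist:
            raise _StageError(f"stage 'calibration' failed for input {kind!r}@r={r}: "
                              "no baseline angle fields")
        with _stage("calibration", f"{kind}@r={r}"):
            cal = calibrate(flist, surface=kind, bin_width_deg=config.bin_width_deg)
        calibrations[(kind, r)] = cal
        if config.out_dir is not None:
            config.out_dir.mkdir(parents=True, exist_ok=True)
            cal.to_json(config.out_dir / f"calib_{kind}_r{r:g}.json")
    return calibrations


def run_study(
    config: StudyConfig,
    calibrations: dict[tuple[str, float], RoughnessCalibration],
    group_pair: tuple[str, str] | None = None,
) -> dict:
    """Score every stack and (optionally) compare groups.

    Returns ``{"metrics": tidy DataFrame, "comparisons": DataFrame | None}``.
    Metric rows carry full provenance (threshold, calibration id, version).
    """
    for kind in config.surfaces:
        for r in config.radii:
            if (kind, r) not in calibrations:
                raise KeyError(f"missing calibration for surface {kind!r} at radius {r}")
    rows = []
    for entry in config.stacks:
        for voi_id, voi in _vois_of(entry, config):
            with _stage("otsu_threshold", voi_id):
                t = otsu_threshold(voi)
            with _stage("voi_volume", voi_id):
                vol = voi_volume(voi, t, voi_id=voi_id)
            base = dict(voi_id=voi_id, subject=entry.id, group=entry.group,
                        timepoint=entry.timepoint, role=entry.role,
                        threshold=t, version=__version__)
            rows.append(dict(base, surface="", radius_vox=float("nan"),
                             metric="V_mm3", value=vol.volume_mm3, calibration=""))
            with _stage("surface_reconstruction", voi_id):
                surfaces = split_surfaces(voi, threshold=t, provenance=voi_id)
            with _stage("roughness", voi_id):
                prof = multi_radius_profile(
                    surfaces,
                    {k: v for k, v in calibrations.items()},
                    radii=config.radii, pitch_um=voi.pitch_um, voi_id=voi_id,
                    kinds=config.surfaces,
                )
            for _, p in prof.iterrows():
                rows.append(dict(base, surface=p.surface, radius_vox=p.radius_vox,
                                 metric="R", value=p.R,
                                 calibration=f"{p.surface}:r{p.radius_vox:g}"))
            activity = entry.load_activity()
            if activity is not None:
                if entry.injected_bq is None or entry.body_weight_g is None:
                    raise _StageError(
                        f"stage 'suv' failed for input {voi_id!r}: PET stack given "
                        "without injected activity / body weight")
                with _stage("suv", voi_id):
                    s = suv_op(activity, entry.injected_bq, entry.body_weight_g,
                               threshold_frac=config.suv_threshold_frac, voi_id=voi_id)
                rows.append(dict(base, surface="", radius_vox=float("nan"),
                                 metric="SUV", value=s.mean_suv, calibration=""))
    metrics = pd.DataFrame(rows)

    comparisons = None
    study = metrics[(metrics.metric == "R") & (metrics.role != "baseline")]
    groups = sorted(g for g in study.group.unique() if g)
    if group_pair is None and len(groups) == 2:
        group_pair = (groups[0], groups[1])
    if group_pair is not None:
        crows = []
        for (kind, r), sub in study.groupby(["surface", "radius_vox"]):
            a = sub[sub.group == group_pair[0]].value.dropna().to_numpy()
            c = sub[sub.group == group_pair[1]].value.dropna().to_numpy()
            if len(a) == 0 or len(c) == 0 or c.mean() == 0:
                log.warning("comparison skipped for %s r=%g: empty group or zero "
                            "control mean", kind, r)
                continue
            cmp_ = compare_groups(a, c, metric=f"R_{kind}_r{r:g}",
                                  n_boot=config.n_boot, seed=config.seed)
            crows.append(dict(metric=cmp_.metric, surface=kind, radius_vox=r,
                              mu_AR=cmp_.mu_AR, sigma_AR=cmp_.sigma_AR,
                              mu_CO=cmp_.mu_CO, sigma_CO=cmp_.sigma_CO,
                              mu_ratio=cmp_.mu_ratio, sigma_ratio=cmp_.sigma_ratio,
                              ci_low=cmp_.ci_low, ci_high=cmp_.ci_high,
                              significant=cmp_.significant))
        comparisons = pd.DataFrame(crows)

    if config.out_dir is not None:
        config.out_dir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(config.out_dir / "metrics.csv", index=False)
        if comparisons is not None:
            comparisons.to_csv(config.out_dir / "comparisons.csv", index=False)
    return {"metrics": metrics, "comparisons": comparisons}
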