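"""Synthetic longitudinal multimodal cohorts with known ground truth.

Emulates the structure of a 200-subject longitudinal study of conversion to
Alzheimer's dementia: two balanced binary classes -- controls plus stable MCI
(label -1) versus progressive MCI plus AD (label +1) -- observed at four time
points before stable diagnosis (``m24``, ``m18``, ``m12``, ``t0``).  Each
subject carries three registered volume channels (whole-brain, gray-matter and
white-matter surrogates) and a 64-column table of neuropsychological scores.

The group difference is planted as a mean intensity decrement (an atrophy
surrogate) inside a fixed spatial mask of the gray-matter channel, with a
magnitude that grows toward the diagnosis time point; a small subset of score
columns is shifted between classes by a standardized effect size.  Everything
is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import VolumeGrid, smooth_array, write_volume, read_volume

__all__ = [
    "CohortConfig",
    "CohortBundle",
    "SubjectRecord",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "default_effect_mask",
    "default_score_names",
]

DEFAULT_TIMEPOINTS = ("m24", "m18", "m12", "t0")
DEFAULT_CHANNELS = ("whole_brain", "GM", "WM")
NEGATIVE_GROUPS = ("CN", "sMCI")
POSITIVE_GROUPS = ("pMCI", "AD")

# 64 scores and sub-scores drawn from a 7-test neuropsychological battery
# (functional assessment, clock drawing, verbal learning, digit span,
# category fluency, trail making, naming).
_SCORE_BATTERY = (
    ("FAQ", 10),
    ("CLOCK", 5),
    ("AVLT", 15),
    ("DS", 6),
    ("CATFLU", 8),
    ("TMT", 6),
    ("BNT", 14),
)


def default_score_names(n_scores: int) -> list[str]:
    """Human-readable score column names; battery-style for the default 64."""
    if n_scores == sum(n for _, n in _SCORE_BATTERY):
        return [f"{test}_{i + 1:02d}" for test, n in _SCORE_BATTERY for i in range(n)]
    return [f"score_{i:03d}" for i in range(n_scores)]


def default_effect_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """An off-center ellipsoid covering roughly a sixth of the grid.

    Serves as the planted "atrophic region"; its size is chosen so that the
    top decile of an importance map can plausibly lie inside it.
    """
    shape = np.asarray(grid_shape, dtype=float)
    center = shape * np.array([0.45, 0.40, 0.45])
    semi = np.maximum(shape * np.array([0.34, 0.32, 0.34]), 1.0)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")
    d2 = (
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    return d2 <= 1.0


def _as_mask(effect_mask, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Accept a boolean grid or a collection of voxel index triples."""
    if effect_mask is None:
        return default_effect_mask(grid_shape)
    arr = np.asarray(effect_mask)
    if arr.dtype == bool:
        if arr.shape != tuple(grid_shape):
            raise ValueError(
                f"effect_mask shape {arr.shape} does not match grid {grid_shape}"
            )
        return arr
    idx = np.atleast_2d(arr).astype(int)
    if idx.shape[1] != 3:
        raise ValueError("effect_mask indices must be (n, 3) voxel triples")
    if (idx < 0).any() or (idx >= np.asarray(grid_shape)).any():
        raise ValueError("effect_mask indices fall outside the grid")
    mask = np.zeros(grid_shape, dtype=bool)
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask


@dataclass
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    Defaults mirror the study design the pipeline targets: 100 subjects per
    binary class, four time points, three volume channels on a 20x24x20 grid
    of 2 mm voxels, and 64 neuropsychological scores of which 8 are
    informative.  ``effect_delta_by_timepoint`` gives the mean intensity
    decrement planted in the positive class's gray-matter channel; it must be
    non-decreasing toward the diagnosis time point.
    """

    n_per_class: int = 100
    grid_shape: tuple[int, int, int] = (20, 24, 20)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    effect_mask: np.ndarray | None = None
    effect_delta_by_timepoint: dict[str, float] | None = None
    noise_sd: float = 1.0
    base_smooth_fwhm_mm: float = 4.0
    n_scores: int = 64
    n_informative_scores: int = 8
    score_effect_d: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3 or any(g < 3 for g in self.grid_shape):
            raise ValueError(
                f"grid_shape {self.grid_shape} too small: every axis needs >= 3 voxels"
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        self.timepoints = tuple(self.timepoints)
        self.channels = tuple(self.channels)
        self.effect_mask = _as_mask(self.effect_mask, self.grid_shape)
        if self.effect_delta_by_timepoint is None:
            deltas = np.linspace(0.3, 0.65, num=len(self.timepoints))
            self.effect_delta_by_timepoint = {
                tp: float(d) for tp, d in zip(self.timepoints, deltas)
            }
        missing = set(self.timepoints) - set(self.effect_delta_by_timepoint)
        if missing:
            raise ValueError(f"effect_delta missing for timepoints {sorted(missing)}")
        seq = [self.effect_delta_by_timepoint[tp] for tp in self.timepoints]
        if any(d < 0 for d in seq):
            raise ValueError("effect deltas must be non-negative")
        if any(b < a - 1e-12 for a, b in zip(seq, seq[1:])):
            raise ValueError(
                "effect deltas must be non-decreasing along the timepoint order"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.base_smooth_fwhm_mm < 0:
            raise ValueError("base_smooth_fwhm_mm must be non-negative")
        if not (0 <= self.n_informative_scores <= self.n_scores):
            raise ValueError("need 0 <= n_informative_scores <= n_scores")

    @property
    def effect_channel(self) -> str:
        """Channel carrying the planted effect: GM if present, else the first."""
        return "GM" if "GM" in self.channels else self.channels[0]


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    binary_label: int
    volumes: dict[tuple[str, str], VolumeGrid]
    scores: dict[str, np.ndarray]


@dataclass
class CohortBundle:
    """A generated cohort plus the ground truth used to plant its effects."""

    subjects: list[SubjectRecord]
    config: CohortConfig
    truth: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def binary_labels(self) -> np.ndarray:
        return np.array([s.binary_label for s in self.subjects], dtype=int)

    def groups(self) -> list[str]:
        return [s.group for s in self.subjects]

    def score_matrix(self, timepoint: str) -> np.ndarray:
        return np.stack([s.scores[timepoint] for s in self.subjects])

    def volume_array(self, timepoint: str, channel: str) -> np.ndarray:
        """(n_subjects, *grid_shape) stack of raw intensities."""
        return np.stack(
            [s.volumes[(timepoint, channel)].intensities for s in self.subjects]
        )


def _group_sequence(n_per_class: int) -> list[tuple[str, int]]:
    neg = [(NEGATIVE_GROUPS[i * len(NEGATIVE_GROUPS) // n_per_class], -1)
           for i in range(n_per_class)]
    pos = [(POSITIVE_GROUPS[i * len(POSITIVE_GROUPS) // n_per_class], +1)
           for i in range(n_per_class)]
    return neg + pos


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Draw a full cohort from the generative model; deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    n_total = 2 * config.n_per_class
    score_names = default_score_names(config.n_scores)
    informative = np.sort(
        rng.choice(config.n_scores, size=config.n_informative_scores, replace=False)
    )
    mask = config.effect_mask
    affine = np.diag([*config.voxel_size_mm, 1.0])

    subjects: list[SubjectRecord] = []
    for i, (group, label) in enumerate(_group_sequence(config.n_per_class)):
        volumes: dict[tuple[str, str], VolumeGrid] = {}
        scores: dict[str, np.ndarray] = {}
        for tp in config.timepoints:
            delta = config.effect_delta_by_timepoint[tp]
            for ch in config.channels:
                vol = rng.normal(0.0, config.noise_sd, size=config.grid_shape)
                if config.base_smooth_fwhm_mm > 0:
                    vol = smooth_array(
                        vol, config.voxel_size_mm, config.base_smooth_fwhm_mm
                    )
                if label == +1 and ch == config.effect_channel:
                    vol[mask] -= delta
                volumes[(tp, ch)] = VolumeGrid(
                    intensities=vol,
                    voxel_size_mm=config.voxel_size_mm,
                    channel=ch,
                    affine=affine,
                )
            sc = rng.normal(0.0, 1.0, size=config.n_scores)
            if label == +1 and config.n_informative_scores > 0:
                sc[informative] += config.score_effect_d
            scores[tp] = sc
        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:04d}",
                group=group,
                binary_label=label,
                volumes=volumes,
                scores=scores,
            )
        )
    truth = {
        "effect_mask": mask,
        "informative_scores": informative,
        "score_names": score_names,
    }
    assert len(subjects) == n_total
    return CohortBundle(subjects=subjects, config=config, truth=truth)


# --------------------------------------------------------------------------
# serialization


def write_cohort(bundle: CohortBundle, directory: str | Path) -> Path:
    """Write NIfTI volumes, a score/label CSV and a JSON manifest.

    Returns the manifest path.  The manifest is written last so a failed
    export never leaves a manifest pointing at missing files.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {directory}: {exc}") from exc

    cfg = bundle.config
    volume_files = []
    for s in bundle.subjects:
        for (tp, ch), vol in s.volumes.items():
            fname = f"{s.subject_id}_{tp}_{ch}.nii"
            try:
                write_volume(vol, directory / fname)
            except OSError as exc:
                raise OSError(f"failed writing {directory / fname}: {exc}") from exc
            volume_files.append(
                {"file": fname, "subject_id": s.subject_id,
                 "timepoint": tp, "channel": ch}
            )

    score_names = bundle.truth["score_names"]
    rows = []
    for s in bundle.subjects:
        for tp in cfg.timepoints:
            rows.append(
                {"subject_id": s.subject_id, "group": s.group, "timepoint": tp,
                 **dict(zip(score_names, s.scores[tp]))}
            )
    scores_path = directory / "scores.csv"
    pd.DataFrame(rows).to_csv(scores_path, index=False)

    manifest = {
        "n_subjects": bundle.n_subjects,
        "timepoints": list(cfg.timepoints),
        "channels": list(cfg.channels),
        "grid_shape": list(cfg.grid_shape),
        "voxel_size_mm": list(cfg.voxel_size_mm),
        "scores_file": "scores.csv",
        "score_names": list(score_names),
        "volumes": volume_files,
        "truth": {
            "effect_mask_indices": np.argwhere(bundle.truth["effect_mask"]).tolist(),
            "informative_scores": np.asarray(
                bundle.truth["informative_scores"]
            ).tolist(),
        },
        "config": {
            "n_per_class": cfg.n_per_class,
            "noise_sd": cfg.noise_sd,
            "base_smooth_fwhm_mm": cfg.base_smooth_fwhm_mm,
            "effect_delta_by_timepoint": cfg.effect_delta_by_timepoint,
            "n_scores": cfg.n_scores,
            "n_informative_scores": cfg.n_informative_scores,
            "score_effect_d": cfg.score_effect_d,
            "seed": cfg.seed,
        },
    }
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path


def read_cohort(manifest_path: str | Path) -> CohortBundle:
    """Reconstruct a :class:`CohortBundle` from a :func:`write_cohort` export."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    directory = manifest_path.parent

    cfgdict = manifest["config"]
    config = CohortConfig(
        n_per_class=cfgdict["n_per_class"],
        grid_shape=tuple(manifest["grid_shape"]),
        voxel_size_mm=tuple(manifest["voxel_size_mm"]),
        timepoints=tuple(manifest["timepoints"]),
        channels=tuple(manifest["channels"]),
        effect_mask=np.asarray(manifest["truth"]["effect_mask_indices"], dtype=int)
        if manifest["truth"]["effect_mask_indices"]
        else np.zeros(manifest["grid_shape"], dtype=bool),
        effect_delta_by_timepoint=cfgdict["effect_delta_by_timepoint"],
        noise_sd=cfgdict["noise_sd"],
        base_smooth_fwhm_mm=cfgdict["base_smooth_fwhm_mm"],
        n_scores=cfgdict["n_scores"],
        n_informative_scores=cfgdict["n_informative_scores"],
        score_effect_d=cfgdict["score_effect_d"],
        seed=cfgdict["seed"],
    )

    scores_df = pd.read_csv(directory / manifest["scores_file"])
    score_names = manifest["score_names"]

    by_subject: dict[str, dict] = {}
    for entry in manifest["volumes"]:
        rec = by_subject.setdefault(entry["subject_id"], {"volumes": {}})
        vol = read_volume(directory / entry["file"])
        vol.channel = entry["channel"]
        rec["volumes"][(entry["timepoint"], entry["channel"])] = vol

    subjects = []
    for sid in sorted(by_subject):
        sub_scores = scores_df[scores_df.subject_id == sid]
        group = sub_scores.group.iloc[0]
        label = -1 if group in NEGATIVE_GROUPS else +1
        scores = {
            row.timepoint: np.asarray([getattr(row, c) for c in score_names])
            for row in sub_scores.itertuples()
        }
        subjects.append(
            SubjectRecord(
                subject_id=sid, group=group, binary_label=label,
                volumes=by_subject[sid]["volumes"], scores=scores,
            )
        )
    truth = {
        "effect_mask": config.effect_mask,
        "informative_scores": np.asarray(
            manifest["truth"]["informative_scores"], dtype=int
        ),
        "score_names": score_names,
    }
    return CohortBundle(subjects=subjects, config=config, truth=truth)
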