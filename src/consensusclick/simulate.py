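"""Synthetic colony scenes and a behavioural model of volunteer clicking.

Real deployments pair time-lapse photographs with clicks from up to ten
volunteers per image.  This module stands in for both: it plants point
targets (adults, chicks, eggs, "other") in a resized-image frame and
simulates volunteers who miss targets with type-dependent probability,
click with isotropic Gaussian noise, confuse labels, add sporadic false
positives, sometimes stop after a tag limit (missing late targets — with
adult-first ordering this systematically starves chicks), occasionally
classify the same image twice, and occasionally drag a click off the
image.  The output is the raw-classification dialect consumed by the rest
of the pipeline, plus a ground-truth counts table usable as a gold
standard.

Everything is deterministic per (scene seed, click seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LABELS, RAW_COLUMNS
from .retirement import simulate_retirement

__all__ = [
    "Scene",
    "VolunteerProfile",
    "generate_scene",
    "simulate_clicks",
    "simulate_survey",
    "scene_truth_counts",
]

#: Default per-type detection probabilities: chicks are missed far more
#: often than adults (partial concealment by a brooding parent).
DEFAULT_DETECTION = MappingProxyType(
    {"adult": 0.95, "chick": 0.6, "egg": 0.5, "other": 0.8}
)

_TAG_ORDER = {"adult": 0, "chick": 1, "egg": 2, "other": 3}


class PackingError(RuntimeError):
    """Targets could not be placed at the requested minimum separation."""


@dataclass(frozen=True)
class Scene:
    """Ground truth for one synthetic image: planted point targets."""

    width: float
    height: float
    targets: pd.DataFrame  # columns: x, y, type
    seed: int | None = None

    def count(self, target_type: str) -> int:
        return int((self.targets["type"] == target_type).sum())


@dataclass(frozen=True)
class VolunteerProfile:
    """Behavioural parameters of one simulated volunteer.

    Parameters
    ----------
    detection : mapping type -> probability
        Chance of marking a target of each type at all.
    click_noise_px : float
        Scale (standard deviation per axis) of isotropic Gaussian click
        noise, in resized-image pixels.
    confusion : mapping type -> mapping type -> probability, optional
        Label confusion: row ``t`` gives the distribution of the label
        applied to a detected target of true type ``t``.  Rows must sum
        to 1.  ``None`` means labels are always correct.
    false_positive_rate : float
        Expected number of spurious clicks per image (Poisson), placed
        uniformly over the frame.
    tag_limit : int or None
        After this many tags the volunteer may stop marking.
    stop_at_limit_prob : float
        Probability of actually stopping once the tag limit is reached.
    adult_first : bool
        Tag all adults before any chicks/eggs/others, so a tag-limit stop
        falls disproportionately on chicks.
    duplicate_session_prob : float
        Chance of classifying the same image a second time (a platform
        failure mode the duplicate filter removes).
    off_image_prob : float
        Chance, per click, of the marker being dragged beyond the image
        boundary (a touch-device failure mode the bounds filter removes).
    """

    detection: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION)
    )
    click_noise_px: float = 5.0
    confusion: Mapping[str, Mapping[str, float]] | None = None
    false_positive_rate: float = 0.0
    tag_limit: int | None = 30
    stop_at_limit_prob: float = 0.5
    adult_first: bool = False
    duplicate_session_prob: float = 0.0
    off_image_prob: float = 0.0

    def __post_init__(self) -> None:
        for t, p in self.detection.items():
            if t not in LABELS:
                raise ValueError(f"unknown target type {t!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"detection probability for {t!r} outside [0,1]")
        if self.confusion is not None:
            for t, row in self.confusion.items():
                total = sum(row.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"confusion row for {t!r} sums to {total}, not 1"
                    )

    @classmethod
    def ideal(cls, click_noise_px: float = 2.0) -> "VolunteerProfile":
        """Perfect detector: every target found, labels always correct."""
        return cls(
            detection={t: 1.0 for t in LABELS},
            click_noise_px=click_noise_px,
            tag_limit=None,
            stop_at_limit_prob=0.0,
        )

    @classmethod
    def chick_miss(
        cls,
        chick_detection: float = 0.5,
        tag_limit: int = 30,
    ) -> "VolunteerProfile":
        """Profile reproducing the chick-undercount failure modes:

        chicks detected only half the time, and adult-first tagging with a
        hard stop at the tag limit so crowded images starve chicks.
        """
        return cls(
            detection={"adult": 0.95, "chick": chick_detection, "egg": 0.5, "other": 0.8},
            adult_first=True,
            tag_limit=tag_limit,
            stop_at_limit_prob=1.0,
        )


def generate_scene(
    n_adults: int,
    n_chicks: int,
    n_eggs: int = 0,
    n_other: int = 0,
    dims: tuple[float, float] = (1000.0, 562.5),
    min_separation: float = 50.0,
    seed: int | None = None,
    max_tries: int = 10_000,
    edge_margin: float | None = None,
) -> Scene:
    """Place targets uniformly in the frame, at least ``min_separation`` apart.

    Targets keep ``edge_margin`` pixels clear of the frame edge (default
    ``min_separation / 2``, i.e. the packing radius): a bird half outside
    the frame is not a clean point target, and volunteers click inside the
    image.  Placement is rejection sampling with a bounded retry budget;
    an infeasible packing (too many targets for the separation) raises
    :class:`PackingError`.
    """
    counts = {"adult": n_adults, "chick": n_chicks, "egg": n_eggs, "other": n_other}
    if any(c < 0 for c in counts.values()):
        raise ValueError("target counts must be non-negative")
    width, height = dims
    if width <= 0 or height <= 0:
        raise ValueError(f"image dimensions must be positive, got {dims!r}")
    margin = min_separation / 2 if edge_margin is None else edge_margin
    if 2 * margin >= width or 2 * margin >= height:
        raise ValueError("edge margin leaves no room for targets")
    rng = np.random.default_rng(seed)
    placed: list[tuple[float, float, str]] = []
    types = [t for t in ("adult", "chick", "egg", "other") for _ in range(counts[t])]
    rng.shuffle(types)
    for t in types:
        for _ in range(max_tries):
            x = rng.uniform(margin, width - margin)
            y = rng.uniform(margin, height - margin)
            if all(
                math.hypot(x - px, y - py) >= min_separation for px, py, _ in placed
            ):
                placed.append((x, y, t))
                break
        else:
            raise PackingError(
                f"could not place {len(types)} targets at separation "
                f">= {min_separation} in a {width}x{height} frame"
            )
    targets = pd.DataFrame(placed, columns=["x", "y", "type"])
    return Scene(width=width, height=height, targets=targets, seed=seed)


def _original_size(scene: Scene) -> tuple[int, int]:
    # Report the published camera resolution matching the resized frame
    # where one exists; otherwise pretend the frame is the original.
    if (scene.width, scene.height) == (1000.0, 562.5):
        return (1920, 1080)
    if (scene.width, scene.height) == (1000.0, 750.0):
        return (2048, 1536)
    return (int(round(scene.width)), int(round(scene.height)))


def _one_session(
    scene: Scene,
    profile: VolunteerProfile,
    rng: np.random.Generator,
) -> tuple[list[dict], bool]:
    """Simulate one classification session; returns (clicks, stopped_early)."""
    targets = scene.targets
    order = np.arange(len(targets))
    if profile.adult_first:
        order = np.array(
            sorted(order, key=lambda i: _TAG_ORDER[targets["type"].iat[i]])
        )
    clicks: list[dict] = []
    stopped = False
    limit_decided = False  # the stop option is offered once, when reached
    n_tags = 0
    for i in order:
        if (
            profile.tag_limit is not None
            and n_tags >= profile.tag_limit
            and not limit_decided
        ):
            limit_decided = True
            stopped = rng.random() < profile.stop_at_limit_prob
        if stopped:
            break
        true_type = targets["type"].iat[i]
        if rng.random() >= profile.detection.get(true_type, 0.0):
            continue
        x = targets["x"].iat[i] + rng.normal(0, profile.click_noise_px)
        y = targets["y"].iat[i] + rng.normal(0, profile.click_noise_px)
        if profile.confusion is not None and true_type in profile.confusion:
            row = profile.confusion[true_type]
            label = rng.choice(list(row.keys()), p=list(row.values()))
        else:
            label = true_type
        if rng.random() < profile.off_image_prob:
            x, y = _drag_off_image(x, y, scene, rng)
        clicks.append({"x": float(x), "y": float(y), "label": str(label)})
        n_tags += 1
    for _ in range(rng.poisson(profile.false_positive_rate)):
        clicks.append(
            {
                "x": float(rng.uniform(0, scene.width)),
                "y": float(rng.uniform(0, scene.height)),
                "label": "adult",
            }
        )
    return clicks, stopped


def _drag_off_image(
    x: float, y: float, scene: Scene, rng: np.random.Generator
) -> tuple[float, float]:
    edge = rng.integers(4)
    offset = rng.uniform(1.0, 50.0)
    if edge == 0:
        return (-offset, y)
    if edge == 1:
        return (scene.width + offset, y)
    if edge == 2:
        return (x, -offset)
    return (x, scene.height + offset)


def simulate_clicks(
    scene: Scene,
    volunteers: Sequence[VolunteerProfile],
    seed: int | None = None,
    *,
    subject_id: str = "synthetic_000001",
    path: str | None = None,
    apply_retirement: bool = False,
    timestamp: str = "2014:01:01 12:00:00",
    temperature_f: float = 32.0,
    lunar_phase: str = "full",
) -> pd.DataFrame:
    """Simulate the classification stream for one subject.

    One table row per click; a volunteer who makes no clicks contributes a
    single blank row (``animals_present`` = "no", empty click fields), as
    in the raw dialect.  With ``apply_retirement`` the stream is truncated
    by the platform's retirement rule, so an all-blank start stops the
    stream after the blank window.

    Duplicate sessions, when a profile triggers them, are appended after
    all first sessions, mimicking a later repeat viewing.
    """
    if len(volunteers) == 0:
        raise ValueError("at least one volunteer profile is required")
    rng = np.random.default_rng(seed)
    osx, osy = _original_size(scene)
    meta = {
        "lunar_phase": lunar_phase,
        "original_size_x": osx,
        "original_size_y": osy,
        "path": path if path is not None else f"SYNTH/{subject_id}",
        "temperature_f": temperature_f,
        "timestamp": timestamp,
        "subject_zooniverse_id": subject_id,
    }

    rows: list[dict] = []
    answers: list[str] = []
    repeats: list[tuple[str, VolunteerProfile]] = []
    for v, profile in enumerate(volunteers):
        if apply_retirement and simulate_retirement(answers).retired:
            break
        name = f"volunteer_{v + 1:03d}"
        clicks, stopped = _one_session(scene, profile, rng)
        answers.append("yes" if clicks else "no")
        rows.extend(_session_rows(name, clicks, stopped, meta))
        if rng.random() < profile.duplicate_session_prob:
            repeats.append((name, profile))
    for name, profile in repeats:
        clicks, stopped = _one_session(scene, profile, rng)
        rows.extend(_session_rows(name, clicks, stopped, meta))

    return pd.DataFrame(rows, columns=list(RAW_COLUMNS))


def _session_rows(
    name: str, clicks: list[dict], stopped: bool, meta: dict
) -> list[dict]:
    base = {
        "user_name": name,
        "all_marked": "incomplete" if stopped else "complete",
        **meta,
    }
    if not clicks:
        return [{**base, "animals_present": "no", "value": "", "x": "", "y": ""}]
    return [
        {
            **base,
            "animals_present": "yes",
            "value": c["label"],
            "x": c["x"],
            "y": c["y"],
        }
        for c in clicks
    ]


def scene_truth_counts(
    scene: Scene, image_name: str, marked_complete: bool = True
) -> dict:
    """Gold-standard row (adult and chick counts) for a synthetic scene."""
    return {
        "image_name": image_name,
        "n_adults": scene.count("adult"),
        "n_chicks": scene.count("chick"),
        "contains_animals": len(scene.targets) > 0,
        "marked_complete": marked_complete,
    }


def simulate_survey(
    n_images: int,
    scene_builder,
    volunteers: Sequence[VolunteerProfile],
    seed: int | None = None,
    *,
    apply_retirement: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a batch of images: raw classifications plus gold standard.

    ``scene_builder(index, seed)`` must return a :class:`Scene`; scene and
    click randomness are derived from ``seed`` so the whole survey is
    reproducible.

    Returns
    -------
    raw : DataFrame
        Concatenated raw-classification rows for all images.
    gold : DataFrame
        One gold-standard row per image (true counts).
    """
    root = np.random.default_rng(seed)
    raw_parts: list[pd.DataFrame] = []
    gold_rows: list[dict] = []
    for i in range(n_images):
        scene_seed = int(root.integers(2**31 - 1))
        click_seed = int(root.integers(2**31 - 1))
        scene = scene_builder(i, scene_seed)
        image_name = f"SYNTHa2014a_{i + 1:06d}"
        raw = simulate_clicks(
            scene,
            volunteers,
            seed=click_seed,
            subject_id=image_name,
            path=f"SYNTHa/{image_name}",
            apply_retirement=apply_retirement,
        )
        raw_parts.append(raw)
        gold_rows.append(scene_truth_counts(scene, image_name))
    raw_df = pd.concat(raw_parts, ignore_index=True)
    gold_df = pd.DataFrame(
        gold_rows,
        columns=["image_name", "n_adults", "n_chicks", "contains_animals", "marked_complete"],
    )
    return raw_df, gold_df
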