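"""Synthetic fixtures: face meshes, lag-coupled behavior cohorts, rater panels.

The real study's videos and rater responses cannot be shared, so every
pipeline stage is exercised on generated data with known ground truth:

* an ellipsoidal face mesh with 51 feature-labeled landmarks,
* cohorts of AR(1) behavior channels where chosen channel pairs carry an
  additive lagged coupling whose strength depends on the diagnostic group,
* rater panels drawn from a logistic skill/difficulty model.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning (one child stream per participant, then one per channel; one per
rater panel), so cohorts are reproducible piecewise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .behavior_series import POSE_CHANNELS, BehaviorMatrix
from .mesh_regions import (
    DEFAULT_REGION_COUNTS,
    FaceMesh,
    LocalizedExpressionBasis,
)
from .rater_comparison import RaterPanel

__all__ = [
    "CohortSpec",
    "RaterSpec",
    "SyntheticCohort",
    "default_channel_descriptors",
    "default_coupled_pairs",
    "gen_mesh",
    "gen_behavior_cohort",
    "gen_rater_panel",
    "deformation_from_coefficients",
]

# iBUG-51 feature counts: 10 brow, 12 eye, 9 nose, 20 mouth landmarks
_LANDMARK_COUNTS = {"brow": 10, "eye": 12, "nose": 9, "mouth": 20}

_AR_BURN_IN = 200


def default_channel_descriptors() -> tuple[str, ...]:
    """The 56 canonical channel names: 53 expression channels then pose."""
    names = []
    for region in ("brows_forehead", "eyes", "mouth_chin"):
        for i in range(DEFAULT_REGION_COUNTS[region]):
            names.append(f"{region}_{i + 1:02d}")
    return tuple(names) + POSE_CHANNELS


def default_coupled_pairs(
    n_pairs: int = 20, lag: int = 3, n_channels: int = 56, seed: int = 0
) -> tuple[tuple[int, int, int], ...]:
    """Deterministically sample distinct (source, target, lag) triples."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0)))
    pairs: list[tuple[int, int, int]] = []
    seen = set()
    while len(pairs) < n_pairs:
        i, j = rng.integers(0, n_channels, size=2)
        if i == j or (i, j) in seen:
            continue
        seen.add((int(i), int(j)))
        pairs.append((int(i), int(j), lag))
    return tuple(pairs)


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic cohort.

    Defaults: 15 ASD / 27 NT participants, 3-minute recordings at 30 fps
    (T = 5400), 56 channels.  Each channel is
    an AR(1) process; for every coupled pair (i, j, L) the target channel j
    additionally receives ``beta_group * x_i[t - L]`` computed from channel
    i's base (uncoupled) series.
    """

    n_asd: int = 15
    n_nt: int = 27
    n_frames: int = 5400
    frame_rate: float = 30.0
    ar_coefficient: float = 0.6
    coupled_pairs: tuple[tuple[int, int, int], ...] | None = None
    coupling_strength: dict[str, float] = field(
        default_factory=lambda: {"ASD": 0.9, "NT": 0.0}
    )
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        pairs = (
            default_coupled_pairs(seed=self.seed)
            if self.coupled_pairs is None
            else tuple(tuple(p) for p in self.coupled_pairs)
        )
        object.__setattr__(self, "coupled_pairs", pairs)
        n_ch = len(default_channel_descriptors())
        for src, tgt, lag in pairs:
            if lag < 1:
                raise ValueError(f"lag must be >= 1, got {lag}")
            if lag >= self.n_frames:
                raise ValueError(f"lag {lag} >= series length {self.n_frames}")
            if not (0 <= src < n_ch and 0 <= tgt < n_ch):
                raise ValueError(f"channel out of range in pair ({src}, {tgt})")
        for strength in self.coupling_strength.values():
            if not np.isfinite(strength):
                raise ValueError("coupling strengths must be finite")


@dataclass(frozen=True)
class RaterSpec:
    """Logistic skill/difficulty model of a rater panel.

    P(rater r correct on participant p) = sigmoid(a_r + b_p), with rater
    skill a_r drawn per expertise stratum and participant difficulty b_p
    shared across raters.
    """

    n_experts: int = 8
    n_nonexperts: int = 11
    expert_skill: tuple[float, float] = (1.8, 0.4)
    nonexpert_skill: tuple[float, float] = (1.2, 0.4)
    difficulty: tuple[float, float] = (0.3, 1.0)
    seed: int = 0


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated behavior matrices with labels and generative ground truth."""

    behaviors: tuple[BehaviorMatrix, ...]
    labels: tuple[str, ...]
    participant_ids: tuple[str, ...]
    ground_truth: dict

    def __iter__(self):
        return iter(zip(self.behaviors, self.labels))


def gen_mesh(n_points: int = 200, seed: int = 0) -> FaceMesh:
    """An ellipsoidal face-like point cloud with 51 labeled landmarks.

    Landmarks sit in four anatomically ordered bands (brows above eyes
    above nose above mouth) on the front of the ellipsoid; the remaining
    points are scattered over the front hemisphere.
    """
    if n_points < 51:
        raise ValueError("mesh needs at least 51 points")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xFACE)))
    semi = np.array([1.0, 1.3, 0.8])  # x right, y up, z forward

    def on_surface(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        # project (x, y) onto the front of the ellipsoid
        inside = np.clip(1.0 - (x / semi[0]) ** 2 - (y / semi[1]) ** 2, 0.0, None)
        z = semi[2] * np.sqrt(inside)
        return np.column_stack([x, y, z])

    bands = {
        "brow": (0.55, np.linspace(-0.6, 0.6, _LANDMARK_COUNTS["brow"])),
        "eye": (0.3, np.linspace(-0.55, 0.55, _LANDMARK_COUNTS["eye"])),
        "nose": (-0.05, np.linspace(-0.25, 0.25, _LANDMARK_COUNTS["nose"])),
        "mouth": (-0.55, np.linspace(-0.45, 0.45, _LANDMARK_COUNTS["mouth"])),
    }
    lm_points, lm_features = [], []
    for feature, (y0, xs) in bands.items():
        ys = np.full_like(xs, y0) + rng.normal(0.0, 0.01, size=xs.shape)
        lm_points.append(on_surface(xs + rng.normal(0.0, 0.01, xs.shape), ys))
        lm_features.extend([feature] * len(xs))
    lm_points = np.vstack(lm_points)

    n_extra = n_points - 51
    xs = rng.uniform(-0.95, 0.95, size=n_extra)
    ys = rng.uniform(-1.2, 1.2, size=n_extra)
    extra = on_surface(xs, ys)

    points = np.vstack([lm_points, extra]).T  # (3, P); landmarks first
    return FaceMesh(points, np.arange(51), tuple(lm_features))


def _ar1_channels(
    rng_children, n_channels: int, n_frames: int, phi: float, noise_sd: float
) -> np.ndarray:
    """Stationary AR(1) series per channel, one child stream per channel."""
    total = n_frames + _AR_BURN_IN
    noise = np.empty((n_channels, total))
    for c in range(n_channels):
        noise[c] = np.random.default_rng(rng_children[c]).normal(
            0.0, noise_sd, size=total
        )
    series = lfilter([1.0], [1.0, -phi], noise, axis=1)
    return series[:, _AR_BURN_IN:]


def gen_behavior_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one cohort of lag-coupled behavior matrices.

    Coupling is additive-lagged-linear on top of each channel's own AR(1)
    dynamics, computed from the *base* series of the source channel, so the
    planted lead–lag structure is exactly the configured (source, target,
    lag) set.
    """
    descriptors = default_channel_descriptors()
    n_ch = len(descriptors)
    labels = ("ASD",) * spec.n_asd + ("NT",) * spec.n_nt
    participant_seeds = np.random.SeedSequence(spec.seed).spawn(len(labels))

    behaviors = []
    for pseed, label in zip(participant_seeds, labels):
        beta = spec.coupling_strength.get(label, 0.0)
        channel_seeds = pseed.spawn(n_ch)
        base = _ar1_channels(
            channel_seeds, n_ch, spec.n_frames, spec.ar_coefficient, spec.noise_sd
        )
        values = base.copy()
        for src, tgt, lag in spec.coupled_pairs:
            values[tgt, lag:] += beta * base[src, : spec.n_frames - lag]
        behaviors.append(BehaviorMatrix(values, descriptors, spec.frame_rate))

    ids = tuple(f"p{i:03d}" for i in range(len(labels)))
    truth = {
        "coupled_pairs": [list(p) for p in spec.coupled_pairs],
        "coupling_strength": dict(spec.coupling_strength),
        "ar_coefficient": spec.ar_coefficient,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "labels": list(labels),
    }
    return SyntheticCohort(tuple(behaviors), labels, ids, truth)


def gen_rater_panel(
    rspec: RaterSpec,
    truth: tuple[str, ...] | list[str],
    return_params: bool = False,
) -> RaterPanel | tuple[RaterPanel, dict]:
    """Draw a rater panel: Bernoulli correctness from the logistic link.

    With ``return_params=True`` the sampled rater skills and participant
    difficulties are returned alongside (ground truth for recovery checks).
    """
    truth = tuple(truth)
    classes = sorted(set(truth))
    if len(classes) != 2:
        raise ValueError("truth must contain exactly two classes")
    flipped = {classes[0]: classes[1], classes[1]: classes[0]}
    rng = np.random.default_rng(np.random.SeedSequence((rspec.seed, 0xA7E)))
    skills = np.concatenate(
        [
            rng.normal(*rspec.expert_skill, size=rspec.n_experts),
            rng.normal(*rspec.nonexpert_skill, size=rspec.n_nonexperts),
        ]
    )
    difficulty = rng.normal(*rspec.difficulty, size=len(truth))
    p_correct = 1.0 / (1.0 + np.exp(-(skills[:, None] + difficulty[None, :])))
    correct = rng.random(p_correct.shape) < p_correct
    truth_arr = np.asarray(truth)
    flipped_arr = np.asarray([flipped[t] for t in truth])
    predictions = np.where(correct, truth_arr[None, :], flipped_arr[None, :])
    expertise = ("expert",) * rspec.n_experts + ("non_expert",) * rspec.n_nonexperts
    panel = RaterPanel(predictions, expertise, truth)
    if return_params:
        return panel, {"skills": skills, "difficulty": difficulty}
    return panel


def deformation_from_coefficients(
    coefficients: np.ndarray, basis: LocalizedExpressionBasis
) -> np.ndarray:
    """Mesh-level deformation ``(3, P)`` synthesized from basis coefficients."""
    coefficients = np.asarray(coefficients, dtype=float)
    flat = basis.components @ coefficients
    return flat.reshape(basis.n_points, 3).T
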