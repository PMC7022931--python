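"""Synthetic longitudinal two-class data with known ground truth.

The generator emulates a preprocessed nontargeted-metabolomics feature
table: a cube of 1500 variables x 100 samples (50 per class) x 4 time
points.  Variables come in three kinds:

* profile variables (8 groups of 40) whose per-time means follow fixed
  class profiles drawn from the palette {2.1, 1.7, 1.2, -1.3}; a group is
  discriminative at a time point exactly when its two class means differ
  there (active cells use 2.1 for one class vs -1.3 for the other, the
  extremes of the preprocessed-intensity range);
* "undistinguishable" profile variables whose means vary over time but
  identically for both classes (values 1.7/1.2), mimicking fragments that
  respond to the stimulus without separating the classes;
* a large uninformative background (1180 variables, mean 1.2 for both
  classes at all times), mimicking fragments that rarely respond.

All draws are independent normals with common SD 1.5.  Under the default
profiles, groups 1-4 are discriminative at exactly one time point each
(short-lived markers, types A'-D'), group 5 at all four time points (a
persistent marker, type A), and groups 6-8 are the undistinguishable
trends (types B-D), so 1300 of the 1500 variables are never
discriminative.  Group 9 is the background; selections landing in a
never-discriminative variable are false recoveries.

Randomness is a counter-based stream split per variable (one child
``SeedSequence`` per variable index), so removing or adding variables
does not perturb the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .data import LongitudinalDataset, VariableGroundTruth

__all__ = [
    "GroupProfile",
    "ProfileSet",
    "GeneratorConfig",
    "make_default_profiles",
    "generate_dataset",
    "count_uninformative",
    "BACKGROUND_GROUP",
]

#: mean palette of the simulation design
HIGH, FLAT, LOW, OPPOSITE = 2.1, 1.7, 1.2, -1.3

BACKGROUND_GROUP = 9


@dataclass(frozen=True)
class GroupProfile:
    """Per-time class means for one variable group."""

    pos_means: tuple[float, ...]
    neg_means: tuple[float, ...]

    def discriminative_at(self) -> frozenset[int]:
        return frozenset(
            t for t, (p, n) in enumerate(zip(self.pos_means, self.neg_means)) if p != n
        )


@dataclass(frozen=True)
class ProfileSet:
    """Mapping from profile-group id to its class-mean trajectories.

    ``group_size`` variables are generated per group; ``sd`` is the common
    noise standard deviation of every draw.
    """

    profiles: Mapping[int, GroupProfile]
    group_size: int = 40
    sd: float = 1.5

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        lengths = {len(p.pos_means) for p in self.profiles.values()}
        lengths |= {len(p.neg_means) for p in self.profiles.values()}
        if len(lengths) > 1:
            raise ValueError("all profiles must cover the same number of time points")

    @property
    def n_timepoints(self) -> int:
        return len(next(iter(self.profiles.values())).pos_means)

    def discriminative_at(self) -> dict[int, frozenset[int]]:
        return {g: p.discriminative_at() for g, p in self.profiles.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Sizes of the simulated study; defaults give the 1500 x 100 x 4 cube."""

    n_per_class: int = 50
    n_background: int = 1180
    n_timepoints: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_background < 0 or self.n_timepoints < 1:
            raise ValueError("invalid generator sizes")


def make_default_profiles() -> ProfileSet:
    """The default 8-group profile design over 4 time points.

    Groups 1-4 (types A'-D') carry the class contrast (2.1 vs -1.3) at
    exactly one time point each and sit at the flat mean 1.7 elsewhere;
    group 5 (type A) carries the contrast at all four time points; groups
    6-8 (types B-D) vary over time but identically for the two classes.
    """
    single = {
        g: GroupProfile(
            pos_means=tuple(HIGH if t == g - 1 else FLAT for t in range(4)),
            neg_means=tuple(OPPOSITE if t == g - 1 else FLAT for t in range(4)),
        )
        for g in (1, 2, 3, 4)
    }
    persistent = {5: GroupProfile(pos_means=(HIGH,) * 4, neg_means=(OPPOSITE,) * 4)}
    undistinguishable = {
        6: GroupProfile(pos_means=(FLAT, FLAT, LOW, LOW), neg_means=(FLAT, FLAT, LOW, LOW)),
        7: GroupProfile(pos_means=(LOW, FLAT, FLAT, LOW), neg_means=(LOW, FLAT, FLAT, LOW)),
        8: GroupProfile(pos_means=(FLAT, LOW, FLAT, LOW), neg_means=(FLAT, LOW, FLAT, LOW)),
    }
    return ProfileSet(profiles={**single, **persistent, **undistinguishable})


def generate_dataset(
    profiles: ProfileSet | None = None, config: GeneratorConfig | None = None
) -> tuple[LongitudinalDataset, VariableGroundTruth]:
    """Draw one simulated dataset and its ground truth.

    Sample order is the 50 positive-class samples followed by the 50
    negative-class samples; variable order is the profile groups in id
    order followed by the background block (group 9).
    """
    profiles = profiles if profiles is not None else make_default_profiles()
    config = config if config is not None else GeneratorConfig()
    T = config.n_timepoints
    if profiles.n_timepoints != T:
        raise ValueError(
            f"profiles cover {profiles.n_timepoints} time points, config wants {T}"
        )
    n = 2 * config.n_per_class
    labels = np.concatenate(
        [np.ones(config.n_per_class, dtype=int), -np.ones(config.n_per_class, dtype=int)]
    )
    group_ids = np.concatenate(
        [
            np.repeat(sorted(profiles.profiles), profiles.group_size),
            np.full(config.n_background, BACKGROUND_GROUP),
        ]
    ).astype(int)
    d = len(group_ids)

    mean_pos = np.empty((d, T))
    mean_neg = np.empty((d, T))
    for g in sorted(profiles.profiles):
        rows = group_ids == g
        mean_pos[rows] = profiles.profiles[g].pos_means
        mean_neg[rows] = profiles.profiles[g].neg_means
    mean_pos[group_ids == BACKGROUND_GROUP] = LOW
    mean_neg[group_ids == BACKGROUND_GROUP] = LOW

    cube = np.empty((d, n, T))
    pos_mask = labels == 1
    for v in range(d):
        # one child stream per variable: draws are stable under variable subsetting
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(v,)))
        z = rng.standard_normal((n, T))
        means = np.where(pos_mask[:, None], mean_pos[v][None, :], mean_neg[v][None, :])
        cube[v] = means + profiles.sd * z

    disc = profiles.discriminative_at()
    disc[BACKGROUND_GROUP] = frozenset()
    truth = VariableGroundTruth(group_ids=group_ids, discriminative_at=disc)
    dataset = LongitudinalDataset(
        cube=cube,
        labels=labels,
        variable_ids=[f"v{g}_{i}" for i, g in enumerate(group_ids, start=1)],
        sample_ids=[f"pos{i+1}" if l == 1 else f"neg{i+1-config.n_per_class}" for i, l in enumerate(labels)],
        time_ids=[f"t{t+1}" for t in range(T)],
    )
    return dataset, truth


def count_uninformative(truth: VariableGroundTruth) -> int:
    """Number of variables never discriminative at any time point."""
    return int(truth.uninformative_mask().sum())
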