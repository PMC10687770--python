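"""Category-level summaries of classifier weights.

Each coordination feature joins two channels, so it carries two category
"sides" (brow, eye, mouth, or pose).  Two summaries are provided: mean and
spread of |weight| per unordered category pair, and the share of each
category among the top-k features.  The top-k share supports two counting
conventions:

``slot``
    each feature contributes its two sides separately; the ratio for a
    category is (category slots) / (2k).  Ratios across the four categories
    sum to 1 at every k.
``membership``
    a feature counts once towards every category it touches; ratios can sum
    to more than 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "FeatureCategoryMap",
    "tag_features",
    "region_pair_weight_summary",
    "topk_category_ratio",
]

CATEGORIES = ("brow", "eye", "mouth", "pose")

_REGION_TO_CATEGORY = {
    "brows_forehead": "brow",
    "eyes": "eye",
    "mouth_chin": "mouth",
    "pose": "pose",
}

_NAME_RE = re.compile(r"^(mu|sigma)\((.+)->(.+)\)$")


def _channel_category(descriptor: str) -> str:
    for region, cat in _REGION_TO_CATEGORY.items():
        if descriptor.startswith(region):
            return cat
    raise ValueError(f"cannot categorize channel {descriptor!r}")


@dataclass(frozen=True)
class FeatureCategoryMap:
    """Category sides of every feature, plus the unordered pair label."""

    names: tuple[str, ...]
    side_a: tuple[str, ...]
    side_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not len(self.names) == len(self.side_a) == len(self.side_b):
            raise ValueError("names and sides must align")

    @property
    def n_features(self) -> int:
        return len(self.names)

    def pair_labels(self) -> tuple[str, ...]:
        """Unordered category-pair label per feature, e.g. ``eye-pose``."""
        return tuple(
            "-".join(sorted((a, b))) for a, b in zip(self.side_a, self.side_b)
        )


def tag_features(
    names: tuple[str, ...] | list[str],
    channel_descriptors: tuple[str, ...] | list[str],
) -> FeatureCategoryMap:
    """Map every feature name to its two category sides.

    ``channel_descriptors`` is accepted for interface symmetry and to
    validate that each side names a known channel.
    """
    known = set(channel_descriptors)
    side_a, side_b = [], []
    for name in names:
        m = _NAME_RE.match(name)
        if not m:
            raise ValueError(f"unparseable feature name {name!r}")
        _, ch_a, ch_b = m.groups()
        if ch_a not in known or ch_b not in known:
            raise ValueError(f"feature {name!r} references unknown channels")
        side_a.append(_channel_category(ch_a))
        side_b.append(_channel_category(ch_b))
    return FeatureCategoryMap(tuple(names), tuple(side_a), tuple(side_b))


def region_pair_weight_summary(
    weights: np.ndarray, fmap: FeatureCategoryMap
) -> pd.DataFrame:
    """Mean and std (ddof 0) of |weight| per unordered category pair."""
    weights = np.abs(np.asarray(weights, dtype=float))
    if weights.shape[0] != fmap.n_features:
        raise ValueError("one weight per feature required")
    df = pd.DataFrame({"pair": fmap.pair_labels(), "absw": weights})
    out = (
        df.groupby("pair")["absw"]
        .agg(mean_abs_weight="mean", std_abs_weight=lambda s: s.std(ddof=0))
        .reset_index()
    )
    return out.sort_values("mean_abs_weight", ascending=False, ignore_index=True)


def _ranked_indices(weights: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    """Feature indices by descending |weight|; ties broken by feature name."""
    absw = np.abs(np.asarray(weights, dtype=float))
    order = sorted(range(absw.shape[0]), key=lambda i: (-absw[i], names[i]))
    return np.asarray(order)


def topk_category_ratio(
    weights: np.ndarray,
    fmap: FeatureCategoryMap,
    ks: tuple[int, ...] | None = None,
    convention: str = "slot",
) -> pd.DataFrame:
    """Share of each category among the k highest-|weight| features.

    Returns a tidy frame with columns ``k``, ``category``, ``ratio``.
    ``k = n_features`` rows give the weight-independent baseline rates.
    """
    if convention not in ("slot", "membership"):
        raise ValueError(f"unknown convention {convention!r}")
    M = fmap.n_features
    if ks is None:
        ks = tuple(k for k in (10, 100, 1000) if k <= M) + (M,)
    order = _ranked_indices(weights, fmap.names)
    side_a = np.asarray(fmap.side_a)[order]
    side_b = np.asarray(fmap.side_b)[order]
    rows = []
    for k in ks:
        if not 1 <= k <= M:
            raise ValueError(f"k={k} outside [1, {M}]")
        a, b = side_a[:k], side_b[:k]
        for cat in CATEGORIES:
            if convention == "slot":
                ratio = (np.sum(a == cat) + np.sum(b == cat)) / (2 * k)
            else:
                ratio = np.sum((a == cat) | (b == cat)) / k
            rows.append({"k": int(k), "category": cat, "ratio": float(ratio)})
    return pd.DataFrame(rows)
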