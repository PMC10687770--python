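"""Facial-region partitioning and region-localized expression bases.

A dense face mesh is split into four regions (brows/forehead, eyes,
nose/cheeks, mouth/chin) by nearest-landmark assignment.  A global PCA-style
expression basis is then *localized*: its components are masked to one
region at a time and re-orthonormalized, producing a fixed number of
components per region.  Per-frame deformations are projected onto the
localized basis by least squares, and the nose/cheek coefficients are
dropped from the downstream channel set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "DEFAULT_REGION_COUNTS",
    "FEATURE_TO_REGION",
    "FaceMesh",
    "RegionPartition",
    "GlobalExpressionBasis",
    "LocalizedExpressionBasis",
    "FrameFit",
    "assign_regions",
    "build_localized_basis",
    "project_expression",
    "select_expression_channels",
]

#: Canonical region order; fixed so every channel ordering is deterministic.
REGIONS = ("brows_forehead", "eyes", "nose_cheeks", "mouth_chin")

#: Landmark feature label -> mesh region.
FEATURE_TO_REGION = {
    "brow": "brows_forehead",
    "eye": "eyes",
    "nose": "nose_cheeks",
    "mouth": "mouth_chin",
}

#: Default per-region component counts for the 60-component localized basis.
DEFAULT_REGION_COUNTS = {
    "brows_forehead": 19,
    "eyes": 20,
    "nose_cheeks": 7,
    "mouth_chin": 14,
}

N_LANDMARKS = 51


@dataclass(frozen=True)
class FaceMesh:
    """A neutral face: dense 3D point cloud with 51 labeled landmarks.

    Parameters
    ----------
    identity_points
        ``(3, P)`` coordinates of the neutral face, arbitrary length units.
    landmark_indices
        51 distinct indices into the ``P`` points (0-based).
    landmark_feature
        Facial feature of each landmark, each one of
        ``{"brow", "eye", "nose", "mouth"}``.
    """

    identity_points: np.ndarray
    landmark_indices: np.ndarray
    landmark_feature: tuple[str, ...]

    def __post_init__(self) -> None:
        pts = np.asarray(self.identity_points, dtype=float)
        idx = np.asarray(self.landmark_indices, dtype=int)
        object.__setattr__(self, "identity_points", pts)
        object.__setattr__(self, "landmark_indices", idx)
        object.__setattr__(self, "landmark_feature", tuple(self.landmark_feature))
        if pts.ndim != 2 or pts.shape[0] != 3:
            raise ValueError(f"identity_points must be (3, P), got {pts.shape}")
        if pts.shape[1] < N_LANDMARKS:
            raise ValueError(f"mesh needs at least {N_LANDMARKS} points")
        if idx.shape != (N_LANDMARKS,):
            raise ValueError(f"expected {N_LANDMARKS} landmark indices, got {idx.shape}")
        if len(set(idx.tolist())) != N_LANDMARKS:
            raise ValueError("landmark indices must be distinct")
        if idx.min() < 0 or idx.max() >= pts.shape[1]:
            raise ValueError("landmark index out of range")
        if len(self.landmark_feature) != N_LANDMARKS:
            raise ValueError("one feature label per landmark required")
        bad = set(self.landmark_feature) - set(FEATURE_TO_REGION)
        if bad:
            raise ValueError(f"unknown landmark features: {sorted(bad)}")

    @property
    def n_points(self) -> int:
        return self.identity_points.shape[1]

    def to_files(self, points_path, landmarks_path) -> None:
        """Write the mesh as two delimited text files (points / landmarks)."""
        pd.DataFrame(self.identity_points.T, columns=["x", "y", "z"]).to_csv(
            points_path, index=False
        )
        pd.DataFrame(
            {"index": self.landmark_indices, "feature": list(self.landmark_feature)}
        ).to_csv(landmarks_path, index=False)

    @classmethod
    def from_files(cls, points_path, landmarks_path) -> "FaceMesh":
        pts = pd.read_csv(points_path)[["x", "y", "z"]].to_numpy().T
        lms = pd.read_csv(landmarks_path)
        return cls(pts, lms["index"].to_numpy(), tuple(lms["feature"]))


@dataclass(frozen=True)
class RegionPartition:
    """Region label of every mesh point."""

    region_of_point: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "region_of_point", tuple(self.region_of_point))
        bad = set(self.region_of_point) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown regions: {sorted(bad)}")

    def point_indices(self, region: str) -> np.ndarray:
        """Indices of the points assigned to ``region``."""
        labels = np.asarray(self.region_of_point)
        return np.flatnonzero(labels == region)

    def __len__(self) -> int:
        return len(self.region_of_point)


@dataclass(frozen=True)
class GlobalExpressionBasis:
    """Non-localized (PCA-style) expression components, shape ``(3P, K)``."""

    components: np.ndarray

    def __post_init__(self) -> None:
        comps = np.asarray(self.components, dtype=float)
        object.__setattr__(self, "components", comps)
        if comps.ndim != 2 or comps.shape[1] < 1:
            raise ValueError("components must be a (3P, K) matrix with K >= 1")
        if not np.isfinite(comps).all():
            raise ValueError("components must be finite")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass(frozen=True)
class LocalizedExpressionBasis:
    """Region-localized expression basis.

    Each column has support only on its region's points and unit Euclidean
    norm; columns within one region are mutually orthogonal.  Column order is
    region-major in ``REGIONS`` order.
    """

    components: np.ndarray
    component_region: tuple[str, ...]
    region_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        comps = np.asarray(self.components, dtype=float)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "component_region", tuple(self.component_region))
        if comps.shape[1] != len(self.component_region):
            raise ValueError("one region label per component required")
        counts = dict(self.region_counts) or {
            r: sum(1 for c in self.component_region if c == r) for r in REGIONS
        }
        object.__setattr__(self, "region_counts", counts)

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def n_points(self) -> int:
        return self.components.shape[0] // 3

    def expression_channel_names(self) -> list[str]:
        """Names of the retained (non-nose) coefficient channels."""
        keep = [i for i, r in enumerate(self.component_region) if r != "nose_cheeks"]
        names = []
        within: dict[str, int] = {}
        for i in keep:
            region = self.component_region[i]
            within[region] = within.get(region, 0) + 1
            names.append(f"{region}_{within[region]:02d}")
        return names

    def to_files(self, matrix_path, regions_path) -> None:
        np.savetxt(matrix_path, self.components, delimiter=",")
        pd.DataFrame({"region": list(self.component_region)}).to_csv(
            regions_path, index=False
        )

    @classmethod
    def from_files(cls, matrix_path, regions_path) -> "LocalizedExpressionBasis":
        comps = np.loadtxt(matrix_path, delimiter=",")
        regions = tuple(pd.read_csv(regions_path)["region"])
        return cls(comps, regions)


@dataclass(frozen=True)
class FrameFit:
    """Per-frame rigid pose + expression deformation (or coefficients).

    ``rotation`` must be a proper rotation (orthogonal, det +1, tol 1e-6).
    ``translation`` is carried for completeness but unused downstream.
    """

    rotation: np.ndarray
    translation: np.ndarray
    deformation: np.ndarray | None = None
    coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        if rot.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6) or not np.isclose(
            np.linalg.det(rot), 1.0, atol=1e-6
        ):
            raise ValueError("rotation must be orthogonal with determinant +1")
        if self.deformation is None and self.coefficients is None:
            raise ValueError("either deformation or coefficients must be given")


def assign_regions(mesh: FaceMesh) -> RegionPartition:
    """Label every mesh point with the region of its nearest landmark.

    Distances are Euclidean on the neutral identity points; ties are broken
    by the lowest landmark index, making the assignment deterministic.

    Raises
    ------
    ValueError
        If the mesh's landmarks do not cover all four facial features.
    """
    features = set(mesh.landmark_feature)
    if features != set(FEATURE_TO_REGION):
        missing = sorted(set(FEATURE_TO_REGION) - features)
        raise ValueError(
            f"mesh is unpartitionable: landmark features missing {missing}"
        )
    pts = mesh.identity_points.T  # (P, 3)
    lm = pts[mesh.landmark_indices]  # (51, 3)
    d2 = ((pts[:, None, :] - lm[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)  # argmin takes the first (lowest) index on ties
    labels = [FEATURE_TO_REGION[mesh.landmark_feature[k]] for k in nearest]
    return RegionPartition(tuple(labels))


def build_localized_basis(
    global_basis: GlobalExpressionBasis,
    partition: RegionPartition,
    region_counts: dict[str, int] | None = None,
) -> LocalizedExpressionBasis:
    """Localize a global expression basis to the four facial regions.

    For each region, rows of the global components belonging to points
    outside the region are zeroed; the masked columns are then orthonormalized
    (reduced QR) and the first ``region_counts[region]`` components retained.
    Components of different regions therefore have disjoint support and the
    whole output has orthonormal columns.

    Raises
    ------
    ValueError
        If a region's masked columns have rank below its requested count.
    """
    counts = dict(DEFAULT_REGION_COUNTS if region_counts is None else region_counts)
    for region in REGIONS:
        counts.setdefault(region, 0)
    total = sum(counts.values())
    if max(counts.values()) > global_basis.n_components:
        raise ValueError(
            f"global basis has K={global_basis.n_components} components, "
            f"fewer than the largest region request"
        )
    W = global_basis.components
    P = W.shape[0] // 3
    if W.shape[0] != 3 * len(partition):
        raise ValueError("basis row count does not match partition size")

    columns: list[np.ndarray] = []
    labels: list[str] = []
    for region in REGIONS:
        k = counts[region]
        if k == 0:
            continue
        mask = np.zeros(P, dtype=bool)
        mask[partition.point_indices(region)] = True
        row_mask = np.repeat(mask, 3)  # points are flattened (x,y,z) per point
        # orthonormalize the region's rows only, so support is exactly zero
        # outside the region (QR on the masked full matrix would leak ~1e-17)
        q, r = np.linalg.qr(W[row_mask, :])
        rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
        if rank < k:
            raise ValueError(
                f"region {region!r} is rank deficient: rank {rank} < requested {k}"
            )
        full = np.zeros((W.shape[0], k))
        full[row_mask, :] = q[:, :k]
        columns.append(full)
        labels.extend([region] * k)

    components = np.hstack(columns)
    return LocalizedExpressionBasis(components, tuple(labels), counts)


def project_expression(
    deformation: np.ndarray, basis: LocalizedExpressionBasis
) -> np.ndarray:
    """Least-squares coefficients of a deformation in the localized basis.

    Returns the minimizer of ``||vec(deformation) - W' e||_2``.  Accepts the
    deformation either as a ``(3, P)`` matrix or already flattened to ``3P``
    (point-major, i.e. ``(x0, y0, z0, x1, ...)``).
    """
    d = np.asarray(deformation, dtype=float)
    if d.ndim == 2:
        if d.shape[0] != 3 or d.shape[1] != basis.n_points:
            raise ValueError(f"deformation shape {d.shape} incompatible with basis")
        d = d.T.ravel()
    elif d.shape != (basis.components.shape[0],):
        raise ValueError(f"deformation length {d.shape} incompatible with basis")
    if not np.isfinite(d).all():
        raise ValueError("deformation contains non-finite entries")
    # Orthonormal columns: the LS solution is the analysis transform W'^T d.
    return basis.components.T @ d


def select_expression_channels(
    coeffs: np.ndarray, basis: LocalizedExpressionBasis
) -> np.ndarray:
    """Drop nose/cheek coefficients, preserving the order of the rest.

    Works on a single coefficient vector or a ``(T, n_components)`` stack.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] != basis.n_components:
        raise ValueError(
            f"expected {basis.n_components} coefficients, got {coeffs.shape[-1]}"
        )
    keep = [i for i, r in enumerate(basis.component_region) if r != "nose_cheeks"]
    return coeffs[..., keep]
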