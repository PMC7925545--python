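"""Bilateral PCA with confidence ellipses, and multi-element clustering.

Two comparison layers:

* **Within an element**: the 3D reference coordinates of left (mirrored) and
  right marks are pooled, PCA-projected onto PC1-PC2, and each side is
  summarised by a 95% confidence ellipse (score covariance scaled by the
  chi-square(2) 0.95 quantile).  The Jaccard area overlap of the two ellipses
  quantifies bilateral similarity.

* **Across elements**: each element-side's feature vector (mean K/F/G/pcf
  curves, mean nearest-neighbour distance, intensity) is a row of a feature
  matrix clustered by UPGMA (unweighted average linkage) on Euclidean
  distances.  Equal-distance merges are broken deterministically by the
  lexicographically smallest (min label, max label) pair.  The tree exports
  to Newick.

Because the six features differ in magnitude by up to six orders, Euclidean
distance on raw values is dominated by the K column; ``scaling="zscore"``
standardises columns first and is what recovers element-pure bilateral
clusters on the reference table.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2
from shapely.geometry import Polygon

__all__ = [
    "EllipseSummary",
    "LinkageTree",
    "pca_bilateral",
    "BilateralPCA",
    "BilateralPCAResults",
    "ellipse_overlap",
    "feature_matrix",
    "FEATURE_ROW_ORDER",
    "FEATURE_COLUMNS",
    "hclust_average",
    "cut_tree",
    "to_newick",
]

FEATURE_ROW_ORDER = ["lHum", "rHum", "lFem", "rFem", "lRad", "rRad",
                     "lTib", "rTib"]
FEATURE_COLUMNS = ["K_obs", "F_obs", "G_obs", "pcf_obs", "nnd", "intensity"]


@dataclass
class EllipseSummary:
    """A confidence ellipse in PC score space."""

    center: np.ndarray        # (2,)
    semi_axes: np.ndarray     # (2,), major first
    orientation: float        # radians, major axis vs PC1
    confidence: float = 0.95

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float)
        if np.any(self.semi_axes <= 0):
            raise ValueError("ellipse semi-axes must be positive")

    def polygon(self, n: int = 256) -> Polygon:
        """Polygonal approximation (n-gon) of the ellipse boundary."""
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        xy = np.column_stack([self.semi_axes[0] * np.cos(t),
                              self.semi_axes[1] * np.sin(t)])
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        rot = np.array([[c, -s], [s, c]])
        return Polygon(xy @ rot.T + self.center)

    def contains(self, scores: np.ndarray) -> np.ndarray:
        """Which 2D score points fall inside the ellipse."""
        d = np.atleast_2d(scores) - self.center
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        rot = np.array([[c, s], [-s, c]])
        local = d @ rot.T
        return (local[:, 0] / self.semi_axes[0]) ** 2 + \
            (local[:, 1] / self.semi_axes[1]) ** 2 <= 1.0


def _fit_ellipse(scores: np.ndarray, confidence: float, side: str) -> EllipseSummary:
    if len(scores) < 3:
        raise ValueError(f"side {side!r}: need at least 3 marks")
    cov = np.cov(scores.T)
    if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 1e-300:
        raise ValueError(f"side {side!r}: degenerate score covariance "
                         "(collinear marks)")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = chi2.ppf(confidence, df=2)
    return EllipseSummary(
        center=scores.mean(axis=0),
        semi_axes=np.sqrt(scale * evals),
        orientation=float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        confidence=confidence,
    )


def pca_bilateral(left_points: np.ndarray, right_points: np.ndarray,
                  confidence: float = 0.95):
    """PCA of pooled left/right 3D mark coordinates with per-side ellipses.

    ``left_points`` must already be canonicalized (mirrored) into the
    right-side frame.  Returns ``(scores_left, scores_right,
    explained_pct, ellipses)`` where ``explained_pct`` are the PC1/PC2
    explained-variance percentages and ``ellipses`` maps side to its
    :class:`EllipseSummary`.
    """
    left = np.asarray(left_points, dtype=float).reshape(-1, 3)
    right = np.asarray(right_points, dtype=float).reshape(-1, 3)
    if len(left) < 3 or len(right) < 3:
        raise ValueError("need at least 3 marks per side")
    pooled = np.vstack([left, right])
    center = pooled.mean(axis=0)
    u, s, vt = np.linalg.svd(pooled - center, full_matrices=False)
    # sign convention: largest-magnitude loading positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    var = s**2 / (len(pooled) - 1)
    explained_pct = 100.0 * var[:2] / var.sum()
    axes = vt[:2].T
    scores_left = (left - center) @ axes
    scores_right = (right - center) @ axes
    ellipses = {
        "left": _fit_ellipse(scores_left, confidence, "left"),
        "right": _fit_ellipse(scores_right, confidence, "right"),
    }
    return scores_left, scores_right, explained_pct, ellipses


def ellipse_overlap(e1: EllipseSummary, e2: EllipseSummary,
                    n: int = 256) -> float:
    """Jaccard area overlap area(∩)/area(∪) on ``n``-gon approximations."""
    p1, p2 = e1.polygon(n), e2.polygon(n)
    inter = p1.intersection(p2).area
    union = p1.union(p2).area
    return float(inter / union) if union > 0 else 0.0


class BilateralPCA:
    """Model object for the bilateral mark-coordinate PCA of one element."""

    def __init__(self, left_points: np.ndarray, right_points: np.ndarray,
                 confidence: float = 0.95):
        self.left_points = np.asarray(left_points, dtype=float).reshape(-1, 3)
        self.right_points = np.asarray(right_points, dtype=float).reshape(-1, 3)
        self.confidence = confidence

    @classmethod
    def from_marks(cls, left_marks, right_marks, mirror_left: bool = True,
                   **kwargs) -> "BilateralPCA":
        """Build from mark lists; mirrors the left side by default."""
        from .bone_model import canonicalize_side, mark_reference_point

        if mirror_left:
            left_marks = canonicalize_side(left_marks, "left")
        lp = np.array([mark_reference_point(m) for m in left_marks])
        rp = np.array([mark_reference_point(m) for m in right_marks])
        return cls(lp, rp, **kwargs)

    def fit(self) -> "BilateralPCAResults":
        sl, sr, pct, ell = pca_bilateral(
            self.left_points, self.right_points, self.confidence)
        return BilateralPCAResults(self, sl, sr, pct, ell)


@dataclass
class BilateralPCAResults:
    model: BilateralPCA
    scores_left: np.ndarray
    scores_right: np.ndarray
    explained_pct: np.ndarray
    ellipses: dict[str, EllipseSummary]

    @property
    def overlap(self) -> float:
        return ellipse_overlap(self.ellipses["left"], self.ellipses["right"])

    def summary(self) -> str:
        e = self.ellipses
        return "\n".join([
            "Bilateral PCA of mark coordinates",
            f"  n_left = {len(self.scores_left)}, "
            f"n_right = {len(self.scores_right)}",
            f"  PC1 {self.explained_pct[0]:.1f}%  "
            f"PC2 {self.explained_pct[1]:.1f}% of variance",
            f"  {self.model.confidence:.0%} ellipse semi-axes: "
            f"left ({e['left'].semi_axes[0]:.2f}, "
            f"{e['left'].semi_axes[1]:.2f}) mm, "
            f"right ({e['right'].semi_axes[0]:.2f}, "
            f"{e['right'].semi_axes[1]:.2f}) mm",
            f"  ellipse overlap (Jaccard): {self.overlap:.3f}",
        ])


# ---------------------------------------------------------------------------
# feature matrix and clustering


def feature_matrix(assemblage: dict) -> pd.DataFrame:
    """Assemble element-side feature vectors into the fixed-order table.

    ``assemblage`` maps labels (lHum, rHum, ... rTib) to
    :class:`~taphos3d.pointprocess3d.FeatureVector` (or mappings with the
    same six keys).  Missing labels produce a warning and a shorter table;
    labels outside the canonical eight keep their given order at the end.
    """
    if len(set(assemblage)) != len(assemblage):
        raise ValueError("duplicate labels")
    rows = {}
    for label, fv in assemblage.items():
        if hasattr(fv, "as_series"):
            rows[label] = fv.as_series()
        else:
            rows[label] = pd.Series({c: fv[c] for c in FEATURE_COLUMNS})
    order = [lb for lb in FEATURE_ROW_ORDER if lb in rows]
    order += [lb for lb in rows if lb not in FEATURE_ROW_ORDER]
    missing = [lb for lb in FEATURE_ROW_ORDER if lb not in rows]
    if missing:
        warnings.warn(f"feature matrix missing element-sides: {missing}")
    return pd.DataFrame([rows[lb] for lb in order], index=order,
                        columns=FEATURE_COLUMNS)


@dataclass
class LinkageTree:
    """Agglomerative merge history over labelled leaves.

    ``merges[k] = (id_a, id_b, height)``: node ids 0..n-1 are leaves in
    ``labels`` order; merge k creates node n + k.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["node_a", "node_b",
                                                  "height"])


def hclust_average(matrix: pd.DataFrame | np.ndarray,
                   scaling: str = "none",
                   labels: list[str] | None = None) -> LinkageTree:
    """UPGMA (unweighted average linkage) on Euclidean distances.

    ``scaling="zscore"`` standardises each column (population std) before
    computing distances; the default ``"none"`` uses the matrix as given.
    Equal-distance candidate merges are broken by the lexicographically
    smallest (min leaf label, max leaf label) of the candidate pair, making
    the tree invariant to input row order.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index) if labels is None else labels
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(len(X))]
    if len(X) < 2:
        raise ValueError("need at least 2 rows to cluster")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    if scaling not in ("none", "zscore"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if scaling == "zscore":
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1))
    # active clusters: node id -> (leaf indices, current members' sort key)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}

    def tie_key(a: int, b: int) -> tuple[str, str]:
        la = min(labels[i] for i in members[a])
        lb = min(labels[i] for i in members[b])
        lo, hi = sorted([la, lb])
        return (lo, hi)

    merges: list[tuple[int, int, float]] = []
    next_id = n
    last_height = -np.inf
    while len(members) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], tie_key(*kv[0])))
        (a, b), h = best
        if h < last_height - 1e-12:
            raise AssertionError("UPGMA merge heights must be nondecreasing")
        last_height = h
        merges.append((a, b, float(h)))
        na, nb = len(members[a]), len(members[b])
        new_members = members.pop(a) + members.pop(b)
        # UPGMA update: unweighted average over leaf pairs
        new_dist = {}
        for c in members:
            da = dist.pop((min(a, c), max(a, c)))
            db = dist.pop((min(b, c), max(b, c)))
            new_dist[c] = (na * da + nb * db) / (na + nb)
        dist.pop((a, b), None)
        members[next_id] = new_members
        for c, d in new_dist.items():
            dist[(min(c, next_id), max(c, next_id))] = d
        next_id += 1
    return LinkageTree(list(labels), merges)


def cut_tree(tree: LinkageTree, k: int) -> dict[str, int]:
    """Partition into ``k`` groups by undoing the last k-1 merges.

    Groups are numbered by first leaf occurrence in label order.  Returns a
    label -> group id mapping.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = {i: i for i in range(n)}
    for step, (a, b, _) in enumerate(tree.merges[: n - k]):
        node = n + step
        parent[a] = node
        parent[b] = node
        parent[node] = node

    def root(i: int) -> int:
        while parent[i] != i:
            i = parent[i]
        return i

    groups: dict[int, int] = {}
    out = {}
    for i, label in enumerate(tree.labels):
        r = root(i)
        if r not in groups:
            groups[r] = len(groups)
        out[label] = groups[r]
    return out


def to_newick(tree: LinkageTree) -> str:
    """Newick export: leaf branch length = its parent's merge height;
    internal branch length = height difference to the parent merge."""
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    text = {i: tree.labels[i] for i in range(n)}
    for step, (a, b, h) in enumerate(tree.merges):
        node = n + step
        ba = h - heights[a]
        bb = h - heights[b]
        text[node] = f"({text[a]}:{ba:g},{text[b]}:{bb:g})"
        heights[node] = h
    return text[n + len(tree.merges) - 1] + ";"
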