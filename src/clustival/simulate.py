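"""Seeded synthetic data generators for metric testing.

Everything the test-suite and the acceptance checks consume is generated
here: labeled Gaussian point clouds whose class centroids realize a
requested matrix of pairwise class differences (via classical
multidimensional scaling), elongated/globular Gaussian scenarios,
interleaved half-moons with alternative labelings, and rectangular
spatial grid toys with controlled error placement (boundary vs interior)
for the spatially aware metrics.  All generators are pure functions of
their configuration and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .embedding import Embedding
from .errors import InputError
from .partitions import HardPartition

__all__ = [
    "MockDataConfig",
    "mock_data",
    "simulation_descriptors",
    "gaussian_scenarios",
    "moons",
    "GridToyConfig",
    "grid_toy",
    "random_partition_pair",
]


@dataclass
class MockDataConfig:
    """Configuration of the MDS-centroid mock generator.

    class_abundances: points per class.  class_differences: symmetric
    K x K matrix of desired pairwise centroid distances (a scalar means
    all pairs equal).  class_sds: per-class spread (standard deviation).
    spread_mode: 'normal' | 'lognormal' | 'multishift' per class or one
    for all.  dim: embedding dimensionality (2 or 3).
    """

    class_abundances: tuple = (100, 100, 100)
    class_differences: object = 10.0
    class_sds: object = 1.0
    spread_mode: object = "normal"
    dim: int = 2
    seed: int = 0

    @property
    def K(self) -> int:
        return len(self.class_abundances)

    def differences_matrix(self) -> np.ndarray:
        D = self.class_differences
        if np.isscalar(D):
            D = np.full((self.K, self.K), float(D))
            np.fill_diagonal(D, 0.0)
        D = np.asarray(D, dtype=float)
        if D.shape != (self.K, self.K) or not np.allclose(D, D.T) or (D < 0).any():
            raise InputError("class_differences must be a symmetric nonnegative K x K matrix")
        return D

    def sds(self) -> np.ndarray:
        s = self.class_sds
        if np.isscalar(s):
            return np.full(self.K, float(s))
        return np.asarray(s, dtype=float)

    def modes(self) -> list:
        m = self.spread_mode
        if isinstance(m, str):
            return [m] * self.K
        return list(m)


def classical_mds(D: np.ndarray, dim: int) -> np.ndarray:
    """Torgerson double-centering embedding of a distance matrix.

    Negative eigenvalues (non-embeddable differences) are truncated with
    a warning; the best rank-dim approximation is returned.
    """
    K = D.shape[0]
    J = np.eye(K) - np.ones((K, K)) / K
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-9 * max(1.0, abs(vals[0]))
    if (vals < -tol).any() or (vals[dim:] > tol).any():
        warnings.warn("difference matrix is not exactly embeddable in the "
                      "requested dimensionality; using the best rank-d fit")
    vals = np.clip(vals[:dim], 0.0, None)
    pts = vecs[:, :dim] * np.sqrt(vals)[None, :]
    return pts


def mock_data(cfg: MockDataConfig) -> tuple[Embedding, HardPartition]:
    """Labeled point cloud with MDS-placed class centroids.

    Points are drawn around each centroid using the class's spread mode:
    'normal' (isotropic Gaussian), 'lognormal' (skewed: log-normal
    offsets re-centered at their median), or 'multishift' (a symmetric
    mixture of two Gaussians shifted from the centroid, giving an
    elongated non-Gaussian class).
    """
    rng = np.random.default_rng(cfg.seed)
    D = cfg.differences_matrix()
    centroids = classical_mds(D, cfg.dim)
    sds = cfg.sds()
    modes = cfg.modes()
    pts, labels = [], []
    for k, n_k in enumerate(cfg.class_abundances):
        if n_k <= 0:
            raise InputError("class abundances must be positive")
        mode, s = modes[k], sds[k]
        if mode == "normal":
            off = rng.normal(0.0, s, size=(n_k, cfg.dim))
        elif mode == "lognormal":
            raw = rng.lognormal(mean=0.0, sigma=1.0, size=(n_k, cfg.dim))
            off = s * (raw - 1.0)  # median-centered, right-skewed
        elif mode == "multishift":
            u = rng.normal(size=cfg.dim)
            u /= np.linalg.norm(u)
            shift = 2.0 * s * u
            signs = np.where(np.arange(n_k) % 2 == 0, 1.0, -1.0)[:, None]
            off = rng.normal(0.0, s, size=(n_k, cfg.dim)) + signs * shift
        else:
            raise InputError(f"unknown spread mode {mode!r}")
        pts.append(centroids[k] + off)
        labels += [f"class{k}"] * n_k
    X = np.vstack(pts)
    return Embedding(X), HardPartition.from_labels(labels)


def simulation_descriptors(cfg: MockDataConfig, labels: HardPartition | None = None) -> dict:
    """Interpretable summaries of a mock configuration.

    size_imbalance: Simpson diversity 1 - sum(p^2) of class abundances.
    signal_to_noise: mean pairwise class difference / mean class sd
    (+inf for zero variability).  spread: mean class spread parameter.
    """
    ab = np.asarray(cfg.class_abundances, dtype=float)
    p = ab / ab.sum()
    size_imbalance = float(1.0 - (p ** 2).sum())
    D = cfg.differences_matrix()
    iu = np.triu_indices(cfg.K, 1)
    mean_diff = float(D[iu].mean()) if len(iu[0]) else 0.0
    mean_sd = float(cfg.sds().mean())
    if mean_sd == 0:
        warnings.warn("zero class variability; signal-to-noise is infinite")
        snr = np.inf
    else:
        snr = mean_diff / mean_sd
    return {"size_imbalance": size_imbalance, "signal_to_noise": snr, "spread": mean_sd}


def gaussian_scenarios(n_per_class: int = 150, separation: float = 6.0, seed: int = 0) -> dict:
    """Two 2-class 2D Gaussian scenarios at matched centroid separation.

    'globular': isotropic classes.  'elongated': one class stretched
    along the axis joining the centroids, producing locally overlapping
    tails (and hence negative silhouette widths) despite the same
    centroid distance.
    """
    rng = np.random.default_rng(seed)
    c0, c1 = np.array([0.0, 0.0]), np.array([separation, 0.0])
    lab = HardPartition.from_labels(["A"] * n_per_class + ["B"] * n_per_class)
    glob = np.vstack([rng.normal(c0, 1.0, size=(n_per_class, 2)),
                      rng.normal(c1, 1.0, size=(n_per_class, 2))])
    elong = np.vstack([c0 + rng.normal(0.0, 1.0, size=(n_per_class, 2)) * [4.0, 0.6],
                       c1 + rng.normal(0.0, 1.0, size=(n_per_class, 2)) * [4.0, 0.6]])
    return {"globular": (Embedding(glob), lab), "elongated": (Embedding(elong), lab)}


def moons(n: int = 200, noise: float = 0.08, seed: int = 0) -> dict:
    """Two interleaved half-moons with two alternative labelings.

    'labels' are the generating moons (a density-style labeling with zero
    construction error); 'cut_labels' split the points by a straight
    vertical cut at the midpoint, mimicking what a centroid-based
    clustering does to this geometry.
    """
    rng = np.random.default_rng(seed)
    n1 = n // 2
    n2 = n - n1
    t1 = np.linspace(0, np.pi, n1)
    t2 = np.linspace(0, np.pi, n2)
    outer = np.column_stack([np.cos(t1), np.sin(t1)])
    inner = np.column_stack([1.0 - np.cos(t2), 0.5 - np.sin(t2)])
    X = np.vstack([outer, inner]) + rng.normal(0.0, noise, size=(n, 2))
    labels = HardPartition.from_labels(["moon1"] * n1 + ["moon2"] * n2)
    midpoint = 0.5
    cut = np.where(X[:, 0] <= midpoint, "left", "right")
    return {"X": Embedding(X), "labels": labels,
            "cut_labels": HardPartition.from_labels(cut)}


@dataclass
class GridToyConfig:
    """Two-domain grid with controlled label-error placement.

    A width x height unit grid is split into a left domain A and right
    domain B ('blocks'), horizontal 'stripes', or a 'checkerboard'.  For
    the blocks layout, n_errors spots of domain A are flipped to label B
    either along the A|B interface ('boundary') or deep inside domain A
    ('interior', with an offset selecting different interior positions).
    All placements flip the same number of A spots to B, so the resulting
    confusion matrices are identical.
    """

    width: int = 12
    height: int = 12
    layout: str = "blocks"
    n_errors: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.layout not in ("blocks", "stripes", "checkerboard"):
            raise InputError(f"unknown layout {self.layout!r}")


def _grid_coords(w: int, h: int) -> np.ndarray:
    xs, ys = np.meshgrid(np.arange(w), np.arange(h))
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


def grid_toy(cfg: GridToyConfig) -> dict:
    """Coordinates, ground truth, and error-placement prediction variants.

    Returns {'coords', 'truth', 'predictions'}; for the blocks layout the
    predictions are P1 (interface errors) and P2-P4 (the same number of
    isolated interior errors at three different placements, each at least
    two cells from the interface, one cell from the field border, and
    three cells apart, so spatially aware metrics see identical local
    configurations).
    """
    w, h = cfg.width, cfg.height
    coords = _grid_coords(w, h)
    x, y = coords[:, 0], coords[:, 1]
    if cfg.layout == "stripes":
        truth = np.where(y < h / 2, "A", "B")
    elif cfg.layout == "checkerboard":
        truth = np.where((x + y) % 2 == 0, "A", "B")
    else:
        truth = np.where(x < w / 2, "A", "B")
    out = {"coords": coords, "truth": HardPartition.from_labels(truth)}
    if cfg.layout != "blocks":
        out["predictions"] = {}
        return out

    interface_col = w // 2 - 1          # rightmost column of domain A
    def flip(cells) -> HardPartition:
        pred = truth.copy()
        for cx, cy in cells:
            idx = int(cy) * w + int(cx)
            if truth[idx] != "A":
                raise InputError("error placement must fall inside domain A")
            pred[idx] = "B"
        return HardPartition.from_labels(pred)

    n_err = cfg.n_errors
    boundary_rows = [1 + 3 * i for i in range(n_err)]
    if not boundary_rows or boundary_rows[-1] > h - 2:
        raise InputError("n_errors exceeds the usable interface length")
    preds = {"P1": flip([(interface_col, r) for r in boundary_rows])}
    # interior placements: >= 2 columns from the interface, >= 1 from the
    # border, >= 3 cells apart -> each error is an isolated island whose
    # neighborhood is entirely domain A
    interior_cols = [1, 2, interface_col - 2]
    for v, col in enumerate(interior_cols, start=2):
        if col > interface_col - 2 or col < 1:
            col = 1
        rows = [1 + 3 * i for i in range(n_err)]
        preds[f"P{v}"] = flip([(col, r) for r in rows])
    out["predictions"] = preds
    return out


def random_partition_pair(n: int, k_truth: int, k_pred: int, rng) -> tuple:
    """Two independent uniformly random hard partitions of n elements
    (each group nonempty)."""
    def draw(k):
        while True:
            codes = rng.integers(0, k, size=n)
            if len(np.unique(codes)) == k:
                return codes
    return (HardPartition.from_labels(draw(k_truth)),
            HardPartition.from_labels(draw(k_pred)))
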