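"""Lesion extraction with an iterative GMM + graph-cut (GrabCut) core.

The initialization rectangle is automatic: the start point sits 5% of each
image dimension from the top-left corner and the end point 7% from the
bottom-right (both truncated to integers), e.g. (21, 21)–(400, 400) on a
430×430 image.  Pixels outside the rectangle are hard background (TB); the
rectangle interior is the unknown region (Tu); the hard-foreground set (TF)
starts empty.

Each iteration:

1. assign every pixel to its most-likely component within its current GMM,
2. refit both mixtures (weights, means, full covariances) from the current
   labels by maximum likelihood,
3. build the graph — data terms are the negative log-likelihood of the
   best component, pairwise terms are ``γ·exp(−β‖z_p − z_q‖²)`` on
   8-neighbors with ``β = 1/(2·E‖z_p − z_q‖²)``, hard-background pixels get
   an infinite foreground cost —
4. solve the s–t min-cut and update the labels on Tu.

Because the data term used everywhere is the best-component likelihood, every
sub-step can only lower the Gibbs energy, so the energy trace is
non-increasing.  Iteration stops when fewer than ``convergence_tol`` of the
Tu pixels change label, or after ``max_iters`` rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from sklearn.cluster import KMeans

from .image_core import InvalidInputError, validate_rgb

__all__ = [
    "RectSpec",
    "TriMap",
    "GrabCutConfig",
    "GrabCutState",
    "auto_rect",
    "init_trimap",
    "grabcut_iterate",
    "segment_lesion",
]

logger = logging.getLogger(__name__)

#: Tri-map labels.
TB, TU, TF = 0, 1, 2

_HARD = 1e9  # terminal capacity enforcing a hard background link


@dataclass
class RectSpec:
    """Half-open rectangle: start inclusive, end exclusive, (row, col)."""

    start: tuple[int, int]
    end: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.start[0] < self.end[0] and self.start[1] < self.end[1]):
            raise InvalidInputError(f"degenerate rectangle {self.start}..{self.end}")
        if self.start[0] < 0 or self.start[1] < 0:
            raise InvalidInputError("rectangle start must be non-negative")


@dataclass
class GrabCutConfig:
    start_pct: float = 5.0
    end_pct: float = 7.0
    n_components: int = 5
    max_iters: int = 5
    convergence_tol: float = 0.001
    gamma: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.start_pct < 50 and 0 < self.end_pct < 50):
            raise InvalidInputError("rectangle percentages must lie in (0, 50)")
        if self.n_components < 1:
            raise InvalidInputError("n_components must be >= 1")


@dataclass
class GrabCutState:
    alpha: np.ndarray  # 0 background / 1 foreground per pixel
    energy: float
    energy_trace: list = field(default_factory=list)
    iterations: int = 0
    gmm_bg: "_GMM | None" = None
    gmm_fg: "_GMM | None" = None


class TriMap:
    """Per-pixel partition into hard background / unknown / hard foreground."""

    def __init__(self, labels: np.ndarray):
        labels = np.asarray(labels)
        if not np.isin(labels, (TB, TU, TF)).all():
            raise InvalidInputError("tri-map labels must be TB/TU/TF")
        self.labels = labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def count(self, label: int) -> int:
        return int((self.labels == label).sum())


def auto_rect(height: int, width: int, cfg: GrabCutConfig | None = None) -> RectSpec:
    """The automatic initialization rectangle.

    start = (int(h·start_pct/100), int(w·start_pct/100)) and
    end = (h − int(h·end_pct/100), w − int(w·end_pct/100)), with ``int``
    truncating toward zero.
    """
    cfg = cfg or GrabCutConfig()
    if height < 20 or width < 20:
        raise InvalidInputError("image must be at least 20 pixels in each dimension")
    start = (int(height * cfg.start_pct / 100.0), int(width * cfg.start_pct / 100.0))
    end = (height - int(height * cfg.end_pct / 100.0), width - int(width * cfg.end_pct / 100.0))
    return RectSpec(start=start, end=end)


def init_trimap(rect: RectSpec, height: int, width: int) -> TriMap:
    """TB outside the rectangle, Tu inside (half-open), TF empty."""
    if rect.end[0] > height or rect.end[1] > width:
        raise InvalidInputError("rectangle exceeds the image extent")
    labels = np.full((height, width), TB, dtype=np.uint8)
    labels[rect.start[0] : rect.end[0], rect.start[1] : rect.end[1]] = TU
    return TriMap(labels)


class _GMM:
    """Full-covariance Gaussian mixture fit by per-component ML from hard assignments."""

    def __init__(self, n_components: int, reg: float = 1e-2):
        self.k = n_components
        self.reg = reg
        self.weights = np.full(n_components, 1.0 / n_components)
        self.means = np.zeros((n_components, 3))
        self._chol: list = []
        self._logdet = np.zeros(n_components)

    def init_kmeans(self, x: np.ndarray, seed: int) -> np.ndarray:
        k = min(self.k, max(len(np.unique(x, axis=0)), 1), len(x))
        km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(x)
        comp = np.zeros(len(x), dtype=np.intp)
        comp[:] = km.labels_
        self.fit(x, comp)
        return comp

    def fit(self, x: np.ndarray, comp: np.ndarray) -> None:
        n = len(x)
        self._chol = []
        logdet = np.zeros(self.k)
        weights = np.empty(self.k)
        for c in range(self.k):
            sel = x[comp == c]
            weights[c] = len(sel) / n
            if len(sel) == 0:
                self.means[c] = 0.0
                cov = np.eye(3)
            else:
                self.means[c] = sel.mean(axis=0)
                d = sel - self.means[c]
                # covariance regularized to stay positive-definite
                cov = (d.T @ d) / len(sel) + self.reg * np.eye(3)
            chol = np.linalg.cholesky(cov)
            self._chol.append(np.linalg.inv(chol))
            logdet[c] = 2.0 * np.log(np.diag(chol)).sum()
        self.weights = weights
        self._logdet = logdet

    def component_neg_log(self, x: np.ndarray) -> np.ndarray:
        """Per-component −log(π_c N(x | μ_c, Σ_c)); empty components are +inf."""
        out = np.full((len(x), self.k), np.inf)
        for c in range(self.k):
            if self.weights[c] <= 0:
                continue
            d = (x - self.means[c]) @ self._chol[c].T
            maha = np.einsum("ij,ij->i", d, d)
            out[:, c] = (
                -np.log(self.weights[c]) + 0.5 * (maha + self._logdet[c] + 3.0 * np.log(2.0 * np.pi))
            )
        return out

    def assign(self, x: np.ndarray) -> np.ndarray:
        return np.argmin(self.component_neg_log(x), axis=1)

    def neg_log_best(self, x: np.ndarray) -> np.ndarray:
        return np.min(self.component_neg_log(x), axis=1)


def _neighbor_edges(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs of all 8-neighbor edges (each undirected edge once)."""
    idx = np.arange(h * w).reshape(h, w)
    pairs = []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = idx[: h - dr, max(-dc, 0) : w - max(dc, 0)]
        b = idx[dr:, max(dc, 0) : w - max(-dc, 0)]
        pairs.append(np.stack([a.ravel(), b.ravel()], axis=1))
    edges = np.concatenate(pairs, axis=0)
    return edges[:, 0], edges[:, 1]


def _beta(colors: np.ndarray, u: np.ndarray, v: np.ndarray) -> float:
    """β = 1/(2·mean squared color distance over 8-neighbor pairs)."""
    diff = colors[u] - colors[v]
    mean_sq = float(np.einsum("ij,ij->", diff, diff)) / max(len(diff), 1)
    if mean_sq <= 0:
        return 0.0
    return 1.0 / (2.0 * mean_sq)


def _pairwise_energy(alpha_flat: np.ndarray, u: np.ndarray, v: np.ndarray, cap: np.ndarray) -> float:
    return float(cap[alpha_flat[u] != alpha_flat[v]].sum())


def grabcut_iterate(img: np.ndarray, trimap: TriMap, cfg: GrabCutConfig | None = None) -> GrabCutState:
    """Run the iterative GMM/min-cut loop and return the final labeling."""
    cfg = cfg or GrabCutConfig()
    img = validate_rgb(img)
    h, w = img.shape[:2]
    if trimap.shape != (h, w):
        raise InvalidInputError("tri-map shape does not match the image")
    labels = trimap.labels
    tu = labels == TU
    if not tu.any():
        raise InvalidInputError("tri-map has no unknown region")

    colors = img.reshape(-1, 3).astype(np.float64)
    alpha = (labels != TB).astype(np.uint8)  # Tu starts as tentative foreground
    alpha_flat = alpha.ravel()
    tu_flat = tu.ravel()
    tb_flat = (labels == TB).ravel()

    if np.ptp(colors, axis=0).max() == 0:
        # degenerate uniform image: both mixtures collapse to one density;
        # the tie is resolved toward background, deterministically
        logger.info("uniform image: unknown region resolved to background")
        state = GrabCutState(alpha=np.zeros((h, w), dtype=np.uint8), energy=0.0, iterations=0)
        return state

    u, v = _neighbor_edges(h, w)
    beta = _beta(colors, u, v)
    diff = colors[u] - colors[v]
    cap_pair = cfg.gamma * np.exp(-beta * np.einsum("ij,ij->i", diff, diff))

    gmm_bg, gmm_fg = _GMM(cfg.n_components), _GMM(cfg.n_components)
    gmm_bg.init_kmeans(colors[alpha_flat == 0], cfg.seed)
    gmm_fg.init_kmeans(colors[alpha_flat == 1], cfg.seed + 1)

    state = GrabCutState(alpha=alpha, energy=np.inf, gmm_bg=gmm_bg, gmm_fg=gmm_fg)
    n = h * w
    src, snk = n, n + 1
    pair_edges = np.stack([u, v], axis=1)

    for it in range(cfg.max_iters):
        # (a)+(b): reassign components and refit both mixtures by ML
        bg_x = colors[alpha_flat == 0]
        fg_x = colors[alpha_flat == 1]
        if len(fg_x) == 0:
            break
        gmm_bg.fit(bg_x, gmm_bg.assign(bg_x))
        gmm_fg.fit(fg_x, gmm_fg.assign(fg_x))

        d_bg = gmm_bg.neg_log_best(colors)
        d_fg = gmm_fg.neg_log_best(colors)
        # hard background links for TB
        d_bg = np.where(tb_flat, 0.0, d_bg)
        d_fg = np.where(tb_flat, _HARD, d_fg)

        # (c)+(d): min-cut. Source is the foreground terminal; the edge
        # source→p is paid when p lands background, so it carries the
        # background data cost (and vice versa).
        g = ig.Graph(n + 2)
        term_src = np.stack([np.full(n, src), np.arange(n)], axis=1)
        term_snk = np.stack([np.arange(n), np.full(n, snk)], axis=1)
        g.add_edges(np.concatenate([pair_edges, term_src, term_snk], axis=0))
        caps = np.concatenate([cap_pair, d_bg, d_fg])
        cut = g.st_mincut(src, snk, capacity=caps.tolist())
        side0, side1 = cut.partition
        fg_part = side0 if src in set(side0) else side1
        fg_side = np.array([i for i in fg_part if i < n], dtype=np.intp)
        new_alpha = np.zeros(n, dtype=np.uint8)
        new_alpha[fg_side] = 1
        new_alpha[tb_flat] = 0
        # (e): only Tu pixels may flip
        changed = int((new_alpha[tu_flat] != alpha_flat[tu_flat]).sum())
        alpha_flat[tu_flat] = new_alpha[tu_flat]

        data_e = float(np.where(alpha_flat == 1, d_fg, d_bg)[~tb_flat].sum())
        energy = data_e + _pairwise_energy(alpha_flat, u, v, cap_pair)
        state.energy_trace.append(energy)
        state.energy = energy
        state.iterations = it + 1
        if changed / max(int(tu_flat.sum()), 1) < cfg.convergence_tol:
            break

    state.alpha = alpha_flat.reshape(h, w)
    return state


def segment_lesion(img: np.ndarray, cfg: GrabCutConfig | None = None) -> np.ndarray:
    """Segment the lesion of a (pre-processed) image; returns a {0,255} mask."""
    cfg = cfg or GrabCutConfig()
    img = validate_rgb(img)
    h, w = img.shape[:2]
    rect = auto_rect(h, w, cfg)
    trimap = init_trimap(rect, h, w)
    state = grabcut_iterate(img, trimap, cfg)
    return (state.alpha * 255).astype(np.uint8)
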