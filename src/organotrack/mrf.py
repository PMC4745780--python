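"""Three-label MRF segmentation of confocal images by alpha-expansion.

Confocal maximum projections are segmented into 'in focus cells',
'cell shadow' and 'background' by minimizing

    E(x) = sum_i theta_{i;l} I{x_i = l}
         + sum_(i,j) theta_{ij;lk} I{x_i = l, x_j = k}

over 4-neighbor pixel pairs. Unaries are negative log densities
theta_{i;l} = -log f_l(z_i) from a 3-component Gaussian mixture fitted to
(entropy-filtered) pixel values; pairwise terms are contrast-sensitive,

    theta_{ij;lk} = lambda0 + lambda1 * exp(-beta/2 * (z_i - z_j)^2)   (l != k)
                  = 0                                                  (l = k),

a scaled Potts model, hence a metric for lambda0, lambda1 >= 0, so
alpha-expansion moves apply. Min-cuts are solved exactly with
scipy.sparse.csgraph.maximum_flow on fixed-point capacities; the expansion
loop only accepts moves that lower the true floating-point energy, so the
energy is monotonically non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from sklearn.mixture import GaussianMixture

from .config import MRFConfig
from .preprocess import entropy_filter, scale_to_8bit

logger = logging.getLogger("organotrack")

__all__ = [
    "LABELS",
    "MixtureModel3",
    "MRFModel",
    "fit_mixture3",
    "build_energy",
    "alpha_expansion",
    "segment_stack",
]

LABELS = ("background", "cell_shadow", "in_focus_cells")
_DENSITY_FLOOR = 1e-12
_SIGMA_FLOOR = 1e-3
_SCALE = 2 ** 20  # fixed-point scale for min-cut capacities


@dataclass
class MixtureModel3:
    """Gaussian mixture with components sorted by mean.

    Component order maps to labels in mean order:
    background < cell_shadow < in_focus_cells.
    """

    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.means)
        self.weights = np.asarray(self.weights, float)[order]
        self.means = np.asarray(self.means, float)[order]
        self.sigmas = np.asarray(self.sigmas, float)[order]
        if np.any(self.sigmas <= 0):
            logger.warning("degenerate mixture component: sigma floored at %g",
                           _SIGMA_FLOOR)
            self.sigmas = np.maximum(self.sigmas, _SIGMA_FLOOR)
        self.weights = self.weights / self.weights.sum()

    def component_density(self, values: np.ndarray) -> np.ndarray:
        """f_l(z) per label, shape values.shape + (3,)."""
        z = np.asarray(values, float)[..., None]
        return (self.weights / (np.sqrt(2 * np.pi) * self.sigmas)
                * np.exp(-0.5 * ((z - self.means) / self.sigmas) ** 2))


def fit_mixture3(values: np.ndarray, seed: int = 0,
                 restarts: int = 5) -> MixtureModel3:
    """EM fit of a 3-component Gaussian mixture, k-means++ init, best of
    ``restarts`` runs by log-likelihood; deterministic under ``seed``."""
    v = np.asarray(values, float).ravel()
    if v.size < 300:
        raise ValueError("need at least 300 samples to fit the mixture")
    if np.ptp(v) == 0:
        raise ValueError("constant sample has no 3-component structure")
    gm = GaussianMixture(n_components=3, covariance_type="spherical",
                         n_init=restarts, init_params="k-means++",
                         random_state=int(seed) % (2 ** 31),
                         reg_covar=1e-6, max_iter=300)
    gm.fit(v[:, None])
    return MixtureModel3(gm.weights_.copy(), gm.means_.ravel().copy(),
                         np.sqrt(gm.covariances_.ravel()))


@dataclass
class MRFModel:
    """Energy model: unary costs and 4-neighbor contrast-sensitive pairwise.

    ``unary[y, x, l]`` = -log f_l(z_yx); ``wh[y, x]`` is the pairwise weight
    between (y, x) and (y, x+1); ``wv[y, x]`` between (y, x) and (y+1, x).
    """

    unary: np.ndarray
    wh: np.ndarray
    wv: np.ndarray
    lambda0: float
    lambda1: float
    beta: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.unary.shape[:2]

    @property
    def n_labels(self) -> int:
        return self.unary.shape[2]

    def energy(self, labeling: np.ndarray) -> float:
        lab = np.asarray(labeling)
        h, w = self.shape
        idx = np.indices((h, w))
        e = float(self.unary[idx[0], idx[1], lab].sum())
        e += float(self.wh[lab[:, :-1] != lab[:, 1:]].sum())
        e += float(self.wv[lab[:-1, :] != lab[1:, :]].sum())
        return e


def build_energy(img: np.ndarray, mixture: MixtureModel3,
                 lambda0: float = 0.5, lambda1: float = 2.0,
                 beta: float = 0.05,
                 contrast_img: np.ndarray | None = None) -> MRFModel:
    """Assemble the MRF energy for a single-channel image.

    ``img`` supplies the unary feature values (typically entropy-filtered);
    ``contrast_img`` the intensities z entering the pairwise contrast term
    (defaults to ``img``; typically the 8-bit raw image). Densities are
    floored at 1e-12 before the log.
    """
    if lambda0 < 0 or lambda1 < 0:
        raise ValueError("lambda0 and lambda1 must be >= 0")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    img = np.asarray(img, float)
    z = img if contrast_img is None else np.asarray(contrast_img, float)
    if z.shape != img.shape:
        raise ValueError("contrast image shape mismatch")
    dens = np.maximum(mixture.component_density(img), _DENSITY_FLOOR)
    unary = -np.log(dens)
    wh = lambda0 + lambda1 * np.exp(-0.5 * beta * (z[:, :-1] - z[:, 1:]) ** 2)
    wv = lambda0 + lambda1 * np.exp(-0.5 * beta * (z[:-1, :] - z[1:, :]) ** 2)
    return MRFModel(unary, wh, wv, float(lambda0), float(lambda1), float(beta))


def _expansion_move(model: MRFModel, lab: np.ndarray, alpha: int) -> np.ndarray:
    """One alpha-expansion move solved as a binary min-cut.

    Node on the source side of the cut keeps its current label; sink side
    switches to alpha. Different-label neighbor pairs get an auxiliary node
    (Boykov-Veksler-Zabih construction).
    """
    h, w = model.shape
    n_pix = h * w
    pix = np.arange(n_pix).reshape(h, w)
    src, snk = n_pix, n_pix + 1
    next_node = n_pix + 2

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    caps: list[np.ndarray] = []

    def add(u, v, c):
        u = np.atleast_1d(np.asarray(u, np.int64)).ravel()
        v = np.atleast_1d(np.asarray(v, np.int64)).ravel()
        c = np.atleast_1d(np.asarray(c, np.int64)).ravel()
        rows.extend([u, v])
        cols.extend([v, u])
        caps.extend([c, np.zeros_like(c)])

    def add_sym(u, v, c):
        u = np.atleast_1d(np.asarray(u, np.int64)).ravel()
        v = np.atleast_1d(np.asarray(v, np.int64)).ravel()
        c = np.atleast_1d(np.asarray(c, np.int64)).ravel()
        rows.extend([u, v])
        cols.extend([v, u])
        caps.extend([c, c])

    to_int = lambda x: np.rint(np.asarray(x) * _SCALE).astype(np.int64)

    idx = np.indices((h, w))
    d_alpha = model.unary[..., alpha]
    d_keep = model.unary[idx[0], idx[1], lab]
    # s->i cut when i goes to alpha; i->t cut when i keeps its label
    add(np.full(n_pix, src), pix, to_int(d_alpha))
    add(pix, np.full(n_pix, snk), to_int(d_keep))

    for (wmat, ij_a, ij_b) in (
        (model.wh, (pix[:, :-1], lab[:, :-1]), (pix[:, 1:], lab[:, 1:])),
        (model.wv, (pix[:-1, :], lab[:-1, :]), (pix[1:, :], lab[1:, :])),
    ):
        pi, li = ij_a[0].ravel(), ij_a[1].ravel()
        pj, lj = ij_b[0].ravel(), ij_b[1].ravel()
        wflat = wmat.ravel()
        same = li == lj
        if same.any():
            c = to_int(wflat[same] * (li[same] != alpha))
            add_sym(pi[same], pj[same], c)
        diff = ~same
        n_aux = int(diff.sum())
        if n_aux:
            aux = np.arange(next_node, next_node + n_aux, dtype=np.int64)
            next_node += n_aux
            add_sym(pi[diff], aux, to_int(wflat[diff] * (li[diff] != alpha)))
            add_sym(aux, pj[diff], to_int(wflat[diff] * (lj[diff] != alpha)))
            add(aux, np.full(n_aux, snk), to_int(wflat[diff]))

    cap = sparse.csr_matrix(
        (np.concatenate(caps), (np.concatenate(rows), np.concatenate(cols))),
        shape=(next_node, next_node), dtype=np.int64)
    cap.sum_duplicates()
    res = maximum_flow(cap, src, snk)
    residual = cap - res.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, src, directed=True,
                                return_predecessors=False)
    source_side = np.zeros(next_node, dtype=bool)
    source_side[reach] = True
    new_lab = lab.copy()
    new_lab[~source_side[:n_pix].reshape(h, w)] = alpha
    return new_lab


def alpha_expansion(model: MRFModel, init_labeling: np.ndarray | None = None,
                    max_sweeps: int = 10) -> tuple[np.ndarray, float]:
    """Minimize the MRF energy by iterated expansion moves.

    Expansion is a local search; to avoid poor local optima, when no
    ``init_labeling`` is given the search restarts from the per-pixel
    maximum-likelihood labeling and from each constant labeling, each
    combined with every label visiting order, keeping the lowest-energy
    result. Each run sweeps until no move lowers the energy (or
    ``max_sweeps``); the energy is checked to be monotonically
    non-increasing after every accepted move. Returns (labeling, final
    energy).
    """
    if np.any(model.wh < 0) or np.any(model.wv < 0):
        raise ValueError("pairwise weights must be >= 0 (metric requirement)")
    labels = list(range(model.n_labels))
    if init_labeling is None:
        import itertools

        inits = [np.argmin(model.unary, axis=2)]
        inits += [np.full(model.shape, l, dtype=np.int64) for l in labels]
        orders = (list(itertools.permutations(labels))
                  if model.n_labels <= 3 else [labels, labels[::-1]])
        results = [_expansion_run(model, init, list(order), max_sweeps)
                   for init in inits for order in orders]
        return min(results, key=lambda r: r[1])
    lab = np.asarray(init_labeling).copy()
    if lab.shape != model.shape:
        raise ValueError("init labeling shape mismatch")
    return _expansion_run(model, lab, labels, max_sweeps)


def _expansion_run(model: MRFModel, lab: np.ndarray, order: list[int],
                   max_sweeps: int) -> tuple[np.ndarray, float]:
    lab = lab.copy()
    energy = model.energy(lab)
    for _ in range(max_sweeps):
        improved = False
        for alpha in order:
            cand = _expansion_move(model, lab, alpha)
            e = model.energy(cand)
            if e < energy - 1e-12:
                assert e <= energy, "expansion move increased the energy"
                lab, energy, improved = cand, e, True
        if not improved:
            break
    return lab, energy


def segment_stack(stack: dict[str, np.ndarray], channels: list[str],
                  config: MRFConfig | None = None, seed: int = 0,
                  entropy_radius: int = 3,
                  max_mixture_samples: int = 50_000,
                  ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-channel MRF segmentation of confocal images or z-stacks + overlay.

    Each requested channel is max-projected (if 3-D), scaled to 8-bit,
    entropy-filtered, mixture-fitted and labeled by alpha-expansion. The
    overlay codes in-focus pixels: 0 = none, 1 = first channel, 2 = second
    channel, 3 = both (co-localization).
    """
    config = config or MRFConfig()
    labelings: dict[str, np.ndarray] = {}
    for ch in channels:
        if ch not in stack:
            raise KeyError(f"channel '{ch}' missing from stack")
        img = np.asarray(stack[ch], float)
        if img.ndim == 3:
            img = img.max(axis=0)  # maximum intensity projection
        img8 = scale_to_8bit(img)
        # unary feature: local entropy (texture) by default, else 8-bit
        # intensity; the mixture is always fit on the same feature the
        # unaries are evaluated on, while pairwise contrast uses raw 8-bit
        if config.mixture_on_entropy:
            feat = entropy_filter(img8, entropy_radius).astype(float)
        else:
            feat = img8.astype(float)
        flat = feat.ravel()
        if flat.size > max_mixture_samples:
            rng = np.random.default_rng(seed)
            flat = rng.choice(flat, size=max_mixture_samples, replace=False)
        mixture = fit_mixture3(flat, seed=seed, restarts=config.em_restarts)
        model = build_energy(feat, mixture, config.lambda0,
                             config.lambda1, config.beta,
                             contrast_img=img8.astype(float))
        lab, _ = alpha_expansion(model, max_sweeps=config.max_sweeps)
        labelings[ch] = lab

    overlay = np.zeros(next(iter(labelings.values())).shape, dtype=np.uint8)
    in_focus = len(LABELS) - 1
    for bit, ch in enumerate(channels[:2]):
        overlay |= ((labelings[ch] == in_focus) << bit).astype(np.uint8)
    return labelings, overlay


def unary_quantiles(model: MRFModel,
                    qs: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95)) -> dict:
    """Quantiles of the unary potentials per label, to guide manual choice of
    the pairwise parameters lambda0, lambda1, beta."""
    return {LABELS[l]: np.quantile(model.unary[..., l], qs).tolist()
            for l in range(model.n_labels)}
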