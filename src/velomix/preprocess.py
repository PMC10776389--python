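"""Preprocessing pipeline for velocity modeling.

Order of operations: gene filtering on raw counts, median-library-size
normalization (factors from pre-filter library sizes), dispersion-based HVG
selection, PCA on log1p spliced, KNN graph in PC space, neighborhood-mean
smoothing of both layers, per-gene min-max scaling to [0, 1], and
steady-state-model gene selection (positive extreme-quantile slope and
positive R^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .data import RunConfig, VelocityDataset, get_logger

__all__ = [
    "SteadyStateFit",
    "filter_genes",
    "normalize_and_hvg",
    "smooth_abundances",
    "minmax_scale",
    "steady_state_select",
    "preprocess",
]

log = get_logger("preprocess")


@dataclass
class SteadyStateFit:
    """Per-gene steady-state regression summary used for gene selection."""

    ss_ratio: np.ndarray  # through-origin slope of u on s (gamma/beta proxy)
    r2: np.ndarray
    selected: np.ndarray  # ss_ratio > 0 and r2 > 0


def filter_genes(ds: VelocityDataset, min_counts: int = 20) -> VelocityDataset:
    """Remove genes with fewer than ``min_counts`` total unspliced or spliced
    counts (genes with counts >= min_counts in both layers are kept).

    Pre-filter library sizes (total spliced counts per cell) are recorded on
    the returned dataset so normalization can use them later.
    """
    u_tot = np.asarray(ds.unspliced_raw.sum(axis=0)).ravel()
    s_tot = np.asarray(ds.spliced_raw.sum(axis=0)).ravel()
    keep = (u_tot >= min_counts) & (s_tot >= min_counts)
    if not keep.any():
        raise ValueError("all genes removed by the count filter")
    out = ds.subset_genes(keep)
    if out.libsize_prefilter is None:
        out.libsize_prefilter = np.asarray(ds.spliced_raw.sum(axis=1)).ravel()
    log.info("filter_genes kept %d/%d genes (min_counts=%d)", keep.sum(), ds.n_genes, min_counts)
    return out


def _normalized_layers(ds: VelocityDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lib = ds.libsize_prefilter
    if lib is None:
        lib = np.asarray(ds.spliced_raw.sum(axis=1)).ravel()
    zero = lib == 0
    if zero.any():
        warnings.warn(f"{zero.sum()} zero-library cells excluded from scaling")
    factors = np.ones_like(lib, dtype=float)
    factors[~zero] = np.median(lib[~zero]) / lib[~zero]
    u = ds.unspliced_raw.multiply(factors[:, None]).toarray()
    s = ds.spliced_raw.multiply(factors[:, None]).toarray()
    return u, s, factors


def dispersion_scores(spliced_norm: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean-binned normalized dispersion of log1p spliced abundances.

    Dispersion is var/mean of the log1p values; genes are placed into
    ``n_bins`` equal-frequency mean bins and dispersions z-scored per bin.
    Constant genes receive the lowest possible score.
    """
    x = np.log1p(spliced_norm)
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    n_bins = min(n_bins, max(1, len(mean)))
    # equal-frequency bins over gene means
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.arange(len(mean)) * n_bins // len(mean)
    score = np.zeros_like(disp)
    for b in np.unique(bins):
        idx = bins == b
        mu, sd = disp[idx].mean(), disp[idx].std()
        score[idx] = (disp[idx] - mu) / sd if sd > 0 else 0.0
    score[var < 1e-12] = -np.inf  # constant genes rank last
    return score


def normalize_and_hvg(ds: VelocityDataset, n_hvg: int = 2000) -> VelocityDataset:
    """Median-library normalization (same per-cell factors for both layers)
    followed by selection of the ``n_hvg`` most dispersed genes."""
    u, s, _ = _normalized_layers(ds)
    if n_hvg < ds.n_genes:
        score = dispersion_scores(s)
        # top-n by score, original gene order preserved
        cutoff_idx = np.argsort(score, kind="stable")[::-1][:n_hvg]
        keep = np.zeros(ds.n_genes, dtype=bool)
        keep[cutoff_idx] = True
    else:
        keep = np.ones(ds.n_genes, dtype=bool)
    out = ds.subset_genes(keep)
    out.unspliced_smooth = u[:, keep]  # pre-smoothing normalized values
    out.spliced_smooth = s[:, keep]
    log.info("normalize_and_hvg kept %d genes", keep.sum())
    return out


def smooth_abundances(
    ds: VelocityDataset, n_pcs: int = 30, k: int = 30, seed: int = 0
) -> VelocityDataset:
    """PCA on log1p spliced, KNN graph (Euclidean in PC space, self included),
    and neighborhood-mean smoothing of both normalized layers."""
    out = ds.copy()
    if out.spliced_smooth is None:
        u, s, _ = _normalized_layers(ds)
        out.unspliced_smooth, out.spliced_smooth = u, s
    n = out.n_cells
    if n <= k:
        warnings.warn(f"k={k} >= n_cells={n}; reducing k to {n - 1}")
        k = n - 1
    x = np.log1p(out.spliced_smooth)
    n_pcs = min(n_pcs, min(x.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    pcs = pca.fit_transform(x - 0.0)
    # deterministic sign convention: largest-magnitude loading positive
    signs = np.sign(
        pca.components_[np.arange(n_pcs), np.argmax(np.abs(pca.components_), axis=1)]
    )
    signs[signs == 0] = 1.0
    pcs = pcs * signs
    out.pca = pcs
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, idx = nn.kneighbors(pcs)  # self is its own nearest neighbor
    rows = np.repeat(np.arange(n), k)
    graph = sp.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    out.neighbor_graph = graph
    out.unspliced_smooth = out.unspliced_smooth[idx].mean(axis=1)
    out.spliced_smooth = out.spliced_smooth[idx].mean(axis=1)
    log.info("smoothed abundances with k=%d over %d PCs", k, n_pcs)
    return out


def minmax_scale(ds: VelocityDataset) -> VelocityDataset:
    """Per-gene, per-layer min-max scaling of smoothed abundances to [0, 1];
    constant genes map to all zeros."""
    if ds.unspliced_smooth is None or ds.spliced_smooth is None:
        raise ValueError("smoothed layers required before scaling")
    out = ds.copy()
    scales = {}
    for name in ("unspliced", "spliced"):
        x = getattr(ds, f"{name}_smooth")
        lo = x.min(axis=0)
        rng = x.max(axis=0) - lo
        const = rng == 0
        if const.any():
            warnings.warn(f"{const.sum()} constant genes scaled to all zeros ({name})")
        safe = np.where(const, 1.0, rng)
        setattr(out, f"{name}_scaled", np.where(const, 0.0, (x - lo) / safe))
        scales[name] = (lo, rng)
    out.scale_ranges = scales  # min and range per layer, for de-scaling
    return out


def steady_state_select(
    ds: VelocityDataset, quantile: float = 0.05, r2_on_all: bool = True
) -> SteadyStateFit:
    """Steady-state regression per gene on the scaled abundances.

    The slope (gamma/beta proxy) is a through-origin least-squares fit of u on
    s restricted to cells in the top and bottom ``quantile`` of u + s; R^2 is
    computed against the line u = slope * s on all cells (restricting it to
    the extreme subset via ``r2_on_all=False`` is far more permissive: even
    independent noise then passes, because a through-origin line always fits
    the two extreme corners).  A gene is selected when both the slope and
    R^2 are positive.
    """
    u, s = ds.unspliced_scaled, ds.spliced_scaled
    if u is None or s is None:
        raise ValueError("scaled layers required for steady-state selection")
    n, g = u.shape
    total = u + s
    lo_cut = np.quantile(total, quantile, axis=0)
    hi_cut = np.quantile(total, 1 - quantile, axis=0)
    extreme = (total <= lo_cut) | (total >= hi_cut)
    ss_ratio = np.full(g, np.nan)
    r2 = np.full(g, np.nan)
    for j in range(g):
        m = extreme[:, j]
        ss2 = float(s[m, j] @ s[m, j])
        if ss2 == 0:
            continue
        slope = float(u[m, j] @ s[m, j]) / ss2
        uj, sj = (u[:, j], s[:, j]) if r2_on_all else (u[m, j], s[m, j])
        res = uj - slope * sj
        tot = uj - uj.mean()
        denom = float(tot @ tot)
        if denom == 0:
            continue
        ss_ratio[j] = slope
        r2[j] = 1.0 - float(res @ res) / denom
    selected = np.nan_to_num(ss_ratio, nan=-1) > 0
    selected &= np.nan_to_num(r2, nan=-1) > 0
    return SteadyStateFit(ss_ratio=ss_ratio, r2=r2, selected=selected)


def preprocess(
    ds: VelocityDataset,
    config: RunConfig | None = None,
    normalize: bool = True,
    select_genes: bool = False,
) -> VelocityDataset:
    """Full pipeline: filter -> (normalize + HVG) -> smooth -> scale
    [-> steady-state gene selection].

    ``normalize=False`` skips library-size normalization and HVG selection,
    appropriate for simulated abundances that carry no library-size artifact.
    """
    cfg = config or RunConfig()
    ds = filter_genes(ds, cfg.min_counts)
    if normalize:
        ds = normalize_and_hvg(ds, cfg.n_hvg)
    ds = smooth_abundances(ds, cfg.n_pcs, cfg.knn_k, cfg.seed)
    ds = minmax_scale(ds)
    if select_genes:
        fit = steady_state_select(ds, cfg.ss_quantile)
        if fit.selected.any():
            ds = ds.subset_genes(fit.selected)
        else:
            warnings.warn("steady-state selection kept no genes; skipping")
    return ds
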