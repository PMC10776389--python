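"""Core data containers, readers/writers and run configuration.

The central container is :class:`VelocityDataset`, a thin cells-by-genes
wrapper around raw unspliced/spliced count layers plus the derived matrices
produced by preprocessing (KNN-smoothed and unit-scaled abundances, PCA,
neighbor graph).  It converts losslessly to/from :class:`anndata.AnnData`,
which backs the h5ad reader/writer; loom files are handled directly through
h5py (genes-by-cells ``/matrix`` with ``/layers``, ``/row_attrs`` and
``/col_attrs``), and MatrixMarket directories hold ``unspliced.mtx`` /
``spliced.mtx`` with barcode/feature TSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

__all__ = [
    "VelocityDataset",
    "RunConfig",
    "load_config",
    "read_dataset",
    "write_dataset",
    "get_logger",
]


# ---------------------------------------------------------------------------
# logging: newline-delimited structured records with level + stage tags
# ---------------------------------------------------------------------------

class _StageFormatter(logging.Formatter):
    def format(self, record):
        stage = getattr(record, "stage", "core")
        return f"{self.formatTime(record, '%Y-%m-%dT%H:%M:%S')}\t{record.levelname}\t{stage}\t{record.getMessage()}"


def get_logger(stage: str = "core") -> logging.LoggerAdapter:
    """Structured logger tagging each line with the pipeline stage."""
    logger = logging.getLogger("velomix")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(_StageFormatter())
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logging.LoggerAdapter(logger, {"stage": stage})


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable constants of the pipeline with their reference defaults.

    The latent dimension d, time horizon t_max, Dirichlet concentration,
    repression-steady-state variance factor c4, switch-penalty weight,
    minibatch size, number of posterior samples L, permutation sample cap,
    and the preprocessing constants (k=30 neighbors, 30 PCs, 2,000 HVGs,
    20-count gene filter) follow the reference protocol.
    """

    n_latent: int = 10
    t_max: float = 20.0
    dirichlet_conc: float = 0.25
    c4_scale: float = 0.1
    switch_penalty_weight: float = 0.2
    batch_size: int = 256
    n_posterior_samples: int = 100
    permutation_n_cap: int = 200
    knn_k: int = 30
    n_pcs: int = 30
    n_hvg: int = 2000
    min_counts: int = 20
    ss_quantile: float = 0.05
    kernel_scale: float = 10.0
    seed: int = 0
    learning_rate: float = 1e-2
    weight_decay: float = 1e-4
    max_epochs: int = 500
    patience: int = 45
    n_hidden: int = 256
    kl_warmup_epochs: int = 400  # linear anneal of both KL terms from 0 to 1
    lr_decay: float = 0.3  # step-size factor applied once warm-up completes

    def __post_init__(self):
        positive = (
            "t_max", "dirichlet_conc", "c4_scale", "switch_penalty_weight",
            "learning_rate", "kernel_scale", "ss_quantile",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be strictly positive")
        for name in ("n_latent", "batch_size", "n_posterior_samples",
                     "permutation_n_cap", "knn_k", "n_pcs", "n_hvg", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"config field {name} must be >= 1")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def load_config(path) -> RunConfig:
    """Read a YAML or JSON config; unspecified keys keep reference defaults,
    unknown keys warn and are ignored."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    raw = raw or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
    return RunConfig(**{k: v for k, v in raw.items() if k in known})


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

_REAL_FIELDS = (
    "unspliced_smooth", "spliced_smooth", "unspliced_scaled", "spliced_scaled",
)


@dataclass
class VelocityDataset:
    """Cells-by-genes unspliced/spliced matrices with derived layers.

    Raw layers are kept sparse (CSR); smoothed and scaled layers are dense
    since KNN averaging densifies them.  ``neighbor_graph`` is a binary CSR
    adjacency with exactly k entries per row (the cell itself included),
    matching the smoothing convention.
    """

    unspliced_raw: sp.csr_matrix
    spliced_raw: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_type: np.ndarray | None = None
    unspliced_smooth: np.ndarray | None = None
    spliced_smooth: np.ndarray | None = None
    unspliced_scaled: np.ndarray | None = None
    spliced_scaled: np.ndarray | None = None
    neighbor_graph: sp.csr_matrix | None = None
    pca: np.ndarray | None = None
    libsize_prefilter: np.ndarray | None = None
    obs_extra: pd.DataFrame | None = None
    var_extra: pd.DataFrame | None = None
    layers_extra: dict = field(default_factory=dict)
    scale_ranges: dict | None = None  # per-layer (min, range) from min-max scaling

    def __post_init__(self):
        self.unspliced_raw = sp.csr_matrix(self.unspliced_raw)
        self.spliced_raw = sp.csr_matrix(self.spliced_raw)
        if self.unspliced_raw.shape != self.spliced_raw.shape:
            raise ValueError(
                f"layer shape mismatch: unspliced {self.unspliced_raw.shape} "
                f"vs spliced {self.spliced_raw.shape}"
            )
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, g = self.unspliced_raw.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("cell/gene id lengths do not match matrix shape")
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)

    @property
    def n_cells(self) -> int:
        return self.unspliced_raw.shape[0]

    @property
    def n_genes(self) -> int:
        return self.unspliced_raw.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.unspliced_raw.shape

    def copy(self) -> "VelocityDataset":
        new = dataclasses.replace(self)
        new.unspliced_raw = self.unspliced_raw.copy()
        new.spliced_raw = self.spliced_raw.copy()
        for f in _REAL_FIELDS + ("pca", "libsize_prefilter"):
            v = getattr(self, f)
            if v is not None:
                setattr(new, f, v.copy())
        if self.neighbor_graph is not None:
            new.neighbor_graph = self.neighbor_graph.copy()
        if self.obs_extra is not None:
            new.obs_extra = self.obs_extra.copy()
        if self.var_extra is not None:
            new.var_extra = self.var_extra.copy()
        new.layers_extra = {k: v.copy() for k, v in self.layers_extra.items()}
        return new

    def subset_genes(self, mask: np.ndarray) -> "VelocityDataset":
        mask = np.asarray(mask)
        new = self.copy()
        new.unspliced_raw = sp.csr_matrix(self.unspliced_raw[:, mask])
        new.spliced_raw = sp.csr_matrix(self.spliced_raw[:, mask])
        new.gene_ids = self.gene_ids[mask]
        for f in _REAL_FIELDS:
            v = getattr(self, f)
            if v is not None:
                setattr(new, f, v[:, mask])
        if self.var_extra is not None:
            new.var_extra = self.var_extra.loc[mask].reset_index(drop=True)
        new.layers_extra = {k: v[:, mask] for k, v in self.layers_extra.items()}
        if self.scale_ranges is not None:
            new.scale_ranges = {
                name: (lo[mask], rng[mask]) for name, (lo, rng) in self.scale_ranges.items()
            }
        return new

    # -- AnnData conversion ---------------------------------------------------
    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.spliced_raw.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids.astype(str), name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene_id")),
        )
        adata.layers["unspliced"] = self.unspliced_raw.copy()
        adata.layers["spliced"] = self.spliced_raw.copy()
        if self.cell_type is not None:
            adata.obs["cell_type"] = pd.Categorical(self.cell_type.astype(str))
        for f in _REAL_FIELDS:
            v = getattr(self, f)
            if v is not None:
                adata.layers[f] = np.asarray(v)
        for name, v in self.layers_extra.items():
            adata.layers[name] = np.asarray(v)
        if self.neighbor_graph is not None:
            adata.obsp["neighbor_graph"] = self.neighbor_graph
        if self.pca is not None:
            adata.obsm["X_pca"] = self.pca
        if self.libsize_prefilter is not None:
            adata.obs["libsize_prefilter"] = self.libsize_prefilter
        if self.obs_extra is not None:
            for c in self.obs_extra.columns:
                adata.obs[c] = np.asarray(self.obs_extra[c])
        if self.var_extra is not None:
            for c in self.var_extra.columns:
                adata.var[c] = np.asarray(self.var_extra[c])
        return adata

    @classmethod
    def from_anndata(
        cls,
        adata: ad.AnnData,
        unspliced_layer: str = "unspliced",
        spliced_layer: str = "spliced",
    ) -> "VelocityDataset":
        for layer in (unspliced_layer, spliced_layer):
            if layer not in adata.layers:
                raise KeyError(
                    f"layer not found: {layer!r}; available layers: "
                    f"{sorted(adata.layers.keys())}"
                )
        known_obs = {"cell_type", "libsize_prefilter"}
        obs_extra = adata.obs.drop(
            columns=[c for c in known_obs if c in adata.obs], errors="ignore"
        )
        ds = cls(
            unspliced_raw=sp.csr_matrix(adata.layers[unspliced_layer]),
            spliced_raw=sp.csr_matrix(adata.layers[spliced_layer]),
            cell_ids=adata.obs_names.to_numpy(),
            gene_ids=adata.var_names.to_numpy(),
            cell_type=(
                adata.obs["cell_type"].to_numpy() if "cell_type" in adata.obs else None
            ),
            libsize_prefilter=(
                np.asarray(adata.obs["libsize_prefilter"])
                if "libsize_prefilter" in adata.obs
                else None
            ),
            obs_extra=obs_extra.reset_index(drop=True) if len(obs_extra.columns) else None,
            var_extra=(
                adata.var.reset_index(drop=True) if len(adata.var.columns) else None
            ),
        )
        for f in _REAL_FIELDS:
            if f in adata.layers:
                setattr(ds, f, np.asarray(adata.layers[f]))
        for name in adata.layers:
            if name not in _REAL_FIELDS + ("unspliced", "spliced"):
                ds.layers_extra[name] = np.asarray(adata.layers[name])
        if "neighbor_graph" in adata.obsp:
            ds.neighbor_graph = sp.csr_matrix(adata.obsp["neighbor_graph"])
        if "X_pca" in adata.obsm:
            ds.pca = np.asarray(adata.obsm["X_pca"])
        return ds


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    if path.suffix == ".h5ad":
        return "h5ad"
    if path.suffix == ".loom":
        return "loom"
    if path.is_dir() or path.suffix == "":
        return "mtx_dir"
    raise ValueError(f"cannot infer format of {path}")


def read_dataset(
    path,
    format: str | None = None,
    unspliced_layer: str = "unspliced",
    spliced_layer: str = "spliced",
) -> VelocityDataset:
    """Read a dataset from h5ad, loom, or an MTX+TSV directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "h5ad":
        adata = ad.read_h5ad(path)
        return VelocityDataset.from_anndata(adata, unspliced_layer, spliced_layer)
    if fmt == "loom":
        return _read_loom(path, unspliced_layer, spliced_layer)
    if fmt == "mtx_dir":
        return _read_mtx_dir(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_dataset(ds: VelocityDataset, path, format: str | None = None):
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "h5ad":
        ds.to_anndata().write_h5ad(path)
    elif fmt == "loom":
        _write_loom(ds, path)
    elif fmt == "mtx_dir":
        _write_mtx_dir(ds, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


# loom layout: /matrix is genes x cells; layers follow the same orientation
def _write_loom(ds: VelocityDataset, path: Path):
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=np.asarray(ds.spliced_raw.todense()).T)
        layers = f.create_group("layers")
        layers.create_dataset("spliced", data=np.asarray(ds.spliced_raw.todense()).T)
        layers.create_dataset("unspliced", data=np.asarray(ds.unspliced_raw.todense()).T)
        for name in _REAL_FIELDS:
            v = getattr(ds, name)
            if v is not None:
                layers.create_dataset(name, data=np.asarray(v).T)
        row_attrs = f.create_group("row_attrs")
        row_attrs.create_dataset(
            "Gene", data=np.array([str(g) for g in ds.gene_ids], dtype="S")
        )
        col_attrs = f.create_group("col_attrs")
        col_attrs.create_dataset(
            "CellID", data=np.array([str(c) for c in ds.cell_ids], dtype="S")
        )
        if ds.cell_type is not None:
            col_attrs.create_dataset(
                "cell_type", data=np.array([str(c) for c in ds.cell_type], dtype="S")
            )


def _read_loom(path: Path, unspliced_layer: str, spliced_layer: str) -> VelocityDataset:
    with h5py.File(path, "r") as f:
        layers = f["layers"] if "layers" in f else {}
        available = sorted(layers.keys()) if layers else []
        for name in (unspliced_layer, spliced_layer):
            if name not in layers:
                raise KeyError(f"layer not found: {name!r}; available layers: {available}")
        u = np.asarray(layers[unspliced_layer]).T
        s = np.asarray(layers[spliced_layer]).T
        gene_ids = np.array([g.decode() for g in f["row_attrs"]["Gene"][:]], dtype=object)
        cell_ids = np.array([c.decode() for c in f["col_attrs"]["CellID"][:]], dtype=object)
        cell_type = None
        if "cell_type" in f["col_attrs"]:
            cell_type = np.array(
                [c.decode() for c in f["col_attrs"]["cell_type"][:]], dtype=object
            )
        ds = VelocityDataset(
            unspliced_raw=sp.csr_matrix(u),
            spliced_raw=sp.csr_matrix(s),
            cell_ids=cell_ids,
            gene_ids=gene_ids,
            cell_type=cell_type,
        )
        for name in _REAL_FIELDS:
            if name in layers:
                setattr(ds, name, np.asarray(layers[name]).T)
        return ds


def _write_mtx_dir(ds: VelocityDataset, path: Path):
    from scipy.io import mmwrite

    path.mkdir(parents=True, exist_ok=True)
    mmwrite(path / "unspliced.mtx", sp.coo_matrix(ds.unspliced_raw))
    mmwrite(path / "spliced.mtx", sp.coo_matrix(ds.spliced_raw))
    pd.Series(ds.cell_ids.astype(str)).to_csv(
        path / "barcodes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(ds.gene_ids.astype(str)).to_csv(
        path / "features.tsv", sep="\t", index=False, header=False
    )
    if ds.cell_type is not None:
        pd.Series(ds.cell_type.astype(str)).to_csv(
            path / "cell_types.tsv", sep="\t", index=False, header=False
        )


def _read_mtx_dir(path: Path) -> VelocityDataset:
    from scipy.io import mmread

    for name in ("unspliced.mtx", "spliced.mtx"):
        if not (path / name).exists():
            present = sorted(p.name for p in path.glob("*.mtx"))
            raise KeyError(f"layer not found: {name!r}; available layers: {present}")
    u = sp.csr_matrix(mmread(path / "unspliced.mtx"))
    s = sp.csr_matrix(mmread(path / "spliced.mtx"))
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(object)
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].to_numpy(object)
    cell_type = None
    if (path / "cell_types.tsv").exists():
        cell_type = pd.read_csv(path / "cell_types.tsv", sep="\t", header=None)[0].to_numpy(
            object
        )
    return VelocityDataset(u, s, cells, genes, cell_type=cell_type)
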