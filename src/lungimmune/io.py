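"""File formats and configuration.

Count matrices travel as Matrix Market (genes x cells, integer counts) with
``barcodes.tsv`` (cell id, condition, pseudo-sample, truth subtype) and
``features.tsv`` (gene id, symbol) sidecars.  Gene sets are GMT, the
ligand–receptor database is a two-column TSV (``source``, ``target``) with
"_"-joined complex subunits, tabular results are CSV, and the pipeline
configuration is YAML with unknown keys rejected.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .clustering import ClusteringParams, MarkerFilter
from .enrichment import EnrichmentParams
from .interaction import InteractionParams, LRDatabase
from .qc import PCAParams, QCThresholds
from .synthetic import GeneratorParams

__all__ = ["read_counts", "write_counts", "read_gmt", "write_gmt",
           "read_lr_db", "write_lr_db", "PipelineConfig", "packaged_data_path"]

_DATA_DIR = Path(__file__).parent / "data"


def packaged_data_path(name: str) -> Path:
    """Path of a packaged fixture (GMT gene sets, LR database)."""
    path = _DATA_DIR / name
    if not path.exists():
        raise FileNotFoundError(f"no packaged data file named {name!r}")
    return path


def write_counts(adata: ad.AnnData, directory: str | Path) -> Path:
    """Write matrix.mtx (genes x cells) + barcodes.tsv + features.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = sparse.csr_matrix(adata.X)
    spio.mmwrite(directory / "matrix.mtx", X.T.astype(np.int64))
    obs = adata.obs
    barcodes = pd.DataFrame({
        "cell": adata.obs_names,
        "condition": obs.get("condition", pd.Series("NA", index=obs.index)),
        "sample": obs.get("sample", pd.Series("NA", index=obs.index)),
        "subtype": obs.get("subtype", pd.Series("NA", index=obs.index)),
    })
    barcodes.to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)
    features = pd.DataFrame({"gene_id": adata.var_names, "symbol": adata.var_names})
    features.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    return directory


def read_counts(directory: str | Path) -> ad.AnnData:
    """Read a matrix.mtx + barcodes.tsv + features.tsv bundle.

    Dimensional mismatches and malformed MTX headers raise errors naming
    the offending file; duplicated gene symbols are suffixed (``-1``, ...)
    with a warning.
    """
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    bc = directory / "barcodes.tsv"
    ft = directory / "features.tsv"
    for path in (mtx, bc, ft):
        if not path.exists():
            raise FileNotFoundError(f"missing sidecar or matrix file: {path}")
    try:
        X = spio.mmread(mtx)
    except Exception as exc:  # malformed header / entries
        raise ValueError(f"malformed Matrix Market file {mtx}: {exc}") from exc
    X = sparse.csr_matrix(X).T  # cells x genes
    barcodes = pd.read_csv(bc, sep="\t", header=None,
                           names=["cell", "condition", "sample", "subtype"])
    features = pd.read_csv(ft, sep="\t", header=None, names=["gene_id", "symbol"])
    if X.shape[0] != len(barcodes):
        raise ValueError(
            f"{mtx} has {X.shape[0]} cells but {bc} lists {len(barcodes)}")
    if X.shape[1] != len(features):
        raise ValueError(
            f"{mtx} has {X.shape[1]} genes but {ft} lists {len(features)}")
    symbols = features["symbol"].astype(str).tolist()
    if len(set(symbols)) != len(symbols):
        warnings.warn("duplicate gene symbols in features.tsv; suffixing")
        seen: dict[str, int] = {}
        deduped = []
        for s in symbols:
            if s in seen:
                seen[s] += 1
                deduped.append(f"{s}-{seen[s]}")
            else:
                seen[s] = 0
                deduped.append(s)
        symbols = deduped
    obs = barcodes.set_index("cell")
    var = pd.DataFrame(index=pd.Index(symbols, name="gene"))
    var["mito"] = var.index.str.lower().str.startswith("mt-")
    adata = ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)
    adata.obs["qc_spike"] = adata.obs.get("qc_spike", "none")
    return adata


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: gene list}; empty sets are skipped."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(g.strip() for g in parts[2:]):
            warnings.warn(f"{path}:{lineno}: gene set with no genes skipped")
            continue
        sets[parts[0]] = [g for g in parts[2:] if g.strip()]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(genes)
             for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_lr_db(path: str | Path, source_tag: str | None = None) -> LRDatabase:
    """Read a ligand–receptor TSV (columns ``source``, ``target``)."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("source", "target"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return LRDatabase.from_frame(frame, source_tag=source_tag or Path(path).stem)


def write_lr_db(db: LRDatabase, path: str | Path) -> None:
    frame = pd.DataFrame({
        "source": [LRDatabase.unit_name(l) for l, _ in db.pairs],
        "target": [LRDatabase.unit_name(r) for _, r in db.pairs],
    })
    frame.to_csv(path, sep="\t", index=False)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class PipelineConfig:
    """Fully-resolved run configuration.

    Unknown keys in the YAML are rejected; every run echoes the resolved
    configuration next to its outputs so any stage can be rerun in
    isolation.
    """

    outdir: str = "lungimmune_run"
    counts_path: str | None = None  # None: simulate instead of reading
    gmt_path: str | None = None     # None: packaged fixture
    lr_db_path: str | None = None   # None: packaged fixture
    seed: int = 0
    conditions: tuple[str, ...] = ("healthy", "LLC1", "Kras")
    qc: QCThresholds = field(default_factory=QCThresholds)
    pca: PCAParams = field(default_factory=PCAParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    marker_filter: MarkerFilter = field(default_factory=MarkerFilter)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    interaction: InteractionParams = field(default_factory=InteractionParams)
    generator: GeneratorParams = field(default_factory=GeneratorParams)

    _BLOCKS = {"qc": QCThresholds, "pca": PCAParams, "clustering": ClusteringParams,
               "marker_filter": MarkerFilter, "enrichment": EnrichmentParams,
               "interaction": InteractionParams, "generator": GeneratorParams}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        scalar_keys = {f.name for f in fields(cls)} - set(cls._BLOCKS)
        unknown = set(raw) - scalar_keys - set(cls._BLOCKS)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        kwargs: dict = {}
        for key, value in raw.items():
            if key in cls._BLOCKS:
                block_cls = cls._BLOCKS[key]
                known = {f.name for f in fields(block_cls)}
                bad = set(value) - known
                if bad:
                    raise ValueError(f"{path}: unknown keys {sorted(bad)} in block {key!r}")
                value = {k: tuple(v) if isinstance(v, list) else v
                         for k, v in value.items()}
                kwargs[key] = block_cls(**value)
            elif key == "conditions":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        payload: dict = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name in self._BLOCKS:
                payload[f.name] = {k: (list(v) if isinstance(v, tuple) else v)
                                   for k, v in asdict(value).items()}
            elif isinstance(value, tuple):
                payload[f.name] = list(value)
            else:
                payload[f.name] = value
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
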