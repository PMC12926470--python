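"""Ground-truth synthetic CD45+ scRNA-seq data.

Generates sparse count matrices that emulate sorted immune cells from a
three-condition design (healthy / LLC1 / Kras), with known subtype labels,
condition-specific marker programs, a mitochondrial gene block, optional QC
failure spikes and planted ligand–receptor co-expression.  Counts follow a
negative-binomial model: per-gene baseline means are log-normal across genes,
marker means are shifted multiplicatively (``exp(log_fold_boost)``) in the
owning population, and a single global dispersion theta controls
overdispersion (``var = mu + mu^2 / theta``).

Cells are assigned subtypes by a multinomial draw from a
:class:`CompositionProfile` and partitioned round-robin into pseudo-samples,
which stand in for the biological replicates the real experiment pooled away
before sequencing.  All randomness flows from one ``numpy`` generator seeded
by ``GeneratorParams.seed``, so identical inputs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CompositionProfile",
    "ProgramSpec",
    "GeneratorParams",
    "generate_dataset",
    "spike_qc_failures",
    "plant_lr_signal",
]

MITO_PREFIX = "mt-"
#: decoy genes included so the gene-family exclusion rules have work to do
RIBO_DECOYS = ["Rps19", "Rps29", "Rpl13", "Rpl37", "Rplp1"]
SEX_DECOYS = ["Xist", "Ddx3y"]
#: ligand/receptor partners kept in the universe at baseline expression so
#: the packaged LR database is testable on generated data
LR_PARTNERS = ["Ccr5", "Xcr1", "Cd40", "Selplg", "Il17ra", "Icosl",
               "Tgfb1", "Tgfbr1", "Tgfbr2", "Cd80", "Cd69", "Ptprc"]


@dataclass(frozen=True)
class CompositionProfile:
    """Expected subtype composition of one condition.

    ``subtype_fractions`` must be non-negative and sum to 1; every subtype
    maps to exactly one major compartment via ``compartment_of``.
    """

    condition: str
    subtype_fractions: dict[str, float]
    compartment_of: dict[str, str]

    def __post_init__(self) -> None:
        fr = self.subtype_fractions
        if not fr:
            raise ValueError("subtype_fractions is empty")
        if any(v < 0 for v in fr.values()):
            raise ValueError("subtype fractions must be non-negative")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype fractions sum to {total!r}, expected 1")
        missing = set(fr) - set(self.compartment_of)
        if missing:
            raise ValueError(f"subtypes without a compartment: {sorted(missing)}")

    @property
    def subtypes(self) -> list[str]:
        return list(self.subtype_fractions)

    def compartment_fractions(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for s, f in self.subtype_fractions.items():
            c = self.compartment_of[s]
            out[c] = out.get(c, 0.0) + f
        return out


@dataclass(frozen=True)
class ProgramSpec:
    """A marker program: genes boosted in one population.

    ``subtype`` may name either a subtype or a compartment; the program then
    applies to every cell of that population.  ``condition=None`` applies the
    program under every condition (identity markers); a condition label
    restricts it (condition-specific programs).  The boost is a shift of the
    natural-log mean, i.e. means are multiplied by ``exp(log_fold_boost)``.
    """

    subtype: str
    condition: str | None
    marker_genes: list[str]
    log_fold_boost: float

    def __post_init__(self) -> None:
        if not self.marker_genes:
            raise ValueError("marker_genes must be non-empty")
        if self.log_fold_boost <= 0:
            raise ValueError("log_fold_boost must be > 0")


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the count simulator.

    ``mito_target_fraction`` is the expected share of each cell's counts
    contributed by the mitochondrial block; it must sit below the QC cutoff
    (8%) so clean cells pass quality control.
    """

    n_genes: int = 2000
    n_cells_per_condition: int = 3000
    n_pseudo_samples_per_condition: int = 3
    baseline_log_mean: float = -0.7
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 2.0
    mito_gene_count: int = 13
    mito_target_fraction: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells_per_condition",
                     "n_pseudo_samples_per_condition", "mito_gene_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.mito_target_fraction < 1.0:
            raise ValueError("mito_target_fraction must be in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial counts via the gamma–Poisson mixture."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam)


def _gene_universe(programs: list[ProgramSpec], params: GeneratorParams) -> pd.Index:
    marker_genes: list[str] = []
    seen: set[str] = set()
    for p in programs:
        for g in p.marker_genes:
            if g not in seen:
                seen.add(g)
                marker_genes.append(g)
    mito = [f"{MITO_PREFIX}{i}" for i in
            ["Nd1", "Nd2", "Co1", "Co2", "Atp8", "Atp6", "Co3", "Nd3", "Nd4l",
             "Nd4", "Nd5", "Nd6", "Cytb"][: params.mito_gene_count]]
    if len(mito) < params.mito_gene_count:
        mito += [f"{MITO_PREFIX}X{i}" for i in range(params.mito_gene_count - len(mito))]
    decoys = [g for g in RIBO_DECOYS + SEX_DECOYS + LR_PARTNERS if g not in seen]
    named = marker_genes + decoys + mito
    n_filler = params.n_genes - len(named)
    if n_filler < 0:
        raise ValueError(
            f"n_genes={params.n_genes} is smaller than the {len(named)} named "
            "genes (markers + decoys + mitochondrial block)")
    filler = [f"Gene{i:05d}" for i in range(n_filler)]
    return pd.Index(marker_genes + decoys + filler + mito, name="gene")


def generate_dataset(
    profile: CompositionProfile | list[CompositionProfile],
    programs: list[ProgramSpec],
    params: GeneratorParams,
) -> ad.AnnData:
    """Simulate counts for one condition (or several, concatenated).

    Returns an :class:`anndata.AnnData` with raw integer counts in ``X``
    (CSR), truth labels in ``obs`` (``condition``, ``sample``, ``subtype``,
    ``compartment``) and a boolean ``mito`` flag in ``var``.
    """
    profiles = [profile] if isinstance(profile, CompositionProfile) else list(profile)
    if not profiles:
        raise ValueError("no composition profile given")
    known = {s for p in profiles for s in p.subtypes}
    compartments = {c for p in profiles for c in p.compartment_of.values()}
    for prog in programs:
        if prog.subtype not in known and prog.subtype not in compartments:
            raise ValueError(f"program references unknown subtype {prog.subtype!r}")

    rng = np.random.default_rng(params.seed)
    genes = _gene_universe(programs, params)
    n_genes = len(genes)
    is_mito = genes.str.lower().str.startswith(MITO_PREFIX)

    # Baseline means: log-normal across genes; program genes pinned to the
    # central baseline so planted signals are never buried in the low tail.
    base_mu = np.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sd,
                                n_genes))
    program_genes = sorted({g for p in programs for g in p.marker_genes})
    base_mu[genes.get_indexer(program_genes)] = np.exp(params.baseline_log_mean)
    # Mitochondrial block sized to hit the target fraction of total counts.
    nonmito_total = base_mu[~is_mito].sum()
    f = params.mito_target_fraction
    base_mu[np.asarray(is_mito)] = f / (1 - f) * nonmito_total / params.mito_gene_count

    obs_frames: list[pd.DataFrame] = []
    blocks: list[sparse.csr_matrix] = []
    for prof in profiles:
        n = params.n_cells_per_condition
        subtypes = np.array(prof.subtypes)
        p = np.array([prof.subtype_fractions[s] for s in subtypes], dtype=float)
        labels = subtypes[rng.choice(len(subtypes), size=n, p=p)]
        samples = np.array([
            f"{prof.condition}_s{i % params.n_pseudo_samples_per_condition + 1}"
            for i in range(n)])
        obs_frames.append(pd.DataFrame({
            "condition": prof.condition,
            "sample": samples,
            "subtype": labels,
            "compartment": [prof.compartment_of[s] for s in labels],
        }))
        # Per-subtype mean vectors, then one NB block draw per subtype.
        cond_counts = np.zeros((n, n_genes), dtype=np.int64)
        for subtype in subtypes:
            idx = np.flatnonzero(labels == subtype)
            if idx.size == 0:
                continue
            mu = base_mu.copy()
            for prog in programs:
                owns = prog.subtype in (subtype, prof.compartment_of[subtype])
                if owns and prog.condition in (None, prof.condition):
                    cols = genes.get_indexer(prog.marker_genes)
                    if (cols < 0).any():
                        raise ValueError("program gene missing from universe")
                    mu[cols] *= np.exp(prog.log_fold_boost)
            draws = _nb_draw(rng, np.broadcast_to(mu, (idx.size, n_genes)),
                             params.nb_dispersion)
            cond_counts[idx] = draws
        blocks.append(sparse.csr_matrix(cond_counts))

    obs = pd.concat(obs_frames, ignore_index=True)
    obs.index = pd.Index([f"cell{i:06d}" for i in range(len(obs))], name="cell")
    obs["qc_spike"] = "none"
    var = pd.DataFrame({"mito": np.asarray(is_mito)}, index=genes)
    X = sparse.vstack(blocks, format="csr")
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["generator_params"] = {
        "seed": params.seed,
        "nb_dispersion": params.nb_dispersion,
        "mito_target_fraction": params.mito_target_fraction,
    }
    return adata


def spike_qc_failures(
    adata: ad.AnnData,
    n_low_gene_cells: int,
    n_high_mito_cells: int,
    params: GeneratorParams,
    *,
    min_genes: int = 300,
    mito_fraction: float = 0.25,
) -> ad.AnnData:
    """Append cells engineered to fail exactly one QC rule each.

    Low-gene spikes express far fewer genes than ``min_genes`` with zero
    mitochondrial counts; high-mito spikes express plenty of genes but carry
    ``mito_fraction`` of their counts in the mitochondrial block.  Clean cells
    are never modified; zero-count requests are no-ops.
    """
    if n_low_gene_cells == 0 and n_high_mito_cells == 0:
        return adata
    rng = np.random.default_rng(params.seed + 0x5B1CE)
    n_genes = adata.n_vars
    mito_cols = np.flatnonzero(adata.var["mito"].to_numpy())
    nonmito_cols = np.flatnonzero(~adata.var["mito"].to_numpy())
    if mito_cols.size == 0:
        raise ValueError("matrix has no mitochondrial genes to spike against")

    rows = []
    kinds = []
    n_low_expr = max(1, min_genes // 6)
    for _ in range(n_low_gene_cells):
        row = np.zeros(n_genes, dtype=np.int64)
        cols = rng.choice(nonmito_cols, size=n_low_expr, replace=False)
        row[cols] = 1
        rows.append(row)
        kinds.append("low_genes")
    for _ in range(n_high_mito_cells):
        row = np.zeros(n_genes, dtype=np.int64)
        cols = rng.choice(nonmito_cols, size=min_genes + 100, replace=False)
        row[cols] = 1 + rng.poisson(1.0, size=cols.size)
        nonmito_total = row.sum()
        mito_total = int(np.ceil(mito_fraction / (1 - mito_fraction) * nonmito_total)) + 1
        per = np.full(mito_cols.size, mito_total // mito_cols.size, dtype=np.int64)
        per[: mito_total % mito_cols.size] += 1
        row[mito_cols] = per
        rows.append(row)
        kinds.append("high_mito")

    spike_obs = pd.DataFrame({
        "condition": adata.obs["condition"].iloc[0] if adata.n_obs else "healthy",
        "sample": "spike",
        "subtype": "spike",
        "compartment": "spike",
        "qc_spike": kinds,
    }, index=[f"spike{i:04d}" for i in range(len(rows))])
    spike_X = sparse.csr_matrix(np.vstack(rows))
    spiked = ad.AnnData(X=spike_X, obs=spike_obs, var=adata.var.copy())
    out = ad.concat([adata, spiked], join="outer", merge="first")
    out.var = adata.var.copy()
    out.uns = dict(adata.uns)
    return out


def plant_lr_signal(
    adata: ad.AnnData,
    ligand: str,
    receptor: str,
    source: str,
    target: str,
    boost: float,
    *,
    seed: int = 0,
) -> ad.AnnData:
    """Plant ligand–receptor co-expression between two subtypes.

    Adds Poisson extra counts with mean ``(exp(boost) - 1) * gene baseline``
    for the ligand in source cells and the receptor in target cells, so the
    group mean rises by a factor of about ``exp(boost)`` while all other
    entries stay untouched.  ``boost = 0`` returns the matrix unchanged.
    """
    for g in (ligand, receptor):
        if g not in adata.var_names:
            raise ValueError(f"gene {g!r} not in the gene table")
    labels = adata.obs["subtype"].to_numpy()
    for s in (source, target):
        if s not in labels:
            raise ValueError(f"subtype {s!r} not present in truth labels")
    if boost == 0:
        return adata
    rng = np.random.default_rng(seed + 0x17A0)
    out = adata.copy()
    X = out.X.tolil()
    scale = np.exp(boost) - 1.0
    for gene, subtype in ((ligand, source), (receptor, target)):
        col = out.var_names.get_loc(gene)
        base = max(float(np.asarray(adata.X[:, col].todense()).mean()), 0.2)
        cells = np.flatnonzero(labels == subtype)
        extra = rng.poisson(scale * base, size=cells.size)
        cur = np.asarray(X[cells, col].todense()).ravel()
        X[cells, col] = cur + extra
    out.X = X.tocsr()
    return out
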