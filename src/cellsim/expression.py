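"""Map pathway activity of sampled cells to mean expression and add
platform-specific measurement noise.

Mean expression for gene i interpolates each annotating pathway's calibrated
range by its activity, ``P*gmax + (1-P)*gmin``, combined across pathways
(arithmetic mean by default).  Means are on a log2-like platform scale;
count platforms exponentiate and normalize before drawing counts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .cell_model import Trajectory
from .pathways import Pathway


@dataclass
class GeneExpressionParams:
    """Sampling grid, platform selection and noise-model parameters.

    Platform selection follows two booleans: ``single_cell`` -> single-cell
    RNA-seq (negative binomial + dropout); else ``rnaseq`` -> bulk RNA-seq
    (negative binomial counts); else microarray (additive Gaussian noise on
    the log-scale means).  Noise defaults are package conventions, not
    literature-derived values.
    """

    sample_freq: float = 4.0
    n_cells: int = 50
    rnaseq: bool = False
    single_cell: bool = False
    microarray_sd: float = 0.25
    library_size: float = 1e5
    nb_dispersion: float = 0.1
    dropout_midpoint: float | None = None  # default: median of the mean matrix
    dropout_shape: float = 1.0
    cell_library_mean: float = 1e4        # expected counts per single cell
    cell_library_log10_sd: float = 0.2
    combine: str | Callable = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_freq <= 0:
            raise ValueError(f"sample_freq must be > 0, got {self.sample_freq}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.dropout_shape <= 0:
            raise ValueError(f"dropout_shape must be > 0, got {self.dropout_shape}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def platform(self) -> str:
        if self.single_cell:
            return "singlecell"
        if self.rnaseq:
            return "rnaseq"
        return "microarray"


@dataclass
class ExpressionResult:
    """Genes x samples matrices plus sample metadata and ground-truth activity."""

    gene_names: list[str]
    sample_meta: pd.DataFrame
    mean_matrix: pd.DataFrame      # genes x samples, platform-scale means
    noisy_matrix: pd.DataFrame     # platform output (intensities or counts)
    activity_matrix: pd.DataFrame  # pathways x samples ground truth
    platform: str


# ---------------------------------------------------------------------------
# sampling and activity
# ---------------------------------------------------------------------------

def sample_cells(trajectory: Trajectory, t: float, n_cells: int,
                 rng: np.random.Generator) -> list[int]:
    """Uniform sample of cell ids without replacement at snapshot time t.

    If the population is smaller than ``n_cells`` the whole population is
    returned and a warning is issued.
    """
    snap = trajectory.snapshot_at(t)
    ids = [c.id for c in snap]
    if len(ids) <= n_cells:
        if len(ids) < n_cells:
            warnings.warn(
                f"population at t={t} has {len(ids)} cells < n_cells={n_cells}; "
                f"sampling all cells", stacklevel=2)
        return sorted(ids)
    picked = rng.choice(np.array(sorted(ids)), size=n_cells, replace=False)
    return [int(i) for i in picked]


def pathway_activity(trajectory: Trajectory, pathways: Sequence[Pathway],
                     cell_ids: Sequence[int], t: float) -> np.ndarray:
    """Evaluate every pathway's rule per cell -> (n_pathways, n_cells) matrix."""
    P = np.empty((len(pathways), len(cell_ids)))
    for k, pwy in enumerate(pathways):
        for j, cid in enumerate(cell_ids):
            p = float(pwy.activity(trajectory, cid, t))
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"pathway {pwy.name!r} produced activity {p} outside [0, 1]")
            P[k, j] = p
    return P


def gene_index(pathways: Sequence[Pathway]) -> list[str]:
    """Ordered union of pathway genes (order of first appearance)."""
    seen: dict[str, None] = {}
    for pwy in pathways:
        for g in pwy.genes:
            seen.setdefault(g, None)
    return list(seen)


def mean_expression(P: np.ndarray, pathways: Sequence[Pathway],
                    mode: str = "bulk", combine: str | Callable = "mean",
                    genes: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Expected expression per gene from pathway activities.

    ``P`` is (n_pathways, n_cells).  In bulk mode each pathway's activity is
    averaged over the sampled cells first and one column is returned; in
    single_cell mode the per-cell activities are used directly, one column per
    cell.  A gene annotated to several pathways combines its per-pathway
    interpolated values with ``combine`` (default arithmetic mean).
    """
    if mode not in ("bulk", "single_cell"):
        raise ValueError(f"mode must be 'bulk' or 'single_cell', got {mode!r}")
    for pwy in pathways:
        if not pwy.calibrated:
            raise ValueError(f"pathway {pwy.name!r} is not calibrated")
    if genes is None:
        genes = gene_index(pathways)
    else:
        genes = list(genes)
        annotated = set(gene_index(pathways))
        orphan = [g for g in genes if g not in annotated]
        if orphan:
            raise ValueError(f"genes not annotated to any pathway: {orphan}")
    pos = {g: i for i, g in enumerate(genes)}

    if mode == "bulk":
        Pk = P.mean(axis=1, keepdims=True)  # (n_pathways, 1)
    else:
        Pk = P
    n_cols = Pk.shape[1]

    if combine == "mean":
        acc = np.zeros((len(genes), n_cols))
        cnt = np.zeros(len(genes))
        for k, pwy in enumerate(pathways):
            idx = np.array([pos[g] for g in pwy.genes])
            expr = np.outer(pwy.gmax, Pk[k]) + np.outer(pwy.gmin, 1.0 - Pk[k])
            acc[idx] += expr
            cnt[idx] += 1.0
        if np.any(cnt == 0):
            orphan = [g for g, c in zip(genes, cnt) if c == 0]
            raise ValueError(f"genes not annotated to any pathway: {orphan}")
        return genes, acc / cnt[:, None]

    # custom combiner: gather per-pathway values per gene (slow path)
    values: list[list[np.ndarray]] = [[] for _ in genes]
    for k, pwy in enumerate(pathways):
        expr = np.outer(pwy.gmax, Pk[k]) + np.outer(pwy.gmin, 1.0 - Pk[k])
        for row, g in enumerate(pwy.genes):
            values[pos[g]].append(expr[row])
    out = np.empty((len(genes), n_cols))
    for i, vals in enumerate(values):
        if not vals:
            raise ValueError(f"gene {genes[i]!r} not annotated to any pathway")
        stacked = np.stack(vals)  # (n_pathways_for_gene, n_cols)
        out[i] = np.apply_along_axis(combine, 0, stacked)
    return genes, out


# ---------------------------------------------------------------------------
# noise models
# ---------------------------------------------------------------------------

def noise_microarray(mean_matrix: np.ndarray, microarray_sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Additive i.i.d. Gaussian noise on log-scale intensities."""
    if microarray_sd == 0:
        return np.array(mean_matrix, copy=True)
    return mean_matrix + rng.normal(0.0, microarray_sd, size=mean_matrix.shape)


def _relative_abundance(mean_matrix: np.ndarray) -> np.ndarray:
    """Per-column relative abundances a_ij = 2^g_ij / sum_i 2^g_ij."""
    pow2 = np.power(2.0, np.asarray(mean_matrix, dtype=float))
    return pow2 / pow2.sum(axis=0, keepdims=True)


def _nb_draw(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson limit
    as dispersion -> 0), via the gamma-Poisson mixture."""
    mu = np.maximum(np.asarray(mu, dtype=float), 0.0)
    if dispersion <= 1e-12:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=np.maximum(mu, 1e-300) * dispersion)
    return rng.poisson(lam)


def noise_bulk_rnaseq(mean_matrix: np.ndarray, library_size: float,
                      nb_dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial bulk counts with per-column expected total library_size."""
    a = _relative_abundance(mean_matrix)
    return _nb_draw(library_size * a, nb_dispersion, rng)


def dropout_probability(mean_matrix: np.ndarray, midpoint: float,
                        shape: float) -> np.ndarray:
    """Logistic dropout probability, decreasing in the log-scale mean."""
    return 1.0 / (1.0 + np.exp(shape * (np.asarray(mean_matrix, dtype=float) - midpoint)))


def noise_single_cell(mean_matrix: np.ndarray, nb_dispersion: float,
                      dropout_midpoint: float, dropout_shape: float,
                      per_cell_library: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """NB counts with per-cell libraries, then logistic expression-dependent
    dropout zeroing each entry independently."""
    a = _relative_abundance(mean_matrix)
    mu = a * np.asarray(per_cell_library, dtype=float)[None, :]
    counts = _nb_draw(mu, nb_dispersion, rng)
    pi = dropout_probability(mean_matrix, dropout_midpoint, dropout_shape)
    keep = rng.random(size=counts.shape) >= pi
    return counts * keep


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def sampling_times(final_hour: float, sample_freq: float) -> np.ndarray:
    """t = 0, f, 2f, ... up to and including the final hour when divisible."""
    return np.arange(0.0, final_hour + 1e-9, sample_freq)


def simulate_gene_expression(trajectory: Trajectory, pathways: Sequence[Pathway],
                             params: GeneExpressionParams,
                             rng: np.random.Generator | None = None) -> ExpressionResult:
    """Full pipeline: sample cells on the time grid, evaluate activities,
    build the mean matrix and apply the selected platform noise model."""
    if rng is not None:
        rng_sample = rng_noise = rng
    else:
        rng_sample = substream(params.seed, "sampling")
        rng_noise = substream(params.seed, "noise")

    times = sampling_times(trajectory.final_time, params.sample_freq)
    genes = gene_index(pathways)
    single = params.platform == "singlecell"
    mode = "single_cell" if single else "bulk"

    mean_cols: list[np.ndarray] = []
    act_cols: list[np.ndarray] = []
    col_names: list[str] = []
    meta_rows: list[dict] = []
    for t in times:
        snap_t = trajectory.times[trajectory.nearest_index(t)]
        cell_ids = sample_cells(trajectory, snap_t, params.n_cells, rng_sample)
        P = pathway_activity(trajectory, pathways, cell_ids, snap_t)
        _, cols = mean_expression(P, pathways, mode=mode, combine=params.combine,
                                  genes=genes)
        mean_cols.append(cols)
        by_id = trajectory.cells_by_id(trajectory.nearest_index(t))
        if single:
            act_cols.append(P)
            for j, cid in enumerate(cell_ids):
                st = by_id[cid]
                col_names.append(f"t{snap_t:g}_c{cid}")
                meta_rows.append({"sample": col_names[-1], "time": snap_t,
                                  "cell_id": cid, "cell_type": st.type_name,
                                  "phase": st.phase})
        else:
            act_cols.append(P.mean(axis=1, keepdims=True))
            col_names.append(f"t{snap_t:g}")
            meta_rows.append({
                "sample": col_names[-1], "time": snap_t,
                "cell_id": ";".join(str(c) for c in cell_ids),
                "cell_type": ";".join(by_id[c].type_name for c in cell_ids),
                "phase": ";".join(by_id[c].phase for c in cell_ids)})

    mean_matrix = np.concatenate(mean_cols, axis=1)
    activity = np.concatenate(act_cols, axis=1)

    platform = params.platform
    if platform == "microarray":
        noisy = noise_microarray(mean_matrix, params.microarray_sd, rng_noise)
    elif platform == "rnaseq":
        noisy = noise_bulk_rnaseq(mean_matrix, params.library_size,
                                  params.nb_dispersion, rng_noise)
    else:
        midpoint = params.dropout_midpoint
        if midpoint is None:
            midpoint = float(np.median(mean_matrix))
        n_cols = mean_matrix.shape[1]
        libs = np.power(10.0, rng_noise.normal(np.log10(params.cell_library_mean),
                                               params.cell_library_log10_sd,
                                               size=n_cols))
        noisy = noise_single_cell(mean_matrix, params.nb_dispersion, midpoint,
                                  params.dropout_shape, libs, rng_noise)

    pwy_names = [p.name for p in pathways]
    return ExpressionResult(
        gene_names=genes,
        sample_meta=pd.DataFrame(meta_rows),
        mean_matrix=pd.DataFrame(mean_matrix, index=genes, columns=col_names),
        noisy_matrix=pd.DataFrame(noisy, index=genes, columns=col_names),
        activity_matrix=pd.DataFrame(activity, index=pwy_names, columns=col_names),
        platform=platform,
    )
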