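"""Synthetic paired RNA/protein data with a known protein interaction graph.

The generator emulates the statistical structure the predictive model
assumes, at desk scale and with no download:

* per cell, K latent gene-program activities drawn log-normal;
* RNA: each gene loads on one program (sparse loadings), value =
  loading * activity + Gaussian noise, clipped at zero — emulating denoised,
  continuous, non-negative expression;
* proteins: a base signal per protein from its programs, coupled through a
  symmetric zero-diagonal ground-truth interaction matrix, then
  log-transformed and centered per protein across cells so that negative,
  CLR-like values occur, plus Gaussian noise;
* prior features: M noisy copies of the |coupling| matrix rescaled to 0–1 —
  emulating M correlated STRING evidence channels.

All randomness comes from one seed; identical configs give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import CellSplit, ExpressionMatrix, PriorFeatureSet, ProteinMatrix, split_cells
from .model import ModelConfig
from .training import RunResult, TrainConfig, best_of_runs, evaluate, train

__all__ = ["SimConfig", "SimTruth", "simulate", "oracle_predictions", "holdout_benchmark"]


@dataclass
class SimConfig:
    """Generator settings.

    Defaults give a panel comparable to a small CITE-seq experiment: 2000
    cells, 300 genes, 10 proteins on 10 latent gene programs, a symmetric
    random coupling of density 0.3, observation noise SD 0.3 on both
    modalities and prior channels perturbed with SD 0.1.
    """

    n_cells: int = 2000
    n_genes: int = 300
    n_proteins: int = 10
    n_modules: int = 10
    coupling: np.ndarray | None = field(default=None, repr=False)
    coupling_density: float = 0.3
    noise_sd: float = 0.3
    prior_noise_sd: float = 0.1
    n_prior_features: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules > self.n_genes:
            raise ValueError("n_modules must not exceed n_genes")
        if self.noise_sd < 0 or self.prior_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.coupling is not None:
            c = np.asarray(self.coupling, dtype=np.float64)
            if c.shape != (self.n_proteins, self.n_proteins):
                raise ValueError(
                    f"coupling must be {self.n_proteins} x {self.n_proteins}, "
                    f"got {c.shape}"
                )
            if not np.allclose(c, c.T) or np.any(np.diag(c) != 0):
                raise ValueError("coupling must be symmetric with zero diagonal")


@dataclass
class SimTruth:
    """Everything needed to reconstruct the generating process."""

    module_loadings: np.ndarray  # genes x modules
    protein_map: np.ndarray  # modules x proteins
    coupling: np.ndarray  # proteins x proteins
    module_activities: np.ndarray  # cells x modules
    protein_centers: np.ndarray  # per-protein across-cell centering offsets
    config: SimConfig


def _sample_coupling(rng: np.random.Generator, n: int, density: float) -> np.ndarray:
    c = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    on = rng.random(len(iu[0])) < density
    c[iu] = np.where(on, rng.uniform(0.5, 1.0, len(iu[0])), 0.0)
    return c + c.T


def simulate(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ProteinMatrix, PriorFeatureSet, SimTruth]:
    """Draw one paired dataset plus its generating truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    c, g, n, k = config.n_cells, config.n_genes, config.n_proteins, config.n_modules

    coupling = (
        np.asarray(config.coupling, dtype=np.float64)
        if config.coupling is not None
        else _sample_coupling(rng, n, config.coupling_density)
    )

    # sparse loadings: every gene on exactly one program, every program used
    gene_module = np.concatenate(
        [np.arange(k), rng.integers(0, k, g - k)]
    )
    loadings = np.zeros((g, k))
    loadings[np.arange(g), gene_module] = rng.uniform(0.5, 1.5, g)

    # each protein reads its own program plus a weak secondary one
    protein_map = np.zeros((k, n))
    protein_map[np.arange(n) % k, np.arange(n)] = 1.0
    secondary = rng.integers(0, k, n)
    protein_map[secondary, np.arange(n)] += rng.uniform(0.0, 0.3, n)

    z = rng.lognormal(mean=0.0, sigma=0.6, size=(c, k))
    rna = np.clip(z @ loadings.T + rng.normal(0.0, config.noise_sd, (c, g)), 0.0, None)

    s = z @ protein_map  # cells x N, positive
    y_raw = np.log1p(s + s @ coupling.T)
    centers = y_raw.mean(axis=0)
    protein = y_raw - centers + rng.normal(0.0, config.noise_sd, (c, n))

    scale = np.max(np.abs(coupling))
    base = np.abs(coupling) / scale if scale > 0 else np.zeros_like(coupling)
    mats = np.zeros((config.n_prior_features, n, n))
    for i in range(config.n_prior_features):
        noisy = base + rng.normal(0.0, config.prior_noise_sd, (n, n))
        # STRING-like channels live on a 0-1 score scale
        noisy = np.clip((noisy + noisy.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(noisy, 0.0)
        mats[i] = noisy

    cell_ids = [f"cell{i:05d}" for i in range(c)]
    gene_ids = [f"gene{i:04d}" for i in range(g)]
    protein_ids = [f"prot{i:02d}" for i in range(n)]
    feature_names = [f"prior_{i + 1}" for i in range(config.n_prior_features)]

    expr = ExpressionMatrix(rna, gene_ids, cell_ids)
    prot = ProteinMatrix(protein, protein_ids, cell_ids)
    priors = PriorFeatureSet(feature_names, mats, protein_ids)
    truth = SimTruth(
        module_loadings=loadings,
        protein_map=protein_map,
        coupling=coupling,
        module_activities=z,
        protein_centers=centers,
        config=config,
    )
    return expr, prot, priors, truth


def oracle_predictions(truth: SimTruth, cell_indices: Sequence[int]) -> np.ndarray:
    """Noise-free protein values from the stored truth (a performance ceiling)."""
    z = truth.module_activities[np.asarray(cell_indices)]
    s = z @ truth.protein_map
    return np.log1p(s + s @ truth.coupling.T) - truth.protein_centers


def holdout_benchmark(
    expr: ExpressionMatrix,
    prot: ProteinMatrix,
    priors: PriorFeatureSet | None,
    model_config: ModelConfig,
    train_config: TrainConfig,
    k_runs: int = 1,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[RunResult, list[RunResult], CellSplit]:
    """Split, train ``k_runs`` times, evaluate, and take the best-of-runs.

    Returns ``(best_of_runs summary, per-run results, the split used)``.
    QC is intentionally skipped: simulated data have no mitochondrial reads.
    """
    split = split_cells(expr.cell_ids, train_fraction, seed)
    pos = {cid: i for i, cid in enumerate(expr.cell_ids)}
    tr = [pos[cid] for cid in split.train_ids]
    te = [pos[cid] for cid in split.test_ids]
    prior_arr = None if priors is None else priors.matrices

    results = []
    for r in range(k_runs):
        tc = replace(train_config, seed=train_config.seed + r)
        ckpt, _ = train(
            expr.values[tr], prot.values[tr], prior_arr, model_config, tc
        )
        results.append(
            evaluate(ckpt, expr.values[te], prot.values[te], prot.protein_ids)
        )
    return best_of_runs(results), results, split
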