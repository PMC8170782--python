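"""Named desk-scale benchmark settings.

The published architecture (hidden 1024/128, d_r=64, d_c=32, lr 1e-6,
350 epochs) is sized for tens of thousands of genes and thousands of cells.
The synthetic benchmarks in this repository run on one CPU in seconds, so
they use a proportionally smaller model and a larger learning rate with
fewer epochs; these are the package's fixed benchmark conditions, defined
once here so the test suite and the reproduction script agree.
"""

from __future__ import annotations

from .model import ModelConfig
from .simulate import SimConfig
from .training import TrainConfig

__all__ = [
    "smoke_sim_config",
    "strongly_coupled_sim_config",
    "smoke_model_config",
    "smoke_train_config",
]


def smoke_sim_config(seed: int, noise_sd: float | None = None) -> SimConfig:
    """The default simulation (2000 cells, 300 genes, 10 proteins);
    ``noise_sd`` overrides both modality noise SDs when given (0 for the
    noiseless identifiability check)."""
    cfg = SimConfig(seed=seed)
    if noise_sd is not None:
        cfg.noise_sd = noise_sd
        if noise_sd == 0:
            cfg.prior_noise_sd = 0.0
    return cfg


def strongly_coupled_sim_config(seed: int) -> SimConfig:
    """Scaled-down, strongly coupled panel for the prior-direction benchmark."""
    return SimConfig(
        n_cells=500,
        n_genes=80,
        n_proteins=8,
        n_modules=8,
        coupling_density=0.7,
        seed=seed,
    )


def smoke_model_config(sim: SimConfig, use_prior: bool = True) -> ModelConfig:
    """Model scaled to the simulated panel (hidden 256/64 or 128/32)."""
    small = sim.n_genes <= 100
    return ModelConfig(
        n_genes=sim.n_genes,
        n_proteins=sim.n_proteins,
        n_prior_features=sim.n_prior_features if use_prior else 1,
        hidden=(128, 32) if small else (256, 64),
        d_r=8 if small else 16,
        d_c=4 if small else 8,
        use_prior=use_prior,
    )


def smoke_train_config(seed: int, epochs: int = 40) -> TrainConfig:
    return TrainConfig(
        epochs=epochs, batch_size=64, learning_rate=1e-3, seed=seed
    )
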