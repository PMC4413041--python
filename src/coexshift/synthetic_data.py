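"""Two-group expression simulator with block-correlation structure.

Each correlated block is generated from a single-factor model: within block
*b* and group *g*, gene expression for sample *s* is

    x = sqrt(rho_bg) * f_s + sqrt(1 - rho_bg) * e_gs

with latent factor ``f_s`` and residual ``e_gs`` independent standard
normals, so the population correlation of two same-block genes is exactly
the block's target ``rho_bg`` for that group.  A factor model was chosen over
drawing from a fixed covariance matrix because it scales to any block
specification and the loading has the closed form ``sqrt(target)``.  Genes
outside every block are independent noise.  The whole matrix is scaled by
``noise_sd`` and shifted by a per-gene baseline, neither of which affects
correlations.

Defaults mirror a small two-group microarray study: 93 genes, 9 disease and
8 normal samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from coexshift.classify import classify_pairs
from coexshift.coexpress import PairCoexpression, pairwise_abs_pearson
from coexshift.cutoff import CutoffResult, ks_cutoff
from coexshift.expression_io import GROUP_DISEASE, GROUP_NORMAL, ExpressionMatrix


@dataclass(frozen=True)
class BlockSpec:
    """A block of genes with a target within-block |r| per group."""

    n_genes: int
    r_disease: float
    r_normal: float

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("block needs at least one gene")
        for r in (self.r_disease, self.r_normal):
            if not 0.0 <= r < 1.0:
                raise ValueError(
                    f"target |r| must be in [0, 1): {r} needs loading^2 > 1" if r >= 1
                    else f"target |r| must be in [0, 1), got {r}"
                )


@dataclass(frozen=True)
class SimulationConfig:
    """Dimensions, block structure, noise scale and seed of one simulation."""

    n_genes: int = 93
    n_disease: int = 9
    n_normal: int = 8
    blocks: tuple[BlockSpec, ...] = ()
    noise_sd: float = 1.0
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if sum(b.n_genes for b in self.blocks) > self.n_genes:
            raise ValueError("block gene counts exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def block_gene_names(self) -> list[list[str]]:
        """Gene names of each block (blocks occupy the first rows, in order)."""
        names = _gene_names(self.n_genes)
        out, start = [], 0
        for b in self.blocks:
            out.append(names[start:start + b.n_genes])
            start += b.n_genes
        return out


def _gene_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{k + 1:0{width}d}" for k in range(n)]


def _simulate_group(cfg: SimulationConfig, rng: np.random.Generator,
                    n_samples: int, which: str) -> np.ndarray:
    x = rng.standard_normal((cfg.n_genes, n_samples))
    start = 0
    for b in cfg.blocks:
        target = b.r_disease if which == GROUP_DISEASE else b.r_normal
        loading = np.sqrt(target)
        factor = rng.standard_normal(n_samples)
        rows = slice(start, start + b.n_genes)
        x[rows] = loading * factor + np.sqrt(1.0 - target) * x[rows]
        start += b.n_genes
    return x


def simulate_expression(config: SimulationConfig) -> ExpressionMatrix:
    """Draw one two-group matrix; deterministic under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    xd = _simulate_group(config, rng, config.n_disease, GROUP_DISEASE)
    xn = _simulate_group(config, rng, config.n_normal, GROUP_NORMAL)
    baseline = config.baseline + rng.standard_normal((config.n_genes, 1))
    values = np.concatenate([xd, xn], axis=1) * config.noise_sd + baseline
    samples = [f"D{k + 1:02d}" for k in range(config.n_disease)] + [
        f"N{k + 1:02d}" for k in range(config.n_normal)
    ]
    groups = pd.Series(
        [GROUP_DISEASE] * config.n_disease + [GROUP_NORMAL] * config.n_normal,
        index=samples,
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), groups=groups
    )


@dataclass
class RecoveryReport:
    """Outcome of one simulated end-to-end run."""

    cutoff: CutoffResult
    significant: bool
    n_differential_pairs: int
    frac_recovered: float  # truly differential pairs landing disease-specific strong
    classification_counts: dict = field(default_factory=dict)


def _differential_pair_mask(config: SimulationConfig, pc: PairCoexpression) -> np.ndarray:
    """Pairs whose population |r| differs between groups: same-block pairs of
    any block with r_disease != r_normal."""
    # a pair is differential when both members sit in the same block whose
    # target |r| differs between groups
    block_id = np.full(config.n_genes, -1)
    start = 0
    for k, b in enumerate(config.blocks):
        if b.r_disease != b.r_normal:
            block_id[start:start + b.n_genes] = k
        start += b.n_genes
    i = pc.pair_index[:, 0]
    j = pc.pair_index[:, 1]
    return (block_id[i] >= 0) & (block_id[i] == block_id[j])


def recovery_experiment(
    config: SimulationConfig, alpha: float = 0.05, zero_var: str = "error"
) -> RecoveryReport:
    """Simulate, run the full cutoff pipeline and report parameter recovery.

    Reports whether the KS comparison is significant at ``alpha`` and which
    fraction of the truly differential (same-block, group-differing) pairs
    the classification places in the disease-specific strong class.
    """
    matrix = simulate_expression(config)
    pc = pairwise_abs_pearson(matrix, zero_var=zero_var)
    result = ks_cutoff(pc)
    classes = classify_pairs(pc, result.C)
    diff_mask = _differential_pair_mask(config, pc)
    n_diff = int(diff_mask.sum())
    if n_diff:
        frac = float((classes.disease_specific_strong_mask & diff_mask).sum() / n_diff)
    else:
        frac = float("nan")
    return RecoveryReport(
        cutoff=result,
        significant=result.p_value < alpha,
        n_differential_pairs=n_diff,
        frac_recovered=frac,
        classification_counts={
            "strong_disease": classes.n_strong_disease,
            "weak_disease": classes.n_weak_disease,
            "strong_normal": classes.n_strong_normal,
            "weak_normal": classes.n_weak_normal,
        },
    )


def replicate_seeds(config: SimulationConfig, n_replicates: int) -> list[SimulationConfig]:
    """Configs for independent replicates, seeds derived from the base seed."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_replicates)
    return [replace(config, seed=int(c.generate_state(1)[0] % (2**31))) for c in children]


def parse_config_file(path) -> SimulationConfig:
    """Read a flat key/value simulation config.

    Lines are ``key = value``; the repeatable key ``block`` takes
    ``n_genes r_disease r_normal``.
    """
    kwargs: dict = {}
    blocks: list[BlockSpec] = []
    for raw in open(path):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "block":
            n, rd, rn = value.split()
            blocks.append(BlockSpec(int(n), float(rd), float(rn)))
        elif key in ("n_genes", "n_disease", "n_normal", "seed"):
            kwargs[key] = int(value)
        elif key in ("noise_sd", "baseline"):
            kwargs[key] = float(value)
        else:
            raise ValueError(f"unknown simulation config key: {key!r}")
    return SimulationConfig(blocks=tuple(blocks), **kwargs)
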