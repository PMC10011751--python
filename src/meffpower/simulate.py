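"""Latent-factor simulation of correlated two-group outcome data.

Outcomes are modelled as noisy indicators of one or two latent constructs
that mediate the intervention effect.  Each observed outcome is

    V_j = a * L + sqrt(1 - a^2) * e_j,

with L a standard-normal latent score shared by the outcomes of a block and
e_j independent standard-normal noise, so every outcome has unit variance.
The loading a induces a mean inter-outcome correlation of a^2 within a
block; to hit a target mean correlation r one sets a = sqrt(r).  An
intervention effect of size E per *outcome* requires a latent shift of
E_l = E / sqrt(r), since only the fraction a of the latent shift reaches
each indicator.  A target of r = 0 cannot carry an effect through a latent
factor at all (the loading vanishes), so it is accepted only for pure-null
(E = 0) data, where it yields independent outcomes.

Three generative layouts are provided:

* ``L1``  — one latent factor behind all k outcomes, shifted by E_l in the
  intervention group.
* ``L2``  — two independent latent factors, each behind a block of
  outcomes; both shifted by E_l.
* ``L2x`` — as L2, but the intervention shifts only the first factor, so
  the second block of outcomes is unaffected.

Each subject contributes a single measurement (no pre/post change scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .correction import CorrelationMatrix

__all__ = [
    "MODELS",
    "SimConfig",
    "OutcomeDataset",
    "loading_from_target",
    "latent_effect",
    "block_split",
    "population_matrix",
    "simulate_dataset",
    "pca_first_component",
]

MODELS = ("L1", "L2", "L2x")


def loading_from_target(target_mean_r: float) -> float:
    """Loading a = sqrt(r) that induces mean inter-outcome correlation r.

    r = 0 is rejected: uncorrelated outcomes cannot be indicators of a
    shared latent factor.
    """
    if not 0.0 < target_mean_r <= 1.0:
        raise ValueError(
            "target mean correlation must be in (0, 1]; r = 0 has no "
            f"latent-factor representation (got {target_mean_r})"
        )
    return math.sqrt(target_mean_r)


def latent_effect(effect_size: float, target_mean_r: float) -> float:
    """Latent shift E_l = E / sqrt(r) needed for a per-outcome effect E."""
    if effect_size == 0.0:
        # no shift needed; valid even in the degenerate r -> 0 limit
        if not 0.0 <= target_mean_r <= 1.0:
            raise ValueError(f"target mean correlation {target_mean_r} outside [0, 1]")
        return 0.0
    return effect_size / loading_from_target(target_mean_r)


def block_split(k: int, model: str) -> tuple[int, ...]:
    """Outcome counts per latent factor: all k for L1; ceil/floor halves for
    the two-factor models (first factor gets the larger share when k is odd)."""
    if model == "L1":
        return (k,)
    if model in ("L2", "L2x"):
        first = math.ceil(k / 2)
        return (first, k - first)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one simulation condition.

    Parameters
    ----------
    model : {"L1", "L2", "L2x"}
    k : int
        Number of outcome measures, 2..12.
    n_per_group : int
        Subjects per arm (control C and intervention I are equal-sized).
    effect_size : float
        Standardised mean difference E on each affected outcome (>= 0).
    target_mean_r : float
        Intended mean inter-outcome correlation within a factor's block,
        in (0, 1]; 0 is allowed only with ``effect_size == 0`` and yields
        independent outcomes.
    n_sims : int
        Monte-Carlo replications for power runs.
    seed : int or None
        Root seed; replications use deterministically spawned substreams.
    """

    model: str
    k: int
    n_per_group: int
    effect_size: float = 0.0
    target_mean_r: float = 0.4
    n_sims: int = 2000
    seed: int | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not 2 <= int(self.k) <= 12:
            raise ValueError(f"k must be in 2..12, got {self.k}")
        if int(self.n_per_group) < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.target_mean_r <= 1.0:
            raise ValueError("target_mean_r must be in [0, 1]")
        if self.target_mean_r == 0.0 and self.effect_size != 0.0:
            raise ValueError(
                "target_mean_r = 0 (independent outcomes) cannot carry a "
                "latent-mediated effect; set effect_size = 0 or r > 0"
            )
        if int(self.n_sims) < 1:
            raise ValueError("n_sims must be >= 1")

    @property
    def loading(self) -> float:
        """Outcome-on-latent loading a = sqrt(target_mean_r)."""
        return 0.0 if self.target_mean_r == 0.0 else math.sqrt(self.target_mean_r)

    @property
    def latent_effect_size(self) -> float:
        """Shift applied to affected latent factors in group I."""
        return latent_effect(self.effect_size, self.target_mean_r)

    @property
    def blocks(self) -> tuple[int, ...]:
        return block_split(self.k, self.model)


def population_matrix(cfg: SimConfig) -> CorrelationMatrix:
    """Population correlation matrix implied by ``cfg``: loading^2 within
    each factor's block, zero across blocks."""
    return CorrelationMatrix.from_blocks(cfg.blocks, cfg.loading**2, 0.0)


@dataclass(frozen=True)
class OutcomeDataset:
    """A simulated two-group multivariate sample.

    ``outcomes`` stacks the control arm (first ``n_per_group`` rows) above
    the intervention arm; ``group`` holds the matching "C"/"I" labels.
    """

    outcomes: np.ndarray
    group: np.ndarray
    config: SimConfig

    @property
    def n_per_group(self) -> int:
        return self.config.n_per_group

    @property
    def control(self) -> np.ndarray:
        return self.outcomes[: self.n_per_group]

    @property
    def intervention(self) -> np.ndarray:
        return self.outcomes[self.n_per_group :]

    def to_dataframe(self) -> pd.DataFrame:
        k = self.outcomes.shape[1]
        df = pd.DataFrame(self.outcomes, columns=[f"V{j + 1}" for j in range(k)])
        df.insert(0, "group", self.group)
        df.insert(0, "subject_id", np.arange(1, len(df) + 1))
        return df

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write ``subject_id, group, V1..Vk`` CSV; with ``sidecar=True``
        also write ``<path>.meta.yaml`` recording the generative truth."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            cfg = self.config
            meta = {
                "model": cfg.model,
                "k": cfg.k,
                "n_per_group": cfg.n_per_group,
                "effect_size": cfg.effect_size,
                "target_mean_r": cfg.target_mean_r,
                "loading": cfg.loading,
                "latent_effect_size": cfg.latent_effect_size,
                "blocks": list(cfg.blocks),
                "seed": cfg.seed,
            }
            path.with_suffix(path.suffix + ".meta.yaml").write_text(
                yaml.safe_dump(meta, sort_keys=False)
            )


def simulate_dataset(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> OutcomeDataset:
    """Draw one two-group sample under ``cfg``.

    The latent scores are drawn first, then the error matrix, so the draw
    order (hence the dataset for a given seed) is fixed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_per_group, cfg.k
    blocks = cfg.blocks
    a = cfg.loading
    noise_scale = math.sqrt(1.0 - a * a)

    latents = rng.standard_normal((2 * n, len(blocks)))
    if cfg.effect_size > 0:
        shift = cfg.latent_effect_size
        n_affected = 1 if cfg.model == "L2x" else len(blocks)
        latents[n:, :n_affected] += shift
    errors = rng.standard_normal((2 * n, k))

    outcomes = np.empty((2 * n, k))
    start = 0
    for j, b in enumerate(blocks):
        cols = slice(start, start + b)
        outcomes[:, cols] = a * latents[:, j : j + 1] + noise_scale * errors[:, cols]
        start += b

    group = np.array(["C"] * n + ["I"] * n)
    return OutcomeDataset(outcomes=outcomes, group=group, config=cfg)


def pca_first_component(
    data, m: int | None = None, return_loadings: bool = False
):
    """First-principal-component scores of the first ``m`` outcome columns.

    The component is computed on both groups combined, after centring but
    without rescaling (the outcomes are unit-variance by construction).
    The sign is oriented so that the loadings sum to a positive value: all
    outcomes are keyed so that improvement is positive, which makes the
    one-tailed group comparison of the scores well defined.

    Parameters
    ----------
    data : OutcomeDataset or ndarray (n_subjects, k)
    m : int, optional
        Number of leading outcome columns to use (default: all k).
    return_loadings : bool
        Also return the oriented loading vector.
    """
    X = data.outcomes if isinstance(data, OutcomeDataset) else np.asarray(data, float)
    k = X.shape[1]
    if m is None:
        m = k
    if not 2 <= m <= k:
        raise ValueError(f"m must be in 2..{k}, got {m}")
    Xc = X[:, :m] - X[:, :m].mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[0]
    if loadings.sum() < 0:
        loadings = -loadings
    scores = Xc @ loadings
    if return_loadings:
        return scores, loadings
    return scores
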