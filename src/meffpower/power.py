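"""Monte-Carlo power and familywise error for multiple-outcome decision rules.

Each replication draws a two-group latent-factor dataset, compares the arms
outcome-by-outcome with a one-tailed two-sample t-test (directional
hypothesis: the intervention improves every outcome it touches), and asks
whether the study as a whole would be declared positive under:

* ``uncorrected`` — any outcome with p < alpha (no multiplicity control);
* ``bonferroni``  — any outcome with p < alpha / k;
* ``meff``        — any outcome with p < alpha / MEff, MEff taken by
  default from the pooled within-group sample correlation matrix of that
  replication (group means removed first, so a real effect does not
  inflate the correlations); optionally from the known population matrix;
* ``pca``         — one test at full alpha on first-principal-component
  scores of all outcomes, both groups combined.

The proportion of positive replications estimates power (or the familywise
error rate when the effect size is zero), reported with its binomial
Monte-Carlo standard error sqrt(p(1-p)/n_sims).
"""

from __future__ import annotations

import math
import time
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .correction import alpha_meff, meff_from_eigenvalues
from .simulate import OutcomeDataset, SimConfig, pca_first_component, population_matrix, simulate_dataset

__all__ = [
    "METHODS",
    "one_tailed_t",
    "per_outcome_pvalues",
    "run_power",
    "single_outcome_power",
    "l2x_reference_power",
]

METHODS = ("uncorrected", "bonferroni", "meff", "pca")


def one_tailed_t(control, intervention, equal_var: bool = False) -> float:
    """One-tailed two-sample t-test p-value for "intervention mean > control".

    Welch (unequal-variance) by default; ``equal_var=True`` selects the
    pooled-variance form.  Under the generative model both arms share a
    variance, so the choice is inconsequential, but it is fixed and
    switchable rather than implicit.
    """
    c = np.asarray(control, dtype=float)
    i = np.asarray(intervention, dtype=float)
    if c.size < 2 or i.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if c.std() == 0.0 and i.std() == 0.0:
        raise ValueError("both groups are constant; the t-test is undefined")
    res = stats.ttest_ind(i, c, equal_var=equal_var, alternative="greater")
    return float(res.pvalue)


def per_outcome_pvalues(data: OutcomeDataset, equal_var: bool = False) -> np.ndarray:
    """Vector of one-tailed per-outcome p-values (I > C) for a dataset."""
    res = stats.ttest_ind(
        data.intervention,
        data.control,
        axis=0,
        equal_var=equal_var,
        alternative="greater",
    )
    return np.asarray(res.pvalue, dtype=float)


def _sample_meff_alpha(data: OutcomeDataset, nominal_alpha: float) -> float:
    # pooled within-group correlations: remove each arm's mean first so a
    # true group effect does not masquerade as inter-outcome correlation
    pooled = np.vstack(
        [
            data.control - data.control.mean(axis=0),
            data.intervention - data.intervention.mean(axis=0),
        ]
    )
    corr = np.corrcoef(pooled, rowvar=False)
    ev = np.linalg.eigvalsh(corr)
    return nominal_alpha / meff_from_eigenvalues(ev)


def run_power(
    cfg: SimConfig,
    methods: Iterable[str] = ("bonferroni", "meff", "pca"),
    nominal_alpha: float = 0.05,
    meff_corr: str = "sample",
    equal_var: bool = False,
    log=None,
) -> pd.DataFrame:
    """Estimate power (or FWER when ``cfg.effect_size == 0``) per method.

    Parameters
    ----------
    cfg : SimConfig
        Condition to simulate; ``cfg.n_sims`` replications are run with
        per-replication RNG substreams spawned from ``cfg.seed``.
    methods : iterable of {"uncorrected", "bonferroni", "meff", "pca"}
    meff_corr : {"sample", "population"}
        Whether the MEff threshold is recomputed from each replication's
        pooled within-group sample correlations, or fixed from the known
        generative matrix.
    log : callable, optional
        Receives one progress line per run (used by the CLI).

    Returns
    -------
    DataFrame with one row per method: condition columns, ``power``,
    ``mc_se`` and ``n_sims``.
    """
    methods = list(dict.fromkeys(methods))
    if not methods:
        raise ValueError("at least one decision rule is required")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; expected {METHODS}")
    if meff_corr not in ("sample", "population"):
        raise ValueError("meff_corr must be 'sample' or 'population'")
    if not 0.0 < nominal_alpha < 1.0:
        raise ValueError("nominal_alpha must be in (0, 1)")

    k = cfg.k
    bonf = nominal_alpha / k
    fixed_meff_alpha = None
    if "meff" in methods and meff_corr == "population":
        fixed_meff_alpha = alpha_meff(population_matrix(cfg), nominal_alpha)

    t0 = time.perf_counter()
    counts = dict.fromkeys(methods, 0)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_sims)
    for child in children:
        data = simulate_dataset(cfg, rng=np.random.default_rng(child))
        p = None
        if any(m in methods for m in ("uncorrected", "bonferroni", "meff")):
            p = per_outcome_pvalues(data, equal_var=equal_var)
        if "uncorrected" in methods and (p < nominal_alpha).any():
            counts["uncorrected"] += 1
        if "bonferroni" in methods and (p < bonf).any():
            counts["bonferroni"] += 1
        if "meff" in methods:
            thr = fixed_meff_alpha
            if thr is None:
                thr = _sample_meff_alpha(data, nominal_alpha)
            if (p < thr).any():
                counts["meff"] += 1
        if "pca" in methods:
            scores = pca_first_component(data)
            n = cfg.n_per_group
            p1 = one_tailed_t(scores[:n], scores[n:], equal_var=equal_var)
            if p1 < nominal_alpha:
                counts["pca"] += 1

    elapsed = time.perf_counter() - t0
    if log is not None:
        log(
            f"power run: model={cfg.model} k={k} n={cfg.n_per_group} "
            f"E={cfg.effect_size} r={cfg.target_mean_r} seed={cfg.seed} "
            f"reps={cfg.n_sims} elapsed={elapsed:.2f}s"
        )

    rows = []
    for m in methods:
        p_hat = counts[m] / cfg.n_sims
        rows.append(
            {
                "model": cfg.model,
                "k": k,
                "target_mean_r": cfg.target_mean_r,
                "effect_size": cfg.effect_size,
                "n_per_group": cfg.n_per_group,
                "method": m,
                "power": p_hat,
                "mc_se": math.sqrt(p_hat * (1.0 - p_hat) / cfg.n_sims),
                "n_sims": cfg.n_sims,
                "seed": cfg.seed,
            }
        )
    return pd.DataFrame(rows)


def single_outcome_power(
    effect_size: float, n_per_group: int, alpha: float = 0.05
) -> float:
    """Analytic one-tailed power of a single two-sample comparison.

    Noncentral-t with df = 2n - 2 and noncentrality E * sqrt(n/2); the
    reference line against which multi-outcome decision rules are judged.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    df = 2 * n_per_group - 2
    ncp = effect_size * math.sqrt(n_per_group / 2.0)
    t_crit = stats.t.isf(alpha, df)
    return float(stats.nct.sf(t_crit, df, ncp))


def l2x_reference_power(
    effect_size: float, n_per_group: int, alpha: float = 0.05
) -> float:
    """Single-outcome reference when only one of two outcome families
    responds to the intervention: the average of the powered and the null
    single-outcome power, i.e. the expectation if the primary outcome were
    picked from either family with equal probability."""
    return 0.5 * (
        single_outcome_power(effect_size, n_per_group, alpha)
        + single_outcome_power(0.0, n_per_group, alpha)
    )
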