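"""Edge-wise group comparison and consistency mapping.

Every metric configuration yields one value per subject per region pair.
For each (configuration, pair) cell a two-tailed non-parametric permutation
test compares patients with controls (statistic: absolute difference of
group means; p = (b + 1)/(n_perm + 1)).  Within each configuration the
p-values over all pairs are corrected with Benjamini-Hochberg FDR; the
correction family is per-configuration, matching per-metric reporting.

Surviving edges are accumulated into a consistency table: per pair, how
many configurations flag it, counted separately for hypoconnectivity
(patients < controls) and hyperconnectivity (patients > controls).  Region
scores sum a region's incident pair counts; lobe-level contrasts compare
region scores between lobes with pairwise t-tests under Bonferroni
correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ConnectivityTensor, pair_index

__all__ = [
    "EdgeTestResult",
    "EffectSize",
    "ConsistencyTable",
    "edge_permutation_test",
    "permutation_pvalues",
    "bh_fdr",
    "select_edges",
    "build_consistency",
    "compare_consistency",
    "lobe_contrasts",
]

DEFAULT_N_PERM = 5000
DEFAULT_ALPHA = 0.05


@dataclass
class EdgeTestResult:
    """Permutation-test outcome for one (metric configuration, pair) cell."""

    metric_config: str
    pair: tuple[int, int]
    p_value: float
    direction: str | None  # "hypo" | "hyper" | None when means are equal
    passes_fdr: bool = False


@dataclass
class EffectSize:
    """Two-sample contrast: t statistic, p-value and pooled-SD Cohen's d."""

    t_statistic: float
    p: float
    cohens_d: float


@dataclass
class ConsistencyTable:
    """Per-pair and per-region counts of configurations flagging a group
    difference, split by direction.  The maximum possible count equals the
    size of the metric registry (101 for the default)."""

    pair_counts: pd.DataFrame  # columns: region_a, region_b, hypo, hyper
    region_scores: pd.DataFrame  # columns: region, hypo, hyper
    n_configs: int
    flagged: list[EdgeTestResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Permutation testing
# ---------------------------------------------------------------------------

def permutation_pvalues(
    values_patient: np.ndarray,
    values_control: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-tailed permutation test over many edges at once.

    ``values_patient`` is (n_patients, n_edges), ``values_control``
    (n_controls, n_edges).  All edges share one set of label permutations,
    which preserves the exchangeability argument per edge.  Returns
    (p_values, mean_differences) where the difference is patient minus
    control.
    """
    A = np.atleast_2d(np.asarray(values_patient, dtype=float))
    B = np.atleast_2d(np.asarray(values_control, dtype=float))
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("need at least 3 subjects per group")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    na, nb = A.shape[0], B.shape[0]
    X = np.vstack([A, B])  # (n, n_edges)
    n = na + nb
    observed_diff = A.mean(axis=0) - B.mean(axis=0)
    observed = np.abs(observed_diff)

    total = X.sum(axis=0)
    # indicator matrix of permuted "patient" memberships
    perm_stats = np.empty((n_perm, X.shape[1]))
    M = np.empty((n_perm, n))
    for i in range(n_perm):
        M[i] = 0.0
        M[i, rng.permutation(n)[:na]] = 1.0
    sum_a = M @ X
    perm_stats = np.abs(sum_a / na - (total - sum_a) / nb)

    exceed = (perm_stats >= observed - 1e-12).sum(axis=0)
    p = (exceed + 1.0) / (n_perm + 1.0)
    return p, observed_diff


def edge_permutation_test(
    values_patient: np.ndarray,
    values_control: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    metric_config: str = "",
    pair: tuple[int, int] = (0, 1),
) -> EdgeTestResult:
    """Two-tailed permutation test for a single edge; deterministic given
    the seed.  Identical groups give p = 1 and an undefined direction."""
    a = np.asarray(values_patient, dtype=float)[:, None]
    b = np.asarray(values_control, dtype=float)[:, None]
    if np.ptp(np.concatenate([a, b])) == 0:
        return EdgeTestResult(metric_config, pair, 1.0, None)
    p, diff = permutation_pvalues(a, b, n_perm=n_perm, seed=seed)
    direction = None
    if diff[0] < 0:
        direction = "hypo"
    elif diff[0] > 0:
        direction = "hyper"
    return EdgeTestResult(metric_config, pair, float(p[0]), direction)


def bh_fdr(p_values: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def select_edges(
    tensor: ConnectivityTensor,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    patient_group: str = "patient",
    control_group: str = "control",
) -> list[EdgeTestResult]:
    """Run the permutation test for every configuration and pair, with BH
    FDR applied per configuration across its edges."""
    pat = tensor.group_mask(patient_group)
    ctl = tensor.group_mask(control_group)
    iu, ju = pair_index(tensor.n_regions)
    results: list[EdgeTestResult] = []
    seq = np.random.SeedSequence(seed)
    for child, (config, values) in zip(seq.spawn(len(tensor.values)),
                                       sorted(tensor.values.items())):
        rng = np.random.default_rng(child)
        p, diff = permutation_pvalues(values[pat], values[ctl],
                                      n_perm=n_perm, seed=rng)
        flags = bh_fdr(p, alpha=alpha)
        for e in range(p.size):
            direction = None
            if diff[e] < 0:
                direction = "hypo"
            elif diff[e] > 0:
                direction = "hyper"
            results.append(EdgeTestResult(
                config, (int(iu[e]), int(ju[e])), float(p[e]), direction,
                passes_fdr=bool(flags[e])))
    return results


# ---------------------------------------------------------------------------
# Consistency mapping
# ---------------------------------------------------------------------------

def build_consistency(results: list[EdgeTestResult],
                      n_regions: int) -> ConsistencyTable:
    """Count, per pair and direction, the configurations that flag it
    (FDR survivors only); region scores sum over incident pairs."""
    configs = sorted({r.metric_config for r in results})
    iu, ju = pair_index(n_regions)
    counts = {"hypo": np.zeros(iu.size, dtype=int),
              "hyper": np.zeros(iu.size, dtype=int)}
    lookup = {(int(a), int(b)): e for e, (a, b) in enumerate(zip(iu, ju))}
    flagged = []
    for r in results:
        if r.passes_fdr and r.direction is not None:
            counts[r.direction][lookup[r.pair]] += 1
            flagged.append(r)
    pair_counts = pd.DataFrame({
        "region_a": iu, "region_b": ju,
        "hypo": counts["hypo"], "hyper": counts["hyper"]})
    region_scores = pd.DataFrame({
        "region": np.arange(n_regions),
        "hypo": [counts["hypo"][(iu == r) | (ju == r)].sum()
                 for r in range(n_regions)],
        "hyper": [counts["hyper"][(iu == r) | (ju == r)].sum()
                  for r in range(n_regions)]})
    return ConsistencyTable(pair_counts, region_scores, len(configs), flagged)


def compare_consistency(scores_a: np.ndarray,
                        scores_b: np.ndarray) -> EffectSize:
    """Two-sample t-test plus pooled-SD Cohen's d between two sets of
    consistency scores (e.g. hypo vs hyper counts of flagged pairs)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 scores per side")
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
           / (a.size + b.size - 2))
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(a, b)
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    return EffectSize(float(t), float(p), float(d))


def lobe_contrasts(
    table: ConsistencyTable,
    lobes: list[str],
    direction: str = "hypo",
    alpha: float = 0.005,
) -> pd.DataFrame:
    """All pairwise lobe contrasts of region consistency scores.

    ``lobes`` assigns a lobe code to each region in table order.  Lobes with
    fewer than 2 regions are excluded with a warning.  Two-sided t-tests
    are Bonferroni-corrected over the number of lobe pairs at the ``alpha``
    family level.
    """
    if direction not in ("hypo", "hyper"):
        raise ValueError("direction must be 'hypo' or 'hyper'")
    scores = table.region_scores[direction].to_numpy(dtype=float)
    lobes_arr = np.asarray(lobes)
    if lobes_arr.size != scores.size:
        raise ValueError("one lobe label per region required")
    by_lobe = {}
    for lobe in sorted(set(lobes_arr)):
        vals = scores[lobes_arr == lobe]
        if vals.size < 2:
            warnings.warn(f"lobe {lobe!r} has fewer than 2 regions; "
                          "excluded from contrasts", stacklevel=2)
            continue
        by_lobe[lobe] = vals
    pairs = list(itertools.combinations(sorted(by_lobe), 2))
    rows = []
    m = len(pairs)
    for la, lb in pairs:
        a, b = by_lobe[la], by_lobe[lb]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append({"lobe_a": la, "lobe_b": lb, "t": float(t),
                     "p": float(p),
                     "significant": bool(p < alpha / m) if m else False})
    return pd.DataFrame(rows)
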