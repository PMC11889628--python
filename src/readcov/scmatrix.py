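"""Structural covariance matrices and permutation-based group comparisons.

Structural covariance (SC) here is the Pearson correlation, across the
subjects of one group, between the mean grey-matter volumes of two regions
after nuisance covariates (TIV, optionally age and nonverbal IQ) have been
regressed out. Group differences are tested by permutation:

* overall: the statistic is the mean over upper-triangle entries of
  ``SC_A - SC_B``; the null is built by randomly reassigning subjects to
  two groups of the original sizes and recomputing both matrices;
* pairwise (post hoc): the per-pair statistic is ``SC_A[i, j] - SC_B[i, j]``
  with the same reassignment scheme, all pairs sharing one permutation
  stream so a single seed reproduces the whole result set; the family of
  pairwise p values is then corrected with the Benjamini-Hochberg step-up
  procedure.

Residualization is fitted once, on the pooled sample of the two groups
being compared, before any permutation; permutations reshuffle the
residuals only. Two-sided p values use the add-one Monte-Carlo formula
``p = (1 + #{|null| >= |observed|}) / (1 + n_perm)``, so p is never zero
and lies in ``[1/(1+n_perm), 1]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateRegionError, DesignError, ValidationError

# permutations are materialized in blocks to bound memory at many regions
_PERM_BLOCK = 128


@dataclass
class SCMatrix:
    """Region x region Pearson correlations for one subject group."""

    regions: list[str]
    values: np.ndarray
    group: str
    n_subjects: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        R = len(self.regions)
        assert self.values.shape == (R, R)
        assert np.allclose(self.values, self.values.T, atol=1e-10)
        assert np.allclose(np.diag(self.values), 1.0, atol=1e-10)
        assert np.all(self.values >= -1 - 1e-10) and np.all(self.values <= 1 + 1e-10)
        assert self.n_subjects >= 3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regions, columns=self.regions)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class PermutationTestResult:
    """Observed statistic, permutation null, and Monte-Carlo p value."""

    observed: float
    null: np.ndarray
    p: float
    n_perm: int
    rng_seed: int
    statistic: str  # tag describing the statistic definition

    def to_json_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "p": self.p,
            "n_perm": self.n_perm,
            "rng_seed": self.rng_seed,
        }


# ---------------------------------------------------------------------------
# residualization


def residualize(
    values: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Regress nuisance covariates out of every region column.

    One ordinary-least-squares fit (intercept + covariates) per region over
    the pooled sample; the output holds the residuals, which have zero mean
    and zero sample correlation with every covariate.
    """
    if len(values) != len(covariates):
        raise ValidationError("values and covariates have different lengths")
    if covariates.isna().any().any():
        raise ValidationError("covariates contain missing values")
    n, k = len(values), covariates.shape[1]
    if n < k + 2:
        raise ValidationError(f"need at least {k + 2} subjects for {k} covariates")
    zero_var = values.std(ddof=0) == 0
    if zero_var.any():
        raise DegenerateRegionError(
            "zero-variance region(s): "
            + ", ".join(values.columns[zero_var])
        )
    X = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(
            f"collinear covariates: {list(covariates.columns)} "
            "(design not full rank)"
        )
    Y = values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# SC matrices


def sc_matrix(residuals: pd.DataFrame, group: str = "") -> SCMatrix:
    """Pearson-correlation SC matrix over one group's residualized volumes."""
    n = len(residuals)
    if n < 3:
        raise ValidationError(f"group {group!r}: need >= 3 subjects, got {n}")
    Y = residuals.to_numpy(dtype=float)
    sd = Y.std(axis=0, ddof=0)
    # relative tolerance: residuals that are pure floating-point dust around
    # zero (e.g. a region exactly proportional to a covariate) count as
    # degenerate even though their sd is not bitwise zero
    tiny = 1e-12 * np.maximum(np.abs(Y).max(axis=0), 1.0)
    degenerate = sd <= tiny
    if np.any(degenerate):
        bad = [c for c, d in zip(residuals.columns, degenerate) if d]
        raise DegenerateRegionError(
            f"group {group!r}: zero residual variance in region(s) "
            + ", ".join(map(str, bad))
        )
    corr = np.corrcoef(Y, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SCMatrix(list(residuals.columns), corr, group, n)


def _standardized(x: np.ndarray) -> np.ndarray:
    """Standardize along the subject axis (axis -2) for correlation products."""
    x = x - x.mean(axis=-2, keepdims=True)
    norm = np.sqrt(np.sum(x * x, axis=-2, keepdims=True))
    return x / norm


def _corr_stack(x: np.ndarray) -> np.ndarray:
    """Correlation matrices for a (..., n, R) stack of data arrays."""
    z = _standardized(x)
    return np.einsum("...nr,...ns->...rs", z, z)


def _check_same_regions(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if list(a.columns) != list(b.columns):
        raise ValidationError(
            f"region mismatch between groups: {list(a.columns)} vs {list(b.columns)}"
        )


def _perm_diffs(
    resA: pd.DataFrame,
    resB: pd.DataFrame,
    n_perm: int,
    rng_seed: int,
    fisher_z: bool,
):
    """Observed and permutation-null SC difference matrices.

    Returns ``(observed_diff, null_diffs)`` where ``null_diffs`` has shape
    ``(n_perm, R, R)``. The null reassigns the pooled subjects at random to
    two groups of the original sizes and recomputes both correlation
    matrices for every permutation.
    """
    _check_same_regions(resA, resB)
    nA, nB = len(resA), len(resB)
    if nA < 3 or nB < 3:
        raise ValidationError("both groups need >= 3 subjects")
    # enforce one memory layout so identical inputs give bitwise-identical
    # correlation matrices regardless of how the frames were constructed
    A = np.ascontiguousarray(resA.to_numpy(dtype=float))
    B = np.ascontiguousarray(resB.to_numpy(dtype=float))
    pooled = np.vstack([A, B])

    def transform(c: np.ndarray) -> np.ndarray:
        if not fisher_z:
            return c
        return np.arctanh(np.clip(c, -1 + 1e-12, 1 - 1e-12))

    obs = transform(_corr_stack(A)) - transform(_corr_stack(B))
    rng = np.random.default_rng(rng_seed)
    R = pooled.shape[1]
    null = np.empty((n_perm, R, R))
    done = 0
    n = nA + nB
    while done < n_perm:
        block = min(_PERM_BLOCK, n_perm - done)
        # one independent uniform permutation of the pooled sample per draw
        perms = np.argsort(rng.random((block, n)), axis=1)
        shuffled = pooled[perms]  # (block, n, R)
        cA = _corr_stack(shuffled[:, :nA, :])
        cB = _corr_stack(shuffled[:, nA:, :])
        null[done : done + block] = transform(cA) - transform(cB)
        done += block
    return obs, null


def _mc_p(observed: float, null: np.ndarray, n_perm: int) -> float:
    return float((1 + np.sum(np.abs(null) >= abs(observed))) / (1 + n_perm))


def compare_sc_overall(
    resA: pd.DataFrame,
    resB: pd.DataFrame,
    n_perm: int = 1000,
    rng_seed: int = 0,
    fisher_z: bool = False,
) -> PermutationTestResult:
    """Permutation test of the mean SC difference between two groups.

    The observed statistic is the mean over the upper triangle of
    ``SC_A - SC_B`` (signed); significance is two-sided via the absolute
    value against the reassignment null.
    """
    obs_diff, null_diff = _perm_diffs(resA, resB, n_perm, rng_seed, fisher_z)
    iu = np.triu_indices(obs_diff.shape[0], k=1)
    observed = float(obs_diff[iu].mean())
    null = null_diff[:, iu[0], iu[1]].mean(axis=1)
    tag = "mean_upper_triangle_diff" + ("_fisher_z" if fisher_z else "")
    return PermutationTestResult(
        observed=observed,
        null=null,
        p=_mc_p(observed, null, n_perm),
        n_perm=n_perm,
        rng_seed=rng_seed,
        statistic=tag,
    )


def compare_sc_pairwise(
    resA: pd.DataFrame,
    resB: pd.DataFrame,
    n_perm: int = 1000,
    rng_seed: int = 0,
    q: float = 0.05,
    fisher_z: bool = False,
) -> pd.DataFrame:
    """Post-hoc per-pair permutation tests with BH-FDR correction.

    All ``R(R-1)/2`` region pairs are tested against one shared permutation
    stream. Returns a DataFrame with columns ``region_i, region_j,
    observed, p, rejected`` (BH at rate ``q``), sorted by p.
    """
    obs_diff, null_diff = _perm_diffs(resA, resB, n_perm, rng_seed, fisher_z)
    iu = np.triu_indices(obs_diff.shape[0], k=1)
    regions = list(resA.columns)
    obs = obs_diff[iu]
    null = null_diff[:, iu[0], iu[1]]  # (n_perm, n_pairs)
    counts = np.sum(np.abs(null) >= np.abs(obs)[None, :], axis=0)
    pvals = (1 + counts) / (1 + n_perm)
    out = pd.DataFrame({
        "region_i": [regions[i] for i in iu[0]],
        "region_j": [regions[j] for j in iu[1]],
        "observed": obs,
        "p": pvals,
    })
    out["rejected"] = bh_fdr(out["p"].to_numpy(), q=q)
    return out.sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# multiple-testing correction


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at FDR level ``q``.

    Sort the m p values ascending, find the largest k with
    ``p_(k) <= k * q / m``, and reject hypotheses 1..k. Returns a boolean
    array aligned with the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValidationError("q must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = (np.arange(1, m + 1) * q) / m
    passed = p[order] <= thresholds
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        k = int(np.max(np.flatnonzero(passed)))
        reject[order[: k + 1]] = True
    return reject


# ---------------------------------------------------------------------------
# result I/O


def write_result_json(result: PermutationTestResult, path: str | Path) -> None:
    """Serialize a permutation result (without the null draws) as JSON."""
    Path(path).write_text(
        json.dumps(result.to_json_dict(), sort_keys=True, indent=2) + "\n"
    )


def write_pairwise_tsv(pairwise: pd.DataFrame, path: str | Path) -> None:
    pairwise.to_csv(path, sep="\t", index=False)
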