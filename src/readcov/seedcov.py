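"""Voxelwise seed-based structural covariance GLM with cluster inference.

For one seed region, each in-mask voxel's GMV across subjects is regressed
on an intercept, nuisance covariates (TIV by default) and the seed's mean
GMV; the seed coefficient's t statistic forms the statistic map. Clusters
of voxels exceeding a one-sided t threshold (voxel-level p < 0.001 by
default, positive direction) are assessed for family-wise-error-corrected
significance by a permutation null of the maximum cluster size: the seed
covariate is permuted across subjects following the Freedman-Lane scheme
(nuisance fit retained, residuals reshuffled) and the full GLM plus
thresholding is recomputed for every permutation. This replaces the
random-field-theory cluster correction used by classical VBM software with
an exchangeability-exact resampling equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .exceptions import DesignError, GeometryError, ValidationError
from .volumes import GMVMap

#: 18-neighbour connectivity (faces + edges) for cluster labeling
_CONNECTIVITY = ndimage.generate_binary_structure(3, 2)


@dataclass
class StatMap:
    """Per-voxel seed t statistics with everything needed for resampling."""

    t: np.ndarray  # 3-D, NaN outside the analysis mask
    df: int
    mask: np.ndarray  # 3-D boolean analysis mask
    affine: np.ndarray
    # data retained for permutation inference (in-mask, subjects x voxels)
    _Y: np.ndarray = field(repr=False)
    _Z: np.ndarray = field(repr=False)  # nuisance incl. intercept
    _seed: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise DesignError("non-positive degrees of freedom")

    def save_t(self, path: str | Path) -> None:
        GMVMap(np.nan_to_num(self.t), self.affine).save(path)


def _standardize_cols(a: np.ndarray) -> np.ndarray:
    """Centre and unit-scale design columns (t statistics are unaffected).

    Keeps the normal equations well conditioned regardless of covariate
    units (e.g. TIV in mm^3). Constant columns are left centred so the
    rank check downstream reports them as collinear with the intercept.
    """
    a = a - a.mean(axis=0, keepdims=True)
    sd = a.std(axis=0, keepdims=True)
    return a / np.where(sd > 0, sd, 1.0)


def _tmap_columns(Y: np.ndarray, X: np.ndarray, XtXinv: np.ndarray,
                  df: int) -> np.ndarray:
    """t statistics for the last design column, one per data column of Y."""
    XtY = X.T @ Y
    beta = XtXinv @ XtY
    sse = np.einsum("nv,nv->v", Y, Y) - np.einsum("kv,kv->v", beta, XtY)
    sigma2 = np.maximum(sse, 0.0) / df
    denom = np.sqrt(sigma2 * XtXinv[-1, -1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[-1] / denom
    t[denom <= 1e-300] = np.nan
    return t


def fit_seed_glm(
    maps: dict[str, GMVMap],
    seed_values: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    mask: np.ndarray | None = None,
) -> StatMap:
    """Ordinary-least-squares seed GLM per voxel.

    ``maps`` maps subject id to a GMVMap on one shared grid;
    ``seed_values`` is the per-subject seed mean GMV (aligned with the map
    order, or a Series indexed by subject id); ``covariates`` holds the
    nuisance columns (e.g. TIV). The design is
    ``[intercept, covariates..., seed]`` and the returned t map is for the
    seed coefficient. Voxels with zero residual variance are masked out
    (NaN). The default analysis mask keeps voxels whose value varies
    across subjects.
    """
    ids = list(maps)
    n = len(ids)
    ref = maps[ids[0]]
    offenders = [sid for sid in ids if not maps[sid].same_grid(ref)]
    if offenders:
        raise GeometryError(
            "maps do not share one grid; offending subjects: "
            + ", ".join(offenders)
        )
    if isinstance(seed_values, pd.Series):
        try:
            seed = seed_values.loc[ids].to_numpy(dtype=float)
        except KeyError as exc:
            raise ValidationError(f"seed values missing for subjects: {exc}")
    else:
        seed = np.asarray(seed_values, dtype=float)
    if seed.shape != (n,):
        raise ValidationError("seed_values length does not match maps")
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame) and not covariates.index.equals(
            pd.Index(ids)
        ):
            cov = covariates.reindex(ids)
            if cov.isna().any().any():
                raise ValidationError("covariates missing for some subjects")
        else:
            cov = pd.DataFrame(np.asarray(covariates, dtype=float))
        Z = np.column_stack([np.ones(n), _standardize_cols(cov.to_numpy(dtype=float))])
        colnames = ["intercept", *map(str, cov.columns)]
    else:
        Z = np.ones((n, 1))
        colnames = ["intercept"]
    X = np.column_stack([Z, _standardize_cols(seed[:, None])])
    colnames.append("seed")
    k = X.shape[1]
    if n < k + 2:
        raise ValidationError(f"need at least {k + 2} subjects for {k} columns")
    if np.linalg.matrix_rank(X) < k:
        raise DesignError(
            f"rank-deficient design (columns: {colnames}); is the seed "
            "covariate constant or collinear with a nuisance column?"
        )
    stack = np.stack([maps[sid].data for sid in ids])  # (n, x, y, z)
    flat = stack.reshape(n, -1)
    if mask is None:
        mask3d = stack.std(axis=0) > 0
    else:
        mask3d = np.asarray(mask, dtype=bool)
        if mask3d.shape != ref.shape:
            raise GeometryError("mask shape does not match the maps")
    if not mask3d.any():
        raise ValidationError("analysis mask is empty")
    Y = flat[:, mask3d.ravel()]
    df = n - k
    XtXinv = np.linalg.inv(X.T @ X)
    tvals = _tmap_columns(Y, X, XtXinv, df)
    t3d = np.full(ref.shape, np.nan)
    t3d.ravel()[np.flatnonzero(mask3d.ravel())] = tvals
    # drop zero-residual-variance voxels from the mask
    good = np.isfinite(t3d) & mask3d
    return StatMap(t=t3d, df=df, mask=good, affine=ref.affine,
                   _Y=Y, _Z=Z, _seed=X[:, -1])


def _max_cluster_size(supra: np.ndarray) -> int:
    if not supra.any():
        return 0
    labels, nlab = ndimage.label(supra, structure=_CONNECTIVITY)
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_inference(
    stat_map: StatMap,
    voxel_p: float = 0.001,
    fwe_alpha: float = 0.05,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Cluster-extent inference by a permutation maximum-cluster-size null.

    The statistic map is thresholded one-sided (positive t) at the
    ``voxel_p`` upper quantile of t(df); connected components use
    18-neighbour connectivity. The null distribution of the maximum
    cluster size is built by Freedman-Lane permutation of the seed
    covariate, and each observed cluster's FWE-corrected p value is
    ``(1 + #{max_perm >= size_obs}) / (1 + n_perm)``.

    Returns a DataFrame of all observed clusters, sorted by size, with
    columns ``cluster_p_fwe, equivk, peak_t, x, y, z, significant``.
    An empty table (no suprathreshold voxel) is returned, not raised.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    tcrit = float(stats.t.isf(voxel_p, stat_map.df))
    tvals = np.where(stat_map.mask, stat_map.t, -np.inf)
    supra = tvals > tcrit
    cols = ["cluster_p_fwe", "equivk", "peak_t", "x", "y", "z", "significant"]
    if not supra.any():
        return pd.DataFrame(columns=cols)
    labels, nlab = ndimage.label(supra, structure=_CONNECTIVITY)
    sizes = np.bincount(labels.ravel())[1:]

    # Freedman-Lane: refit the reduced (nuisance-only) model once, permute
    # its residuals, and redo the full fit per permutation. Re-adding the
    # nuisance fit is skipped: it lies in the column space of the full
    # design, so it changes neither the seed coefficient nor the SSE.
    Y, Z, seed = stat_map._Y, stat_map._Z, stat_map._seed
    gamma, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    Rz = (Y - Z @ gamma).astype(np.float32)
    X = np.column_stack([Z, seed]).astype(np.float32)
    XtXinv = np.linalg.inv(X.T @ X)
    df = stat_map.df
    n = Y.shape[0]
    mask_flat = np.flatnonzero(stat_map.mask.ravel())
    shape = stat_map.mask.shape

    rng = np.random.default_rng(rng_seed)
    null_max = np.empty(n_perm, dtype=int)
    supra_buf = np.zeros(np.prod(shape), dtype=bool)
    for i in range(n_perm):
        perm = rng.permutation(n)
        tstar = _tmap_columns(Rz[perm], X, XtXinv, df)
        hits = np.nan_to_num(tstar, nan=-np.inf) > tcrit
        if not hits.any():
            null_max[i] = 0
            continue
        supra_buf[:] = False
        supra_buf[mask_flat[hits]] = True
        null_max[i] = _max_cluster_size(supra_buf.reshape(shape))

    rows = []
    for lab in range(1, nlab + 1):
        size = int(sizes[lab - 1])
        inside = labels == lab
        masked_t = np.where(inside, tvals, -np.inf)
        peak_flat = int(np.argmax(masked_t))
        ijk = np.unravel_index(peak_flat, shape)
        world = stat_map.affine @ np.array([*ijk, 1.0])
        p_fwe = float((1 + np.sum(null_max >= size)) / (1 + n_perm))
        rows.append({
            "cluster_p_fwe": p_fwe,
            "equivk": size,
            "peak_t": float(tvals[ijk]),
            "x": float(world[0]),
            "y": float(world[1]),
            "z": float(world[2]),
            "significant": p_fwe <= fwe_alpha,
        })
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("equivk", ascending=False, kind="stable").reset_index(
        drop=True
    )


def write_cluster_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def suprathreshold_mask(
    stat_map: StatMap, voxel_p: float = 0.001
) -> GMVMap:
    """Binary mask of voxels above the one-sided voxel threshold."""
    tcrit = float(stats.t.isf(voxel_p, stat_map.df))
    supra = (np.where(stat_map.mask, stat_map.t, -np.inf) > tcrit).astype(float)
    return GMVMap(supra, stat_map.affine)
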