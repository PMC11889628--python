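"""Synthetic cohorts with known ground-truth covariance structure.

Real grey-matter-volume data for this kind of study is restricted, so every
downstream stage is exercised on simulated cohorts whose generating
parameters are known exactly. The generator emulates, per subject group:

* phenotype marginals (age range, sex, handedness, nonverbal-IQ percentile,
  reading-fluency percentile, intracranial volume, MRI quality rating,
  comorbidity flags) with fluency drawn so that intended poor readers fall
  at or below the 16th percentile and typical readers at or above the 25th;
* regional mean GMV values whose inter-regional correlation matrix equals a
  configurable group-specific target, on top of a shared linear TIV
  confound and optional age/IQ covariate effects;
* optionally, small voxelwise GMV maps containing a seed sphere and planted
  clusters whose intensities covary with the seed across subjects, plus a
  global TIV scaling — the substrate for seed-based covariance GLM tests.

Regional volumes are drawn as ``mean + sd * z`` with ``z ~ MVN(0, C)`` via
Cholesky factorization of the target correlation matrix ``C``. Matrices
that are not symmetric positive semi-definite are rejected outright rather
than repaired, so the simulated ground truth is always exactly the
configured one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import POOR_CUTOFF, TYPICAL_CUTOFF
from .exceptions import ConfigurationError
from .volumes import GMVMap, ROISpec, make_sphere_roi

#: the five seed regions used for the reading-network covariance matrices
DEFAULT_REGIONS = ("VWFA_lex", "VWFA_per", "STG", "IFG", "IPL")


@dataclass(frozen=True)
class GroupProfile:
    """Phenotype marginals for one subject group."""

    cohort: str  # {"child", "adult"}
    age_range: tuple[float, float]
    fluency_mean: float | None  # None -> uniform on (0, poor cutoff]
    fluency_sd: float | None
    fluency_bounds: tuple[float, float]
    iq_mean: float | None  # None -> IQ not assessed
    iq_sd: float | None
    quality_mean: float
    quality_sd: float
    p_male: float
    handedness_probs: tuple[float, float, float]  # left, right, both
    comorbidity_rates: Mapping[str, float] = field(default_factory=dict)


# Marginals chosen to emulate the demographic structure of a school-age
# reading cohort: typical readers centred high on the fluency scale, poor
# readers compressed under the 16th percentile, IQ percentiles mildly lower
# in the poor group, near-identical MRI quality across child groups.
GROUP_PROFILES: dict[str, GroupProfile] = {
    "typical_adult": GroupProfile(
        cohort="adult", age_range=(18.0, 40.0),
        fluency_mean=62.09, fluency_sd=21.55,
        fluency_bounds=(TYPICAL_CUTOFF, 100.0),
        iq_mean=None, iq_sd=None,
        quality_mean=87.06, quality_sd=0.32,
        p_male=49 / 134, handedness_probs=(0.0, 1.0, 0.0),
    ),
    "typical_child": GroupProfile(
        cohort="child", age_range=(6.88, 12.09),
        fluency_mean=59.35, fluency_sd=21.40,
        fluency_bounds=(TYPICAL_CUTOFF, 100.0),
        iq_mean=62.07, iq_sd=17.22,
        quality_mean=86.33, quality_sd=1.20,
        p_male=52 / 110, handedness_probs=(10 / 110, 98 / 110, 2 / 110),
        comorbidity_rates={"ADHD": 0.03, "dyscalculia": 0.02},
    ),
    "poor_child": GroupProfile(
        cohort="child", age_range=(7.47, 12.16),
        fluency_mean=None, fluency_sd=None,
        fluency_bounds=(0.0, POOR_CUTOFF),
        iq_mean=56.08, iq_sd=17.81,
        quality_mean=86.34, quality_sd=1.12,
        p_male=32 / 68, handedness_probs=(5 / 68, 63 / 68, 0.0),
        comorbidity_rates={"ADHD": 0.15, "dyscalculia": 0.10},
    ),
}


@dataclass(frozen=True)
class MapGrid:
    """Geometry of simulated voxel maps: shape, isotropic voxel size, affine."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 2.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        # centre the grid on the world origin
        aff[:3, 3] = -self.voxel_size * (np.asarray(self.shape) - 1) / 2.0
        return aff


@dataclass
class SimulationConfig:
    """Everything needed to simulate one cohort.

    ``target_corr`` maps each group name to a region x region correlation
    matrix (symmetric, unit diagonal, PSD). ``beta_tiv`` is the per-region
    slope of volume on (TIV - tiv_mean); ``covariate_effects`` optionally
    maps a phenotype column (``age``, ``iq_percentile``) to per-region
    slopes on the mean-centred covariate. Map simulation uses ``map_grid``,
    a seed sphere, planted clusters, a seed amplitude, a seed-to-cluster
    ``coupling_strength`` and a multiplicative TIV scaling per SD of TIV.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"typical_child": 110, "poor_child": 68}
    )
    region_names: Sequence[str] = DEFAULT_REGIONS
    target_corr: Mapping[str, np.ndarray] | None = None
    region_means: np.ndarray | None = None
    region_sds: np.ndarray | None = None
    tiv_mean: float = 1.45e6  # mm^3
    tiv_sd: float = 1.2e5
    beta_tiv: np.ndarray | float = 3e-7  # volume units per mm^3 of TIV
    covariate_effects: Mapping[str, np.ndarray] | None = None
    map_grid: MapGrid | None = None
    seed_roi: ROISpec | None = None
    cluster_rois: Sequence[ROISpec] = ()
    seed_amp: float = 0.08
    coupling_strength: float = 0.0
    map_tiv_coupling: float = 0.0  # relative intensity scaling per SD of TIV
    baseline: float = 0.5
    noise_sd: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        R = len(self.region_names)
        if self.region_means is None:
            self.region_means = np.full(R, 0.55)
        if self.region_sds is None:
            self.region_sds = np.full(R, 0.06)
        self.region_means = np.asarray(self.region_means, dtype=float)
        self.region_sds = np.asarray(self.region_sds, dtype=float)
        if self.target_corr is None:
            self.target_corr = {
                g: _uniform_corr(R, 0.45 if not g.startswith("poor") else 0.25)
                for g in self.n_per_group
            }
        self.target_corr = {
            g: np.asarray(c, dtype=float) for g, c in self.target_corr.items()
        }
        if np.isscalar(self.beta_tiv):
            self.beta_tiv = np.full(R, float(self.beta_tiv))  # type: ignore[assignment]
        self.beta_tiv = np.asarray(self.beta_tiv, dtype=float)
        self.validate()

    def validate(self) -> None:
        R = len(self.region_names)
        for g, n in self.n_per_group.items():
            if g not in GROUP_PROFILES:
                raise ConfigurationError(
                    f"unknown group {g!r}; known: {sorted(GROUP_PROFILES)}"
                )
            if n < 3:
                raise ConfigurationError(f"group {g!r}: n_per_group must be >= 3")
        if self.region_means.shape != (R,) or self.region_sds.shape != (R,):
            raise ConfigurationError("region_means/region_sds length mismatch")
        if np.any(self.region_sds < 0):
            raise ConfigurationError("region_sds must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.beta_tiv.shape != (R,):
            raise ConfigurationError("beta_tiv length mismatch")
        for g, corr in self.target_corr.items():
            _check_corr(corr, R, g)
        if self.covariate_effects:
            for cov, slopes in self.covariate_effects.items():
                if np.asarray(slopes).shape != (R,):
                    raise ConfigurationError(
                        f"covariate_effects[{cov!r}] length mismatch"
                    )


def _uniform_corr(R: int, rho: float) -> np.ndarray:
    c = np.full((R, R), rho)
    np.fill_diagonal(c, 1.0)
    return c


def _check_corr(corr: np.ndarray, R: int, label: str) -> None:
    if corr.shape != (R, R):
        raise ConfigurationError(f"target_corr[{label!r}] must be {R}x{R}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ConfigurationError(f"target_corr[{label!r}] is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ConfigurationError(f"target_corr[{label!r}] diagonal is not 1")
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ConfigurationError(
            f"target_corr[{label!r}] is not positive semi-definite"
        )


# ---------------------------------------------------------------------------
# phenotypes


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def simulate_phenotypes(cfg: SimulationConfig) -> pd.DataFrame:
    """Draw one subject table for the configured groups.

    Reading-fluency percentiles are drawn inside each group's admissible
    band — ``(0, 16]`` for intended poor readers, ``[25, 100]`` truncated
    normal for typical readers — so classification by the percentile rule
    reproduces the configured group sizes exactly. TIV is normal truncated
    to positive values; quality ratings are clipped into ``(0, 100]``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    rows = []
    counter = 0
    for group in sorted(cfg.n_per_group):
        n = cfg.n_per_group[group]
        prof = GROUP_PROFILES[group]
        age = rng.uniform(*prof.age_range, size=n)
        if prof.fluency_mean is None:
            # uniform on (0, cutoff]: 1 - U with U in [0, 1)
            lo, hi = prof.fluency_bounds
            fluency = hi - (hi - lo) * rng.random(n)
        else:
            fluency = _truncnorm(rng, prof.fluency_mean, prof.fluency_sd,
                                 *prof.fluency_bounds, n)
        if prof.iq_mean is None:
            iq = np.full(n, np.nan)
        else:
            iq = _truncnorm(rng, prof.iq_mean, prof.iq_sd, 0.0, 100.0, n)
        tiv = _truncnorm(rng, cfg.tiv_mean, cfg.tiv_sd, 1e-9, np.inf, n)
        quality = np.clip(
            rng.normal(prof.quality_mean, prof.quality_sd, size=n), 1e-9, 100.0
        )
        sex = np.where(rng.random(n) < prof.p_male, "m", "f")
        hand = rng.choice(
            ["l", "r", "b"], size=n, p=np.asarray(prof.handedness_probs)
            / sum(prof.handedness_probs),
        )
        flags = []
        for _ in range(n):
            carried = sorted(
                f for f, rate in prof.comorbidity_rates.items()
                if rng.random() < rate
            )
            flags.append(";".join(carried))
        for i in range(n):
            counter += 1
            rows.append({
                "id": f"sub-{counter:04d}",
                "cohort": prof.cohort,
                "group": group,
                "age": age[i],
                "sex": sex[i],
                "handedness": hand[i],
                "iq_percentile": iq[i],
                "reading_fluency_percentile": fluency[i],
                "tiv": tiv[i],
                "quality_rating": quality[i],
                "comorbidity": flags[i],
                "map_ref": "",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regional volumes


def simulate_roi_volumes(
    cfg: SimulationConfig, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Regional mean-GMV table with group-specific correlation structure.

    Per subject: ``volume = mean + sd * z + beta_tiv * (tiv - tiv_mean)``
    with ``z ~ MVN(0, target_corr[group])``, plus optional mean-centred
    covariate effects. Returns a subjects x regions DataFrame indexed by id.
    """
    cfg.validate()
    missing = set(subjects["group"]) - set(cfg.target_corr)
    if missing:
        raise ConfigurationError(
            f"no target_corr for group(s) {sorted(missing)}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.rng_seed, 1]).generate_state(1)[0]
    )
    R = len(cfg.region_names)
    chol = {g: np.linalg.cholesky(_psd_jitter(c))
            for g, c in cfg.target_corr.items()}
    values = np.empty((len(subjects), R))
    tiv = subjects["tiv"].to_numpy(dtype=float)
    for g in sorted(set(subjects["group"])):
        sel = np.flatnonzero((subjects["group"] == g).to_numpy())
        z = rng.standard_normal((sel.size, R)) @ chol[g].T
        values[sel] = cfg.region_means + cfg.region_sds * z
    values += np.outer(tiv - cfg.tiv_mean, cfg.beta_tiv)
    if cfg.covariate_effects:
        for cov, slopes in cfg.covariate_effects.items():
            x = subjects[cov].to_numpy(dtype=float)
            x = np.where(np.isnan(x), np.nanmean(x), x)
            values += np.outer(x - x.mean(), np.asarray(slopes, dtype=float))
    return pd.DataFrame(values, index=pd.Index(subjects["id"], name="id"),
                        columns=list(cfg.region_names))


def _psd_jitter(corr: np.ndarray) -> np.ndarray:
    """Make a PSD (possibly singular) matrix Cholesky-factorable.

    Validation has already rejected genuinely non-PSD inputs; this only
    lifts exact zero eigenvalues above floating-point noise.
    """
    try:
        np.linalg.cholesky(corr)
        return corr
    except np.linalg.LinAlgError:
        return corr + 1e-12 * np.eye(corr.shape[0])


# ---------------------------------------------------------------------------
# voxel maps


@dataclass
class SimulatedMaps:
    """Simulated per-subject maps plus the generating latent variables."""

    maps: dict[str, GMVMap]
    latents: pd.DataFrame  # per subject: the seed latent s and TIV factor
    grid: MapGrid


def simulate_gmv_maps(
    cfg: SimulationConfig, subjects: pd.DataFrame
) -> SimulatedMaps:
    """Per-subject voxel maps with a seed sphere and planted covarying clusters.

    Each subject's map is ``baseline + seed_amp * s`` inside the seed
    sphere, ``+ coupling_strength * s`` inside every planted cluster, plus
    i.i.d. voxel noise, all scaled by ``1 + map_tiv_coupling * (tiv -
    tiv_mean) / tiv_sd``. ``s ~ N(0, 1)`` is the subject-level seed latent,
    returned alongside the maps so recovery tests can check against ground
    truth. All maps share one affine.
    """
    cfg.validate()
    if cfg.map_grid is None:
        raise ConfigurationError("map_grid must be set to simulate voxel maps")
    if cfg.seed_roi is None:
        raise ConfigurationError("seed_roi must be set to simulate voxel maps")
    grid = cfg.map_grid
    ref = GMVMap(np.zeros(grid.shape), grid.affine)
    try:
        seed_mask = make_sphere_roi(cfg.seed_roi, ref).as_boolean()
        cluster_masks = [
            make_sphere_roi(c, ref).as_boolean() for c in cfg.cluster_rois
        ]
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.rng_seed, 2]).generate_state(1)[0]
    )
    maps: dict[str, GMVMap] = {}
    latents = []
    tiv = subjects["tiv"].to_numpy(dtype=float)
    for i, sid in enumerate(subjects["id"]):
        s = rng.standard_normal()
        data = np.full(grid.shape, cfg.baseline)
        data[seed_mask] += cfg.seed_amp * s
        for cm in cluster_masks:
            data[cm] += cfg.coupling_strength * s
        if cfg.noise_sd > 0:
            data += rng.normal(0.0, cfg.noise_sd, size=grid.shape)
        factor = 1.0 + cfg.map_tiv_coupling * (tiv[i] - cfg.tiv_mean) / cfg.tiv_sd
        data *= factor
        maps[str(sid)] = GMVMap(data, grid.affine)
        latents.append({"id": str(sid), "s": s, "tiv_factor": factor})
    return SimulatedMaps(maps, pd.DataFrame(latents).set_index("id"), grid)


# ---------------------------------------------------------------------------
# config I/O


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    """Serialize a config to YAML (arrays as nested lists)."""
    d = dataclasses.asdict(cfg)
    d["n_per_group"] = dict(cfg.n_per_group)
    d["region_names"] = list(cfg.region_names)
    d["target_corr"] = {g: c.tolist() for g, c in cfg.target_corr.items()}
    for k in ("region_means", "region_sds", "beta_tiv"):
        d[k] = getattr(cfg, k).tolist()
    if cfg.covariate_effects:
        d["covariate_effects"] = {
            k: np.asarray(v).tolist() for k, v in cfg.covariate_effects.items()
        }
    if cfg.map_grid is not None:
        d["map_grid"] = {"shape": list(cfg.map_grid.shape),
                         "voxel_size": cfg.map_grid.voxel_size}
    d["seed_roi"] = _roi_to_dict(cfg.seed_roi)
    d["cluster_rois"] = [_roi_to_dict(c) for c in cfg.cluster_rois]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path: str | Path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("target_corr"):
        d["target_corr"] = {g: np.asarray(c) for g, c in d["target_corr"].items()}
    if d.get("map_grid"):
        d["map_grid"] = MapGrid(tuple(d["map_grid"]["shape"]),
                                float(d["map_grid"]["voxel_size"]))
    if d.get("seed_roi"):
        d["seed_roi"] = _roi_from_dict(d["seed_roi"])
    d["cluster_rois"] = [_roi_from_dict(c) for c in d.get("cluster_rois") or []]
    return SimulationConfig(**d)


def _roi_to_dict(roi: ROISpec | None):
    if roi is None:
        return None
    return {"name": roi.name, "center": list(roi.center), "radius": roi.radius}


def _roi_from_dict(d) -> ROISpec:
    return ROISpec(d["name"], tuple(d["center"]), d["radius"])
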