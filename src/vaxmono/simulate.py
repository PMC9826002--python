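"""Synthetic data: the simulation-study design and geography fixtures.

The generative model mirrors the study design used to compare the CP and RB
constructions: a shared logit-scale linear predictor built from an intercept
and three covariates drawn iid from N(0,1), Gamma(1,1) and Student-t(2), a
Matérn(nu=1) spatial field, an iid nugget, and fixed *incremental shifts* on
the logit scale for the later doses,

    eta1(s) = x(s)'beta + omega(s) + eps(s),
    eta2(s) = eta1(s) + delta2,    eta3(s) = eta1(s) + delta3,

with delta2 > delta3 so that p1(s) > p2(s) > p3(s) everywhere.  Defaults:
beta = (0.5, 0.8, 0.8, 0.2), sigma2 = 1, r = 2.62, sigma2_eps = 1,
delta2 = -1.3, delta3 = -2.5.  Observation locations are uniform over a
square window scaled so the first quartile of pairwise distances is close to
the default range (the field convention from which r is derived); sample
sizes are
discrete-uniform U{2,K} for a ladder of upper bounds K, and success counts
are deterministic fractions y_k = n * p_k — no binomial noise — which keeps
the counts exactly monotone and the truth recoverable.

One truth realisation is shared by all datasets of a study; the default
ladder of 8 size families times 3 target indicators yields 24 datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy.linalg import cholesky
from scipy.spatial.distance import pdist
from scipy.special import expit
from shapely.geometry import box, mapping as _geom_mapping

from .data_model import AdminUnit, ClusterDataset, PredictionGrid, write_cluster_table
from .geomodel import MaternParams, ModelParams, matern_cov_matrix
from .indicators import IndicatorDataset

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "DEFAULT_SIZE_FAMILIES",
    "SMALL_SIZE_FAMILIES",
    "simulate_covariates",
    "simulate_truth",
    "draw_sample_sizes",
    "make_counts",
    "generate_study",
    "make_fixture_geography",
    "write_admin_geojson",
    "write_study",
]

DEFAULT_SIZE_FAMILIES = (10, 20, 30, 40, 50, 60, 70, 80)
#: sensitivity preset with smaller cluster samples
SMALL_SIZE_FAMILIES = (8, 10, 12, 15, 20, 25, 30, 35)
COVARIATE_NAMES = ["x_norm", "x_gamma", "x_t2"]
DOSE_LABELS = ("p1", "p2", "p3")


@dataclass
class SimConfig:
    """Study-design constants; defaults reproduce the reference design."""

    seed: int = 0
    m_obs: int = 300
    window: tuple[float, float] = (8.0, 8.0)
    grid_shape: tuple[int, int] = (10, 10)
    true_params: ModelParams = field(
        default_factory=lambda: ModelParams(
            beta=np.array([0.5, 0.8, 0.8, 0.2]), sigma2=1.0, range=2.62, sigma2_eps=1.0
        )
    )
    increments: tuple[float, float] = (-1.3, -2.5)
    size_families: tuple[int, ...] = DEFAULT_SIZE_FAMILIES
    spatial: bool = True
    range_from_quartile: bool = False
    round_counts: bool = False
    redraw_residuals: bool = False

    def __post_init__(self) -> None:
        d2, d3 = self.increments
        if not d2 > d3:
            raise ValueError(f"increments must satisfy delta2 > delta3, got {self.increments}")
        if any(k < 2 for k in self.size_families):
            raise ValueError("size-family upper bounds K must be >= 2")
        if self.m_obs < 1:
            raise ValueError("m_obs must be >= 1")


@dataclass
class SimTruth:
    """One realisation of the truth at observation and grid locations."""

    coords_obs: np.ndarray          # (m, 2)
    coords_grid: np.ndarray         # (L, 2)
    X_obs: np.ndarray               # (m, 3)
    X_grid: np.ndarray              # (L, 3)
    p_obs: np.ndarray               # (m, 3) — columns p1, p2, p3
    p_grid: np.ndarray              # (L, 3)
    omega_obs: np.ndarray
    omega_grid: np.ndarray
    range_used: float
    covariate_names: list[str] = field(default_factory=lambda: list(COVARIATE_NAMES))


@dataclass
class SimStudy:
    truth: SimTruth
    cluster_datasets: dict            # K -> ClusterDataset (joint three-dose table)
    datasets: dict                    # (K, dose label) -> IndicatorDataset
    config: SimConfig
    seed_log: dict = field(default_factory=dict)


def simulate_covariates(m: int, rng) -> np.ndarray:
    """(m, 3) matrix of iid N(0,1), Gamma(1,1) and Student-t(2) covariates."""
    rng = np.random.default_rng(rng)
    return np.column_stack(
        [rng.standard_normal(m), rng.gamma(1.0, 1.0, m), rng.standard_t(2, m)]
    )


def _grid_coords(cfg: SimConfig) -> np.ndarray:
    nx, ny = cfg.grid_shape
    wx, wy = cfg.window
    xs = (np.arange(nx) + 0.5) * wx / nx
    ys = (np.arange(ny) + 0.5) * wy / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def simulate_truth(cfg: SimConfig, rng=None) -> SimTruth:
    """Draw one joint truth realisation over observation + grid locations.

    The Matérn field omega is drawn *jointly* over both point sets (skipped
    when ``cfg.spatial`` is false), a nugget eps is drawn per location, and
    the incremental shifts produce the later doses from the same
    realisation.  With ``redraw_residuals`` the nugget is redrawn per dose
    (the alternative reading of "changes in the residual terms"), after
    which monotonicity is restored with a running minimum.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    wx, wy = cfg.window
    coords_obs = rng.uniform((0, 0), (wx, wy), size=(cfg.m_obs, 2))
    coords_grid = _grid_coords(cfg)
    m, L = len(coords_obs), len(coords_grid)
    X_obs = simulate_covariates(m, rng)
    X_grid = simulate_covariates(L, rng)
    tp = cfg.true_params
    r_used = tp.range
    if cfg.range_from_quartile and m > 1:
        r_used = float(np.quantile(pdist(coords_obs), 0.25))
    allc = np.vstack([coords_obs, coords_grid])
    if cfg.spatial:
        Sig = matern_cov_matrix(allc, None, MaternParams(tp.sigma2, r_used))
        Sig[np.diag_indices_from(Sig)] += 1e-8 * tp.sigma2
        omega = cholesky(Sig, lower=True) @ rng.standard_normal(m + L)
    else:
        omega = np.zeros(m + L)
    sd_eps = np.sqrt(tp.sigma2_eps)
    d2, d3 = cfg.increments
    deltas = np.array([0.0, d2, d3])

    def _dose_probs(X, om, n_loc):
        fixed = np.column_stack([np.ones(n_loc), X]) @ tp.beta + om
        if cfg.redraw_residuals:
            eta = fixed[:, None] + sd_eps * rng.standard_normal((n_loc, 3)) + deltas
            p = expit(eta)
            return np.minimum.accumulate(p, axis=1)
        eta = (fixed + sd_eps * rng.standard_normal(n_loc))[:, None] + deltas
        return expit(eta)

    p_obs = _dose_probs(X_obs, omega[:m], m)
    p_grid = _dose_probs(X_grid, omega[m:], L)
    return SimTruth(
        coords_obs=coords_obs,
        coords_grid=coords_grid,
        X_obs=X_obs,
        X_grid=X_grid,
        p_obs=p_obs,
        p_grid=p_grid,
        omega_obs=omega[:m],
        omega_grid=omega[m:],
        range_used=r_used,
    )


def draw_sample_sizes(m: int, K: int, rng) -> np.ndarray:
    """iid discrete-uniform sample sizes on {2, ..., K}."""
    if K < 2:
        raise ValueError(f"size-family upper bound K must be >= 2, got {K}")
    rng = np.random.default_rng(rng)
    return rng.integers(2, K + 1, size=m).astype(float)


def make_counts(n, p1, p2, p3, round_counts: bool = False):
    """Deterministic success counts y_k = n * p_k (fractional unless rounded).

    Deterministic counts carry the truth exactly into the data while the
    binomial likelihood still weights them by n; rounding (optional) keeps
    monotonicity because rounding is order preserving.
    """
    n = np.asarray(n, float)
    p = np.column_stack([np.asarray(p1, float), np.asarray(p2, float), np.asarray(p3, float)])
    if np.any(np.diff(p, axis=1) > 1e-12):
        raise ValueError("make_counts requires monotone p1 >= p2 >= p3")
    y = n[:, None] * p
    if round_counts:
        y = np.round(y)
    return y[:, 0], y[:, 1], y[:, 2]


def generate_study(cfg: SimConfig) -> SimStudy:
    """Generate the full study: one truth, |size_families| x 3 datasets.

    All randomness is derived from ``cfg.seed`` through a spawned seed tree,
    so regeneration with the same config is byte-identical.
    """
    root = np.random.SeedSequence(cfg.seed)
    truth_seq, *family_seqs = root.spawn(1 + len(cfg.size_families))
    truth = simulate_truth(cfg, rng=np.random.default_rng(truth_seq))
    m = cfg.m_obs
    ids = np.array([f"c{i:05d}" for i in range(m)], dtype=object)
    cluster_datasets = {}
    datasets = {}
    seed_log = {"root": cfg.seed}
    for K, seq in zip(cfg.size_families, family_seqs):
        rng = np.random.default_rng(seq)
        n = draw_sample_sizes(m, K, rng)
        y1, y2, y3 = make_counts(n, truth.p_obs[:, 0], truth.p_obs[:, 1],
                                 truth.p_obs[:, 2], cfg.round_counts)
        cluster_datasets[K] = ClusterDataset(
            cluster_id=ids.copy(),
            coords=truth.coords_obs,
            n=n,
            y=np.column_stack([y1, y2, y3]),
            covariates=truth.X_obs,
            covariate_names=list(truth.covariate_names),
        )
        for j, dose in enumerate(DOSE_LABELS):
            datasets[(K, dose)] = IndicatorDataset(
                indicator=dose,
                cluster_id=ids.copy(),
                coords=truth.coords_obs,
                trials=n,
                successes=(y1, y2, y3)[j],
                covariates=truth.X_obs,
                covariate_names=list(truth.covariate_names),
                approach="truth",
            )
        seed_log[f"family_K{K}"] = seq.entropy
    return SimStudy(truth=truth, cluster_datasets=cluster_datasets,
                    datasets=datasets, config=cfg, seed_log=seed_log)


def make_fixture_geography(cfg: SimConfig, truth: SimTruth | None = None, seed: int | None = None):
    """Synthetic grid + nested admin rectangles + log-normal population.

    Returns ``(PredictionGrid, [AdminUnit...])`` where the units form two
    nested levels: a 2x2 partition of the window ("state") and a 4x4
    partition ("district").  Covariates come from ``truth`` when given (so
    the grid matches a simulated study) or are drawn fresh.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    coords = truth.coords_grid if truth is not None else _grid_coords(cfg)
    X = truth.X_grid if truth is not None else simulate_covariates(len(coords), rng)
    population = rng.lognormal(mean=5.0, sigma=1.0, size=len(coords))
    grid = PredictionGrid(
        cell_id=np.array([f"g{i:05d}" for i in range(len(coords))], dtype=object),
        coords=coords,
        covariates=X,
        population=population,
        covariate_names=list(COVARIATE_NAMES),
    )
    wx, wy = cfg.window
    units = []
    for level, nb in (("state", 2), ("district", 4)):
        for i in range(nb):
            for j in range(nb):
                units.append(
                    AdminUnit(
                        unit_id=f"{level[0].upper()}{i}{j}",
                        level=level,
                        geometry=box(i * wx / nb, j * wy / nb,
                                     (i + 1) * wx / nb, (j + 1) * wy / nb),
                    )
                )
    return grid, units


def write_admin_geojson(units: list[AdminUnit], path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"unit_id": u.unit_id, "level": u.level},
            "geometry": _geom_mapping(u.geometry),
        }
        for u in units
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def write_study(study: SimStudy, out_dir) -> None:
    """Write a study as a directory of truth tables, cluster tables and logs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = study.truth
    import pandas as pd

    for tag, coords, X, p in (
        ("obs", t.coords_obs, t.X_obs, t.p_obs),
        ("grid", t.coords_grid, t.X_grid, t.p_grid),
    ):
        df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1]})
        for j, name in enumerate(t.covariate_names):
            df[name] = X[:, j]
        for j, dose in enumerate(DOSE_LABELS):
            df[dose] = p[:, j]
        df.to_csv(out / f"truth_{tag}.csv", index=False, float_format="%.10g")
    for K, ds in study.cluster_datasets.items():
        write_cluster_table(ds, out / f"clusters_K{K}.csv")
    cfg = study.config
    echo = {
        "seed": cfg.seed, "m_obs": cfg.m_obs, "window": cfg.window,
        "grid_shape": cfg.grid_shape, "increments": cfg.increments,
        "size_families": cfg.size_families, "spatial": cfg.spatial,
        "beta": list(map(float, cfg.true_params.beta)),
        "sigma2": cfg.true_params.sigma2, "range": cfg.true_params.range,
        "sigma2_eps": cfg.true_params.sigma2_eps,
        "range_used": t.range_used,
    }
    (out / "config_echo.json").write_text(json.dumps(echo, indent=1, default=str))
    (out / "seed_log.json").write_text(json.dumps(study.seed_log, indent=1, default=str))
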