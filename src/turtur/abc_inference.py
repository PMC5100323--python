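"""Approximate Bayesian computation: reference table, model choice, estimation.

The reference table holds one row per simulation: the scenario id, the
parameter draw, and the four SNP summary statistics. Model choice uses
plain rejection ("direct": the posterior probability of a scenario is its
frequency among the accepted closest simulations) and weighted multinomial
logistic regression of scenario membership on the summary statistics,
evaluated at the observed point. Parameter estimation uses local-linear
regression adjustment (Beaumont-style) on log-transformed parameters with
Epanechnikov kernel weights.

Distances are Euclidean after standardising each statistic by its
reference-table standard deviation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .coalescent_sim import (
    DEFAULT_LOCUS_MUTATION_RATE,
    simulate_locus_counts_batch,
)
from .demographic_models import (
    SCENARIO_IDS,
    SCENARIO_TOPOLOGIES,
    PriorSpec,
    sample_parameters_batch,
)
from .sumstats import STAT_NAMES, SnpSummaryStats, snp_stats_from_counts_batch

__all__ = [
    "ReferenceTable",
    "ModelChoiceResult",
    "PosteriorSummary",
    "GoodnessOfFit",
    "build_reference_table",
    "standardize_and_distance",
    "model_choice_direct",
    "model_choice_logistic",
    "estimate_parameters",
    "pca_goodness_of_fit",
    "PARAM_COLUMNS",
]

logger = logging.getLogger(__name__)

PARAM_COLUMNS = ("N1", "N2", "N3", "N4", "t1", "t2", "t3")


@dataclass
class ReferenceTable:
    """Simulation reference table plus provenance metadata."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"scenario", *STAT_NAMES}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        if self.data[list(STAT_NAMES)].isna().any().any():
            raise ValueError("reference table contains missing statistic entries")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def stats_matrix(self) -> np.ndarray:
        return self.data[list(STAT_NAMES)].to_numpy(dtype=float)

    def scenario_ids(self) -> np.ndarray:
        return self.data["scenario"].to_numpy(dtype=int)

    def append(self, other: "ReferenceTable") -> "ReferenceTable":
        return ReferenceTable(
            data=pd.concat([self.data, other.data], ignore_index=True),
            meta={**self.meta, "appended": True},
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.meta.items():
                fh.write(f"# {key}: {value}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        meta: dict = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, value = line[1:].strip().partition(":")
                meta[key.strip()] = value.strip()
        data = pd.read_csv(path, skiprows=skip)
        return cls(data=data, meta=meta)


def _padded_epoch_arrays(
    scenario_id: int,
    draws: dict[str, np.ndarray],
    generation_time: float,
    n_epochs: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(B, n_epochs) epoch start/size arrays, right-padded with the last epoch."""
    topology = SCENARIO_TOPOLOGIES[scenario_id]
    B = len(next(iter(draws.values())))
    starts = np.zeros((B, n_epochs))
    sizes = np.zeros((B, n_epochs))
    for j, (size_name, time_name) in enumerate(topology):
        starts[:, j] = 0.0 if time_name is None else draws[time_name] / generation_time
        sizes[:, j] = draws[size_name]
    for j in range(len(topology), n_epochs):
        starts[:, j] = starts[:, len(topology) - 1]
        sizes[:, j] = sizes[:, len(topology) - 1]
    return starts, sizes


def build_reference_table(
    priors: PriorSpec,
    n_sims_per_scenario: int,
    n_individuals: int,
    n_loci: int,
    rng: np.random.Generator,
    scenario_ids: tuple[int, ...] = SCENARIO_IDS,
    locus_mutation_rate: float = DEFAULT_LOCUS_MUTATION_RATE,
    missing_rate: float = 0.1,
    generation_time: float = 1.0,
    batch_size: int = 64,
    max_failure_fraction: float = 0.05,
) -> ReferenceTable:
    """Simulate the ABC reference table with equal allocation per scenario.

    Degenerate simulations (fewer than two polymorphic loci, so a summary
    statistic is undefined) are dropped and counted; if they exceed
    ``max_failure_fraction`` of a scenario's allocation the build aborts.
    """
    if n_sims_per_scenario < 1:
        raise ValueError("n_sims_per_scenario must be >= 1")
    m = 2 * n_individuals
    n_epochs = max(len(SCENARIO_TOPOLOGIES[s]) for s in scenario_ids)
    frames = []
    dropped: dict[int, int] = {}
    for sid in scenario_ids:
        draws = sample_parameters_batch(priors, sid, n_sims_per_scenario, rng, generation_time)
        starts, sizes = _padded_epoch_arrays(sid, draws, generation_time, n_epochs)
        stats = np.empty((n_sims_per_scenario, len(STAT_NAMES)))
        bad = np.zeros(n_sims_per_scenario, dtype=bool)
        for lo in range(0, n_sims_per_scenario, batch_size):
            hi = min(lo + batch_size, n_sims_per_scenario)
            counts = simulate_locus_counts_batch(
                m,
                n_loci,
                rng,
                epoch_starts=starts[lo:hi],
                epoch_sizes=sizes[lo:hi],
                locus_mutation_rate=locus_mutation_rate,
            )
            if missing_rate > 0:
                n_missing = rng.binomial(n_individuals, missing_rate, size=counts.shape)
            else:
                n_missing = np.zeros_like(counts)
            copies = 2 * (n_individuals - n_missing)
            derived = rng.hypergeometric(counts, m - counts, np.maximum(copies, 1))
            derived = np.where(copies > 0, derived, 0)
            stats[lo:hi], bad[lo:hi] = snp_stats_from_counts_batch(derived, copies)
        n_bad = int(bad.sum())
        if n_bad > max(2, max_failure_fraction * n_sims_per_scenario):
            raise RuntimeError(
                f"scenario {sid}: {n_bad}/{n_sims_per_scenario} degenerate simulations "
                "(check the mutation rate / priors)"
            )
        if n_bad:
            dropped[sid] = n_bad
            logger.info("scenario %d: dropped %d degenerate simulations", sid, n_bad)
        frame = pd.DataFrame({name: draws.get(name, np.nan) for name in PARAM_COLUMNS})
        frame.insert(0, "scenario", sid)
        frame[list(STAT_NAMES)] = stats
        frames.append(frame.loc[~bad])
    data = pd.concat(frames, ignore_index=True)
    meta = {
        "n_sims_per_scenario": n_sims_per_scenario,
        "n_individuals": n_individuals,
        "n_loci": n_loci,
        "locus_mutation_rate": locus_mutation_rate,
        "missing_rate": missing_rate,
        "generation_time": generation_time,
        "dropped": dropped,
        "columns": "scenario," + ",".join(PARAM_COLUMNS) + "," + ",".join(STAT_NAMES),
    }
    return ReferenceTable(data=data, meta=meta)


def _observed_vector(observed) -> np.ndarray:
    if isinstance(observed, SnpSummaryStats):
        return observed.as_array()
    return np.asarray(observed, dtype=float)


def standardize_and_distance(
    table: ReferenceTable, observed
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row Euclidean distances after SD-standardisation.

    Returns ``(distances, sds, used)`` where ``used`` flags statistics with
    non-zero reference-table standard deviation (zero-variance statistics
    are excluded from the distance with a warning).
    """
    obs = _observed_vector(observed)
    if not np.all(np.isfinite(obs)):
        raise ValueError("observed statistics must be finite")
    stats = table.stats_matrix()
    sds = stats.std(axis=0, ddof=0)
    used = sds > 0
    if not used.all():
        names = [STAT_NAMES[i] for i in np.flatnonzero(~used)]
        warnings.warn(f"zero-variance statistics excluded from distance: {names}", stacklevel=2)
    z = (stats[:, used] - obs[used]) / sds[used]
    return np.sqrt((z**2).sum(axis=1)), sds, used


@dataclass
class ModelChoiceResult:
    """Posterior scenario probabilities with 95 % CIs."""

    probabilities: dict[int, float]
    ci95: dict[int, tuple[float, float]]
    method: str
    tolerance: float
    n_accepted: int
    degenerate: bool = False

    def best_scenario(self) -> int:
        return max(self.probabilities, key=self.probabilities.get)


def _accepted_indices(distances: np.ndarray, tolerance: float) -> np.ndarray:
    n_accept = math.ceil(tolerance * len(distances))
    if n_accept < 1:
        raise ValueError("tolerance too small: no simulation accepted")
    order = np.argsort(distances, kind="stable")
    return order[:n_accept]


def model_choice_direct(
    table: ReferenceTable,
    observed,
    tolerance: float = 0.001,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> ModelChoiceResult:
    """Rejection-based model choice: scenario frequencies among the accepted.

    The 95 % CI per scenario is a nonparametric bootstrap over accepted rows.
    """
    rng = np.random.default_rng() if rng is None else rng
    distances, _, _ = standardize_and_distance(table, observed)
    acc = _accepted_indices(distances, tolerance)
    scen = table.scenario_ids()
    all_ids = np.unique(scen)
    acc_scen = scen[acc]
    probs = {int(s): float(np.mean(acc_scen == s)) for s in all_ids}
    boot = rng.choice(acc_scen, size=(n_bootstrap, len(acc_scen)), replace=True)
    ci = {}
    for s in all_ids:
        freqs = (boot == s).mean(axis=1)
        ci[int(s)] = (float(np.quantile(freqs, 0.025)), float(np.quantile(freqs, 0.975)))
    return ModelChoiceResult(
        probabilities=probs,
        ci95=ci,
        method="direct",
        tolerance=tolerance,
        n_accepted=len(acc),
        degenerate=len(np.unique(acc_scen)) < 2,
    )


def _epanechnikov(distances: np.ndarray) -> np.ndarray:
    d_max = distances.max()
    if d_max == 0:
        return np.ones_like(distances)
    return 1.0 - (distances / d_max) ** 2


def _logistic_ci(
    Z: np.ndarray,
    weights: np.ndarray,
    proba: np.ndarray,
    p_at_obs: np.ndarray,
) -> np.ndarray | None:
    """Delta-method 95 % half-widths for softmax probabilities at the origin.

    Uses the reference-class parameterisation; parameters are the per-class
    (intercept, slopes) blocks for the first C-1 classes. Returns None when
    the weighted information matrix is singular.
    """
    n, d = Z.shape
    C = proba.shape[1]
    X = np.column_stack([np.ones(n), Z])
    dd = d + 1
    k = (C - 1) * dd
    H = np.zeros((k, k))
    for a in range(C - 1):
        for b in range(C - 1):
            wab = weights * (proba[:, a] * ((a == b) - proba[:, b]))
            H[a * dd : (a + 1) * dd, b * dd : (b + 1) * dd] = (X * wab[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    x0 = np.zeros(dd)
    x0[0] = 1.0
    half = np.empty(C)
    for s in range(C):
        grad = np.zeros(k)
        for c in range(C - 1):
            dpde = p_at_obs[s] * ((s == c) - p_at_obs[c])
            grad[c * dd : (c + 1) * dd] = dpde * x0
        var = float(grad @ cov @ grad)
        half[s] = 1.96 * math.sqrt(max(var, 0.0))
    return half


def model_choice_logistic(
    table: ReferenceTable,
    observed,
    tolerance: float = 0.01,
    rng: np.random.Generator | None = None,
) -> ModelChoiceResult:
    """Weighted multinomial logistic-regression model choice.

    Regresses scenario membership on the standardised statistics over the
    accepted fraction with Epanechnikov weights in distance, then evaluates
    the class probabilities at the observed point. Falls back to the direct
    estimate (with a logged warning) on separation or non-convergence.
    """
    distances, sds, used = standardize_and_distance(table, observed)
    acc = _accepted_indices(distances, tolerance)
    scen = table.scenario_ids()
    acc_scen = scen[acc]
    classes = np.unique(acc_scen)
    if len(classes) < 2:
        only = int(classes[0])
        probs = {int(s): (1.0 if s == only else 0.0) for s in np.unique(scen)}
        ci = {s: (p, p) for s, p in probs.items()}
        return ModelChoiceResult(probs, ci, "logistic", tolerance, len(acc), degenerate=True)

    obs = _observed_vector(observed)
    stats = table.stats_matrix()
    Z = (stats[acc][:, used] - obs[used]) / sds[used]
    w = _epanechnikov(distances[acc])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            clf = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-8)
            clf.fit(Z, acc_scen, sample_weight=w)
        p_at_obs = clf.predict_proba(np.zeros((1, Z.shape[1])))[0]
        proba_train = clf.predict_proba(Z)
        half = _logistic_ci(Z, w, proba_train, p_at_obs)
        if half is None:
            raise np.linalg.LinAlgError("singular information matrix")
    except (ConvergenceWarning, np.linalg.LinAlgError, ValueError) as err:
        logger.warning("logistic model choice failed (%s); falling back to direct", err)
        fallback = model_choice_direct(table, observed, tolerance=tolerance, rng=rng)
        fallback.method = "direct-fallback"
        return fallback

    all_ids = np.unique(scen)
    probs = {int(s): 0.0 for s in all_ids}
    ci = {int(s): (0.0, 0.0) for s in all_ids}
    for j, s in enumerate(clf.classes_):
        probs[int(s)] = float(p_at_obs[j])
        lo = max(0.0, p_at_obs[j] - half[j])
        hi = min(1.0, p_at_obs[j] + half[j])
        ci[int(s)] = (float(lo), float(hi))
    return ModelChoiceResult(probs, ci, "logistic", tolerance, len(acc))


@dataclass
class PosteriorSummary:
    """Posterior mean/median and 95 % equal-tailed interval per parameter."""

    scenario_id: int
    summaries: dict[str, dict[str, float]]  # param -> {mean, median, q025, q975}
    n_accepted: int
    adjusted: bool

    def interval(self, name: str) -> tuple[float, float]:
        s = self.summaries[name]
        return s["q025"], s["q975"]


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cdf = np.cumsum(w) / w.sum()
    return float(np.interp(q, cdf, v))


def estimate_parameters(
    table: ReferenceTable,
    observed,
    scenario_id: int,
    tolerance: float = 0.01,
    adjust: bool = True,
) -> PosteriorSummary:
    """Local-linear regression-adjusted posterior for one scenario.

    Parameters are log-transformed, regressed on the standardised statistic
    offsets with Epanechnikov weights, and the fitted trend is subtracted so
    every accepted draw is translated to the observed point. Summaries are
    computed on the back-transformed weighted sample. Parameters with zero
    variance among accepted draws (fixed priors) are reported as point
    masses and excluded from the regression.
    """
    sub_mask = table.scenario_ids() == scenario_id
    if not sub_mask.any():
        raise ValueError(f"no rows for scenario {scenario_id}")
    sub = ReferenceTable(data=table.data.loc[sub_mask].reset_index(drop=True), meta=table.meta)
    distances, sds, used = standardize_and_distance(sub, observed)
    acc = _accepted_indices(distances, tolerance)
    obs = _observed_vector(observed)
    Z = (sub.stats_matrix()[acc][:, used] - obs[used]) / sds[used]
    w = _epanechnikov(distances[acc])

    param_names = [
        c for c in PARAM_COLUMNS if c in sub.data.columns and sub.data[c].notna().all()
    ]
    summaries: dict[str, dict[str, float]] = {}
    adjusted_flag = False
    for name in param_names:
        values = sub.data[name].to_numpy(dtype=float)[acc]
        if np.ptp(values) == 0:
            v = float(values[0])
            summaries[name] = {"mean": v, "median": v, "q025": v, "q975": v}
            continue
        theta = np.log(values)
        theta_star = theta
        if adjust:
            X = np.column_stack([np.ones(len(acc)), Z])
            sw = np.sqrt(w)
            coef, _, rank, _ = np.linalg.lstsq(X * sw[:, None], theta * sw, rcond=None)
            if rank < X.shape[1]:
                warnings.warn(
                    f"rank-deficient regression for {name}; using unadjusted rejection posterior",
                    stacklevel=2,
                )
            else:
                theta_star = theta - Z @ coef[1:]
                adjusted_flag = True
        back = np.exp(theta_star)
        summaries[name] = {
            "mean": float(np.average(back, weights=w)),
            "median": _weighted_quantile(back, w, 0.5),
            "q025": _weighted_quantile(back, w, 0.025),
            "q975": _weighted_quantile(back, w, 0.975),
        }
    return PosteriorSummary(
        scenario_id=scenario_id,
        summaries=summaries,
        n_accepted=len(acc),
        adjusted=adjusted_flag,
    )


@dataclass
class GoodnessOfFit:
    """PCA goodness-of-fit: observed-point percentile per scenario cloud."""

    percentiles: dict[int, float]
    observed_coords: np.ndarray
    explained_variance_ratio: np.ndarray
    poor_fit: bool
    scatter: pd.DataFrame | None = None


def pca_goodness_of_fit(
    table: ReferenceTable,
    observed,
    n_components: int = 2,
    subsample: int = 20000,
    rng: np.random.Generator | None = None,
    keep_scatter: bool = False,
) -> GoodnessOfFit:
    """Project the observed statistics into the PCA of the simulated ones.

    For each scenario, reports the percentile of the observed point's
    distance to the scenario centroid within that scenario's own
    distance-to-centroid distribution. All percentiles above 99 raise the
    ``poor_fit`` flag.
    """
    if table.n_rows < 10:
        raise ValueError("need at least 10 reference rows")
    stats = table.stats_matrix()
    if n_components > stats.shape[1]:
        raise ValueError("more components requested than statistics available")
    rng = np.random.default_rng() if rng is None else rng
    mean = stats.mean(axis=0)
    sds = stats.std(axis=0, ddof=0)
    used = sds > 0
    z = (stats[:, used] - mean[used]) / sds[used]
    obs = (_observed_vector(observed)[used] - mean[used]) / sds[used]

    fit_idx = (
        rng.choice(len(z), size=subsample, replace=False) if len(z) > subsample else slice(None)
    )
    pca = PCA(n_components=min(n_components, z.shape[1]))
    pca.fit(z[fit_idx])
    coords = pca.transform(z)
    obs_coords = pca.transform(obs[None, :])[0]

    scen = table.scenario_ids()
    percentiles = {}
    for s in np.unique(scen):
        cloud = coords[scen == s]
        centroid = cloud.mean(axis=0)
        d_cloud = np.linalg.norm(cloud - centroid, axis=1)
        d_obs = np.linalg.norm(obs_coords - centroid)
        percentiles[int(s)] = float(100.0 * np.mean(d_cloud <= d_obs))
    poor = all(p > 99.0 for p in percentiles.values())
    scatter = None
    if keep_scatter:
        scatter = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(coords.shape[1])])
        scatter.insert(0, "scenario", scen)
    return GoodnessOfFit(
        percentiles=percentiles,
        observed_coords=obs_coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
        poor_fit=poor,
        scatter=scatter,
    )
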