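"""Parameter estimation and goodness-of-fit validation.

The fitting pipeline mirrors standard practice for unstructured kinetic
models: a weighted nonlinear least-squares fit provides a deterministic
point estimate and sampler initialisation, after which a
Metropolis-within-Gibbs random-walk sampler (component-wise updates in
log-parameter space, log-uniform box priors) draws from the posterior.
The point estimate reported from a sampler run is the component-wise
posterior median.  Model adequacy is judged per state variable with a
variance-weighted Pearson chi-squared statistic against the chi-squared
critical value at the 95% level.

All fitting happens in log-parameter space, which both enforces
positivity and copes with rate constants spanning five orders of
magnitude.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .exceptions import ConfigurationError, DomainError, ObservationParseError, SolverError
from .model import (
    RATE_PARAMETER_NAMES,
    STATE_NAMES,
    ParameterSet,
    StoichiometryConstants,
)
from .solver import SolverConfig, StateTrajectory, simulate

__all__ = [
    "ObservationSet",
    "PriorBox",
    "Chi2Result",
    "FitResult",
    "log_likelihood",
    "least_squares_fit",
    "gibbs_fit",
    "chi_squared_gof",
    "KineticsLeastSquares",
    "KineticsGibbs",
]

logger = logging.getLogger(__name__)

#: default free parameters: every kinetic constant and correction factor.
#: Saturation maxima and stoichiometry are fixed (identifiability).
DEFAULT_FREE = RATE_PARAMETER_NAMES

#: fast-but-accurate solver settings used inside fitting loops; the
#: solver error (~1e-7 relative) is far below any measurement noise.
FIT_SOLVER = SolverConfig(method="runge_kutta", abs_tol=1e-7, rel_tol=1e-7)


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

OBSERVATION_COLUMNS = ("time_hr", "state", "replicate", "value", "sd", "batch")


@dataclass
class ObservationSet:
    """Replicate measurements of the six states at the sampling times.

    ``values`` has shape ``(6, n_times, n_replicates)`` (NaN for missing
    replicates); ``sds`` ``(6, n_times)`` holds the per-point measurement
    standard deviation of a *single* replicate.
    """

    times: np.ndarray
    values: np.ndarray
    sds: np.ndarray
    batch_label: str = "control"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        self.sds = np.asarray(self.sds, float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ConfigurationError("need at least two sampling times")
        if np.any(self.times < 0) or not np.all(np.diff(self.times) > 0):
            raise ConfigurationError("times must be nonnegative and strictly increasing")
        if self.values.ndim != 3 or self.values.shape[:2] != (6, len(self.times)):
            raise ConfigurationError(
                f"values must have shape (6, {len(self.times)}, n_rep), got {self.values.shape}"
            )
        if self.sds.shape != (6, len(self.times)):
            raise ConfigurationError(f"sds must have shape (6, {len(self.times)})")
        if np.any(self.sds < 0):
            raise ConfigurationError("standard deviations must be >= 0")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def replicate_counts(self) -> np.ndarray:
        """Number of non-missing replicates per (state, time)."""
        return np.sum(~np.isnan(self.values), axis=2)

    def means(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=2)

    def sample_sds(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanstd(self.values, axis=2, ddof=1)

    def state_ranges(self) -> np.ndarray:
        m = self.means()
        return m.max(axis=1) - m.min(axis=1)

    def initial_state(self) -> np.ndarray:
        """Replicate-mean state at the first sampling time, floored at zero.

        Measurement noise can push the mean of a zero-valued state (e.g.
        lactate at inoculation) slightly negative; concentrations cannot
        be negative, so the state estimate is clipped.
        """
        return np.clip(self.means()[:, 0], 0.0, None)

    def effective_sds(self, floor_frac: float = 0.05) -> np.ndarray:
        """Per-point SDs with a fallback for missing/zero entries.

        Zero (or NaN) reported SDs are replaced by ``floor_frac`` times the
        state's observed range, preventing infinite weights; positive
        reported SDs are used as given.
        """
        fallback = floor_frac * np.maximum(self.state_ranges(), 1e-300)
        sds = np.where(np.isfinite(self.sds) & (self.sds > 0), self.sds,
                       fallback[:, None])
        return sds

    # -- serialisation ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sn in enumerate(STATE_NAMES):
            for j, t in enumerate(self.times):
                for r in range(self.n_replicates):
                    v = self.values[i, j, r]
                    if np.isnan(v):
                        continue
                    rows.append((t, sn, r + 1, v, self.sds[i, j], self.batch_label))
        return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservationSet":
        missing = set(OBSERVATION_COLUMNS) - set(df.columns)
        if missing:
            raise ObservationParseError(f"missing observation columns: {sorted(missing)}")
        for line, (_, row) in enumerate(df.iterrows(), start=2):
            if row["time_hr"] < 0:
                raise ObservationParseError(f"line {line}: negative time {row['time_hr']!r}")
            if row["state"] not in STATE_NAMES:
                raise ObservationParseError(f"line {line}: unknown state {row['state']!r}")
        times = np.sort(df["time_hr"].unique())
        n_rep = int(df["replicate"].max())
        values = np.full((6, len(times), n_rep), np.nan)
        sds = np.zeros((6, len(times)))
        t_index = {t: j for j, t in enumerate(times)}
        s_index = {s: i for i, s in enumerate(STATE_NAMES)}
        for _, row in df.iterrows():
            i, j = s_index[row["state"]], t_index[row["time_hr"]]
            values[i, j, int(row["replicate"]) - 1] = row["value"]
            sds[i, j] = row["sd"]
        batch = df["batch"].iloc[0] if len(df) else "unknown"
        return cls(times, values, sds, batch_label=str(batch))


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorBox:
    """Independent log-uniform priors: a positive box per free parameter."""

    lower: dict
    upper: dict

    def __post_init__(self) -> None:
        for name in self.lower:
            lo, hi = self.lower[name], self.upper[name]
            if not (0 < lo < hi):
                raise ConfigurationError(f"prior for {name} needs 0 < lower < upper, got ({lo}, {hi})")

    @classmethod
    def around(cls, p: ParameterSet, free=DEFAULT_FREE, decades: float = 2.0) -> "PriorBox":
        """Box spanning ``decades`` orders of magnitude either side of ``p``."""
        f = 10.0 ** decades
        lower = {n: getattr(p, n) / f for n in free}
        upper = {n: getattr(p, n) * f for n in free}
        return cls(lower, upper)

    def bounds_log(self, free) -> tuple[np.ndarray, np.ndarray]:
        return (np.log([self.lower[n] for n in free]),
                np.log([self.upper[n] for n in free]))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _predict(p, s, y0, times, solver_cfg):
    cfg = solver_cfg or FIT_SOLVER
    cfg = SolverConfig(**{**cfg.__dict__, "t_grid": tuple(times), "t_end": max(times[-1], 1e-9)})
    return simulate(p, s, y0, cfg).states.T          # (6, n_times)


def log_likelihood(
    obs: ObservationSet,
    p: ParameterSet,
    s: StoichiometryConstants | None = None,
    solver_cfg: SolverConfig | None = None,
    y0=None,
    sd_floor_frac: float = 0.05,
) -> float:
    """Gaussian log-likelihood of the observations under parameters ``p``.

    Sums ``-0.5*((obs - pred)/sigma)**2 - log(sigma)`` over every replicate
    observation; a solver failure scores ``-inf`` (the draw is rejected).
    """
    if y0 is None:
        y0 = obs.initial_state()
    try:
        pred = _predict(p, s, y0, obs.times, solver_cfg)
    except SolverError as err:
        logger.warning("solver failure in likelihood evaluation: %s", err)
        return -np.inf
    sig = obs.effective_sds(sd_floor_frac)
    resid = (obs.values - pred[:, :, None]) / sig[:, :, None]
    mask = ~np.isnan(resid)
    if not np.all(np.isfinite(resid[mask])):
        return -np.inf
    n_per_point = np.sum(mask, axis=2)
    return float(-0.5 * np.sum(resid[mask] ** 2) - np.sum(n_per_point * np.log(sig)))


def _weighted_residuals(x, free, template, s, y0, times, means, sig_mean, solver_cfg):
    p = template.replace(**dict(zip(free, np.exp(x))))
    try:
        pred = _predict(p, s, y0, times, solver_cfg)
    except (SolverError, DomainError):
        return np.full(means.size, 1e8)
    r = (means - pred) / sig_mean
    r = np.where(np.isfinite(r), r, 1e8)
    return r.ravel()


def least_squares_fit(
    obs: ObservationSet,
    p0: ParameterSet,
    bounds: PriorBox | None = None,
    free=DEFAULT_FREE,
    s: StoichiometryConstants | None = None,
    solver_cfg: SolverConfig | None = None,
    y0=None,
    sd_floor_frac: float = 0.05,
    return_details: bool = False,
):
    """Weighted least squares on replicate means, in log-parameter space.

    Residuals are ``(mean - prediction)/(sd/sqrt(n_rep))``.  Used both as
    a deterministic recovery cross-check and as the sampler initialiser.
    """
    if bounds is None:
        bounds = PriorBox.around(p0, free)
    if y0 is None:
        y0 = obs.initial_state()
    means = obs.means()
    counts = np.maximum(obs.replicate_counts(), 1)
    sig_mean = obs.effective_sds(sd_floor_frac) / np.sqrt(counts)
    x0 = np.log(p0.values(free))
    lo, hi = bounds.bounds_log(free)
    x0 = np.clip(x0, lo, hi)
    res = optimize.least_squares(
        _weighted_residuals, x0,
        args=(free, p0, s, y0, obs.times, means, sig_mean, solver_cfg),
        bounds=(lo, hi), method="trf", x_scale="jac",
        ftol=1e-15, xtol=1e-15, gtol=1e-15,
    )
    if res.status <= 0:
        raise SolverError(
            f"least squares did not converge (status {res.status}): {res.message}; "
            f"last iterate {dict(zip(free, np.exp(res.x)))}"
        )
    fitted = p0.replace(**dict(zip(free, np.exp(res.x))))
    logger.info("least_squares_fit: cost=%.4g nfev=%d", res.cost, res.nfev)
    if return_details:
        return fitted, res
    return fitted


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chi2Result:
    """Pearson chi-squared verdict for one state variable."""

    state: str
    statistic: float
    dof: int
    critical: float
    passed: bool


def chi_squared_gof(
    obs: ObservationSet,
    traj: StateTrajectory,
    alpha: float = 0.05,
    n_params_per_state: dict | None = None,
) -> dict[str, Chi2Result]:
    """Variance-weighted chi-squared goodness of fit, per state variable.

    ``statistic = sum_t ((mean_obs - pred) / (sd/sqrt(n_rep)))**2`` with
    ``dof = n_times - n_params`` for that state.  ``n_params_per_state``
    allocates fitted degrees of freedom to states; by default no
    correction is applied (appropriate when the trajectory was not fitted
    to these observations, e.g. a true-parameter or external prediction).
    """
    pred = traj.interpolate(obs.times).T if not np.array_equal(traj.times, obs.times) \
        else traj.states.T
    means = obs.means()
    counts = np.maximum(obs.replicate_counts(), 1)
    sig_mean = obs.effective_sds() / np.sqrt(counts)
    n_params_per_state = n_params_per_state or {}
    out = {}
    for i, name in enumerate(STATE_NAMES):
        dof = len(obs.times) - int(n_params_per_state.get(name, 0))
        if dof <= 0:
            raise ConfigurationError(
                f"dof <= 0 for state {name}; pool states or reduce the "
                "per-state parameter allocation"
            )
        stat = float(np.sum(((means[i] - pred[i]) / sig_mean[i]) ** 2))
        crit = float(stats.chi2.ppf(1.0 - alpha, dof))
        out[name] = Chi2Result(name, stat, dof, crit, stat <= crit)
    return out


# ---------------------------------------------------------------------------
# Metropolis-within-Gibbs sampling
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Posterior draws, point estimate and validation summary of one fit."""

    samples: pd.DataFrame            # one row per recorded draw, natural scale
    point_estimate: ParameterSet     # posterior medians (free) + fixed values
    chi2: dict                       # state -> Chi2Result
    n_draws: int                     # total Monte-Carlo trials performed
    seed: int | None
    acceptance_rates: dict = field(default_factory=dict)
    rhat: dict = field(default_factory=dict)
    prior: PriorBox | None = None

    @property
    def accepted_run(self) -> bool:
        """Whether the run meets the >= 10,000-trial sampling standard."""
        return self.n_draws >= 10_000

    @property
    def all_states_pass(self) -> bool:
        return all(c.passed for c in self.chi2.values())

    def summary(self) -> pd.DataFrame:
        q = self.samples.quantile([0.025, 0.5, 0.975]).T
        q.columns = ["q2.5", "median", "q97.5"]
        return q

    def to_json(self, path: str | Path) -> None:
        import json

        doc = {
            "point_estimate": self.point_estimate.to_dict(),
            "intervals": {k: list(v) for k, v in
                          self.summary()[["q2.5", "q97.5"]].iterrows()},
            "chi_squared": {
                k: {"statistic": c.statistic, "dof": c.dof,
                    "critical": c.critical, "passed": bool(c.passed)}
                for k, c in self.chi2.items()
            },
            "n_draws": self.n_draws,
            "seed": self.seed,
            "acceptance_rates": self.acceptance_rates,
            "rhat": self.rhat,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    def samples_to_csv(self, path: str | Path) -> None:
        self.samples.to_csv(path, index=False, float_format="%.12g")


def _split_rhat(chain: np.ndarray) -> float:
    """Split-chain potential scale reduction via arviz."""
    import arviz as az

    n = len(chain) - len(chain) % 4
    if n < 8:
        return float("nan")
    split = chain[:n].reshape(4, n // 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.rhat(az.convert_to_dataset(split))["x"].values).item())


def gibbs_fit(
    obs: ObservationSet,
    priors: PriorBox | None = None,
    n_draws: int = 10_000,
    seed: int | None = None,
    p0: ParameterSet | None = None,
    free=DEFAULT_FREE,
    s: StoichiometryConstants | None = None,
    solver_cfg: SolverConfig | None = None,
    y0=None,
    burn_in_frac: float = 0.2,
    sd_floor_frac: float = 0.05,
    init_from_least_squares: bool = True,
    alpha: float = 0.05,
) -> FitResult:
    """Component-wise Metropolis-within-Gibbs posterior sampling.

    One *draw* is one component update (a Monte-Carlo trial); accepted
    runs perform at least 10,000 of them.  Proposal scales are adapted
    towards a 44% acceptance rate during the burn-in (the first
    ``burn_in_frac`` of trials) and frozen afterwards so the post-burn-in
    chain is Markovian.  The parameter vector is recorded once per sweep
    after burn-in; the point estimate is the component-wise posterior
    median.
    """
    if p0 is None:
        raise ConfigurationError("gibbs_fit needs an initial ParameterSet p0")
    if priors is None:
        priors = PriorBox.around(p0, free)
    if y0 is None:
        y0 = obs.initial_state()
    if init_from_least_squares:
        p0 = least_squares_fit(obs, p0, priors, free, s, solver_cfg, y0, sd_floor_frac)
    rng = np.random.default_rng(seed)
    lo, hi = priors.bounds_log(free)
    x = np.clip(np.log(p0.values(free)), lo, hi)
    d = len(free)

    def ll_of(xv):
        p = p0.replace(**dict(zip(free, np.exp(xv))))
        return log_likelihood(obs, p, s, solver_cfg, y0, sd_floor_frac)

    ll = ll_of(x)
    if not np.isfinite(ll):
        raise SolverError("initial point has non-finite likelihood; check p0/priors")
    scales = np.full(d, 0.05)
    burn = int(burn_in_frac * n_draws)
    accepted = np.zeros(d)
    tried = np.zeros(d)
    rows = []
    trial = 0
    n_accepted_total = 0
    while trial < n_draws:
        for i in range(d):
            trial += 1
            xp = x.copy()
            xp[i] += scales[i] * rng.standard_normal()
            tried[i] += 1
            if lo[i] <= xp[i] <= hi[i]:
                llp = ll_of(xp)
                if np.log(rng.uniform()) < llp - ll:
                    x, ll = xp, llp
                    accepted[i] += 1
                    n_accepted_total += 1
            if trial <= burn:
                scales[i] *= np.exp(0.15 * (accepted[i] / tried[i] - 0.44))
        if trial > burn:
            rows.append(np.exp(x))
    if n_accepted_total == 0:
        raise SolverError("Metropolis-within-Gibbs chain rejected every proposal")
    rates = accepted / np.maximum(tried, 1)
    for name, r in zip(free, rates):
        if not 0.05 <= r <= 0.7:
            warnings.warn(
                f"acceptance rate for {name} is {r:.2f}, outside [0.05, 0.70]",
                stacklevel=2,
            )
    samples = pd.DataFrame(rows, columns=list(free))
    medians = samples.median()
    point = p0.replace(**medians.to_dict())
    rhat = {n: _split_rhat(np.log(samples[n].to_numpy())) for n in free}
    bad = {n: v for n, v in rhat.items() if np.isfinite(v) and v > 1.1}
    if bad:
        warnings.warn(f"split-chain R-hat above 1.1 for: {bad}", stacklevel=2)
    cfg = solver_cfg or FIT_SOLVER
    traj = simulate(point, s, y0,
                    SolverConfig(**{**cfg.__dict__, "t_grid": tuple(obs.times),
                                    "t_end": float(obs.times[-1])}))
    chi2 = chi_squared_gof(obs, traj, alpha=alpha)
    logger.info("gibbs_fit: %d trials, %d recorded sweeps, seed=%s",
                trial, len(rows), seed)
    return FitResult(samples, point, chi2, trial, seed,
                     acceptance_rates=dict(zip(free, rates)), rhat=rhat, prior=priors)


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------

class KineticsLeastSquares(BaseEstimator):
    """Deterministic weighted least-squares fit of the kinetic model.

    Parameters
    ----------
    p0 : ParameterSet
        Starting point (and template for fixed parameters).
    free : sequence of str
        Names of the parameters to fit; the rest stay at their ``p0`` values.
    prior_decades : float
        Half-width of the box bounds, in orders of magnitude around ``p0``.
    y0 : array-like or None
        Initial state; defaults to the replicate-mean observations at t=0.

    Attributes
    ----------
    params_ : ParameterSet
        Fitted parameters.
    optimizer_result_ : scipy.optimize.OptimizeResult
    chi2_ : dict of Chi2Result
    """

    def __init__(self, p0=None, free=DEFAULT_FREE, prior_decades=2.0,
                 stoichiometry=None, solver=None, y0=None, sd_floor_frac=0.05):
        self.p0 = p0
        self.free = free
        self.prior_decades = prior_decades
        self.stoichiometry = stoichiometry
        self.solver = solver
        self.y0 = y0
        self.sd_floor_frac = sd_floor_frac

    def fit(self, X: ObservationSet, y=None):
        if self.p0 is None:
            raise ConfigurationError("KineticsLeastSquares requires p0")
        bounds = PriorBox.around(self.p0, self.free, self.prior_decades)
        y0 = self.y0 if self.y0 is not None else X.initial_state()
        self.params_, self.optimizer_result_ = least_squares_fit(
            X, self.p0, bounds, self.free, self.stoichiometry, self.solver,
            y0, self.sd_floor_frac, return_details=True,
        )
        self.y0_ = np.asarray(y0, float)
        traj = simulate(self.params_, self.stoichiometry, y0,
                        SolverConfig(t_grid=tuple(X.times), t_end=float(X.times[-1])))
        self.chi2_ = chi_squared_gof(X, traj)
        return self

    def predict(self, t) -> np.ndarray:
        """Model trajectory at times ``t``, shape (len(t), 6)."""
        t = np.atleast_1d(np.asarray(t, float))
        cfg = SolverConfig(t_grid=tuple(np.sort(t)), t_end=float(max(t.max(), 1e-9)))
        traj = simulate(self.params_, self.stoichiometry, self.y0_, cfg)
        return traj.interpolate(t)

    def score(self, X: ObservationSet, y=None) -> float:
        """Gaussian log-likelihood of ``X`` under the fitted parameters."""
        return log_likelihood(X, self.params_, self.stoichiometry, self.solver,
                              self.y0_, self.sd_floor_frac)


class KineticsGibbs(BaseEstimator):
    """Metropolis-within-Gibbs posterior sampler for the kinetic model.

    Wraps :func:`gibbs_fit`; optionally initialises from a least-squares
    fit (default).  ``random_state`` seeds every stochastic element.

    Attributes
    ----------
    params_ : ParameterSet (posterior medians)
    samples_ : pandas.DataFrame of posterior draws
    result_ : FitResult
    chi2_ : dict of Chi2Result
    """

    def __init__(self, p0=None, free=DEFAULT_FREE, n_draws=10_000,
                 burn_in_frac=0.2, prior_decades=2.0, random_state=None,
                 init_from_least_squares=True, stoichiometry=None, solver=None,
                 y0=None, sd_floor_frac=0.05):
        self.p0 = p0
        self.free = free
        self.n_draws = n_draws
        self.burn_in_frac = burn_in_frac
        self.prior_decades = prior_decades
        self.random_state = random_state
        self.init_from_least_squares = init_from_least_squares
        self.stoichiometry = stoichiometry
        self.solver = solver
        self.y0 = y0
        self.sd_floor_frac = sd_floor_frac

    def fit(self, X: ObservationSet, y=None):
        if self.p0 is None:
            raise ConfigurationError("KineticsGibbs requires p0")
        y0 = self.y0 if self.y0 is not None else X.initial_state()
        priors = PriorBox.around(self.p0, self.free, self.prior_decades)
        self.result_ = gibbs_fit(
            X, priors, n_draws=self.n_draws, seed=self.random_state,
            p0=self.p0, free=self.free, s=self.stoichiometry,
            solver_cfg=self.solver, y0=y0, burn_in_frac=self.burn_in_frac,
            sd_floor_frac=self.sd_floor_frac,
            init_from_least_squares=self.init_from_least_squares,
        )
        self.params_ = self.result_.point_estimate
        self.samples_ = self.result_.samples
        self.chi2_ = self.result_.chi2
        self.y0_ = np.asarray(y0, float)
        return self

    def predict(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        cfg = SolverConfig(t_grid=tuple(np.sort(t)), t_end=float(max(t.max(), 1e-9)))
        traj = simulate(self.params_, self.stoichiometry, self.y0_, cfg)
        return traj.interpolate(t)

    def score(self, X: ObservationSet, y=None) -> float:
        return log_likelihood(X, self.params_, self.stoichiometry, self.solver,
                              self.y0_, self.sd_floor_frac)
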