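"""Horizontal movement: track geometry and a 2-state hidden Markov model.

Daily positions give step lengths (great-circle km on a 6371-km sphere) and
turning angles (signed bearing changes).  Movement is classified into
"directed" (long, straight daily steps) and "localised" (short, tortuous)
states with a hidden Markov model: gamma-distributed step lengths and
von Mises turning angles per state, a first-order transition matrix with its
stationary distribution as the initial law.  The model is fitted by direct
numerical maximisation of the forward log-likelihood (log-sum-exp
stabilised) from multiple random starts, in the Model.fit() -> Results
idiom; decoding is Viterbi, and model checking uses one-step-ahead
probability-integral-transform pseudo-residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, i0e, logsumexp

__all__ = [
    "Track",
    "read_track",
    "great_circle_km",
    "initial_bearing_rad",
    "steps_and_angles",
    "straightness_index",
    "track_summary",
    "TrackSummary",
    "MovementHMM",
    "HmmFit",
    "depth_by_state",
]

EARTH_RADIUS_KM = 6371.0
STATE_NAMES = ("directed", "localised")


# ---------------------------------------------------------------------------
# track container and geometry
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """Daily positions with derived step/angle/state columns."""

    df: pd.DataFrame            # date, lat, lon, bathy_m [, step_km, angle_rad, state]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
        out.to_csv(path, index=False, float_format="%.8g")


def read_track(path: str | Path) -> Track:
    df = pd.read_csv(path, parse_dates=["date"])
    return Track(df)


def great_circle_km(lat1, lon1, lat2, lon2,
                    radius_km: float = EARTH_RADIUS_KM):
    """Haversine great-circle distance in km."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat, dlon = la2 - la1, lo2 - lo1
    a = np.sin(dlat / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2) ** 2
    return 2 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_rad(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2 (radians from north)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlon = lo2 - lo1
    y = np.sin(dlon) * np.cos(la2)
    x = np.cos(la1) * np.sin(la2) - np.sin(la1) * np.cos(la2) * np.cos(dlon)
    return np.arctan2(y, x)


def wrap_angle(a):
    """Wrap to (-pi, pi]."""
    w = np.mod(-np.asarray(a) + np.pi, 2 * np.pi)
    return -(w - np.pi)


def steps_and_angles(track: Track) -> Track:
    """Daily step lengths (km) and signed turning angles (radians).

    Step ``d`` is the distance from day ``d-1`` to day ``d``; the turning
    angle at day ``d`` is the bearing change between consecutive steps, so
    angles exist only from the third day on.
    """
    df = track.df.copy()
    lat, lon = df["lat"].to_numpy(), df["lon"].to_numpy()
    n = len(df)
    step = np.full(n, np.nan)
    angle = np.full(n, np.nan)
    if n >= 2:
        step[1:] = great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
        bearing = initial_bearing_rad(lat[:-1], lon[:-1], lat[1:], lon[1:])
        if n >= 3:
            angle[2:] = wrap_angle(np.diff(bearing))
    df["step_km"] = step
    df["angle_rad"] = angle
    return Track(df, dict(track.meta))


def straightness_index(track: Track, start: int = 0, stop: int | None = None
                       ) -> float:
    """Net displacement over cumulative path length, clamped to [0, 1]."""
    df = track.df.iloc[start: stop]
    lat, lon = df["lat"].to_numpy(), df["lon"].to_numpy()
    if len(df) < 2:
        return np.nan
    cum = float(np.sum(great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])))
    if cum <= 0:
        raise ValueError("straightness index undefined for zero path length")
    net = float(great_circle_km(lat[0], lon[0], lat[-1], lon[-1]))
    return float(np.clip(net / cum, 0.0, 1.0))


@dataclass
class TrackSummary:
    straightness: float
    weekly_straightness: list[float]
    cumulative_km: float
    net_km: float


def track_summary(track: Track) -> TrackSummary:
    df = track.df
    lat, lon = df["lat"].to_numpy(), df["lon"].to_numpy()
    cum = float(np.sum(great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])))
    net = float(great_circle_km(lat[0], lon[0], lat[-1], lon[-1]))
    weekly = []
    for w0 in range(0, len(df) - 1, 7):
        seg = df.iloc[w0: w0 + 8]
        if len(seg) >= 2:
            try:
                weekly.append(straightness_index(Track(seg)))
            except ValueError:
                weekly.append(np.nan)
    return TrackSummary(straightness=float(np.clip(net / cum, 0, 1)) if cum > 0 else np.nan,
                        weekly_straightness=weekly,
                        cumulative_km=cum, net_km=net)


# ---------------------------------------------------------------------------
# hidden Markov model
# ---------------------------------------------------------------------------

def _stationary(P: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


class MovementHMM:
    """2-state (gamma step, von Mises angle) hidden Markov movement model.

    Parameters
    ----------
    steps : array of daily step lengths (km); NaN entries are skipped in the
        emission density (treated as uninformative).
    angles : array of turning angles (radians); NaN where undefined (the
        first step, gaps) — those days contribute the step density only.
    n_states : number of latent states (default 2).
    """

    def __init__(self, steps, angles=None, n_states: int = 2):
        self.steps = np.asarray(steps, dtype=float)
        if angles is None:
            angles = np.full_like(self.steps, np.nan)
        self.angles = np.asarray(angles, dtype=float)
        if len(self.steps) != len(self.angles):
            raise ValueError("steps and angles must be equal length")
        keep = np.isfinite(self.steps)
        self.steps = self.steps[keep]
        self.angles = self.angles[keep]
        if len(self.steps) < 3 * n_states:
            raise ValueError("too few steps to fit the model")
        if np.any(self.steps <= 0):
            raise ValueError("step lengths must be strictly positive")
        self.n_states = n_states
        self.n_obs = len(self.steps)

    @classmethod
    def from_track(cls, track: "Track", n_states: int = 2) -> "MovementHMM":
        if "step_km" not in track.df.columns:
            track = steps_and_angles(track)
        df = track.df
        return cls(df["step_km"].to_numpy()[1:], df["angle_rad"].to_numpy()[1:],
                   n_states=n_states)

    # -- parameter packing ---------------------------------------------------
    def _unpack(self, x: np.ndarray):
        K = self.n_states
        shapes = np.exp(x[0:K])
        scales = np.exp(x[K:2 * K])
        mus = wrap_angle(x[2 * K:3 * K])
        kappas = np.exp(x[3 * K:4 * K])
        logits = x[4 * K:].reshape(K, K - 1)
        P = np.empty((K, K))
        for i in range(K):
            row = np.concatenate(([0.0], logits[i]))
            row = np.exp(row - logsumexp(row))
            P[i] = row
        return shapes, scales, mus, kappas, P

    def _log_emissions(self, shapes, scales, mus, kappas) -> np.ndarray:
        # gamma: (a-1) ln x - x/s - a ln s - ln G(a); von Mises:
        # k cos(x - mu) - ln(2 pi I0(k)), with missing angles contributing 1
        s = self.steps[:, None]
        a = np.asarray(shapes)[None, :]
        sc = np.asarray(scales)[None, :]
        logb = ((a - 1) * np.log(s) - s / sc - a * np.log(sc) - gammaln(a))
        ang = self.angles[:, None]
        k = np.asarray(kappas)[None, :]
        mu = np.asarray(mus)[None, :]
        with np.errstate(invalid="ignore"):
            vm = k * (np.cos(ang - mu) - 1.0) - np.log(2 * np.pi * i0e(k))
        logb = logb + np.where(np.isfinite(ang), vm, 0.0)
        return logb

    def loglike(self, x: np.ndarray) -> float:
        """Forward log-likelihood (scaled linear-space recursion)."""
        shapes, scales, mus, kappas, P = self._unpack(x)
        logb = self._log_emissions(shapes, scales, mus, kappas)
        # per-row scaling keeps the linear recursion in range
        shift = logb.max(axis=1)
        b = np.exp(logb - shift[:, None])
        alpha = _stationary(P) * b[0]
        ll = shift[0]
        for t in range(1, self.n_obs):
            c = alpha.sum()
            if c <= 0 or not np.isfinite(c):
                return -np.inf
            ll += np.log(c)
            alpha = (alpha / c) @ P * b[t]
        c = alpha.sum()
        if c <= 0 or not np.isfinite(c):
            return -np.inf
        return float(ll + np.log(c) + shift[1:].sum())

    def _initial_guess(self, rng: np.random.Generator) -> np.ndarray:
        K = self.n_states
        qs = np.quantile(self.steps, np.linspace(0.8, 0.2, K))
        means = qs * rng.lognormal(0.0, 0.2, K)
        sds = means * rng.uniform(0.4, 1.0, K)
        shapes = (means / sds) ** 2
        scales = sds ** 2 / means
        mus = rng.vonmises(0.0, 4.0, K)
        kappas = rng.lognormal(0.0, 0.7, K)
        x = np.concatenate([np.log(shapes), np.log(scales), mus,
                            np.log(kappas)])
        logits = np.log(rng.uniform(0.05, 0.4, (K, K - 1)))
        return np.concatenate([x, logits.ravel()])

    def fit(self, n_restarts: int = 25, seed: int | None = 0,
            maxiter: int = 500) -> "HmmFit":
        """Maximise the forward likelihood from ``n_restarts`` random starts."""
        rng = np.random.default_rng(seed)
        best = None
        n_ok = 0
        for _ in range(n_restarts):
            x0 = self._initial_guess(rng)
            try:
                res = optimize.minimize(
                    lambda x: -self.loglike(x), x0, method="L-BFGS-B",
                    options={"maxiter": maxiter})
            except (ValueError, FloatingPointError):
                continue
            if not np.isfinite(res.fun):
                continue
            n_ok += res.success
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError("HMM fit failed from every restart")
        return HmmFit(self, best.x, loglik=-best.fun,
                      converged=bool(n_ok > 0), n_restarts=n_restarts)


@dataclass
class HmmFit:
    """Fitted movement HMM: estimates, decoding and diagnostics.

    States are relabelled so state 0 ("directed") has the larger gamma step
    mean.
    """

    model: MovementHMM
    x: np.ndarray
    loglik: float
    converged: bool
    n_restarts: int

    def __post_init__(self) -> None:
        shapes, scales, mus, kappas, P = self.model._unpack(self.x)
        means = shapes * scales
        order = np.argsort(-means)  # directed = larger step mean
        self.step_shape = shapes[order]
        self.step_scale = scales[order]
        self.step_mean = means[order]
        self.step_sd = np.sqrt(shapes[order]) * scales[order]
        self.angle_mean = mus[order]
        self.angle_kappa = kappas[order]
        self.transition = P[np.ix_(order, order)]
        self.stationary = _stationary(self.transition)
        self._order = order

    @property
    def aic(self) -> float:
        k = len(self.x)
        return 2 * k - 2 * self.loglik

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "state": STATE_NAMES[: self.model.n_states],
            "step_mean_km": self.step_mean,
            "step_sd_km": self.step_sd,
            "angle_mean_rad": self.angle_mean,
            "angle_kappa": self.angle_kappa,
            "stationary_prob": self.stationary,
        })

    def _log_emissions(self) -> np.ndarray:
        logb = self.model._log_emissions(
            self.step_shape, self.step_scale, self.angle_mean,
            self.angle_kappa)
        return logb

    def decode(self) -> np.ndarray:
        """Viterbi most-probable state path (0 = directed)."""
        logb = self._log_emissions()
        logP = np.log(self.transition)
        n, K = logb.shape
        delta = np.log(self.stationary) + logb[0]
        back = np.zeros((n, K), dtype=int)
        for t in range(1, n):
            cand = delta[:, None] + logP
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(K)] + logb[t]
        path = np.empty(n, dtype=int)
        path[-1] = int(np.argmax(delta))
        for t in range(n - 2, -1, -1):
            path[t] = back[t + 1][path[t + 1]]
        return path

    def pseudo_residuals(self) -> np.ndarray:
        """One-step-ahead PIT residuals of the step lengths (uniform if correct)."""
        logb = self._log_emissions()
        n, K = logb.shape
        cdf = stats.gamma.cdf(self.model.steps[:, None], self.step_shape,
                              scale=self.step_scale)
        u = np.empty(n)
        pred = self.stationary.copy()
        for t in range(n):
            u[t] = float(pred @ cdf[t])
            post = pred * np.exp(logb[t] - logb[t].max())
            post /= post.sum()
            pred = post @ self.transition
        return u

    def summary(self) -> str:
        lines = [
            "2-state movement HMM (gamma steps, von Mises angles)",
            f"n obs: {self.model.n_obs}   log-likelihood: {self.loglik:.2f}   "
            f"AIC: {self.aic:.2f}   converged: {self.converged}",
            "",
            self.params_frame().to_string(index=False,
                                          float_format=lambda v: f"{v:.3f}"),
            "",
            "transition matrix (rows: from directed, localised):",
            np.array2string(self.transition, precision=3),
        ]
        return "\n".join(lines)


def decode_states(fit: HmmFit) -> np.ndarray:
    return fit.decode()


def pseudo_residuals(fit: HmmFit) -> np.ndarray:
    return fit.pseudo_residuals()


# ---------------------------------------------------------------------------
# depth by day/night and movement state
# ---------------------------------------------------------------------------

def depth_by_state(df: pd.DataFrame):
    """Linear mixed model of log mean depth on day/night x movement state.

    ``df`` needs columns ``fish_id``, ``period`` ("day"/"night"), ``state``
    ("directed"/"localised") and ``mean_depth_m`` (> 0).  A per-fish random
    intercept absorbs between-individual depth preferences.  Returns the
    fitted statsmodels MixedLM results.
    """
    import statsmodels.formula.api as smf

    d = df.copy()
    d = d[np.isfinite(d["mean_depth_m"]) & (d["mean_depth_m"] > 0)]
    d["log_depth"] = np.log(d["mean_depth_m"])
    model = smf.mixedlm("log_depth ~ C(period) * C(state)", data=d,
                        groups=d["fish_id"])
    return model.fit(reml=True)
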