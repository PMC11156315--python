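"""Maximum-likelihood fitting of the navigation model to trajectories,
plus GPS preprocessing mirroring the homing-pigeon pipeline.

The model's next-heading distribution is treated as a weighted mixture
of Von Mises components (goal, social, memory, continuity), each centred
on a bearing that is reconstructible from the trajectory context:

* goal      — bearing from the current position to the goal;
* social    — convergence/alignment composite of the partner's state,
  collapsed to its mean direction (the p-weighted circular mean of the
  bearing to the partner's predicted position and the partner's heading);
* memory    — bearing to the current target of the memorised landmark
  sequence, replayed over the trajectory with the same capture-threshold
  progression rule the simulator uses; uniform (kappa = 0) on an agent's
  first journey;
* continuity — the previous observed heading.

Weights live on the simplex; concentrations are estimated on the
circular-SD scale (better conditioned) with a single memory kappa for
journeys >= 2.  Components that are undefined at a given observation
(no partner, exhausted landmark sequence, first step of a journey) are
dropped there and the weights renormalised, exactly as in the generative
model.  Because the generative step *averages* one sample per component
rather than drawing from the mixture, the mixture likelihood is an
approximation; parameter-recovery tests on simulated data bound the
error this introduces.

The latent landmark sequence of a real animal is unobservable; fitting
therefore requires an explicit landmark-sequence provider.  For
simulator output the true memorised sequences are exported alongside the
trajectories.  For field data no such provider exists and the memory
component must be configured explicitly (this gap is documented rather
than papered over).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .circkit import kappa_from_circular_sd
from .navigator import CAPTURE_RADIUS, social_mixing_proportion
from .world import World

__all__ = [
    "Trajectory",
    "Observations",
    "FitResult",
    "headings_from_trajectory",
    "mixture_log_density",
    "trajectory_from_record",
    "build_observations",
    "observations_from_result",
    "fit_parameters",
    "fit_result",
    "GPSConfig",
    "utm_from_latlon",
    "preprocess_gps",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class Trajectory:
    """Time-ordered planar positions of one agent on one journey."""

    agent_id: int
    journey: int  # the agent's own 1-based journey (experience) index
    times: np.ndarray
    xy: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if len(self.times) != len(self.xy):
            raise ValueError("times and xy must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")


def headings_from_trajectory(traj: Trajectory) -> np.ndarray:
    """Per-step displacement bearings; zero-displacement steps dropped."""
    if len(traj.xy) < 2:
        raise ValueError("need at least two samples to derive headings")
    d = np.diff(traj.xy, axis=0)
    keep = (d[:, 0] != 0) | (d[:, 1] != 0)
    return np.arctan2(d[keep, 1], d[keep, 0])


def mixture_log_density(h: float, components) -> float:
    """Log density at ``h`` of a weighted Von Mises mixture.

    ``components`` is a sequence of ``(VonMisesComponent, weight)``
    pairs; weights must sum to 1.  kappa = 0 components contribute the
    uniform density 1 / (2 pi).
    """
    ws = [w for _, w in components]
    if any(w < 0 for w in ws) or abs(sum(ws) - 1.0) > 1e-9:
        raise ValueError("mixture weights must be non-negative and sum to 1")
    dens = 0.0
    for comp, w in components:
        if w == 0.0:
            continue
        if comp.kappa == 0.0:
            dens += w / (2.0 * math.pi)
        else:
            # log I0(k) = log(i0e(k)) + k, stable for large kappa
            log_i0 = math.log(special.i0e(comp.kappa)) + comp.kappa
            dens += w * math.exp(comp.kappa * math.cos(h - comp.mu) - _LOG_2PI - log_i0)
    if dens <= 0.0:
        return -math.inf
    return math.log(dens)


# ---------------------------------------------------------------------------
# observation tables

_K = 4  # component order: goal, social, memory, continuity
_GOAL, _SOCIAL, _MEMORY, _CONTINUITY = range(_K)


@dataclass
class Observations:
    """Stacked per-step regression targets for the mixture likelihood.

    ``mu[i, k]`` is component k's centre direction at observation i;
    ``active[i, k]`` whether it is defined there; ``uniform[i, k]``
    whether it contributes the uniform density (first-journey memory).
    """

    h: np.ndarray  # (n,) observed headings
    mu: np.ndarray  # (n, 4)
    active: np.ndarray  # (n, 4) bool
    uniform: np.ndarray  # (n, 4) bool

    def __len__(self) -> int:
        return len(self.h)

    def stack(self, other: "Observations") -> "Observations":
        return Observations(
            np.concatenate([self.h, other.h]),
            np.vstack([self.mu, other.mu]),
            np.vstack([self.active, other.active]),
            np.vstack([self.uniform, other.uniform]),
        )

    def subsample(self, n: int, seed: int = 0) -> "Observations":
        """A seeded random subset of at most ``n`` observations (steps
        are treated as independent by the likelihood, so subsampling
        only widens the estimator's variance)."""
        if len(self) <= n:
            return self
        idx = np.sort(np.random.default_rng(seed).choice(len(self), size=n, replace=False))
        return Observations(self.h[idx], self.mu[idx], self.active[idx], self.uniform[idx])


def trajectory_from_record(record) -> Trajectory:
    """Build a Trajectory from a simulator JourneyRecord (needs paths)."""
    if record.positions is None:
        raise ValueError("record has no stored positions; simulate with keep_paths=True")
    n = len(record.positions)
    return Trajectory(
        agent_id=record.agent_id,
        journey=record.journey_of_agent,
        times=np.arange(n, dtype=float),
        xy=record.positions,
    )


def _replay_memory_targets(
    xy: np.ndarray,
    sequence: list[int],
    world: World,
    capture_radius: float,
) -> np.ndarray:
    """Replay the landmark-progression rule over a path: for each time
    index, the landmark ID the agent was navigating towards, or -1."""
    out = np.full(len(xy), -1, dtype=np.int64)
    if not sequence:
        return out
    pts = world.landmarks
    r2 = capture_radius * capture_radius
    ptr = 0
    n = len(sequence)
    for t in range(len(xy)):
        if ptr < n:
            lx, ly = pts[sequence[ptr]]
            if (lx - xy[t, 0]) ** 2 + (ly - xy[t, 1]) ** 2 <= r2:
                ptr += 1
        out[t] = sequence[ptr] if ptr < n else -1
    return out


def build_observations(
    traj: Trajectory,
    world: World,
    partner: Trajectory | None = None,
    memory_sequence: list[int] | None = None,
    capture_radius: float = CAPTURE_RADIUS,
) -> Observations:
    """Per-step component centres and availability for one trajectory.

    ``partner`` supplies the social context (positions/headings aligned
    on the same time grid); ``memory_sequence`` the memorised landmark
    IDs of this agent (its own first-journey route).
    """
    xy = traj.xy
    h_all = np.arctan2(np.diff(xy[:, 1]), np.diff(xy[:, 0]))  # heading taken at t
    n = len(h_all)  # observations: steps t = 0 .. n-1
    gx, gy = world.goal
    mu = np.zeros((n, _K))
    active = np.zeros((n, _K), dtype=bool)
    uniform = np.zeros((n, _K), dtype=bool)

    # goal: bearing from position at t
    mu[:, _GOAL] = np.arctan2(gy - xy[:-1, 1], gx - xy[:-1, 0])
    active[:, _GOAL] = True

    # continuity: previous heading; first step has none
    mu[1:, _CONTINUITY] = h_all[:-1]
    active[1:, _CONTINUITY] = True

    # memory
    if traj.journey == 1:
        active[:, _MEMORY] = True
        uniform[:, _MEMORY] = True
    elif memory_sequence:
        targets = _replay_memory_targets(xy[:-1], memory_sequence, world, capture_radius)
        has = targets >= 0
        tid = np.where(has, targets, 0)
        lx = world.landmarks[tid, 0]
        ly = world.landmarks[tid, 1]
        mu[:, _MEMORY] = np.arctan2(ly - xy[:-1, 1], lx - xy[:-1, 0])
        active[:, _MEMORY] = has

    # social
    if partner is not None:
        pxy = partner.xy
        m = min(n, len(pxy) - 1)  # partner present at times 0..len-1
        if m > 0:
            ph = np.arctan2(np.diff(pxy[:, 1]), np.diff(pxy[:, 0]))
            # partner's heading *at* time t is the one that produced its
            # position at t, i.e. ph[t-1]; undefined at t=0
            for t in range(m):
                px, py = pxy[t]
                dxc, dyc = px - xy[t, 0], py - xy[t, 1]
                if t == 0:
                    if dxc == 0 and dyc == 0:
                        continue
                    mu[t, _SOCIAL] = math.atan2(dyc, dxc)
                    active[t, _SOCIAL] = True
                    continue
                hd = ph[t - 1]
                fx, fy = px + math.cos(hd), py + math.sin(hd)
                dxf, dyf = fx - xy[t, 0], fy - xy[t, 1]
                d = math.hypot(dxc, dyc)
                if d == 0.0 or (dxf == 0 and dyf == 0):
                    mu[t, _SOCIAL] = hd
                else:
                    p = social_mixing_proportion(d)
                    conv = math.atan2(dyf, dxf)
                    cx = p * math.cos(conv) + (1 - p) * math.cos(hd)
                    cy = p * math.sin(conv) + (1 - p) * math.sin(hd)
                    mu[t, _SOCIAL] = math.atan2(cy, cx) if (cx or cy) else conv
                active[t, _SOCIAL] = True
    return Observations(h_all, mu, active, uniform)


def observations_from_result(result, world: World | None = None) -> Observations:
    """Stack observations over every journey of a simulated experiment.

    Uses the stored paths, the exported memorised landmark sequences and
    the per-journey pairing structure of the result.
    """
    if result.records is None:
        raise ValueError("result has no stored paths; simulate with keep_paths=True")
    from .world import build_world

    obs: Observations | None = None
    by_journey: dict[tuple[int, int], list] = {}
    for r in result.records:
        by_journey.setdefault((r.run, r.journey), []).append(r)
    worlds: dict[int, World] = {}
    for (run, _), recs in sorted(by_journey.items()):
        if world is None:
            if run not in worlds:
                from .engine import _landmark_seed

                kw = dict(result.world_kwargs)
                kw.setdefault("landmark_seed", _landmark_seed((result.base_seed, run)))
                worlds[run] = build_world(**kw)
            w = worlds[run]
        else:
            w = world
        trajs = {r.agent_id: trajectory_from_record(r) for r in recs}
        for r in recs:
            partner = next((t for a, t in trajs.items() if a != r.agent_id), None)
            seq = result.memories.get((run, r.agent_id))
            o = build_observations(
                trajs[r.agent_id],
                w,
                partner=partner,
                memory_sequence=seq,
                capture_radius=result.spec.capture_radius,
            )
            obs = o if obs is None else obs.stack(o)
    return obs


# ---------------------------------------------------------------------------
# maximum likelihood


@dataclass
class FitResult:
    """Estimated mixture parameters with convergence diagnostics."""

    weights: dict[str, float]
    kappas: dict[str, float]
    sds: dict[str, float]
    nll: float
    n_obs: int
    converged: bool
    n_starts: int
    messages: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "weights": self.weights,
            "kappas": self.kappas,
            "circular_sds": self.sds,
            "nll": self.nll,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


_NAMES = ("goal", "social", "memory", "continuity")


def _kappa_of_resultant(r: np.ndarray) -> np.ndarray:
    """Fisher's approximation to A^-1 (mean resultant length -> kappa)."""
    r = np.clip(r, 0.0, 1.0 - 1e-12)
    small = 2 * r + r**3 + 5 * r**5 / 6
    mid = -0.4 + 1.39 * r + 0.43 / (1 - r)
    large = 1.0 / (r**3 - 4 * r**2 + 3 * r + 1e-300)
    return np.where(r < 0.53, small, np.where(r < 0.85, mid, large))


def _nll_mean(params: np.ndarray, obs: Observations, comp_idx: list[int], sd_bounds) -> float:
    """Negative log-likelihood under the averaged-sample heading model.

    The generative step draws one sample per component and takes their
    weighted circular mean, so the heading is (approximately) Von Mises
    around the direction of the mean resultant m = sum_k w_k R(kappa_k)
    u(mu_k), with a concentration obtained by moment matching: the
    transverse variance of the resultant, divided by |m|^2, gives the
    angular variance, which maps back to a concentration through the
    mean-resultant-length relation.
    """
    k = len(comp_idx)
    logits = np.concatenate([[0.0], params[: k - 1]])
    w = np.exp(logits - logits.max())
    w /= w.sum()
    sd = np.clip(np.exp(params[k - 1 :]), sd_bounds[0], sd_bounds[1])
    kappa = np.array([kappa_from_circular_sd(s) for s in sd])
    R1 = special.i1e(kappa) / special.i0e(kappa)
    R2 = special.ive(2, kappa) / special.ive(0, kappa)

    act = obs.active[:, comp_idx]  # (n, k)
    unif = obs.uniform[:, comp_idx]
    mu = obs.mu[:, comp_idx]
    wact = act * w
    wnorm = wact / np.maximum(wact.sum(axis=1, keepdims=True), 1e-300)
    r1 = np.where(unif, 0.0, R1)  # uniform components carry no direction
    r2 = np.where(unif, 0.0, R2)
    mx = (wnorm * r1 * np.cos(mu)).sum(axis=1)
    my = (wnorm * r1 * np.sin(mu)).sum(axis=1)
    theta0 = np.arctan2(my, mx)
    rho = np.maximum(np.hypot(mx, my), 1e-9)
    b = mu - theta0[:, None]
    var_k = (1.0 - r2 * np.cos(2 * b)) / 2.0 - (r1 * np.sin(b)) ** 2
    var_t = (wnorm**2 * np.where(act, var_k, 0.0)).sum(axis=1)
    sigma2 = var_t / rho**2
    k_eff = _kappa_of_resultant(np.exp(-sigma2 / 2.0))
    log_i0 = np.log(special.i0e(k_eff)) + k_eff
    ll = k_eff * np.cos(obs.h - theta0) - _LOG_2PI - log_i0
    return -float(ll.sum())


def _nll_mixture(params: np.ndarray, obs: Observations, comp_idx: list[int], sd_bounds) -> float:
    k = len(comp_idx)
    logits = np.concatenate([[0.0], params[: k - 1]])
    w = np.exp(logits - logits.max())
    w /= w.sum()
    log_sd = params[k - 1 :]
    sd = np.exp(log_sd)
    kappa = np.array([kappa_from_circular_sd(min(max(s, sd_bounds[0]), sd_bounds[1])) for s in sd])

    n = len(obs.h)
    dens = np.zeros((n, k))
    act = obs.active[:, comp_idx]
    for j, c in enumerate(comp_idx):
        unif = obs.uniform[:, c]
        vm = act[:, j] & ~unif
        if np.any(vm):
            log_i0 = math.log(special.i0e(kappa[j])) + kappa[j]
            dens[vm, j] = np.exp(
                kappa[j] * np.cos(obs.h[vm] - obs.mu[vm, c]) - _LOG_2PI - log_i0
            )
        dens[unif & act[:, j], j] = 1.0 / (2.0 * math.pi)
    wact = act * w  # (n, k)
    denom = wact.sum(axis=1)
    ok = denom > 0
    mix = (wact[ok] * dens[ok]).sum(axis=1) / denom[ok]
    return -float(np.sum(np.log(np.maximum(mix, 1e-300))))


def fit_parameters(
    obs: Observations,
    include_social: bool | None = None,
    n_starts: int = 8,
    seed: int = 0,
    sd_bounds: tuple[float, float] = (0.05, 2.0),
    method: str = "mean",
) -> FitResult:
    """Maximum-likelihood estimation of weights (simplex) and
    per-component circular SDs, with multi-start local optimisation.

    ``method="mean"`` (default) uses the averaged-sample likelihood that
    matches the generative heading update (one draw per component,
    weighted circular mean); ``method="mixture"`` treats the heading as
    a draw from the weighted Von Mises mixture itself.  The mixture
    reading badly over-attributes weight to the continuity component on
    simulated data, because the averaged heading is always close to the
    previous one; it is kept for comparison with mixture-based analyses.

    ``sd_bounds`` constrains each component's circular SD.  The upper
    bound matters: a component with SD beyond ~2 (kappa < 0.27) is
    directionally almost uniform, and unbounded diffuse components can
    pad the weight vector without changing the implied heading law (an
    identifiability ridge); bounding the SD removes that degeneracy
    while comfortably containing the model's actual spreads (<= 1.0).

    ``include_social=None`` auto-detects from the observations (solo
    data has no social component).  A fit that fails to converge from
    every start is returned flagged, not silently.
    """
    if len(obs) == 0:
        raise ValueError("no observations to fit")
    if include_social is None:
        include_social = bool(obs.active[:, _SOCIAL].any())
    fn = {"mean": _nll_mean, "mixture": _nll_mixture}[method]
    comp_idx = [_GOAL] + ([_SOCIAL] if include_social else []) + [_MEMORY, _CONTINUITY]
    k = len(comp_idx)
    rng = np.random.default_rng(seed)
    best = None
    messages = []
    any_converged = False
    for s in range(n_starts):
        w0 = rng.dirichlet(np.ones(k))
        logits0 = np.log(w0 / w0[0])[1:]
        sd0 = rng.uniform(0.25, 1.5, size=k)
        x0 = np.concatenate([logits0, np.log(sd0)])
        res = optimize.minimize(
            fn,
            x0,
            args=(obs, comp_idx, sd_bounds),
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        messages.append(f"start {s}: nll={res.fun:.2f} converged={res.success}")
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    logits = np.concatenate([[0.0], best.x[: k - 1]])
    w = np.exp(logits - logits.max())
    w /= w.sum()
    sd = np.clip(np.exp(best.x[k - 1 :]), sd_bounds[0], sd_bounds[1])
    names = [_NAMES[c] for c in comp_idx]
    weights = {nm: float(wi) for nm, wi in zip(names, w)}
    sds = {nm: float(s) for nm, s in zip(names, sd)}
    kappas = {nm: float(kappa_from_circular_sd(s)) for nm, s in zip(names, sd)}
    return FitResult(
        weights=weights,
        kappas=kappas,
        sds=sds,
        nll=float(best.fun),
        n_obs=len(obs),
        converged=any_converged,
        n_starts=n_starts,
        messages=messages,
    )


def fit_result(result, world: World | None = None, **kwargs) -> FitResult:
    """Convenience: build observations from a simulated experiment and fit."""
    return fit_parameters(observations_from_result(result, world), **kwargs)


# ---------------------------------------------------------------------------
# GPS preprocessing (transverse Mercator + filters)

# WGS84 ellipsoid
_A = 6378137.0
_F = 1 / 298.257223563
_K0 = 0.9996
_E2 = _F * (2 - _F)


def utm_from_latlon(lat: float, lon: float, zone: int) -> tuple[float, float]:
    """Forward UTM projection (WGS84, northern-hemisphere convention).

    Karney-style transverse Mercator series (6th order in the third
    flattening), accurate to well under a millimetre for UTM use.
    """
    if not (-80.0 <= lat <= 84.0):
        raise ValueError("latitude outside UTM domain")
    n = _F / (2 - _F)
    lon0 = math.radians((zone - 1) * 6 - 180 + 3)
    phi = math.radians(lat)
    lam = math.radians(lon) - lon0

    # conformal latitude via its tangent (exact)
    e = math.sqrt(_E2)
    t = math.tan(phi)
    sigma = math.sinh(e * math.atanh(e * t / math.sqrt(1 + t * t)))
    tp = t * math.sqrt(1 + sigma * sigma) - sigma * math.sqrt(1 + t * t)
    xi_p = math.atan2(tp, math.cos(lam))
    eta_p = math.asinh(math.sin(lam) / math.hypot(tp, math.cos(lam)))

    # Krueger series coefficients (alpha), 6th order in n
    n2, n3, n4, n5, n6 = n * n, n**3, n**4, n**5, n**6
    alpha = [
        n / 2 - 2 * n2 / 3 + 5 * n3 / 16 + 41 * n4 / 180 - 127 * n5 / 288 + 7891 * n6 / 37800,
        13 * n2 / 48 - 3 * n3 / 5 + 557 * n4 / 1440 + 281 * n5 / 630 - 1983433 * n6 / 1935360,
        61 * n3 / 240 - 103 * n4 / 140 + 15061 * n5 / 26880 + 167603 * n6 / 181440,
        49561 * n4 / 161280 - 179 * n5 / 168 + 6601661 * n6 / 7257600,
        34729 * n5 / 80640 - 3418889 * n6 / 1995840,
        212378941 * n6 / 319334400,
    ]
    xi = xi_p
    eta = eta_p
    for j, a_j in enumerate(alpha, start=1):
        xi += a_j * math.sin(2 * j * xi_p) * math.cosh(2 * j * eta_p)
        eta += a_j * math.cos(2 * j * xi_p) * math.sinh(2 * j * eta_p)
    a_hat = _A / (1 + n) * (1 + n2 / 4 + n4 / 64 + n6 / 256)
    easting = _K0 * a_hat * eta + 500000.0
    northing = _K0 * a_hat * xi
    return easting, northing


@dataclass(frozen=True)
class GPSConfig:
    """Knobs of the GPS-track preprocessing pipeline.

    Defaults mirror the pigeon pipeline: UTM grid zone 30, samples kept
    only at speeds in [25, 150] km/h, whole flights dropped when any fix
    strays further than twice the start-goal distance from the
    start-goal midpoint or when the goal is never approached, and
    downsampling to 0.05 Hz (one sample every 20 s).
    """

    utm_zone: int = 30
    min_speed_kmh: float = 25.0
    max_speed_kmh: float = 150.0
    downsample_s: float = 20.0
    start: tuple[float, float] | None = None  # UTM metres
    goal: tuple[float, float] | None = None
    goal_radius_m: float = 500.0
    excursion_factor: float = 2.0


def preprocess_gps(
    track: pd.DataFrame,
    config: GPSConfig,
    agent_id: int = 0,
    journey: int = 1,
) -> Trajectory | None:
    """Convert one raw GPS track to a planar Trajectory, or None if the
    whole flight is excluded.

    ``track`` needs columns ``time`` (seconds, strictly increasing),
    ``lat`` and ``lon``.  Unparseable rows are dropped (counted, not
    fatal).  Sample-level speed filtering removes fixes whose speed from
    the previous retained fix falls outside the configured band; the
    midpoint-excursion and goal-arrival rules then exclude whole flights.
    """
    cols = {"time", "lat", "lon"}
    if not cols.issubset(track.columns):
        raise ValueError(f"track must have columns {sorted(cols)}")
    df = track[["time", "lat", "lon"]].apply(pd.to_numeric, errors="coerce").dropna()
    df = df.sort_values("time")
    df = df[~df["time"].duplicated()]
    if len(df) < 2:
        return None
    e, nn = zip(*(utm_from_latlon(la, lo, config.utm_zone) for la, lo in zip(df["lat"], df["lon"])))
    t = df["time"].to_numpy(dtype=float)
    xy = np.column_stack([e, nn])

    # sample-wise speed filter against the previous *retained* fix
    keep = [0]
    for i in range(1, len(xy)):
        j = keep[-1]
        dt = t[i] - t[j]
        v_kmh = np.hypot(*(xy[i] - xy[j])) / dt * 3.6
        if config.min_speed_kmh <= v_kmh <= config.max_speed_kmh:
            keep.append(i)
    if len(keep) < 2:
        return None
    t, xy = t[keep], xy[keep]

    if config.start is not None and config.goal is not None:
        start = np.asarray(config.start)
        goal = np.asarray(config.goal)
        mid = (start + goal) / 2.0
        limit = config.excursion_factor * np.linalg.norm(goal - start)
        if np.any(np.linalg.norm(xy - mid, axis=1) > limit):
            return None  # strayed too far off course
        if np.min(np.linalg.norm(xy - goal, axis=1)) > config.goal_radius_m:
            return None  # never reached the goal

    # downsample: first fix of every downsample_s window
    keep2 = [0]
    for i in range(1, len(t)):
        if t[i] - t[keep2[-1]] >= config.downsample_s:
            keep2.append(i)
    t, xy = t[keep2], xy[keep2]
    if len(t) < 2:
        return None
    return Trajectory(agent_id=agent_id, journey=journey, times=t, xy=xy)
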