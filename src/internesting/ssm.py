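"""Two-state switching correlated random walk (DCRWS) state-space model.

The movement process is a first-difference correlated random walk whose
persistence and turning behaviour switch under a hidden two-state Markov
chain: with ``d_t = x_t - x_{t-1}`` (degrees lon/lat at a regular 8-h step),

    d_t ~ Normal2( gamma[b_t] * T(theta[b_t]) @ d_{t-1}, diag(sigma^2) )

where ``T`` is a 2x2 rotation, ``b_t`` in {1, 2} follows a Markov chain with
transition probabilities alpha1 = P(1|1), alpha2 = P(1|2), and state 1 is the
persistent "migration" state (identifiability: gamma1 > gamma2). Each
irregular Argos fix observed at fractional position j within interval t is

    y = (1 - j) * x_{t-1} + j * x_t + eps,

with eps per-coordinate Student-t, degrees of freedom and base scale fixed
per location class (RunConfig.lc_error_table) and a free common inflation
psi. Observation-error scales are applied per coordinate in degrees
(scale_km / 111.195 for both axes).

Inference is Metropolis-within-Gibbs: stride-3 blocked random-walk updates
of the latent positions, forward-filtering backward-sampling for the state
chain, conjugate draws for alpha (Beta) and sigma^2 (inverse gamma), and
random-walk Metropolis for gamma, theta and log psi, with proposal scales
adapted during burn-in only. Two chains; convergence monitored by the
between/within-chain R-hat per parameter.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geo import KM_PER_DEGREE, LatLon
from .io_formats import ArgosFix, RunConfig

log = logging.getLogger("internesting")

PARAM_NAMES = ("gamma1", "gamma2", "theta1", "theta2", "alpha1", "alpha2",
               "sigma_lon", "sigma_lat", "psi")

MODE_MIGRATION = "migration"
MODE_INTERNESTING = "internesting"
MODE_UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class SSMParams:
    """Posterior summary (mean, sd) per movement parameter."""

    mean: dict
    sd: dict


@dataclass
class SSMFit:
    """Posterior over regular-interval positions and behavioural states."""

    turtle_id: str
    times: list  # regular instants, strictly increasing, constant spacing
    lon: np.ndarray  # posterior mean longitude per step
    lat: np.ndarray
    b_mean: np.ndarray  # posterior mean state index per step, in [1, 2]
    params: SSMParams
    rhat: dict
    converged: bool
    seed: int
    modes: list = field(default_factory=list)

    @property
    def positions(self) -> list[LatLon]:
        return [LatLon(float(la), float(lo)) for la, lo in zip(self.lat, self.lon)]


@dataclass(frozen=True)
class InternestingPeriod:
    """Tagging date to the date of the last inter-nesting-classified step."""

    turtle_id: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("inter-nesting period start after end")

    @property
    def length_days(self) -> int:
        return (self.end - self.start).days + 1  # inclusive of both dates


# ---------------------------------------------------------------------------
# model terms


def rotation_apply(theta: float, vx, vy):
    """Apply the 2x2 rotation T(theta) to vectors (vx, vy)."""
    c, s = math.cos(theta), math.sin(theta)
    return c * vx - s * vy, s * vx + c * vy


def _proc_terms(X: np.ndarray, b: np.ndarray, gamma, theta, sigma) -> np.ndarray:
    """Per-step process log densities; entry t holds the term for step t.

    Steps 0 and 1 carry no term (d_1 is given a diffuse prior).
    """
    K = X.shape[0] - 1
    out = np.zeros(K + 1)
    if K < 2:
        return out
    D = np.diff(X, axis=0)  # D[i] = d_{i+1}
    prev, cur = D[:-1], D[1:]
    st = b[2:]
    g = gamma[st]
    ct, sn = np.cos(theta)[st], np.sin(theta)[st]
    px = g * (ct * prev[:, 0] - sn * prev[:, 1])
    py = g * (sn * prev[:, 0] + ct * prev[:, 1])
    rx = (cur[:, 0] - px) / sigma[0]
    ry = (cur[:, 1] - py) / sigma[1]
    out[2:] = -0.5 * (rx * rx + ry * ry) - math.log(sigma[0]) - math.log(sigma[1])
    return out


def _obs_terms(X: np.ndarray, obs) -> np.ndarray:
    """Per-fix observation log densities (Student-t, both coordinates)."""
    t, j, y, nu, scale = obs
    mu = (1.0 - j)[:, None] * X[t - 1] + j[:, None] * X[t]
    z = (y - mu) / scale[:, None]
    return (-np.log(scale) * 2.0
            - 0.5 * (nu + 1.0) * (np.log1p(z[:, 0] ** 2 / nu) + np.log1p(z[:, 1] ** 2 / nu)))


def _ffbs(log_emit: np.ndarray, alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Forward filter, backward sample the 2-state chain over steps 1..K.

    ``log_emit[t, s]`` is the process log density of step t under state s
    (rows 0 and 1 are flat). Returns states in {0, 1} with entry 0 mirroring
    entry 1.
    """
    K = log_emit.shape[0] - 1
    P = np.array([[alpha[0], 1.0 - alpha[0]], [alpha[1], 1.0 - alpha[1]]])
    # stationary distribution of the chain as the initial law
    pi1 = alpha[1] / max(1.0 - alpha[0] + alpha[1], 1e-12)
    f = np.empty((K + 1, 2))
    w = np.array([pi1, 1.0 - pi1])
    m = log_emit[1].max()
    e = np.exp(log_emit[1] - m) * w
    f[1] = e / e.sum()
    for t in range(2, K + 1):
        pred = f[t - 1] @ P
        m = log_emit[t].max()
        e = np.exp(log_emit[t] - m) * pred
        s = e.sum()
        f[t] = e / s if s > 0 else np.array([0.5, 0.5])
    b = np.zeros(K + 1, dtype=np.int64)
    u = rng.random(K + 1)
    b[K] = 0 if u[K] < f[K, 0] else 1
    for t in range(K - 1, 0, -1):
        w0 = f[t, 0] * P[0, b[t + 1]]
        w1 = f[t, 1] * P[1, b[t + 1]]
        tot = w0 + w1
        p0 = w0 / tot if tot > 0 else 0.5
        b[t] = 0 if u[t] < p0 else 1
    b[0] = b[1]
    return b


# ---------------------------------------------------------------------------
# regularisation


def regularize(track: list[ArgosFix], interval_hours: float):
    """Regular time grid anchored at the first fix truncated to the hour."""
    t0 = track[0].timestamp.replace(minute=0, second=0, microsecond=0)
    step = dt.timedelta(hours=interval_hours)
    span_h = (track[-1].timestamp - t0).total_seconds() / 3600.0
    K = max(2, math.ceil(span_h / interval_hours))
    times = [t0 + i * step for i in range(K + 1)]
    s = np.array([(f.timestamp - t0).total_seconds() / 3600.0 / interval_hours for f in track])
    k = np.floor(s).astype(int)
    j = s - k
    t_idx = k + 1
    at_end = t_idx > K
    t_idx[at_end] = K
    j[at_end] = 1.0
    return times, K, t_idx, j


# ---------------------------------------------------------------------------
# the sampler


def _run_chain(obs, K: int, init_X: np.ndarray, config: RunConfig, rng: np.random.Generator):
    n_iter, burn, thin = config.mcmc_iterations, config.mcmc_burn_in, config.mcmc_thin
    X = init_X.copy()
    b = np.ones(K + 1, dtype=np.int64)
    gamma = np.array([0.7, 0.3])
    theta = np.array([0.0, 0.0])
    alpha = np.array([0.9, 0.2])
    d0 = np.diff(init_X, axis=0)
    sigma = np.clip(d0.std(axis=0), 1e-3, None)
    psi = 1.0

    # proposal scales, adapted during burn-in only
    x_step = float(np.median(obs[4])) if len(obs[4]) else 0.01
    gt_step = np.array([0.05, 0.05])  # gamma, theta share a per-state scale
    psi_step = 0.2
    acc_x = np.zeros(1)
    try_x = np.zeros(1)
    acc_gt = np.zeros(2)
    try_gt = np.zeros(2)
    acc_psi = 0.0
    try_psi = 0.0

    colors = [np.arange(c, K + 1, 3) for c in range(3)]
    n_obs = obs[0].shape[0]
    keep = []
    b_sum = np.zeros(K + 1)
    X_sum = np.zeros_like(X)
    n_keep = 0

    proc = _proc_terms(X, b, gamma, theta, sigma)
    oll = _obs_terms(X, obs)

    for it in range(n_iter):
        # --- latent positions, stride-3 coloured Metropolis
        for nodes in colors:
            prop = X.copy()
            prop[nodes] += rng.normal(0.0, x_step, size=(nodes.size, 2))
            proc_p = _proc_terms(prop, b, gamma, theta, sigma)
            oll_p = _obs_terms(prop, obs)
            dproc = np.concatenate([proc_p - proc, [0.0, 0.0]])
            dobs = np.bincount(obs[0], weights=oll_p - oll, minlength=K + 3)
            delta = dproc[nodes] + dproc[nodes + 1] + dproc[nodes + 2] + dobs[nodes] + dobs[np.minimum(nodes + 1, K + 2)]
            accept = np.log(rng.random(nodes.size)) < delta
            moved = nodes[accept]
            if moved.size:
                X[moved] = prop[moved]
                proc = _proc_terms(X, b, gamma, theta, sigma)
                oll = _obs_terms(X, obs)
            acc_x += accept.sum()
            try_x += nodes.size

        # --- hidden states by FFBS
        log_emit = np.zeros((K + 1, 2))
        for s in range(2):
            bs = np.full(K + 1, s, dtype=np.int64)
            log_emit[:, s] = _proc_terms(X, bs, gamma, theta, sigma)
        b = _ffbs(log_emit, alpha, rng)
        proc = _proc_terms(X, b, gamma, theta, sigma)

        # --- gamma/theta per state: several random-walk sweeps, with an
        # occasional independence (prior-draw) proposal to hop between
        # persistence/turn-angle modes
        for _sweep in range(5):
            for s in range(2):
                g_p = gamma.copy()
                th_p = theta.copy()
                if rng.random() < 0.1:
                    g_p[s] = rng.uniform(1e-6, 1.0 - 1e-6)
                    th_p[s] = rng.uniform(-math.pi, math.pi)
                else:
                    g_p[s] = gamma[s] + rng.normal(0.0, gt_step[s])
                    g_p[s] = min(max(g_p[s], 1e-6), 1.0 - 1e-6) if 0.0 < g_p[s] < 1.0 else (
                        abs(g_p[s]) if g_p[s] < 0 else 2.0 - g_p[s])  # reflect into (0,1)
                    g_p[s] = min(max(g_p[s], 1e-6), 1.0 - 1e-6)
                    th_p[s] = math.remainder(
                        theta[s] + rng.normal(0.0, 2.0 * gt_step[s]), 2.0 * math.pi
                    )
                proc_p = _proc_terms(X, b, g_p, th_p, sigma)
                if math.log(rng.random()) < proc_p.sum() - proc.sum():
                    gamma, theta, proc = g_p, th_p, proc_p
                    acc_gt[s] += 1
                try_gt[s] += 1

        # --- alpha, conjugate Beta from transition counts over steps 1..K
        bb = b[1:]
        n00 = int(np.sum((bb[:-1] == 0) & (bb[1:] == 0)))
        n01 = int(np.sum((bb[:-1] == 0) & (bb[1:] == 1)))
        n10 = int(np.sum((bb[:-1] == 1) & (bb[1:] == 0)))
        n11 = int(np.sum((bb[:-1] == 1) & (bb[1:] == 1)))
        alpha = np.clip(
            np.array([rng.beta(1 + n00, 1 + n01), rng.beta(1 + n10, 1 + n11)]),
            1e-4, 1.0 - 1e-4,
        )

        # --- sigma, conjugate inverse gamma on each axis
        if K >= 2:
            D = np.diff(X, axis=0)
            st = b[2:]
            ct, sn = np.cos(theta)[st], np.sin(theta)[st]
            g = gamma[st]
            px = g * (ct * D[:-1, 0] - sn * D[:-1, 1])
            py = g * (sn * D[:-1, 0] + ct * D[:-1, 1])
            ss = np.array([np.sum((D[1:, 0] - px) ** 2), np.sum((D[1:, 1] - py) ** 2)])
            shape = 0.001 + (K - 1) / 2.0
            scale_ig = 0.001 + ss / 2.0
            sigma = np.sqrt(scale_ig / rng.gamma(shape, 1.0, size=2))
            sigma = np.clip(sigma, 1e-6, None)
            proc = _proc_terms(X, b, gamma, theta, sigma)

        # --- psi, Metropolis on log scale, prior log psi ~ N(0, 1)
        if n_obs:
            lp = math.log(psi)
            lp_p = lp + rng.normal(0.0, psi_step)
            obs_p = (obs[0], obs[1], obs[2], obs[3], obs[4] / psi * math.exp(lp_p))
            oll_p = _obs_terms(X, obs_p)
            dlp = (oll_p.sum() - oll.sum()) - 0.5 * (lp_p ** 2 - lp ** 2)
            if math.log(rng.random()) < dlp:
                psi = math.exp(lp_p)
                obs = obs_p
                oll = oll_p
                acc_psi += 1
            try_psi += 1

        # --- identifiability: state 1 is the persistent (migration) state
        if gamma[0] < gamma[1]:
            gamma = gamma[::-1].copy()
            theta = theta[::-1].copy()
            alpha = np.array([1.0 - alpha[1], 1.0 - alpha[0]])
            b = 1 - b

        # --- burn-in adaptation every 50 iterations (frozen afterwards)
        if it < burn and (it + 1) % 50 == 0:
            batch = (it + 1) // 50
            rate = acc_x[0] / max(try_x[0], 1.0)
            x_step *= math.exp((rate - 0.3) / math.sqrt(batch))
            for s in range(2):
                r = acc_gt[s] / max(try_gt[s], 1.0)
                gt_step[s] *= math.exp((r - 0.3) / math.sqrt(batch))
            r = acc_psi / max(try_psi, 1.0)
            psi_step *= math.exp((r - 0.3) / math.sqrt(batch))
            acc_x[:] = 0
            try_x[:] = 0
            acc_gt[:] = 0
            try_gt[:] = 0
            acc_psi = try_psi = 0.0

        if it >= burn and (it - burn) % thin == 0:
            keep.append([gamma[0], gamma[1], theta[0], theta[1],
                         alpha[0], alpha[1], sigma[0], sigma[1], psi])
            b_sum += b
            X_sum += X
            n_keep += 1

    draws = np.array(keep)
    return draws, b_sum / n_keep, X_sum / n_keep


def fit_dcrws(track: list[ArgosFix], config: RunConfig, seed: int) -> SSMFit:
    """Fit the switching CRW state-space model to one turtle's Argos track.

    A fixed ``seed`` gives bitwise-identical output. Tracks whose two-chain
    R-hat exceeds ``config.rhat_threshold`` on any parameter are returned
    flagged (``converged=False``) rather than raising, mirroring the
    SSM/non-SSM split of the downstream summaries.
    """
    track = [f for f in track if f.lc != "Z"]
    if len(track) < 20:
        raise ValueError(f"track too short for SSM: {len(track)} fixes (< 20)")
    span_days = (track[-1].timestamp - track[0].timestamp).total_seconds() / 86400.0
    if span_days < 5:
        raise ValueError(f"track too short for SSM: spans {span_days:.1f} days (< 5)")

    times, K, t_idx, j = regularize(track, config.ssm_interval_hours)
    y = np.array([[f.pos.lon, f.pos.lat] for f in track])
    nu = np.array([config.lc_error_table[f.lc][0] for f in track])
    scale = np.array([config.lc_error_table[f.lc][1] for f in track]) / KM_PER_DEGREE
    obs = (t_idx, j, y, nu, scale)

    # initialise latent path by linear interpolation of the fixes
    s_obs = t_idx - 1 + j
    grid = np.arange(K + 1, dtype=float)
    init_X = np.column_stack([np.interp(grid, s_obs, y[:, 0]), np.interp(grid, s_obs, y[:, 1])])

    ss = np.random.SeedSequence(seed)
    chains = []
    for child in ss.spawn(config.mcmc_chains):
        rng = np.random.default_rng(child)
        chains.append(_run_chain(obs, K, init_X, config, rng))

    all_draws = np.vstack([c[0] for c in chains])
    mean = {n: float(all_draws[:, i].mean()) for i, n in enumerate(PARAM_NAMES)}
    sd = {n: float(all_draws[:, i].std(ddof=1)) for i, n in enumerate(PARAM_NAMES)}
    rhat = {
        n: _gelman_rubin([c[0][:, i] for c in chains]) for i, n in enumerate(PARAM_NAMES)
    }
    converged = all(r <= config.rhat_threshold for r in rhat.values())
    if not converged:
        log.warning("fit_dcrws(%s): R-hat above %.2f on %s — SSM flagged not possible",
                    track[0].turtle_id, config.rhat_threshold,
                    [n for n, r in rhat.items() if r > config.rhat_threshold])

    b_mean = 1.0 + np.mean([c[1] for c in chains], axis=0)
    X_mean = np.mean([c[2] for c in chains], axis=0)
    fit = SSMFit(
        turtle_id=track[0].turtle_id,
        times=times,
        lon=X_mean[:, 0],
        lat=X_mean[:, 1],
        b_mean=b_mean,
        params=SSMParams(mean=mean, sd=sd),
        rhat=rhat,
        converged=converged,
        seed=seed,
    )
    fit.modes = classify_modes(fit, config.mode_cutoff_low, config.mode_cutoff_high)
    return fit


def _gelman_rubin(chains: list[np.ndarray]) -> float:
    """Two-chain potential scale reduction factor."""
    m = len(chains)
    n = min(len(c) for c in chains)
    arr = np.array([c[:n] for c in chains])
    W = arr.var(axis=1, ddof=1).mean()
    B_over_n = arr.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    V = (n - 1) / n * W + (1 + 1 / m) * B_over_n
    return float(math.sqrt(V / W))


def classify_modes(fit: SSMFit, low: float = 1.25, high: float = 1.75) -> list[str]:
    """Label each step from its posterior mean state index."""
    out = []
    for bm in fit.b_mean:
        if not 1.0 <= bm <= 2.0:
            raise ValueError(f"behavioural index {bm} outside [1, 2]")
        if bm < low:
            out.append(MODE_MIGRATION)
        elif bm > high:
            out.append(MODE_INTERNESTING)
        else:
            out.append(MODE_UNCERTAIN)
    return out


def extract_internesting_period(fit: SSMFit, capture_date: dt.date) -> InternestingPeriod | None:
    """Tagging date to the date of the final inter-nesting-labelled step.

    Interleaved migration steps are included (the period is a single span),
    and None is returned for a turtle that never left migration mode.
    """
    modes = fit.modes or classify_modes(fit)
    last = None
    for t, mode in zip(fit.times, modes):
        if mode == MODE_INTERNESTING:
            last = t
    if last is None:
        return None
    end = last.date()
    if end < capture_date:
        end = capture_date
    return InternestingPeriod(fit.turtle_id, capture_date, end)
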