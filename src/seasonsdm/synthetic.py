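"""Synthetic climate, occurrences and scenarios with a known seasonal niche.

The generator emulates the structure the chained family assumes: smooth
spatial climate fields with a seasonal cycle, presences sampled from a known
logistic niche over seasonal climate with a tunable carryover term on the
previous season's suitability, and scenario stacks produced by additive
deltas.  Each (variable, month) field is a latitudinal linear gradient plus a
spatially constant seasonal sinusoid plus spatially smoothed, month-specific
noise; the noise is what makes the niche patchy (and the hull-wide background
contrast informative), and its month-specificity is what gives the previous
season's suitability information the current season's months do not carry.

The true suitability follows the recursion

    q_s(cell) = logistic(beta0_s + beta_s . z_s(cell) + lambda * q_{s-1}(cell))

where z_s are the cell's z-scored seasonal-mean climate values, initialized by
one unrolled warm-up cycle through the four seasons.  lambda = 0 makes the
seasons independent; the default lambda = 2 is the carryover regime in which
the chained family holds an advantage over the independent one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid_climate import ClimateStack, GridSpec
from .occurrences import SEASONS, SEASON_MONTHS

#: Default fixture variables (a compact 4-variable analogue of the 11-code set).
SYNTH_VARIABLES: tuple[str, ...] = ("tasmean", "pr", "hurs", "clt")


def _sigmoid(x):
    return expit(x)


def field_parameters(variables=SYNTH_VARIABLES, seed: int = 0) -> dict[str, dict]:
    """The seeded per-variable field parameters :func:`simulate_climate` uses.

    Exposed so scenario construction can reason about the generative fields:
    ``gradient`` is the latitudinal slope (in value units per normalized
    latitude, sign alternating by variable index), ``amplitude`` and ``phase``
    parametrize the seasonal sinusoid.
    """
    out = {}
    for i, v in enumerate(variables):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        a = rng.uniform(0.3, 0.6) * (-1 if i % 2 else 1)
        b = rng.uniform(0.5, 1.0)
        phase = rng.uniform(0, 12)
        out[v] = {"gradient": a, "amplitude": b, "phase": phase}
    return out


def northward_deltas(stack: ClimateStack, truth: SyntheticTruth,
                     magnitude: float = 0.8) -> dict[str, float]:
    """Additive climate deltas that move the true niche poleward.

    For each season the suitability log-odds has a latitudinal trend
    g_s = sum_v beta_sv * slope(z_sv); a uniform log-odds offset of opposite
    sign to g_s moves that season's suitability boundary north (contraction
    from the south where the niche favors the north, expansion to the north
    where it favors the south).  The per-variable deltas are the least-squares
    solution of  sum_v beta_sv * delta_v / sd_sv = -magnitude * sign(g_s)
    over the four seasons — a scenario whose *known* effect on the generative
    niche is a northward optimum shift of ``magnitude`` logits.
    """
    z = seasonal_z(stack)
    n_rows, n_cols = stack.grid.shape
    lat_norm = np.linspace(-1.0, 1.0, n_rows)[:, None] * np.ones((1, n_cols))
    l = lat_norm[stack.valid]
    l_c = l - l.mean()
    A = np.zeros((len(SEASONS), len(stack.variables)))
    target = np.zeros(len(SEASONS))
    for si, s in enumerate(SEASONS):
        g = 0.0
        months = [m - 1 for m in SEASON_MONTHS[s]]
        for vi in range(len(stack.variables)):
            zv = z[s][vi][stack.valid]
            slope = float(np.dot(zv - zv.mean(), l_c) / np.dot(l_c, l_c))
            g += truth.beta[s][vi] * slope
            sd = stack.values[vi, months].mean(axis=0)[stack.valid].std()
            A[si, vi] = truth.beta[s][vi] / (sd if sd > 0 else 1.0)
        target[si] = -magnitude * np.sign(g)
    delta, *_ = np.linalg.lstsq(A, target, rcond=None)
    return {v: float(d) for v, d in zip(stack.variables, delta)}


def simulate_climate(
    grid: GridSpec,
    variables=SYNTH_VARIABLES,
    seed: int = 0,
    smoothness: float = 3.0,
    noise_amplitude: float = 6.0,
    period_label: str = "historical",
) -> ClimateStack:
    """Deterministic synthetic per-month climatologies on ``grid``.

    Per variable: a latitudinal gradient (seeded coefficient, alternating
    sign), a seasonal sinusoid (seeded amplitude and phase, spatially
    constant) and per-month smoothed Gaussian noise (sigma = ``smoothness``
    cells).  All cells are valid.  ``noise_amplitude`` multiplies white noise
    *before* smoothing, so the spatial standard deviation of the noise term
    shrinks as smoothness grows and vanishes in the smooth limit.
    """
    n_rows, n_cols = grid.shape
    lat_norm = np.linspace(-1.0, 1.0, n_rows)[:, None] * np.ones((1, n_cols))
    values = np.empty((len(variables), 12, n_rows, n_cols))
    for i, _v in enumerate(variables):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        # draw order must match field_parameters(), which re-derives these
        a = rng.uniform(0.3, 0.6) * (-1 if i % 2 else 1)   # gradient coefficient
        b = rng.uniform(0.5, 1.0)                          # sinusoid amplitude
        phase = rng.uniform(0, 12)
        for m in range(1, 13):
            noise = gaussian_filter(
                noise_amplitude * rng.standard_normal((n_rows, n_cols)),
                sigma=smoothness, mode="reflect",
            )
            values[i, m - 1] = a * lat_norm + b * np.sin(2 * np.pi * (m - phase) / 12) + noise
    return ClimateStack(grid, tuple(variables), values,
                        valid=np.ones(grid.shape, dtype=bool),
                        period_label=period_label)


@dataclass
class SyntheticTruth:
    """Generative niche parameters: the oracle every recovery test checks against."""

    beta0: dict[str, float]
    beta: dict[str, np.ndarray]          # season -> coefficients over variables
    lam: float = 2.0                     # carryover weight on q_{s-1}
    n: int = 2000                        # total presence records
    seed: int = 0
    deltas: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"beta0": self.beta0,
                "beta": {s: list(map(float, b)) for s, b in self.beta.items()},
                "lam": self.lam, "n": self.n, "seed": self.seed,
                "deltas": self.deltas}

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(beta0=dict(d["beta0"]),
                   beta={s: np.asarray(b, dtype=float) for s, b in d["beta"].items()},
                   lam=d["lam"], n=d["n"], seed=d["seed"], deltas=dict(d["deltas"]))


def default_truth(variables=SYNTH_VARIABLES, lam: float = 2.0, n: int = 2000,
                  seed: int = 0) -> SyntheticTruth:
    """Fixture niche: per season one main (+3.5) and one secondary (-2.0) driver.

    The main driver rotates with the season (season i loads on variable
    i mod V), so each season occupies a different part of climate space.  The
    intercept -6.5 keeps the suitable fraction near 10% so a hull-wide uniform
    background is a sharp contrast, while the climate term stays soft enough
    that the bounded carryover (lambda * q, swing at most lambda) retains
    weight near the niche boundary.
    """
    V = len(variables)
    beta0, beta = {}, {}
    for i, s in enumerate(SEASONS):
        b = np.zeros(V)
        b[i % V] = 3.5
        b[(i + 2) % V] = -2.0
        beta0[s] = -6.5
        beta[s] = b
    return SyntheticTruth(beta0=beta0, beta=beta, lam=lam, n=n, seed=seed)


def band_truth(variables=SYNTH_VARIABLES, lam: float = 2.0, n: int = 2000,
               seed: int = 0) -> SyntheticTruth:
    """Gradient-dominated niche: one strong driver per season, moderate intercept.

    Paired with a low ``noise_amplitude`` climate this yields a latitudinal
    band occupying roughly a third of the domain — the regime for checking
    directional (range-shift) fidelity of projections, as opposed to the
    patchy :func:`default_truth` regime used for discrimination recovery.
    """
    V = len(variables)
    beta0, beta = {}, {}
    for i, s in enumerate(SEASONS):
        b = np.zeros(V)
        b[i % V] = 6.0
        beta0[s] = -3.0
        beta[s] = b
    return SyntheticTruth(beta0=beta0, beta=beta, lam=lam, n=n, seed=seed)


def seasonal_z(stack: ClimateStack,
               reference: ClimateStack | None = None) -> dict[str, np.ndarray]:
    """Per-season, per-variable seasonal-mean fields z-scored over valid cells.

    With ``reference`` given, the z-scoring uses the reference stack's means
    and standard deviations (scenario fields expressed on the baseline scale,
    so additive climate deltas shift z instead of being normalized away).
    """
    ref = reference if reference is not None else stack
    out = {}
    for s in SEASONS:
        months = [m - 1 for m in SEASON_MONTHS[s]]
        mean = stack.values[:, months].mean(axis=1)          # (V, rows, cols)
        ref_mean = ref.values[:, months].mean(axis=1)
        z = np.empty_like(mean)
        for v in range(mean.shape[0]):
            vals = ref_mean[v][ref.valid]
            sd = vals.std()
            z[v] = (mean[v] - vals.mean()) / (sd if sd > 0 else 1.0)
        out[s] = z
    return out


def true_suitability(stack: ClimateStack, truth: SyntheticTruth,
                     reference: ClimateStack | None = None) -> dict[str, np.ndarray]:
    """Per-season true suitability rasters q_s from the logistic recursion."""
    z = seasonal_z(stack, reference)
    eta = {s: truth.beta0[s] + np.tensordot(truth.beta[s], z[s], axes=(0, 0))
           for s in SEASONS}
    q_prev = np.full(stack.grid.shape, 0.5)
    q: dict[str, np.ndarray] = {}
    for _cycle in range(2):  # cycle 0 is the unrolled warm-up
        for s in SEASONS:
            q[s] = _sigmoid(eta[s] + truth.lam * q_prev)
            q_prev = q[s]
    return q


def simulate_occurrences(stack: ClimateStack, truth: SyntheticTruth):
    """Draw presence records from the true niche.

    Per season, n_s cells are drawn multinomially (with replacement, mimicking
    clustered citizen-science records) with probability proportional to q_s
    over valid cells; each record gets a uniform month within the season,
    coordinates uniform within its cell, and a year in 2010-2024.  Returns
    (records DataFrame with lat/lon/year/month/season, true q_s rasters).
    """
    q = true_suitability(stack, truth)
    rng = np.random.default_rng(truth.seed)
    grid = stack.grid
    rows_v, cols_v = np.nonzero(stack.valid)
    n_per = [truth.n // 4 + (1 if i < truth.n % 4 else 0) for i in range(4)]
    frames = []
    for i, s in enumerate(SEASONS):
        weights = q[s][rows_v, cols_v]
        total = weights.sum()
        if not np.isfinite(total) or total <= 1e-12:
            raise ValueError(f"degenerate suitability in season {s}: all q ~ 0")
        idx = rng.choice(len(rows_v), size=n_per[i], replace=True, p=weights / total)
        r, c = rows_v[idx], cols_v[idx]
        lat = grid.lat_min + (r + rng.uniform(0, 1, len(r))) * grid.cell_size
        lon = grid.lon_min + (c + rng.uniform(0, 1, len(c))) * grid.cell_size
        months = rng.choice(SEASON_MONTHS[s], size=len(r))
        years = rng.integers(2010, 2025, size=len(r))
        frames.append(pd.DataFrame({"lat": lat, "lon": lon, "year": years,
                                    "month": months, "season": s}))
    records = pd.concat(frames, ignore_index=True)
    return records, q


def simulate_scenario(stack: ClimateStack, deltas: dict[str, float],
                      scenario_label: str = "scenario") -> ClimateStack:
    """Additive per-variable climate shift applied to all 12 months."""
    out = stack.copy()
    for var, delta in deltas.items():
        out.values[out.var_index(var)] += float(delta)
    out.scenario_label = scenario_label
    return out
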