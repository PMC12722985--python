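"""Lattice models of motile-cell access to a tumor boundary blocked by fences.

A single motile cell performs a continuous-time random walk on a square
lattice (lattice constant ``a`` = 10 μm, one cell diameter).  The strip is
periodic in x with width ``L``; the tumor boundary is the line y = 0 and is
absorbing (a hop down from the first row is a boundary hit); the top of the
strip at ``y_max`` reflects.  A *fence* is a row of immobile cells occupying
lattice sites just above the boundary: moves into fence sites are rejected
(the walker reflects, time still advances) and every rejection is counted.

Hop dynamics use exponential waiting times with per-direction rate D/a², so
the walk reproduces the diffusion coefficient ``D`` exactly in the mean.  A
chemotaxis variant adds a constant extra downward rate v/a for walkers
within a near-boundary drift region, modeling chemokine attraction whose
strength v(b) grows with the fence length b and saturates.

Analytic oracles for the no-fence case follow from the image method: the
probability that a walker starting a height y0 above an absorbing line
reaches it within T is erfc(y0 / sqrt(4 D T)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "LatticeConfig",
    "FenceSpec",
    "ChemotaxisConfig",
    "WalkOutcome",
    "AccessRatioResult",
    "analytic_hit_probability",
    "analytic_first_passage_density",
    "analytic_denominator",
    "make_fence",
    "make_hairy_fence",
    "start_grid",
    "simulate_walk",
    "simulate_walkers",
    "tumor_access_ratio",
    "nonreflecting_fraction_analytic",
    "reflection_histogram",
    "chemotactic_access_ratio",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry and kinetics of the strip.

    a      lattice constant, μm (cell size)
    L      strip width, μm (periodic in x)
    y_max  reflecting top of the strip, μm
    D      diffusion coefficient, μm²/min
    T      default time horizon, min
    S      samples per start site
    """

    a: float = 10.0
    L: float = 230.0
    y_max: float = 1500.0
    D: float = 2.5
    T: float = 3600.0
    S: int = 5000

    def __post_init__(self) -> None:
        if self.L % self.a or self.y_max % self.a:
            raise ValueError("L and y_max must be integer multiples of a")
        if self.D <= 0 or self.T <= 0:
            raise ValueError("D and T must be positive")

    @property
    def n_cols(self) -> int:
        return int(round(self.L / self.a))

    @property
    def n_rows(self) -> int:
        return int(round(self.y_max / self.a))

    @property
    def hop_rate(self) -> float:
        """Per-direction hop rate D/a², min⁻¹."""
        return self.D / self.a**2


@dataclass(frozen=True)
class FenceSpec:
    """A fence: a set of occupied (row, col) lattice sites.

    Rows are counted from 1 (the row of sites at y = a, adjacent to the
    boundary).  A linear fence occupies b/a consecutive sites in row 1,
    centered in x; a hairy fence has a random half of those sites displaced
    up to row 2 (their row-1 sites vacated).
    """

    b: float
    shape: str = "linear"
    sites: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class ChemotaxisConfig:
    """Near-boundary drift induced by a chemokine-secreting fence.

    Walkers at heights y <= drift_depth gain a constant extra downward hop
    rate v(b)/a, with v(b) = v_max * min(b, b_sat) / b_sat: drift speed
    grows linearly with fence length and saturates at v_max once the fence
    reaches b_sat.
    """

    drift_depth: float = 50.0  # μm
    v_max: float = 5.0  # μm/min
    b_sat: float = 150.0  # μm

    def v(self, b: float) -> float:
        return self.v_max * min(b, self.b_sat) / self.b_sat


@dataclass(frozen=True)
class WalkOutcome:
    hit: bool
    fpt: float  # min; only meaningful when hit
    n_reflections: int


@dataclass
class AccessRatioResult:
    """Tumor access ratio R_b(T) and its reflection decomposition."""

    b: float
    T: float
    n_hit_fence: int
    n_hit_nofence: float  # simulated count, or analytic expectation
    n_nr: int  # boundary hitters that never reflected off the fence
    n_r: int  # boundary hitters with >= 1 fence reflection
    ratio: float
    analytic_denominator: bool


# ---------------------------------------------------------------------------
# analytic oracles (image method, no fence)


def analytic_hit_probability(y0: float, D: float, T: float) -> float:
    """P(reach the absorbing line y=0 within T | start height y0 > 0)."""
    if y0 <= 0:
        raise ValueError("y0 must be positive")
    if T <= 0:
        return 0.0
    return float(special.erfc(y0 / np.sqrt(4.0 * D * T)))


def analytic_first_passage_density(t, y0: float, D: float):
    """First-passage time density y0/sqrt(4πDt³)·exp(-y0²/4Dt) (min⁻¹)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = y0 / np.sqrt(4.0 * np.pi * D * tp**3) * np.exp(-(y0**2) / (4.0 * D * tp))
    return out


def analytic_denominator(start_ys, D: float, T: float, S: int) -> float:
    """Expected number of boundary hits without a fence: S·Σᵢ erfc(yᵢ/√(4DT)).

    The closed form is the time integral of the boundary current summed over
    start heights, one term per start site with S walkers each.
    """
    ys = np.asarray(list(start_ys), dtype=float)
    if np.any(ys <= 0):
        raise ValueError("all start heights must be positive")
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0 or len(ys) == 0:
        return 0.0
    return float(S * np.sum(special.erfc(ys / np.sqrt(4.0 * D * T))))


# ---------------------------------------------------------------------------
# fences and start grids


def make_fence(b: float, config: LatticeConfig = LatticeConfig()) -> FenceSpec:
    """Linear fence of length b (μm), centered in x in the first row."""
    n = int(round(b / config.a))
    if not 0 <= n <= config.n_cols:
        raise ValueError("fence length must lie in [0, L]")
    start = (config.n_cols - n) // 2
    sites = frozenset((1, start + j) for j in range(n))
    return FenceSpec(b=float(b), shape="linear", sites=sites)


def make_hairy_fence(
    b: float, seed: int, config: LatticeConfig = LatticeConfig()
) -> FenceSpec:
    """Fence with a random half of its sites pushed up by one lattice site.

    The displaced sites move to row 2 and their row-1 positions are vacated,
    producing an irregular ("hairy") barrier of the same cell count.
    """
    base = make_fence(b, config)
    cols = sorted(c for (_, c) in base.sites)
    rng = np.random.default_rng(seed)
    n_up = len(cols) // 2
    up = set(rng.choice(cols, size=n_up, replace=False).tolist()) if n_up else set()
    sites = frozenset(
        (2, c) if c in up else (1, c) for c in cols
    )
    return FenceSpec(b=float(b), shape="hairy", sites=sites)


def start_grid(
    config: LatticeConfig,
    fence: FenceSpec | None = None,
    max_height: float = 90.0,
) -> np.ndarray:
    """(n, 2) array of (row, col) start sites: all columns, rows a..max_height.

    Sites occupied by ``fence`` are excluded (a walker cannot start inside
    the fence); pass ``fence=None`` for the full grid used by the no-fence
    reference run.
    """
    n_rows = int(max_height // config.a)
    occupied = fence.sites if fence is not None else frozenset()
    sites = [
        (r, c)
        for r in range(1, n_rows + 1)
        for c in range(config.n_cols)
        if (r, c) not in occupied
    ]
    return np.array(sites, dtype=np.int64)


# ---------------------------------------------------------------------------
# simulation engine


def _fence_grid(config: LatticeConfig, fence: FenceSpec | None) -> np.ndarray:
    grid = np.zeros((config.n_rows + 2, config.n_cols), dtype=bool)
    if fence is not None:
        for r, c in fence.sites:
            grid[r, c] = True
    return grid


def simulate_walkers(
    config: LatticeConfig,
    fence: FenceSpec | None,
    starts: np.ndarray,
    n_per_start: int,
    rng: np.random.Generator,
    T: float | None = None,
    drift_rate: float = 0.0,
    drift_rows: int = 0,
    return_rows: bool = False,
):
    """Simulate n_per_start walkers from every start site, vectorized.

    Returns (hit, fpt, n_reflections) arrays of length
    len(starts) * n_per_start, ordered start-major.  ``drift_rate`` is the
    extra downward hop rate v/a (min⁻¹) applied at rows <= drift_rows.
    With ``return_rows`` a fourth array holds each walker's final row
    (0 for absorbed walkers).
    """
    T = config.T if T is None else float(T)
    fg = _fence_grid(config, fence)
    starts = np.asarray(starts, dtype=np.int64).reshape(-1, 2)
    if fg[starts[:, 0], starts[:, 1]].any():
        raise ValueError("a start site lies inside the fence")
    if (starts[:, 0] < 1).any():
        raise ValueError("start rows must be >= 1 (y >= a)")

    n_walk = len(starts) * n_per_start
    row = np.repeat(starts[:, 0], n_per_start).astype(np.int64)
    col = np.repeat(starts[:, 1], n_per_start).astype(np.int64)
    t = np.zeros(n_walk)
    nref = np.zeros(n_walk, dtype=np.int64)
    orig = np.arange(n_walk)

    hit_out = np.zeros(n_walk, dtype=bool)
    fpt_out = np.full(n_walk, np.nan)
    nref_out = np.zeros(n_walk, dtype=np.int64)
    row_out = np.zeros(n_walk, dtype=np.int64)

    k = config.hop_rate
    W = config.n_cols
    R = config.n_rows
    use_drift = drift_rate > 0 and drift_rows > 0

    while len(row):
        if use_drift:
            rate = np.where(row <= drift_rows, 4.0 * k + drift_rate, 4.0 * k)
        else:
            rate = 4.0 * k
        t = t + rng.exponential(1.0, size=len(row)) / rate
        timed_out = t > T
        u = rng.random(len(row)) * rate

        absorbed = np.zeros(len(row), dtype=bool)
        live = ~timed_out

        # direction bands: [0,k) +x, [k,2k) -x, [2k,3k) +y, rest downward
        m = live & (u < k)
        nc = (col + 1) % W
        blocked = fg[row[m], nc[m]]
        nref[m] += blocked
        col[m] = np.where(blocked, col[m], nc[m])

        m = live & (u >= k) & (u < 2 * k)
        nc = (col - 1) % W
        blocked = fg[row[m], nc[m]]
        nref[m] += blocked
        col[m] = np.where(blocked, col[m], nc[m])

        m = live & (u >= 2 * k) & (u < 3 * k)
        nr = row[m] + 1
        at_top = nr > R
        blocked = np.zeros(len(nr), dtype=bool)
        ok = ~at_top
        blocked[ok] = fg[nr[ok], col[m][ok]]
        nref[m] += blocked
        row[m] = np.where(at_top | blocked, row[m], nr)

        m = live & (u >= 3 * k)
        nr = row[m] - 1
        hit_now = nr == 0
        blocked = np.zeros(len(nr), dtype=bool)
        ok = ~hit_now
        blocked[ok] = fg[nr[ok], col[m][ok]]
        nref[m] += blocked
        row[m] = np.where(hit_now | blocked, row[m], nr)
        absorbed[m] = hit_now

        finished = timed_out | absorbed
        if finished.any():
            idx = orig[finished]
            hit_out[idx] = absorbed[finished]
            fpt_out[idx] = np.where(absorbed[finished], t[finished], np.nan)
            nref_out[idx] = nref[finished]
            row_out[idx] = np.where(absorbed[finished], 0, row[finished])
            keep = ~finished
            row, col, t, nref, orig = (
                row[keep],
                col[keep],
                t[keep],
                nref[keep],
                orig[keep],
            )
    if return_rows:
        return hit_out, fpt_out, nref_out, row_out
    return hit_out, fpt_out, nref_out


def simulate_walk(
    config: LatticeConfig,
    fence: FenceSpec | None,
    start: tuple[int, int],
    seed: int,
    chemo: ChemotaxisConfig | None = None,
    T: float | None = None,
) -> WalkOutcome:
    """One trajectory from a single (row, col) start site."""
    drift_rate, drift_rows = 0.0, 0
    if chemo is not None:
        b = fence.b if fence is not None else 0.0
        drift_rate = chemo.v(b) / config.a
        drift_rows = int(chemo.drift_depth // config.a)
    rng = np.random.default_rng(seed)
    hit, fpt, nref = simulate_walkers(
        config,
        fence,
        np.array([start]),
        1,
        rng,
        T=T,
        drift_rate=drift_rate,
        drift_rows=drift_rows,
    )
    return WalkOutcome(bool(hit[0]), float(fpt[0]), int(nref[0]))


# ---------------------------------------------------------------------------
# experiment drivers


def nonreflecting_fraction_analytic(b: float, L: float) -> float:
    """Never-reflecting hitters over no-fence hitters: (L - b)/L."""
    if not 0 <= b <= L:
        raise ValueError("b must lie in [0, L]")
    return (L - b) / L


def tumor_access_ratio(
    config: LatticeConfig,
    b_values,
    T_values,
    seed: int = 0,
    S: int | None = None,
    analytic_denom: bool = True,
    hairy: bool = False,
) -> list[AccessRatioResult]:
    """R_b(T) over a grid of fence lengths and horizons.

    For each fence length one batch of walkers is simulated to max(T); the
    result for every smaller horizon follows by filtering first-passage
    times, since a trajectory's law up to absorption does not depend on the
    horizon.  The no-fence denominator runs from the *full* start grid
    (including sites a fence would occupy) and may be replaced by its exact
    closed form (default).
    """
    S = config.S if S is None else S
    b_values = [float(b) for b in np.atleast_1d(b_values)]
    T_values = sorted(float(T) for T in np.atleast_1d(T_values))
    T_max = T_values[-1]
    full_grid = start_grid(config)
    start_ys = full_grid[:, 0] * config.a

    denom: dict[float, float] = {}
    if analytic_denom:
        for T in T_values:
            denom[T] = analytic_denominator(start_ys, config.D, T, S)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        hit0, fpt0, _ = simulate_walkers(config, None, full_grid, S, rng, T=T_max)
        for T in T_values:
            denom[T] = float(np.sum(hit0 & (fpt0 <= T)))

    results = []
    for i, b in enumerate(b_values):
        fence = (
            make_hairy_fence(b, seed=seed + 7 * i + 1, config=config)
            if hairy
            else make_fence(b, config)
        )
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1 + i]))
        grid = start_grid(config, fence)
        hit, fpt, nref = simulate_walkers(config, fence, grid, S, rng, T=T_max)
        for T in T_values:
            sel = hit & (fpt <= T)
            n_hit = int(sel.sum())
            n_nr = int((sel & (nref == 0)).sum())
            results.append(
                AccessRatioResult(
                    b=b,
                    T=T,
                    n_hit_fence=n_hit,
                    n_hit_nofence=denom[T],
                    n_nr=n_nr,
                    n_r=n_hit - n_nr,
                    ratio=n_hit / denom[T] if denom[T] > 0 else np.nan,
                    analytic_denominator=analytic_denom,
                )
            )
    return results


def reflection_histogram(hit: np.ndarray, nref: np.ndarray) -> dict[int, float]:
    """Normalized histogram of fence-reflection counts among boundary hitters."""
    hitters = nref[np.asarray(hit, dtype=bool)]
    if len(hitters) == 0:
        raise ValueError("no boundary hitters: histogram undefined")
    counts = np.bincount(hitters)
    total = counts.sum()
    return {int(n): float(c) / total for n, c in enumerate(counts) if c}


def chemotactic_access_ratio(
    config: LatticeConfig,
    chemo: ChemotaxisConfig,
    b_values,
    T: float,
    seed: int = 0,
    S: int | None = None,
    analytic_denom: bool = True,
) -> list[AccessRatioResult]:
    """Access ratio when the fence also attracts walkers chemotactically.

    Numerator runs have the fence plus near-boundary drift at v(b); the
    denominator is the plain no-fence, no-drift diffusion from the full
    start grid (analytic by default).  With b = 0 there is no drift and the
    ratio is 1 up to Monte-Carlo error.
    """
    S = config.S if S is None else S
    b_values = [float(b) for b in np.atleast_1d(b_values)]
    full_grid = start_grid(config)
    start_ys = full_grid[:, 0] * config.a
    if analytic_denom:
        d = analytic_denominator(start_ys, config.D, T, S)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        hit0, fpt0, _ = simulate_walkers(config, None, full_grid, S, rng, T=T)
        d = float(np.sum(hit0))
    drift_rows = int(chemo.drift_depth // config.a)

    results = []
    for i, b in enumerate(b_values):
        fence = make_fence(b, config)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1 + i]))
        grid = start_grid(config, fence)
        hit, fpt, nref = simulate_walkers(
            config,
            fence,
            grid,
            S,
            rng,
            T=T,
            drift_rate=chemo.v(b) / config.a,
            drift_rows=drift_rows,
        )
        n_hit = int(hit.sum())
        n_nr = int((hit & (nref == 0)).sum())
        results.append(
            AccessRatioResult(
                b=b,
                T=T,
                n_hit_fence=n_hit,
                n_hit_nofence=d,
                n_nr=n_nr,
                n_r=n_hit - n_nr,
                ratio=n_hit / d if d > 0 else np.nan,
                analytic_denominator=analytic_denom,
            )
        )
    return results
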