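"""Kinetic Monte Carlo interacting-cell-system (ICS) model of the TME.

Agents live on a 100 × 100 lattice of 10 μm chambers covering a 1 mm² tissue
region.  Chamber capacity is expressed in quarter-units (capacity 4): an
activated CD8+ T cell takes 1 quarter, tumor cells and tumor-associated
macrophages (TAMs) take 2 each, and an implanted fence cell fills its
chamber completely and permanently.  Two cells are in contact when they
share a chamber or occupy edge-adjacent chambers.

Event channels (standard Gillespie direct method):

* tumor proliferation at rate k_C per cell, daughter placed in the first
  layer with space (same chamber, then 8, 16, 24 surrounding chambers),
  if necessary expelling a CD8 cell; aborted if the 49-chamber
  neighborhood is full;
* CD8 proliferation/recruitment at k_pro / r_rec, throttled by a logistic
  carrying-capacity term (1 - (N_TC + N_Te)/N_cc) and a Michaelis-Menten
  kill-feedback term D_C/(D_12 + D_C), where D_C counts tumor kills in the
  trailing memory window T_m;
* lysis of a contacted tumor cell at k_lys per CD8-tumor contact pair;
* CD8 exhaustion at k_exh (tumor contact) / k_exh_tam (TAM contact) per
  pair — exhausted cells are removed immediately;
* TAM recruitment (r_M) and death (gamma_M);
* motility hops for CD8 cells and TAMs, with the CD8 hop rate divided by
  ``tam_slowdown`` while in contact with a TAM; the lattice is periodic
  and a CD8 cell crossing the boundary is removed with probability 1/2.

All rate constants are package defaults tuned for ~10²-10³ agents on a
synthetic slide; every one is overridable through :class:`IcsParams`.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Slide

__all__ = [
    "IcsParams",
    "ChamberLattice",
    "PopulationTrajectory",
    "init_state",
    "implant_fences",
    "cd8_proliferation_rate",
    "cd8_recruitment_rate",
    "IcsSimulation",
    "run_simulation",
    "run_ensemble",
    "fence_implantation_experiment",
    "EXPERIMENT_PARAMS",
]

GRID = 100  # chambers per side
CHAMBER_UM = 10.0
CAPACITY = 4  # quarter-units per chamber
SIZE_Q = {"tumor": 2, "cd8": 1, "tam": 2, "fence": 4}


@dataclass(frozen=True)
class IcsParams:
    """Rate constants (min⁻¹ unless noted) and interaction parameters."""

    k_C: float = 2.0e-4  # tumor proliferation per cell (~2.4 d doubling)
    k_pro: float = 2.0e-3  # max CD8 proliferation per cell
    r_rec: float = 0.05  # max CD8 recruitment (per system)
    N_cc: int = 500  # CD8 carrying capacity
    D_12: float = 10.0  # Michaelis constant, kills per memory window
    T_m: float = 720.0  # kill-memory span, min (12 h)
    r_M: float = 0.01  # TAM recruitment (per system)
    gamma_M: float = 1.0e-4  # TAM death per cell
    D_mot: float = 0.1  # CD8 hop-attempt rate per cell
    D_mot_tam: float = 0.01  # TAM hop-attempt rate per cell
    tam_slowdown: float = 33.0  # CD8 hop-rate divisor under TAM contact
    boundary_removal_p: float = 0.5  # CD8 removal chance at boundary crossing
    k_lys: float = 1.0e-3  # lysis per CD8-tumor contact pair
    k_exh: float = 2.0e-4  # exhaustion per CD8-tumor contact pair
    k_exh_tam: float = 2.0e-4  # exhaustion per CD8-TAM contact pair
    count_removed_in_load: bool = True  # N_Te in the carrying-capacity term

    def __post_init__(self) -> None:
        for name in (
            "k_C", "k_pro", "r_rec", "D_12", "T_m", "r_M", "gamma_M",
            "D_mot", "D_mot_tam", "k_lys", "k_exh", "k_exh_tam",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tam_slowdown < 1:
            raise ValueError("tam_slowdown must be >= 1")
        if not 0.0 <= self.boundary_removal_p <= 1.0:
            raise ValueError("boundary_removal_p must lie in [0, 1]")


def cd8_proliferation_rate(
    N_TC: int, N_Te: int, N_cc: int, D_C: int, D_12: float, k_pro: float
) -> float:
    """Per-cell CD8 proliferation rate with carrying-capacity and
    kill-feedback throttles, floored at zero."""
    if N_cc <= 0:
        raise ValueError("N_cc must be positive")
    logistic = max(0.0, 1.0 - (N_TC + N_Te) / N_cc)
    feedback = D_C / (D_12 + D_C) if (D_12 + D_C) > 0 else 0.0
    return k_pro * logistic * feedback


def cd8_recruitment_rate(
    N_TC: int, N_Te: int, N_cc: int, D_C: int, D_12: float, r_rec: float
) -> float:
    """System-level CD8 recruitment rate; same throttles as proliferation."""
    return cd8_proliferation_rate(N_TC, N_Te, N_cc, D_C, D_12, r_rec)


class _Agents:
    """Growable position store with O(1) swap-remove."""

    def __init__(self, capacity: int = 64):
        self.x = np.zeros(capacity, dtype=np.int64)
        self.y = np.zeros(capacity, dtype=np.int64)
        self.n = 0

    def add(self, x: int, y: int) -> None:
        if self.n == len(self.x):
            self.x = np.concatenate([self.x, np.zeros_like(self.x)])
            self.y = np.concatenate([self.y, np.zeros_like(self.y)])
        self.x[self.n] = x
        self.y[self.n] = y
        self.n += 1

    def remove(self, i: int) -> None:
        self.n -= 1
        self.x[i] = self.x[self.n]
        self.y[i] = self.y[self.n]

    @property
    def xs(self) -> np.ndarray:
        return self.x[: self.n]

    @property
    def ys(self) -> np.ndarray:
        return self.y[: self.n]

    def copy(self) -> "_Agents":
        out = _Agents(max(64, len(self.x)))
        out.x[: self.n] = self.x[: self.n]
        out.y[: self.n] = self.y[: self.n]
        out.n = self.n
        return out


@dataclass
class ChamberLattice:
    """Lattice state: occupancy in quarter-units plus per-type agent stores."""

    occ: np.ndarray
    fence: np.ndarray
    tumor: _Agents
    cd8: _Agents
    tam: _Agents
    n_te: int = 0  # exhausted-and-removed CD8 tally

    @classmethod
    def empty(cls) -> "ChamberLattice":
        return cls(
            occ=np.zeros((GRID, GRID), dtype=np.int8),
            fence=np.zeros((GRID, GRID), dtype=bool),
            tumor=_Agents(),
            cd8=_Agents(),
            tam=_Agents(),
        )

    def copy(self) -> "ChamberLattice":
        return ChamberLattice(
            occ=self.occ.copy(),
            fence=self.fence.copy(),
            tumor=self.tumor.copy(),
            cd8=self.cd8.copy(),
            tam=self.tam.copy(),
            n_te=self.n_te,
        )

    def counts(self) -> dict[str, int]:
        return {
            "tumor": self.tumor.n,
            "cd8": self.cd8.n,
            "tam": self.tam.n,
            "n_te": self.n_te,
        }

    def place(self, kind: str, x: int, y: int) -> None:
        q = SIZE_Q[kind]
        if self.occ[x, y] + q > CAPACITY:
            raise ValueError(f"chamber ({x},{y}) cannot hold a {kind}")
        self.occ[x, y] += q
        getattr(self, kind).add(x, y)

    def check_invariants(self) -> None:
        assert (self.occ <= CAPACITY).all() and (self.occ >= 0).all()
        recount = np.zeros((GRID, GRID), dtype=np.int64)
        for kind in ("tumor", "cd8", "tam"):
            a = getattr(self, kind)
            np.add.at(recount, (a.xs, a.ys), SIZE_Q[kind])
        recount[self.fence] = CAPACITY
        assert (recount == self.occ).all()


# deterministic ring offsets: same chamber, 8, 16, 24 surrounding chambers
_RINGS: list[np.ndarray] = []
for radius in range(4):
    offs = [
        (dx, dy)
        for dx in range(-radius, radius + 1)
        for dy in range(-radius, radius + 1)
        if max(abs(dx), abs(dy)) == radius
    ]
    _RINGS.append(np.array(sorted(offs), dtype=np.int64).reshape(-1, 2))


def _nearest_free(
    state: ChamberLattice,
    x: int,
    y: int,
    q: int,
    rng: np.random.Generator,
    max_radius: int = 3,
    exclude_origin: bool = False,
) -> tuple[int, int] | None:
    """Nearest chamber (ring order) with >= q free quarters; random tie-break."""
    for radius in range(1 if exclude_origin else 0, max_radius + 1):
        offs = _RINGS[radius] if radius < len(_RINGS) else np.array(
            sorted(
                (dx, dy)
                for dx in range(-radius, radius + 1)
                for dy in range(-radius, radius + 1)
                if max(abs(dx), abs(dy)) == radius
            ),
            dtype=np.int64,
        ).reshape(-1, 2)
        cx = (x + offs[:, 0]) % GRID
        cy = (y + offs[:, 1]) % GRID
        ok = np.flatnonzero(state.occ[cx, cy] + q <= CAPACITY)
        if len(ok):
            j = ok[rng.integers(len(ok))] if len(ok) > 1 else ok[0]
            return int(cx[j]), int(cy[j])
    return None


def init_state(
    slide: Slide,
    agent_map: dict[str, str],
    seed: int = 0,
) -> ChamberLattice:
    """Discretize a slide into the chamber lattice.

    ``agent_map`` maps phenotype labels to agent kinds ('tumor', 'cd8',
    'tam'); unmapped phenotypes are ignored.  Cells are binned to the
    chamber containing their centroid; when a chamber would overflow the
    cell is relocated to the nearest chamber with space (deterministic ring
    scan, seeded tie-break).
    """
    state = ChamberLattice.empty()
    rng = np.random.default_rng(seed)
    step_x = slide.extent[0] / GRID
    step_y = slide.extent[1] / GRID
    for c in slide.cells:
        kind = agent_map.get(c.phenotype)
        if kind is None:
            continue
        if kind not in ("tumor", "cd8", "tam"):
            raise ValueError(f"unknown agent kind {kind!r}")
        x = min(GRID - 1, int(c.x / step_x))
        y = min(GRID - 1, int(c.y / step_y))
        q = SIZE_Q[kind]
        if state.occ[x, y] + q > CAPACITY:
            spot = _nearest_free(state, x, y, q, rng, max_radius=10)
            if spot is None:
                raise ValueError(f"cannot place cell {c.cell_id!r}: lattice full")
            x, y = spot
        state.place(kind, x, y)
    return state


def _relocate_or_remove(
    state: ChamberLattice, kind: str, idx: int, rng: np.random.Generator
) -> None:
    """Move an agent to the nearest OTHER chamber with space, or remove it."""
    agents = getattr(state, kind)
    x, y = int(agents.x[idx]), int(agents.y[idx])
    q = SIZE_Q[kind]
    state.occ[x, y] -= q
    spot = _nearest_free(state, x, y, q, rng, exclude_origin=True)
    agents.remove(idx)
    if spot is not None:
        state.occ[spot] += q
        agents.add(*spot)


def boundary_chambers(state: ChamberLattice) -> np.ndarray:
    """(n, 2) chambers holding tumor cells adjacent to a tumor-free chamber."""
    t = np.zeros((GRID, GRID), dtype=bool)
    t[state.tumor.xs, state.tumor.ys] = True
    nbr_free = (
        ~np.roll(t, 1, 0) | ~np.roll(t, -1, 0) | ~np.roll(t, 1, 1) | ~np.roll(t, -1, 1)
    )
    return np.argwhere(t & nbr_free)


def implant_fences(
    state: ChamberLattice,
    n_fences: int = 20,
    diameter_um: float = 50.0,
    seed: int = 0,
) -> ChamberLattice:
    """Implant disc-shaped frozen fences centered on tumor-boundary chambers.

    Each fence is a rasterized disc of chambers (~21 chambers at 50 μm
    diameter) that become fully occupied and immutable.  Agents already in
    those chambers are displaced to the nearest chamber with space (removed
    if none nearby), so implantation perturbs positions, not populations,
    wherever space allows.
    """
    if n_fences == 0:
        return state
    rng = np.random.default_rng(seed)
    centers = boundary_chambers(state)
    if len(centers) == 0:
        raise ValueError("no tumor-boundary chambers to anchor fences")
    pick = rng.choice(len(centers), size=min(n_fences, len(centers)), replace=False)
    r = diameter_um / 2.0 / CHAMBER_UM
    span = int(np.floor(r))
    disc = np.array(
        [
            (dx, dy)
            for dx in range(-span, span + 1)
            for dy in range(-span, span + 1)
            if dx * dx + dy * dy <= r * r
        ],
        dtype=np.int64,
    )
    for ci in pick:
        cx, cy = centers[ci]
        for dx, dy in disc:
            x, y = int((cx + dx) % GRID), int((cy + dy) % GRID)
            if state.fence[x, y]:
                continue
            # displace residents before freezing the chamber
            for kind in ("tumor", "cd8", "tam"):
                agents = getattr(state, kind)
                while True:
                    here = np.flatnonzero(
                        (agents.xs == x) & (agents.ys == y)
                    )
                    if len(here) == 0:
                        break
                    _relocate_or_remove(state, kind, int(here[0]), rng)
            state.fence[x, y] = True
            state.occ[x, y] = CAPACITY
    return state


class IcsSimulation:
    """One stochastic realization, advanced event by event (Gillespie).

    Per-type chamber-count grids for tumor cells and TAMs are maintained
    incrementally so per-step rate computation touches only the (small)
    agent arrays, not the full lattice.
    """

    def __init__(
        self,
        state: ChamberLattice,
        params: IcsParams = IcsParams(),
        seed: int = 0,
        debug_invariants: bool = False,
    ):
        self.state = state
        self.p = params
        self.rng = np.random.default_rng(seed)
        self.t = 0.0
        self.kill_log: deque[float] = deque()
        self.debug = debug_invariants
        self.tg = self._count_grid("tumor")
        self.mg = self._count_grid("tam")

    # -- bookkeeping -------------------------------------------------------

    def _count_grid(self, kind: str) -> np.ndarray:
        g = np.zeros((GRID, GRID), dtype=np.int32)
        a = getattr(self.state, kind)
        np.add.at(g, (a.xs, a.ys), 1)
        return g

    def _grid_of(self, kind: str) -> np.ndarray | None:
        return {"tumor": self.tg, "tam": self.mg}.get(kind)

    def _add(self, kind: str, x: int, y: int) -> None:
        s = self.state
        s.occ[x, y] += SIZE_Q[kind]
        getattr(s, kind).add(x, y)
        g = self._grid_of(kind)
        if g is not None:
            g[x, y] += 1

    def _remove_idx(self, kind: str, i: int) -> None:
        s = self.state
        agents = getattr(s, kind)
        x, y = int(agents.x[i]), int(agents.y[i])
        s.occ[x, y] -= SIZE_Q[kind]
        agents.remove(i)
        g = self._grid_of(kind)
        if g is not None:
            g[x, y] -= 1

    def _move_agent(self, kind: str, i: int, nx: int, ny: int) -> None:
        s = self.state
        agents = getattr(s, kind)
        x, y = int(agents.x[i]), int(agents.y[i])
        q = SIZE_Q[kind]
        s.occ[x, y] -= q
        s.occ[nx, ny] += q
        agents.x[i], agents.y[i] = nx, ny
        g = self._grid_of(kind)
        if g is not None:
            g[x, y] -= 1
            g[nx, ny] += 1

    def _relocate_or_remove(self, kind: str, i: int) -> None:
        agents = getattr(self.state, kind)
        x, y = int(agents.x[i]), int(agents.y[i])
        q = SIZE_Q[kind]
        spot = _nearest_free(self.state, x, y, q, self.rng, exclude_origin=True)
        if spot is None:
            self._remove_idx(kind, i)
        else:
            self._move_agent(kind, i, *spot)

    def _contact_counts(self, xs, ys, grid) -> np.ndarray:
        """Per-agent count of `grid` occupants in the plus-neighborhood."""
        c = grid[xs, ys].astype(np.int64)
        c += grid[(xs + 1) % GRID, ys]
        c += grid[(xs - 1) % GRID, ys]
        c += grid[xs, (ys + 1) % GRID]
        c += grid[xs, (ys - 1) % GRID]
        return c

    @property
    def d_c(self) -> int:
        """Tumor kills within the trailing memory window T_m."""
        while self.kill_log and self.kill_log[0] < self.t - self.p.T_m:
            self.kill_log.popleft()
        return len(self.kill_log)

    # -- one event ---------------------------------------------------------

    def step(self) -> bool:
        """Execute one event; returns False when the total rate is zero."""
        s, p = self.state, self.p
        n_t, n_c, n_m = s.tumor.n, s.cd8.n, s.tam.n

        if n_c:
            xs, ys = s.cd8.xs, s.cd8.ys
            tn = self._contact_counts(xs, ys, self.tg)
            if n_m:
                mn = self._contact_counts(xs, ys, self.mg)
                exh_w = p.k_exh * tn + p.k_exh_tam * mn
                mot_w = np.where(mn > 0, p.D_mot / p.tam_slowdown, p.D_mot)
            else:
                exh_w = p.k_exh * tn
                mot_w = np.full(n_c, p.D_mot)
            pairs_ct = int(tn.sum())
        else:
            tn = exh_w = mot_w = np.zeros(0)
            pairs_ct = 0
        d_c = self.d_c
        n_te_load = s.n_te if p.count_removed_in_load else 0

        g_pro = cd8_proliferation_rate(n_c, n_te_load, p.N_cc, d_c, p.D_12, p.k_pro)
        r_rec = cd8_recruitment_rate(n_c, n_te_load, p.N_cc, d_c, p.D_12, p.r_rec)

        rates = (
            p.k_C * n_t,  # 0 tumor proliferation
            g_pro * n_c,  # 1 CD8 proliferation
            r_rec,  # 2 CD8 recruitment
            p.r_M,  # 3 TAM recruitment
            p.gamma_M * n_m,  # 4 TAM death
            float(exh_w.sum()),  # 5 CD8 exhaustion
            p.k_lys * pairs_ct,  # 6 tumor lysis
            float(mot_w.sum()),  # 7 CD8 hop
            p.D_mot_tam * n_m,  # 8 TAM hop
        )
        cum = np.cumsum(rates)
        total = cum[-1]
        if total <= 0:
            return False
        self.t += self.rng.exponential(1.0 / total)
        ch = int(np.searchsorted(cum, self.rng.random() * total, side="right"))

        if ch == 0:
            self._tumor_proliferate()
        elif ch == 1:
            i = self.rng.integers(n_c)
            x, y = int(s.cd8.x[i]), int(s.cd8.y[i])
            if s.occ[x, y] + 1 <= CAPACITY:
                self._add("cd8", x, y)
        elif ch == 2:
            self._recruit("cd8")
        elif ch == 3:
            self._recruit("tam")
        elif ch == 4:
            if n_m:
                self._remove_idx("tam", int(self.rng.integers(n_m)))
        elif ch == 5:
            self._remove_idx("cd8", self._weighted_pick(exh_w))
            s.n_te += 1
        elif ch == 6:
            self._lyse(tn)
        elif ch == 7:
            self._hop("cd8", self._weighted_pick(mot_w))
        elif ch == 8:
            self._hop("tam", int(self.rng.integers(n_m)))

        if self.debug:
            s.check_invariants()
            assert (self.tg == self._count_grid("tumor")).all()
            assert (self.mg == self._count_grid("tam")).all()
        return True

    def _weighted_pick(self, w: np.ndarray) -> int:
        cum = np.cumsum(w)
        return int(np.searchsorted(cum, self.rng.random() * cum[-1], side="right"))

    def _tumor_proliferate(self) -> None:
        s = self.state
        i = self.rng.integers(s.tumor.n)
        x, y = int(s.tumor.x[i]), int(s.tumor.y[i])
        q = SIZE_Q["tumor"]
        for ring in _RINGS:
            cx = (x + ring[:, 0]) % GRID
            cy = (y + ring[:, 1]) % GRID
            ok = np.flatnonzero(s.occ[cx, cy] + q <= CAPACITY)
            if len(ok):
                j = ok[self.rng.integers(len(ok))] if len(ok) > 1 else ok[0]
                self._add("tumor", int(cx[j]), int(cy[j]))
                return
        # no room: try expelling one CD8 cell within the 49-chamber block
        for ring in _RINGS:
            cx = (x + ring[:, 0]) % GRID
            cy = (y + ring[:, 1]) % GRID
            roomy = np.flatnonzero(s.occ[cx, cy] - 1 + q <= CAPACITY)
            for j in roomy:
                tx, ty = int(cx[j]), int(cy[j])
                here = np.flatnonzero((s.cd8.xs == tx) & (s.cd8.ys == ty))
                if len(here):
                    self._relocate_or_remove("cd8", int(here[0]))
                    if s.occ[tx, ty] + q <= CAPACITY:
                        self._add("tumor", tx, ty)
                    return
        # 49-chamber neighborhood saturated: proliferation does not occur

    def _recruit(self, kind: str) -> None:
        s = self.state
        q = SIZE_Q[kind]
        free = np.argwhere(s.occ + q <= CAPACITY)
        if len(free) == 0:
            return
        x, y = free[self.rng.integers(len(free))]
        self._add(kind, int(x), int(y))

    def _lyse(self, tn: np.ndarray) -> None:
        s = self.state
        ci = self._weighted_pick(tn.astype(float))
        x, y = int(s.cd8.x[ci]), int(s.cd8.y[ci])
        nbrs = [(x, y), ((x + 1) % GRID, y), ((x - 1) % GRID, y),
                (x, (y + 1) % GRID), (x, (y - 1) % GRID)]
        weights = np.array([self.tg[a, b] for a, b in nbrs], dtype=float)
        k = self._weighted_pick(weights)
        tx, ty = nbrs[k]
        victim = np.flatnonzero((s.tumor.xs == tx) & (s.tumor.ys == ty))[0]
        self._remove_idx("tumor", int(victim))
        self.kill_log.append(self.t)

    def _hop(self, kind: str, i: int) -> None:
        s, p = self.state, self.p
        agents = getattr(s, kind)
        q = SIZE_Q[kind]
        x, y = int(agents.x[i]), int(agents.y[i])
        dx, dy = ((1, 0), (-1, 0), (0, 1), (0, -1))[self.rng.integers(4)]
        nx_raw, ny_raw = x + dx, y + dy
        crossing = not (0 <= nx_raw < GRID and 0 <= ny_raw < GRID)
        nx, ny = nx_raw % GRID, ny_raw % GRID
        if s.occ[nx, ny] + q > CAPACITY:
            return  # blocked (includes fence chambers, always full)
        if crossing and kind == "cd8" and self.rng.random() < p.boundary_removal_p:
            self._remove_idx(kind, i)
            return
        self._move_agent(kind, i, nx, ny)

    # -- runs --------------------------------------------------------------

    def run(self, duration: float, sample_times: np.ndarray) -> np.ndarray:
        """Advance to ``duration``, sampling populations at ``sample_times``.

        Returns an (n_times, 4) array of [tumor, cd8, tam, n_te].
        """
        out = np.zeros((len(sample_times), 4), dtype=np.int64)
        k = 0
        while k < len(sample_times):
            s = self.state
            cur = (s.tumor.n, s.cd8.n, s.tam.n, s.n_te)
            alive = self.step()
            t_new = self.t if alive else np.inf
            if t_new > duration:
                t_new = np.inf  # events past the horizon never observed
            while k < len(sample_times) and sample_times[k] < t_new:
                out[k] = cur
                k += 1
        return out


@dataclass
class PopulationTrajectory:
    """Sampled population time series for one realization."""

    times: np.ndarray
    tumor: np.ndarray
    cd8: np.ndarray
    tam: np.ndarray
    n_te: np.ndarray


def run_simulation(
    state: ChamberLattice,
    params: IcsParams = IcsParams(),
    duration: float = 3600.0,
    n_samples: int = 25,
    seed: int = 0,
) -> PopulationTrajectory:
    """One realization from a (copied) initial state."""
    times = np.linspace(0.0, duration, n_samples)
    sim = IcsSimulation(state.copy(), params, seed=seed)
    arr = sim.run(duration, times)
    return PopulationTrajectory(times, arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


def run_ensemble(
    state: ChamberLattice,
    params: IcsParams = IcsParams(),
    duration: float = 3600.0,
    n_runs: int = 300,
    n_samples: int = 25,
    seed: int = 0,
) -> tuple[list[PopulationTrajectory], pd.DataFrame]:
    """Independent seeded replicates from one initial state, plus the
    ensemble-mean time series (time in minutes)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    ss = np.random.SeedSequence(seed)
    trajs = [
        run_simulation(state, params, duration, n_samples, seed=child)
        for child in ss.spawn(n_runs)
    ]
    times = trajs[0].times
    mean = pd.DataFrame(
        {
            "time": times,
            "tumor": np.mean([tr.tumor for tr in trajs], axis=0),
            "cd8": np.mean([tr.cd8 for tr in trajs], axis=0),
            "tam": np.mean([tr.tam for tr in trajs], axis=0),
            "n_te": np.mean([tr.n_te for tr in trajs], axis=0),
        }
    )
    return trajs, mean


# canonical fence-implantation experiment: tumor disc + CD8 annulus, no TAMs
# (isolates the spatial-exclusion mechanism from TAM-mediated effects)
EXPERIMENT_PARAMS = IcsParams(
    D_mot=0.1,  # hop attempts at 0.1/min ≈ D = 2.5 μm²/min T-cell motility
    r_rec=0.01,
    k_pro=5.0e-4,
    r_M=0.0,
    k_lys=4.0e-3,
    N_cc=300,
)


def fence_implantation_experiment(
    n_runs: int = 300,
    duration: float = 3600.0,
    n_fences: int = 20,
    params: IcsParams = EXPERIMENT_PARAMS,
    seed: int = 0,
) -> dict[str, float]:
    """Paired ensembles with and without implanted boundary fences.

    Runs ``n_runs`` replicates of the same synthetic initial condition (a
    tumor disc ringed by cytotoxic CD8 cells) in a control and a
    fence-implanted variant and compares the ensemble-mean final tumor
    populations.  Returns the means, their difference, its standard error,
    and the relative increase.
    """
    from .synthetic import generate_ics_slide

    slide = generate_ics_slide(seed=seed)
    base = init_state(slide, {"Tumor": "tumor", "CD8": "cd8"}, seed=seed)
    fenced = implant_fences(base.copy(), n_fences=n_fences, seed=seed + 1)
    tr0, mean0 = run_ensemble(
        base, params, duration=duration, n_runs=n_runs, n_samples=5, seed=seed + 2
    )
    tr1, mean1 = run_ensemble(
        fenced, params, duration=duration, n_runs=n_runs, n_samples=5, seed=seed + 3
    )
    f0 = np.array([t.tumor[-1] for t in tr0], dtype=float)
    f1 = np.array([t.tumor[-1] for t in tr1], dtype=float)
    diff = float(f1.mean() - f0.mean())
    se = float(np.sqrt(f0.var(ddof=1) / len(f0) + f1.var(ddof=1) / len(f1)))
    return {
        "mean_tumor_unfenced": float(f0.mean()),
        "mean_tumor_fenced": float(f1.mean()),
        "diff": diff,
        "se_diff": se,
        "pct_increase": 100.0 * diff / f0.mean(),
        "n_runs": float(n_runs),
    }
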