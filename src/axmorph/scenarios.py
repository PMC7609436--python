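"""Gastrulation scenarios: tissue initialization, ingression, leader presets.

The simulated field is a 2D lattice with the anterior at row 0.  Axial
mesoderm is initialised as an anterior-most leading-edge arc, the prechordal
plate (ppl) behind it, the trailing notochordal plate (NC) as a column, and
lateral plate mesoderm (lpm) flanking and trailing; new lpm cells ingress
into a posterior zone at a fixed schedule while all mesodermal cells are
driven anteriorly by a linear potential.  A run stops when the lpm spans a
target anterior–posterior extension (default 400 µm) or when a maximum-MCS
guard fires.

Three leader scenarios modify the ppl relative to baseline:

* ``mobile_leaders``           – ppl motility doubled (a 100% increase).
* ``adhesive_leaders``         – ppl–ppl bond strength doubled.
* ``mobile_adhesive_leaders``  – both modifications together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cpm import _kernels
from .cpm.types import (
    MEDIUM_ID,
    N_TYPES,
    AdhesionMatrix,
    CellRecord,
    CellType,
    LatticeState,
    ModelParams,
    PotentialField,
)

__all__ = [
    "ScenarioConfig",
    "TissueLayout",
    "IngressionSchedule",
    "Trajectory",
    "SCENARIO_NAMES",
    "baseline_adhesion",
    "baseline_params",
    "default_layout",
    "build_initial_state",
    "ingress_cells",
    "scenario_preset",
    "lpm_ap_extent",
    "run_until_stop",
    "run_scenario",
    "replicate_study",
]

SCENARIO_NAMES = (
    "baseline",
    "mobile_leaders",
    "adhesive_leaders",
    "mobile_adhesive_leaders",
)


@dataclass
class IngressionSchedule:
    """Fixed-batch lpm ingression: ``batch`` new cells every ``interval`` MCS."""

    interval: int = 10
    batch: int = 10
    cell_type: CellType = CellType.LPM
    enabled: bool = True


@dataclass
class TissueLayout:
    """Initial tissue geometry in lattice-site coordinates.

    ``regions`` lists blocks (type, ap0, ap1, ml0, ml1) which are tiled with
    square cells of side ``cell_side``; ``ingression_zone`` is the posterior
    row band (ap0, ap1) that receives newly ingressing lpm cells.
    """

    shape: tuple[int, int]
    site_size: float
    cell_side: int
    regions: list[tuple[CellType, int, int, int, int]]
    ingression_zone: tuple[int, int]

    @property
    def cell_V0(self) -> int:
        return self.cell_side**2

    @property
    def cell_S0(self) -> int:
        # boundary-link count of an isolated square cell under the Moore
        # neighbourhood: 4 corner sites x 5 links + edge sites x 3 links
        s = self.cell_side
        return 20 + 12 * (s - 2) if s >= 2 else 8


def default_layout(scale: str = "desk") -> TissueLayout:
    """Study-condition layouts.

    ``desk`` is the replication scale (~100 x 200 sites at 2 µm/site,
    5 x 5-site cells); ``tiny`` is a seconds-scale smoke configuration that
    cannot reach the 400 µm stop and therefore guard-terminates.
    """
    if scale == "desk":
        return TissueLayout(
            shape=(230, 100),
            site_size=2.0,
            cell_side=5,
            regions=[
                (CellType.LEADING_EDGE, 107, 112, 5, 95),
                (CellType.PPL, 112, 122, 35, 65),
                (CellType.NC, 122, 172, 40, 60),
                (CellType.LPM, 112, 122, 5, 35),
                (CellType.LPM, 112, 122, 65, 95),
                (CellType.LPM, 122, 212, 5, 40),
                (CellType.LPM, 122, 212, 60, 95),
                (CellType.LPM, 172, 212, 40, 60),
            ],
            ingression_zone=(220, 230),
        )
    if scale == "tiny":
        return TissueLayout(
            shape=(48, 30),
            site_size=2.0,
            cell_side=3,
            regions=[
                (CellType.LEADING_EDGE, 12, 15, 3, 27),
                (CellType.PPL, 15, 21, 9, 21),
                (CellType.NC, 21, 33, 12, 18),
                (CellType.LPM, 15, 39, 3, 9),
                (CellType.LPM, 15, 39, 21, 27),
                (CellType.LPM, 33, 39, 12, 18),
            ],
            ingression_zone=(42, 48),
        )
    raise ValueError(f"unknown scale {scale!r}; expected 'desk' or 'tiny'")


@dataclass
class ScenarioConfig:
    """One leader scenario: which knobs differ from baseline, plus run control."""

    name: str
    ppl_mobility_multiplier: float = 1.0
    ppl_adhesion_multiplier: float = 1.0
    base_mobility: float = 1.0
    schedule: IngressionSchedule = field(default_factory=IngressionSchedule)
    stop_threshold_um: float = 400.0
    max_mcs: int = 3000
    save_interval: int = 100

    def __post_init__(self) -> None:
        if self.ppl_mobility_multiplier <= 0 or self.ppl_adhesion_multiplier <= 0:
            raise ValueError("scenario multipliers must be > 0")
        if self.stop_threshold_um < 0:
            raise ValueError("stop threshold must be >= 0")


def baseline_adhesion() -> AdhesionMatrix:
    """Baseline contact-energy matrix (calibrated, reduced units).

    Lower J = stronger adhesion.  Cell–medium contact costs 8 for every
    type.  The leading edge is by far the most cohesive tissue (negative
    homotypic contact energy: its cells rarely change neighbours); NC is
    moderately cohesive and adheres to the ppl ahead of it; the baseline
    (non-adhesive) ppl is no stickier to itself than to any other mesoderm;
    lpm is loose.
    """
    M, LE, PPL, NC, LPM = (int(t) for t in CellType)
    J = np.full((N_TYPES, N_TYPES), 5.5)
    J[M, :] = 8.0
    J[:, M] = 8.0
    J[M, M] = 0.0
    J[LE, LE] = -4.0
    J[PPL, PPL] = 5.5
    J[NC, NC] = 4.0
    J[LPM, LPM] = 6.0
    J[LE, PPL] = J[PPL, LE] = 4.0
    J[PPL, NC] = J[NC, PPL] = 3.0
    return AdhesionMatrix(J)


def baseline_params(seed: int = 0) -> ModelParams:
    """Calibrated baseline parameters (reduced units, mesodermal mobility 1)."""
    return ModelParams(
        lambda_V=5.0,
        lambda_S=0.05,
        lambda_M=5.0,
        T=8.0,
        seed=seed,
    )


def scenario_preset(
    name: str, seed: int = 0, scale: str = "desk"
) -> tuple[ScenarioConfig, AdhesionMatrix, ModelParams]:
    """Parameter bundle for a named scenario; only the stated knobs differ
    from baseline (ppl mobility x2 and/or ppl–ppl bond strength x2)."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; valid names: {SCENARIO_NAMES}")
    mobile = name in ("mobile_leaders", "mobile_adhesive_leaders")
    adhesive = name in ("adhesive_leaders", "mobile_adhesive_leaders")
    config = ScenarioConfig(
        name=name,
        ppl_mobility_multiplier=2.0 if mobile else 1.0,
        ppl_adhesion_multiplier=2.0 if adhesive else 1.0,
    )
    if scale == "tiny":
        config = replace(config, max_mcs=40, save_interval=10)
    J = baseline_adhesion()
    if adhesive:
        ppl = CellType.PPL
        J = J.with_bond_strength(ppl, ppl, 2.0 * J.bond_strength(ppl, ppl))
    params = baseline_params(seed=seed)
    if mobile:
        params.mu_by_type = dict(params.mu_by_type)
        params.mu_by_type[CellType.PPL] = 2.0 * config.base_mobility
    return config, J, params


def build_initial_state(layout: TissueLayout, params: ModelParams) -> LatticeState:
    """Tile each layout region with square cells and return the lattice."""
    state = LatticeState(layout.shape, layout.site_size)
    s = layout.cell_side
    next_id = 1
    for ctype, a0, a1, m0, m1 in layout.regions:
        if not (0 <= a0 < a1 <= layout.shape[0] and 0 <= m0 < m1 <= layout.shape[1]):
            raise ValueError(f"region {(ctype, a0, a1, m0, m1)} does not fit the grid")
        for a in range(a0, a1 - s + 1, s):
            for m in range(m0, m1 - s + 1, s):
                block = state.owner[a : a + s, m : m + s]
                if np.any(block != MEDIUM_ID):
                    raise ValueError("layout regions overlap")
                rec = CellRecord(
                    id=next_id,
                    type=ctype,
                    V0=layout.cell_V0,
                    S0=layout.cell_S0,
                )
                sites = np.array(
                    [(a + i, m + j) for i in range(s) for j in range(s)]
                )
                state.add_cell(rec, sites)
                next_id += 1
    state.recount(params)
    return state


def _free_anchors(
    owner: np.ndarray, zone: tuple[int, int], side: int
) -> list[tuple[int, int]]:
    a0, a1 = zone
    n_ap, n_ml = owner.shape
    a1 = min(a1, n_ap)
    anchors = []
    for a in range(a0, a1 - side + 1):
        for m in range(0, n_ml - side + 1):
            if np.all(owner[a : a + side, m : m + side] == MEDIUM_ID):
                anchors.append((a, m))
    return anchors


def ingress_cells(
    state: LatticeState,
    schedule: IngressionSchedule,
    rng: np.random.Generator,
    layout: TissueLayout,
) -> int:
    """Insert one batch of new lpm cells into the posterior ingression zone.

    Returns the number of cells actually placed (fewer than the batch when
    the zone is saturated; that is a skip, not an error).  Existing cells
    are untouched: new cells only occupy medium sites.
    """
    if not schedule.enabled:
        return 0
    placed = 0
    side = layout.cell_side
    next_id = max(state.cells, default=0) + 1
    for _ in range(schedule.batch):
        anchors = _free_anchors(state.owner, layout.ingression_zone, side)
        if not anchors:
            break
        a, m = anchors[rng.integers(len(anchors))]
        rec = CellRecord(
            id=next_id,
            type=schedule.cell_type,
            V0=layout.cell_V0,
            S0=layout.cell_S0,
        )
        sites = np.array([(a + i, m + j) for i in range(side) for j in range(side)])
        state.add_cell(rec, sites)
        # every link out of a freshly placed square block is heterolabel
        rec.S = layout.cell_S0
        next_id += 1
        placed += 1
    return placed


def lpm_ap_extent(state: LatticeState) -> float:
    """AP bounding-box extension of the lpm in µm (inclusive box; 0 if absent)."""
    tg = state.type_grid()
    rows = np.nonzero((tg == int(CellType.LPM)).any(axis=1))[0]
    if len(rows) == 0:
        return 0.0
    return float((rows[-1] - rows[0] + 1) * state.site_size)


@dataclass
class Trajectory:
    """Result of one scenario run."""

    final_state: LatticeState
    snapshots: list[tuple[int, np.ndarray]]
    trace: pd.DataFrame
    termination: str  # 'threshold' or 'guard'
    mcs: int
    config: ScenarioConfig


class _KernelState:
    """Flat-array view of a LatticeState for the numba kernel."""

    def __init__(self, state: LatticeState, params: ModelParams, field: PotentialField):
        n = max(state.cells, default=0)
        self.state = state
        self.owner = state.owner  # mutated in place
        self.type_by_id = np.zeros(n + 1, np.int64)
        self.V = np.zeros(n + 1, np.int64)
        self.V0 = np.zeros(n + 1, np.float64)
        self.S = np.zeros(n + 1, np.int64)
        self.S0 = np.zeros(n + 1, np.float64)
        self.removed = np.zeros(n + 1, np.int8)
        for cid, rec in state.cells.items():
            self.type_by_id[cid] = int(rec.type)
            self.V[cid] = rec.V
            self.V0[cid] = rec.V0
            self.S[cid] = rec.S
            self.S0[cid] = rec.S0
            self.removed[cid] = 1 if rec.removed else 0
        self.J = np.zeros((N_TYPES, N_TYPES))
        self.mu = params.mu_array()
        self.c_ap = field.values(state.shape[0])
        self.params = params

    def set_adhesion(self, J: AdhesionMatrix) -> None:
        self.J = np.ascontiguousarray(J.J)

    def grow(self) -> None:
        """Extend per-cell arrays after ingression added new records."""
        old_n = len(self.V)
        n = max(self.state.cells, default=0)
        extra = n + 1 - old_n
        if extra <= 0:
            return
        self.type_by_id = np.concatenate([self.type_by_id, np.zeros(extra, np.int64)])
        self.V = np.concatenate([self.V, np.zeros(extra, np.int64)])
        self.V0 = np.concatenate([self.V0, np.zeros(extra, np.float64)])
        self.S = np.concatenate([self.S, np.zeros(extra, np.int64)])
        self.S0 = np.concatenate([self.S0, np.zeros(extra, np.float64)])
        self.removed = np.concatenate([self.removed, np.zeros(extra, np.int8)])
        for cid, rec in self.state.cells.items():
            if cid >= old_n:
                self.type_by_id[cid] = int(rec.type)
                self.V[cid] = rec.V
                self.V0[cid] = rec.V0
                self.S[cid] = rec.S
                self.S0[cid] = rec.S0

    def writeback(self) -> None:
        for cid, rec in self.state.cells.items():
            rec.V = int(self.V[cid])
            rec.S = int(self.S[cid])
            rec.removed = bool(self.removed[cid]) or rec.V == 0


_NO_LOG_INT = np.zeros((0, 6), np.int64)
_NO_LOG_F = np.zeros(0, np.float64)


def run_until_stop(
    state: LatticeState,
    scenario: ScenarioConfig,
    J: AdhesionMatrix,
    params: ModelParams,
    layout: TissueLayout,
    field: PotentialField | None = None,
    seed: int | None = None,
    compute_energy: bool = True,
) -> Trajectory:
    """Run MCS + ingression until the lpm AP extension reaches the stop
    threshold or the max-MCS guard fires.

    The extension is measured every MCS, so a threshold termination happens
    at the first step whose snapshot crosses the threshold (a threshold of 0
    terminates before any MCS).  Fixed seed and config give a bit-identical
    trajectory.
    """
    if field is None:
        field = PotentialField(slope=1.0, anterior_favourable=True)
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)  # ingression placement
    _kernels.seed_kernel_rng(seed % (2**31 - 1))  # Monte Carlo stream

    ks = _KernelState(state, params, field)
    ks.set_adhesion(J)
    stats = np.zeros((1, 3), np.float64)

    rows = []
    snapshots: list[tuple[int, np.ndarray]] = [(0, state.owner.copy())]
    termination = "guard"
    mcs = 0
    while True:
        extent = lpm_ap_extent(state)
        if extent >= scenario.stop_threshold_um:
            termination = "threshold"
            break
        if mcs >= scenario.max_mcs:
            termination = "guard"
            break
        if (
            scenario.schedule.enabled
            and scenario.schedule.interval > 0
            and mcs % scenario.schedule.interval == 0
            and mcs > 0
        ):
            ingress_cells(state, scenario.schedule, rng, layout)
            ks.grow()
        _kernels.run_sweeps(
            ks.owner,
            ks.type_by_id,
            ks.V,
            ks.V0,
            ks.S,
            ks.S0,
            ks.removed,
            ks.J,
            ks.mu,
            params.lambda_V,
            params.lambda_S,
            params.lambda_M,
            ks.c_ap,
            params.T,
            1,
            stats,
            compute_energy,
            _NO_LOG_INT,
            _NO_LOG_F,
            0,
        )
        mcs += 1
        state.step_count += 1
        rows.append(
            {
                "mcs": mcs,
                "energy": stats[0, 2],
                "attempts": int(stats[0, 0]),
                "accepted": int(stats[0, 1]),
                "lpm_extent_um": lpm_ap_extent(state),
            }
        )
        if mcs % scenario.save_interval == 0:
            snapshots.append((mcs, state.owner.copy()))
    ks.writeback()
    if snapshots[-1][0] != mcs:
        snapshots.append((mcs, state.owner.copy()))
    trace = pd.DataFrame(
        rows, columns=["mcs", "energy", "attempts", "accepted", "lpm_extent_um"]
    )
    return Trajectory(
        final_state=state,
        snapshots=snapshots,
        trace=trace,
        termination=termination,
        mcs=mcs,
        config=scenario,
    )


def run_scenario(name: str, seed: int = 0, scale: str = "desk", **kwargs) -> Trajectory:
    """Convenience wrapper: preset + layout + initial state + run."""
    config, J, params = scenario_preset(name, seed=seed, scale=scale)
    for k, v in kwargs.items():
        setattr(config, k, v)
    layout = default_layout(scale)
    state = build_initial_state(layout, params)
    return run_until_stop(state, config, J, params, layout, seed=seed)


def replicate_study(
    scenario_names: list[str] | tuple[str, ...] = SCENARIO_NAMES,
    n_seeds: int = 10,
    scale: str = "desk",
    seed0: int = 0,
) -> pd.DataFrame:
    """Run every scenario over ``n_seeds`` seeds and tabulate morphometrics.

    Per run: NC AP length / ML width / aspect ratio, ppl aspect ratio,
    leading-edge front curvature class, termination reason and MCS count.
    """
    from . import morphometrics as mm

    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    rows = []
    for name in scenario_names:
        for i in range(n_seeds):
            seed = seed0 + i
            traj = run_scenario(name, seed=seed, scale=scale)
            st = traj.final_state
            nc_ap, nc_ml, nc_ar = mm.tissue_extents(st, CellType.NC)
            ppl_ap, ppl_ml, ppl_ar = mm.tissue_extents(st, CellType.PPL)
            try:
                front = mm.front_curvature_class(st, CellType.LEADING_EDGE)
            except ValueError:
                front = "undefined"
            rows.append(
                {
                    "scenario": name,
                    "seed": seed,
                    "nc_ap_um": nc_ap,
                    "nc_ml_um": nc_ml,
                    "nc_aspect": nc_ar,
                    "ppl_aspect": ppl_ar,
                    "front_class": front,
                    "termination": traj.termination,
                    "mcs": traj.mcs,
                }
            )
    return pd.DataFrame(rows)
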