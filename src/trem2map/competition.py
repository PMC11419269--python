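"""Sequential competition binding: simulation and quantification.

In a sequential BLI competition experiment the receptor-loaded sensor is
dipped first into competitor (or buffer for the control arm), moved to
buffer to dissociate, then dipped into the probe ligand.  If the two
ligands occupy the same surface, pre-bound competitor lowers the free
receptor available during the second association; the readout is

    percent decrease = 100 * (1 - mag2_with / mag2_without)

where ``mag2`` is the second-association step height.  Because the sensor
moves to a fresh well for the second association, the competitor's solution
concentration is zero there and pre-bound competitor can only dissociate --
which is what makes the order of addition matter: a slowly dissociating
first ligand blocks far more effectively than a fast one.

The shared-site model is single-site competitive Langmuir kinetics,

    dR_A/dt = kon_A c_A (Rmax - R_A - R_B) - koff_A R_A     (and symmetric in B),

integrated across all phases; with ``shared_site=False`` the two ligands
bind independent sites and simply add.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import KineticParams, Sensorgram

__all__ = [
    "CompetitionSchedule",
    "CompetitionAssay",
    "CompetitionResult",
    "percent_decrease",
    "classify_block",
    "extract_assoc2_magnitude",
    "simulate_competition",
    "titration_block_curve",
]

PHASE_BASELINE = "baseline"
PHASE_ASSOC1 = "assoc1"
PHASE_DISSOC1 = "dissoc1"
PHASE_ASSOC2 = "assoc2"


@dataclass(frozen=True)
class CompetitionSchedule:
    """Phase durations (s) of a sequential-binding cycle."""

    baseline: float = 60.0
    assoc1: float = 300.0
    dissoc1: float = 120.0
    assoc2: float = 300.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if min(self.assoc1, self.dissoc1, self.assoc2, self.dt) <= 0:
            raise ValueError("phase durations and dt must be positive")
        if self.baseline < 0:
            raise ValueError("baseline duration must be >= 0")


@dataclass(frozen=True)
class CompetitionAssay:
    """One arm of a sequential competition experiment.

    ``conc_first = 0`` is the no-competitor control arm, which must be
    measured alongside every comparison.
    """

    first_ligand: str
    conc_first: float  # molar; 0 = control arm
    second_ligand: str
    conc_second: float  # molar
    schedule: CompetitionSchedule = CompetitionSchedule()

    def __post_init__(self) -> None:
        if self.conc_first < 0 or self.conc_second <= 0:
            raise ValueError("conc_first must be >= 0 and conc_second > 0")


@dataclass(frozen=True)
class CompetitionResult:
    mag2_with: float
    mag2_without: float
    percent_decrease: float
    classification: str  # "full-block" | "partial" | "none"


def percent_decrease(mag2_with: float, mag2_without: float) -> float:
    """Percent decrease of the second-association signal vs the control arm.

    Clipped to at most 100: a negative second-association step (pre-bound
    competitor dissociating faster than the probe binds) is complete block.
    Enhancement (negative decrease) is passed through with a warning.
    """
    if mag2_without <= 0:
        raise ValueError("control-arm magnitude must be positive")
    value = min(100.0, 100.0 * (1.0 - mag2_with / mag2_without))
    if value < 0:
        warnings.warn(
            f"second association enhanced rather than blocked ({value:.1f}% decrease)"
        )
    return value


def classify_block(
    pct: float, full_block: float = 90.0, no_block: float = 10.0
) -> str:
    """Narrative label for a percent decrease (cutoffs configurable)."""
    if pct >= full_block:
        return "full-block"
    if pct < no_block:
        return "none"
    return "partial"


def extract_assoc2_magnitude(trace: Sensorgram, phase: str = PHASE_ASSOC2) -> float:
    """Second-association step height: signal at phase end minus phase start.

    Measuring the step rather than the absolute level insulates the metric
    against incomplete dissociation of the first ligand.
    """
    mask = trace.phase_mask(phase)
    sig = trace.signal[mask]
    return float(sig[-1] - sig[0])


def _integrate_phase(
    r0: np.ndarray,
    t_grid: np.ndarray,
    params_a: KineticParams,
    params_b: KineticParams,
    c_a: float,
    c_b: float,
    shared_site: bool,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Integrate the two-species occupancy ODE over one phase."""

    def rhs(_t: float, r: np.ndarray) -> list[float]:
        ra, rb = r
        if shared_site:
            free_a = free_b = params_a.rmax - ra - rb
        else:
            free_a, free_b = params_a.rmax - ra, params_b.rmax - rb
        return [
            params_a.kon * c_a * free_a - params_a.koff * ra,
            params_b.kon * c_b * free_b - params_b.koff * rb,
        ]

    if len(t_grid) == 1:
        return r0[:, None].repeat(1, axis=1)
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        r0,
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"competition integrator failed: {sol.message}")
    return sol.y


def simulate_competition(
    shared_site: bool,
    params_a: KineticParams,
    params_b: KineticParams,
    assay: CompetitionAssay,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Sensorgram:
    """Simulate a sequential competition trace (A first, then B).

    For the shared-site model both ligands draw on the same pool of sites
    (``params_a.rmax`` is the shared capacity and ``params_b.rmax`` is
    ignored); total occupancy R_A + R_B never exceeds it.  The per-species
    occupancies are returned in ``metadata["r_a"]`` / ``metadata["r_b"]``.
    """
    if shared_site and params_a.rmax != params_b.rmax:
        warnings.warn("shared-site model uses params_a.rmax as the common capacity")
    sched = assay.schedule
    edges = np.cumsum([sched.baseline, sched.assoc1, sched.dissoc1, sched.assoc2])
    n = int(round(edges[-1] / sched.dt)) + 1
    time = np.arange(n) * sched.dt
    phase = np.empty(n, dtype=object)
    phase[time < edges[0]] = PHASE_BASELINE
    phase[(time >= edges[0]) & (time < edges[1])] = PHASE_ASSOC1
    phase[(time >= edges[1]) & (time < edges[2])] = PHASE_DISSOC1
    phase[time >= edges[2]] = PHASE_ASSOC2
    phase = phase.astype(str)

    # The sensor moves to a new well at each phase change: competitor A is
    # present only during assoc1, probe B only during assoc2.
    concentrations = {
        PHASE_BASELINE: (0.0, 0.0),
        PHASE_ASSOC1: (assay.conc_first, 0.0),
        PHASE_DISSOC1: (0.0, 0.0),
        PHASE_ASSOC2: (0.0, assay.conc_second),
    }
    r_a = np.zeros(n)
    r_b = np.zeros(n)
    state = np.array([0.0, 0.0])
    for name in (PHASE_BASELINE, PHASE_ASSOC1, PHASE_DISSOC1, PHASE_ASSOC2):
        mask = phase == name
        if not mask.any():
            continue
        t_grid = time[mask]
        c_a, c_b = concentrations[name]
        y = _integrate_phase(
            state, t_grid, params_a, params_b, c_a, c_b, shared_site, rtol, atol
        )
        r_a[mask], r_b[mask] = y[0], y[1]
        state = y[:, -1].copy()

    return Sensorgram(
        time=time,
        signal=r_a + r_b,
        phase=phase,
        analyte_conc=assay.conc_second,
        sensor_id=f"{assay.first_ligand}->{assay.second_ligand}",
        metadata={
            "r_a": r_a,
            "r_b": r_b,
            "shared_site": shared_site,
            "conc_first": assay.conc_first,
            "conc_second": assay.conc_second,
        },
    )


def titration_block_curve(
    arms: list[tuple[float, Sensorgram]],
    complete_block_level: float = 95.0,
    full_block: float = 90.0,
    no_block: float = 10.0,
) -> pd.DataFrame:
    """Percent-decrease table over a competitor titration.

    ``arms`` pairs each first-ligand concentration with its trace and must
    include the control arm (concentration 0), be strictly increasing, and
    contain no duplicates.  The returned frame carries the lowest
    concentration achieving ``complete_block_level`` in
    ``DataFrame.attrs["complete_block_conc"]`` (None if never reached).
    """
    if not arms:
        raise ValueError("empty titration")
    concs = [c for c, _ in arms]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("first-ligand concentrations must be strictly increasing")
    if concs[0] != 0.0:
        raise ValueError("titration must include the no-competitor control arm (conc 0)")
    mag0 = extract_assoc2_magnitude(arms[0][1])
    rows = []
    for conc, trace in arms:
        mag = extract_assoc2_magnitude(trace)
        pct = percent_decrease(mag, mag0)
        rows.append(
            {
                "conc_first": conc,
                "assoc2_magnitude": mag,
                "percent_decrease": pct,
                "classification": classify_block(pct, full_block, no_block),
            }
        )
    table = pd.DataFrame(rows)
    blocked = table[table.percent_decrease >= complete_block_level]
    table.attrs["complete_block_conc"] = (
        float(blocked.conc_first.iloc[0]) if not blocked.empty else None
    )
    table.attrs["complete_block_level"] = complete_block_level
    return table
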