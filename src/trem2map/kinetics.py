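"""1:1 Langmuir sensorgram model, referencing, and K_D fitting.

Biolayer interferometry reports an optical thickness shift (nm) as analyte
binds a sensor-immobilized receptor.  For a 1:1 interaction with rate
constants ``kon`` (1/(M s)) and ``koff`` (1/s) at analyte concentration
``c``, the association phase follows

    R(t) = Req * (1 - exp(-kobs * t)),   kobs = kon*c + koff,
    Req  = Rmax * c / (c + KD),          KD   = koff / kon,

and the dissociation phase decays as ``R_end * exp(-koff * (t - t_d))``.

Two K_D routes are provided, mirroring standard instrument-software
workflows: a steady-state fit of equilibrium responses to the one-site
hyperbola, and a global kinetic fit of full traces across a concentration
series (with a two-component comparison fit used to flag biphasic data for
which a 1:1 model is not appropriate, e.g. oligomeric analytes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .variants import BindingSentinel

__all__ = [
    "PhaseSchedule",
    "Sensorgram",
    "KineticParams",
    "SteadyStateSeries",
    "FitResult",
    "ReqEstimate",
    "FoldChange",
    "simulate_one_to_one",
    "double_reference_subtract",
    "extract_Req",
    "fit_steady_state",
    "fit_kinetic_one_to_one",
    "fold_change",
]

PHASE_BASELINE = "baseline"
PHASE_ASSOCIATION = "association"
PHASE_DISSOCIATION = "dissociation"


@dataclass(frozen=True)
class PhaseSchedule:
    """Durations (s) of the three phases of a plain kinetics cycle."""

    baseline: float = 60.0
    association: float = 300.0
    dissociation: float = 300.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if min(self.association, self.dissociation, self.dt) <= 0:
            raise ValueError("association, dissociation and dt must be positive")
        if self.baseline < 0:
            raise ValueError("baseline duration must be >= 0")


@dataclass
class Sensorgram:
    """Annotated time/signal trace for one sensor at one analyte concentration."""

    time: np.ndarray
    signal: np.ndarray
    phase: np.ndarray  # per-sample phase label
    analyte_conc: float  # molar
    sensor_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.phase = np.asarray(self.phase)
        if not (len(self.time) == len(self.signal) == len(self.phase)):
            raise ValueError("time, signal and phase must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def phase_names(self) -> list[str]:
        seen: list[str] = []
        for p in self.phase:
            if p not in seen:
                seen.append(str(p))
        return seen

    def phase_mask(self, name: str) -> np.ndarray:
        mask = self.phase == name
        if not mask.any():
            raise ValueError(f"sensorgram has no {name!r} phase (has {self.phase_names})")
        return mask

    def phase_start_time(self, name: str) -> float:
        return float(self.time[self.phase_mask(name)][0])


@dataclass(frozen=True)
class KineticParams:
    """1:1 interaction parameters; ``kd`` is always derived as koff/kon."""

    kon: float  # 1/(M s)
    koff: float  # 1/s
    rmax: float  # response units

    def __post_init__(self) -> None:
        if min(self.kon, self.koff, self.rmax) <= 0:
            raise ValueError("kon, koff and rmax must all be positive")

    @property
    def kd(self) -> float:
        return self.koff / self.kon

    @classmethod
    def from_kd(cls, kd: float, koff: float = 0.01, rmax: float = 1.0) -> "KineticParams":
        """Factor a K_D into (kon, koff); default koff = 0.01 1/s."""
        if kd <= 0:
            raise ValueError("KD must be positive")
        return cls(kon=koff / kd, koff=koff, rmax=rmax)


@dataclass(frozen=True)
class SteadyStateSeries:
    concentrations: np.ndarray  # molar
    req: np.ndarray  # response units
    source: str = "simulated"  # "simulated" | "extracted"

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", np.asarray(self.concentrations, float))
        object.__setattr__(self, "req", np.asarray(self.req, float))
        if self.concentrations.shape != self.req.shape:
            raise ValueError("concentrations and Req must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class FitResult:
    model: str  # "steady-state" | "one-to-one" | "two-component"
    kd: float  # molar
    rmax: float
    kon: float | None = None
    koff: float | None = None
    stderr: dict[str, float] | None = None
    residual_rms: float = math.nan
    converged: bool = False
    biphasic_flag: bool = False


@dataclass(frozen=True)
class ReqEstimate:
    req: float
    equilibrated: bool


@dataclass(frozen=True)
class FoldChange:
    """K_D ratio vs wild type, always expressed as a factor >= 1."""

    factor: float | None
    direction: str  # "affinity-increase" | "affinity-decrease" | "unchanged" | "not-computable"


def one_to_one_curve(
    params: KineticParams, conc: float, schedule: PhaseSchedule
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form 1:1 trace on the schedule's grid: (time, signal, phase)."""
    if conc < 0:
        raise ValueError("analyte concentration must be >= 0")
    t_total = schedule.baseline + schedule.association + schedule.dissociation
    n = int(round(t_total / schedule.dt)) + 1
    time = np.arange(n) * schedule.dt
    t_a = schedule.baseline
    t_d = schedule.baseline + schedule.association
    phase = np.where(
        time < t_a,
        PHASE_BASELINE,
        np.where(time < t_d, PHASE_ASSOCIATION, PHASE_DISSOCIATION),
    )
    signal = np.zeros(n)
    if conc > 0:
        kobs = params.kon * conc + params.koff
        req = params.rmax * conc / (conc + params.kd)
        assoc = phase == PHASE_ASSOCIATION
        signal[assoc] = req * (1.0 - np.exp(-kobs * (time[assoc] - t_a)))
        r_end = req * (1.0 - np.exp(-kobs * schedule.association))
        dissoc = phase == PHASE_DISSOCIATION
        signal[dissoc] = r_end * np.exp(-params.koff * (time[dissoc] - t_d))
    return time, signal, phase


def simulate_one_to_one(
    params: KineticParams,
    conc: float,
    schedule: PhaseSchedule = PhaseSchedule(),
    sensor_id: str = "",
) -> Sensorgram:
    """Noise-free 1:1 Langmuir sensorgram (baseline/association/dissociation)."""
    time, signal, phase = one_to_one_curve(params, conc, schedule)
    return Sensorgram(
        time=time,
        signal=signal,
        phase=phase,
        analyte_conc=conc,
        sensor_id=sensor_id,
        metadata={"kon": params.kon, "koff": params.koff, "rmax": params.rmax, "kd": params.kd},
    )


def double_reference_subtract(
    sample: Sensorgram,
    loaded_in_buffer: Sensorgram,
    reference_in_analyte: Sensorgram,
    time_tolerance: float = 1e-9,
) -> Sensorgram:
    """Double-reference correction: sample - (loaded pin in buffer) - (bare pin in analyte).

    All three traces must share a common time grid (within
    ``time_tolerance``).  Each trace is first baseline-aligned (its
    baseline-phase mean subtracted, when a baseline phase is present)
    so constant offsets cancel exactly.
    """
    for other in (loaded_in_buffer, reference_in_analyte):
        if len(other) != len(sample) or np.max(np.abs(other.time - sample.time)) > time_tolerance:
            raise ValueError("reference trace time grid does not match the sample grid")

    def aligned(sg: Sensorgram) -> np.ndarray:
        if (sg.phase == PHASE_BASELINE).any():
            return sg.signal - sg.signal[sg.phase == PHASE_BASELINE].mean()
        return sg.signal

    corrected = aligned(sample) - aligned(loaded_in_buffer) - aligned(reference_in_analyte)
    return replace(
        sample,
        signal=corrected,
        metadata={**sample.metadata, "double_referenced": True},
    )


def extract_Req(
    sensorgram: Sensorgram,
    window_fraction: float = 0.1,
    equilibration_tolerance: float = 0.01,
    phase: str = PHASE_ASSOCIATION,
) -> ReqEstimate:
    """Equilibrium response: mean of the final ``window_fraction`` of association.

    The estimate is flagged not-equilibrated when the trace is still rising:
    the relative difference between the final window's mean and the mean of
    the preceding equal-sized window exceeds ``equilibration_tolerance``.
    """
    mask = sensorgram.phase_mask(phase)
    assoc = sensorgram.signal[mask]
    n_window = int(round(len(assoc) * window_fraction))
    if n_window < 3:
        raise ValueError(
            f"association window of {n_window} samples is too short (need >= 3); "
            "lengthen the phase or raise window_fraction"
        )
    last = assoc[-n_window:]
    prev = assoc[-2 * n_window : -n_window] if len(assoc) >= 2 * n_window else assoc[:n_window]
    req = float(last.mean())
    scale = max(abs(req), np.finfo(float).tiny)
    equilibrated = abs(req - float(prev.mean())) / scale <= equilibration_tolerance
    return ReqEstimate(req=req, equilibrated=equilibrated)


def fit_steady_state(series: SteadyStateSeries) -> FitResult:
    """Fit Req(c) = Rmax c / (c + KD) by nonlinear least squares.

    Requires at least four concentration points.  Initial values follow
    robust defaults: KD from the concentration nearest half-maximal Req,
    Rmax from the largest observed response times 1.2; both bounded
    positive.  A series with no curvature (all points effectively in the
    linear regime) is reported as non-converged rather than returning a
    spuriously precise K_D.
    """
    c = series.concentrations
    r = series.req
    if len(c) < 4:
        raise ValueError("steady-state fit needs at least 4 concentration points")
    rmax0 = float(r.max()) * 1.2
    kd0 = float(c[np.argmin(np.abs(r - rmax0 / 2.4))])
    model = lmfit.Model(lambda conc, rmax, kd: rmax * conc / (conc + kd))
    params = model.make_params(
        rmax=dict(value=rmax0, min=0.0),
        kd=dict(value=kd0, min=0.0),
    )
    result = model.fit(r, params, conc=c)
    kd = float(result.params["kd"].value)
    rmax = float(result.params["rmax"].value)
    rms = float(np.sqrt(np.mean(result.residual**2)))
    # Without points above the half-saturation point the hyperbola is not
    # identifiable: KD runs away past the probed range and the covariance
    # matrix degenerates.
    converged = bool(result.success) and result.errorbars and kd < 100 * c.max()
    stderr = None
    if converged:
        stderr = {
            "kd": float(result.params["kd"].stderr),
            "rmax": float(result.params["rmax"].stderr),
        }
    return FitResult(
        model="steady-state",
        kd=kd,
        rmax=rmax,
        stderr=stderr,
        residual_rms=rms,
        converged=converged,
    )


def _one_to_one_residuals(
    p: lmfit.Parameters, sensorgrams: list[Sensorgram], global_rmax: bool
) -> np.ndarray:
    out = []
    for i, sg in enumerate(sensorgrams):
        rmax = p["rmax"].value if global_rmax else p[f"rmax_{i}"].value
        params = KineticParams(kon=p["kon"].value, koff=p["koff"].value, rmax=rmax)
        out.append(sg.signal - _predict_on_grid(params, sg))
    return np.concatenate(out)


def _predict_on_grid(params: KineticParams, sg: Sensorgram) -> np.ndarray:
    """1:1 model evaluated on a sensorgram's own grid and phase labels."""
    pred = np.zeros(len(sg))
    if sg.analyte_conc <= 0:
        return pred
    assoc = sg.phase == PHASE_ASSOCIATION
    dissoc = sg.phase == PHASE_DISSOCIATION
    t_a = sg.time[assoc][0]
    kobs = params.kon * sg.analyte_conc + params.koff
    req = params.rmax * sg.analyte_conc / (sg.analyte_conc + params.kd)
    pred[assoc] = req * (1.0 - np.exp(-kobs * (sg.time[assoc] - t_a)))
    if dissoc.any():
        t_d = sg.time[dissoc][0]
        t_assoc_end = sg.time[assoc][-1]
        r_end = req * (1.0 - np.exp(-kobs * (t_assoc_end - t_a)))
        pred[dissoc] = r_end * np.exp(-params.koff * (sg.time[dissoc] - t_d))
    return pred


def _two_component_residuals(p: lmfit.Parameters, sensorgrams: list[Sensorgram]) -> np.ndarray:
    pa = KineticParams(p["kon1"].value, p["koff1"].value, p["rmax1"].value)
    pb = KineticParams(p["kon2"].value, p["koff2"].value, p["rmax2"].value)
    out = []
    for sg in sensorgrams:
        out.append(sg.signal - _predict_on_grid(pa, sg) - _predict_on_grid(pb, sg))
    return np.concatenate(out)


def fit_kinetic_one_to_one(
    sensorgrams: list[Sensorgram],
    global_rmax: bool = True,
    check_biphasic: bool = True,
    biphasic_factor: float = 2.0,
    koff_init: float = 0.01,
) -> FitResult:
    """Global 1:1 kinetic fit (shared kon/koff) across a concentration series.

    Requires traces at >= 3 analyte concentrations.  ``biphasic_flag`` is
    set when an unconstrained two-component fit reduces the residual RMS by
    more than ``biphasic_factor`` -- the signature of heterogeneous
    (e.g. oligomeric-analyte) binding for which the 1:1 K_D is not
    meaningful.
    """
    concs = {sg.analyte_conc for sg in sensorgrams if sg.analyte_conc > 0}
    if len(concs) < 3:
        raise ValueError(
            f"kinetic fit needs >= 3 distinct positive concentrations, got {len(concs)}"
        )
    # initialize KD from the concentration closest to half-maximal response
    maxima = {sg.analyte_conc: sg.signal.max() for sg in sensorgrams if sg.analyte_conc > 0}
    top = max(maxima.values())
    kd0 = min(maxima, key=lambda c: abs(maxima[c] - top / 2))
    rmax0 = top * 1.2

    p = lmfit.Parameters()
    p.add("koff", value=koff_init, min=1e-8)
    p.add("kon", value=koff_init / kd0, min=1e-2)
    if global_rmax:
        p.add("rmax", value=rmax0, min=1e-12)
    else:
        for i in range(len(sensorgrams)):
            p.add(f"rmax_{i}", value=rmax0, min=1e-12)

    minimizer = lmfit.Minimizer(
        _one_to_one_residuals, p, fcn_args=(sensorgrams, global_rmax)
    )
    result = minimizer.minimize(method="leastsq")
    rp = result.params
    kon, koff = float(rp["kon"].value), float(rp["koff"].value)
    rmax = float(rp["rmax"].value) if global_rmax else float(
        np.mean([rp[f"rmax_{i}"].value for i in range(len(sensorgrams))])
    )
    rms = float(np.sqrt(np.mean(result.residual**2)))
    converged = bool(result.success) and bool(result.errorbars)
    stderr = None
    if converged and rp["kon"].stderr is not None:
        stderr = {k: float(rp[k].stderr) for k in ("kon", "koff") if rp[k].stderr is not None}

    biphasic = False
    if check_biphasic:
        p2 = lmfit.Parameters()
        for suffix, factor in (("1", 3.0), ("2", 1 / 3.0)):
            p2.add(f"kon{suffix}", value=kon * factor, min=1e-2)
            p2.add(f"koff{suffix}", value=koff * factor, min=1e-8)
            p2.add(f"rmax{suffix}", value=rmax / 2, min=1e-12)
        result2 = lmfit.Minimizer(
            _two_component_residuals, p2, fcn_args=(sensorgrams,)
        ).minimize(method="leastsq")
        rms2 = float(np.sqrt(np.mean(result2.residual**2)))
        if rms2 > 0 and rms / rms2 > biphasic_factor:
            biphasic = True
        if not converged and rms2 == 0 and rms > 0:
            biphasic = True

    if not converged:
        warnings.warn(
            f"1:1 kinetic fit did not converge cleanly (residual RMS {rms:.3g})"
        )
    return FitResult(
        model="one-to-one",
        kd=koff / kon,
        rmax=rmax,
        kon=kon,
        koff=koff,
        stderr=stderr,
        residual_rms=rms,
        converged=converged,
        biphasic_flag=biphasic,
    )


def fold_change(
    kd_variant: float | BindingSentinel,
    kd_wt: float,
) -> FoldChange:
    """K_D fold change of a variant versus wild type.

    The factor is always the ratio >= 1; the direction is derived from the
    K_D ratio alone (a lower variant K_D is an affinity increase).
    Sentinel inputs (no binding detected, not fit, ...) yield a typed
    not-computable result instead of NaN arithmetic.
    """
    if kd_wt is None or isinstance(kd_wt, BindingSentinel):
        raise ValueError("wild-type KD must be a positive number")
    if kd_wt <= 0:
        raise ValueError("wild-type KD must be positive")
    if kd_variant is None or isinstance(kd_variant, BindingSentinel):
        return FoldChange(factor=None, direction="not-computable")
    if kd_variant <= 0:
        raise ValueError("variant KD must be positive")
    if kd_variant == kd_wt:
        return FoldChange(factor=1.0, direction="unchanged")
    if kd_variant < kd_wt:
        return FoldChange(factor=kd_wt / kd_variant, direction="affinity-increase")
    return FoldChange(factor=kd_variant / kd_wt, direction="affinity-decrease")
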