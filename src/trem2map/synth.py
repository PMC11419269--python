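"""Synthetic inputs for the pipeline: sensorgram families, biphasic traces,
competition arms, and sequence pairs with planted complementary windows.

Everything here is a pure function of its parameters and an explicit seed;
generator settings are embedded in each output's metadata so any fixture
can be regenerated bit-exactly.  Defaults mirror the study conditions: a
1:1 Langmuir model at the tabulated K_D values, two-fold concentration
series (62.5-1000 nM for the cytokine/complement ligands, 0.012-50 uM for
apolipoprotein titrations), additive Gaussian noise in response units, and
optional linear baseline drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .competition import CompetitionAssay, CompetitionSchedule, simulate_competition
from .hydropathy import HydropathyScale, kyte_doolittle
from .kinetics import KineticParams, PhaseSchedule, Sensorgram, simulate_one_to_one

__all__ = [
    "GeneratorSpec",
    "NANOMOLAR_SERIES",
    "APOE4_SERIES",
    "make_sensorgram_family",
    "make_biphasic_family",
    "make_competition_arms",
    "make_complementary_pair",
]

#: Two-fold series 62.5-1000 nM (molar), used for C1q- and IL-34-style runs.
NANOMOLAR_SERIES = tuple(1000e-9 / 2**i for i in reversed(range(5)))

#: Two-fold series 0.0122-50 uM (molar), spanning the apoE4 titration range.
APOE4_SERIES = tuple(50e-6 / 2**i for i in reversed(range(13)))


@dataclass(frozen=True)
class GeneratorSpec:
    """Reproducible settings for sensorgram generation (seed is mandatory)."""

    seed: int
    noise_sd: float = 0.0  # response units
    drift_slope: float = 0.0  # response units per second
    concentrations: tuple[float, ...] = NANOMOLAR_SERIES
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _decorate(
    sg: Sensorgram, spec: GeneratorSpec, rng: np.random.Generator, extra: dict
) -> Sensorgram:
    signal = sg.signal + spec.drift_slope * sg.time
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=len(sg))
    return replace(
        sg,
        signal=signal,
        metadata={
            **sg.metadata,
            **extra,
            "seed": spec.seed,
            "noise_sd": spec.noise_sd,
            "drift_slope": spec.drift_slope,
        },
    )


def make_sensorgram_family(
    kd: float,
    spec: GeneratorSpec,
    koff: float = 0.01,
    rmax: float = 1.0,
) -> list[Sensorgram]:
    """One 1:1 trace per concentration in the series, with noise and drift.

    Only K_D is reported by the binding tables, so any (kon, koff)
    factorization is admissible; the default fixes koff = 0.01 1/s.
    """
    if not spec.concentrations:
        raise ValueError("empty concentration series")
    params = KineticParams.from_kd(kd, koff=koff, rmax=rmax)
    rng = np.random.default_rng(spec.seed)
    family = []
    for i, conc in enumerate(spec.concentrations):
        sg = simulate_one_to_one(params, conc, spec.schedule, sensor_id=f"sim-{i}")
        family.append(_decorate(sg, spec, rng, {"generator": "one-to-one"}))
    return family


def make_biphasic_family(
    params_fast: KineticParams,
    params_slow: KineticParams,
    weight: float,
    spec: GeneratorSpec,
) -> list[Sensorgram]:
    """Two-component traces: pointwise ``w * fast + (1-w) * slow``.

    Emulates heterogeneous (oligomeric-analyte) binding that defeats a 1:1
    fit.  Identical components are accepted but warned about, since the
    mixture then degenerates to a single 1:1 trace.
    """
    if not 0.0 < weight < 1.0:
        raise ValueError("weight must be in (0, 1)")
    if not spec.concentrations:
        raise ValueError("empty concentration series")
    if (params_fast.kon, params_fast.koff) == (params_slow.kon, params_slow.koff):
        import warnings

        warnings.warn("identical components: biphasic mixture reduces to 1:1")
    rng = np.random.default_rng(spec.seed)
    family = []
    for i, conc in enumerate(spec.concentrations):
        fast = simulate_one_to_one(params_fast, conc, spec.schedule)
        slow = simulate_one_to_one(params_slow, conc, spec.schedule)
        mixed = replace(
            fast,
            signal=weight * fast.signal + (1 - weight) * slow.signal,
            sensor_id=f"biphasic-{i}",
            metadata={"weight": weight},
        )
        family.append(_decorate(mixed, spec, rng, {"generator": "biphasic"}))
    return family


def make_competition_arms(
    shared_site: bool,
    params_a: KineticParams,
    params_b: KineticParams,
    first_concentrations: tuple[float, ...],
    conc_second: float,
    spec: GeneratorSpec,
    first_ligand: str = "A",
    second_ligand: str = "B",
    schedule: CompetitionSchedule | None = None,
) -> list[tuple[float, Sensorgram]]:
    """Competition traces over a first-ligand titration (0 = control arm)."""
    if not first_concentrations:
        raise ValueError("empty titration series")
    schedule = schedule or CompetitionSchedule()
    rng = np.random.default_rng(spec.seed)
    arms = []
    for conc in first_concentrations:
        assay = CompetitionAssay(
            first_ligand=first_ligand,
            conc_first=conc,
            second_ligand=second_ligand,
            conc_second=conc_second,
            schedule=schedule,
        )
        trace = simulate_competition(shared_site, params_a, params_b, assay)
        arms.append((conc, _decorate(trace, spec, rng, {"generator": "competition"})))
    return arms


def make_complementary_pair(
    motif_length: int,
    target_length: int,
    insert_position: int,
    seed: int,
    scale: HydropathyScale | None = None,
    min_pair_difference: float = 4.6,
) -> tuple[str, str, dict]:
    """A random motif and target with one planted anticomplementary window.

    The target background is uniform over the 20 residues; at
    ``insert_position`` (1-based) the motif's hydropathy complement is
    planted, choosing per position the opposite-sign residue with the
    largest index difference.  By construction the planted window scores
    100 % sign match and per-pair |dH| >= 4.9 on the Kyte-Doolittle scale
    (so C >= 0.544, clearing the 0.5 cutoff).  A ``min_pair_difference``
    above what the scale can deliver is rejected.

    Returns (motif sequence, target sequence, truth record); the truth
    record stores the planted coordinates and the window's expected scores.
    """
    scale = scale or kyte_doolittle()
    if motif_length < 2:
        raise ValueError("motif_length must be >= 2")
    if insert_position < 1 or insert_position + motif_length - 1 > target_length:
        raise ValueError("planted window does not fit in the target")
    rng = np.random.default_rng(seed)
    residues = sorted(scale.values)
    motif = "".join(rng.choice(residues, size=motif_length))

    def complement(residue: str) -> str:
        h = scale[residue]
        opposite = [r for r in residues if scale[r] * h < 0]
        best = max(opposite, key=lambda r: abs(scale[r] - h))
        if abs(scale[best] - h) < min_pair_difference:
            raise ValueError(
                f"no residue of opposite sign to {residue} reaches "
                f"|dH| >= {min_pair_difference}"
            )
        return best

    window = "".join(complement(r) for r in motif)
    background = list(rng.choice(residues, size=target_length))
    start0 = insert_position - 1
    background[start0 : start0 + motif_length] = window
    target = "".join(background)

    from .hydropathy import complementarity, percent_match, binarize

    mp = binarize(motif, scale)
    wp = binarize(window, scale)
    truth = {
        "seed": seed,
        "start": insert_position,
        "end": insert_position + motif_length - 1,
        "motif": motif,
        "window": window,
        "percent_match": percent_match(mp.signs, wp.signs),
        "complementarity": complementarity(mp.indices, wp.indices),
    }
    return motif, target, truth
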