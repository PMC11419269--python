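"""The TREM2 point-mutant panel: parsing, sequence editing, site classes.

Variant names follow the panel-label convention ``W44D/L69D/L71D`` (wild-type
residue, 1-based precursor position, substituted residue, slash-joined).
Positions are classified into the receptor's putative binding surfaces:
the hydrophobic site on the CDR loops, the electropositive basic site, two
basic-adjacent positions, the crosslinking-identified "site 2", and the
Alzheimer's-disease risk positions.

The packaged fixture ``data/variant_kd.tsv`` carries every panel member
named in the binding tables with its per-ligand equilibrium constants;
qualitative table entries ("N.B.D.", "No Binding", ...) are preserved as
typed sentinels, never coerced to numbers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import pandas as pd

__all__ = [
    "Mutation",
    "TREM2Variant",
    "BindingSentinel",
    "SITE_MAP",
    "AD_RISK_POSITIONS",
    "parse_variant_name",
    "format_variant_name",
    "apply_mutations",
    "classify_site",
    "load_variant_table",
    "parse_kd_entry",
]

#: Position -> binding-surface class on the TREM2 Ig domain.
SITE_MAP: dict[str, frozenset[int]] = {
    "hydrophobic": frozenset({41, 44, 69, 70, 71, 74, 89}),
    "basic": frozenset({46, 47, 62, 76, 77, 78}),
    "basic-adjacent": frozenset({75, 85}),
    "site2": frozenset({122, 123}),
}

#: Positions whose variants are late-onset AD risk alleles (flagged on top
#: of any structural-site membership).
AD_RISK_POSITIONS = frozenset({47, 62, 87, 96})

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class BindingSentinel(Enum):
    """Qualitative binding-table entries that are not numeric K_D values."""

    NO_BINDING_DETECTED = "N.B.D."
    NO_BINDING = "No Binding"
    DECREASED_BINDING = "Decreased binding"
    BINDING_NOT_FIT = "Binding (not fit)"

    def __str__(self) -> str:  # renders as the printed table text
        return self.value


@dataclass(frozen=True, order=True)
class Mutation:
    wt_residue: str = field(compare=False)
    position: int
    mut_residue: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.wt_residue == self.mut_residue:
            raise ValueError(f"mutation at {self.position} does not change the residue")

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"

    def inverted(self) -> "Mutation":
        return Mutation(self.mut_residue, self.position, self.wt_residue)


@dataclass(frozen=True)
class TREM2Variant:
    name: str
    mutations: tuple[Mutation, ...]
    site_class: str
    ad_risk: bool = False

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)


def parse_variant_name(name: str) -> TREM2Variant:
    """Parse a slash-delimited variant name; ``"WT"`` has no mutations.

    Mutations are returned in ascending position order regardless of input
    order; duplicate positions are rejected.
    """
    name = name.strip()
    if name.upper() == "WT":
        return TREM2Variant(name="WT", mutations=(), site_class="wild-type")
    mutations = []
    for token in name.split("/"):
        m = _MUTATION_RE.match(token.strip())
        if m is None:
            raise ValueError(f"malformed mutation token {token!r} in {name!r}")
        mutations.append(Mutation(m.group(1), int(m.group(2)), m.group(3)))
    positions = [m.position for m in mutations]
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate mutated position in {name!r}")
    mutations.sort()
    site_class = classify_site(frozenset(positions))
    return TREM2Variant(
        name=format_variant_name(mutations),
        mutations=tuple(mutations),
        site_class=site_class,
        ad_risk=bool(set(positions) & AD_RISK_POSITIONS),
    )


def format_variant_name(mutations: tuple[Mutation, ...] | list[Mutation]) -> str:
    if not mutations:
        return "WT"
    return "/".join(str(m) for m in mutations)


def apply_mutations(sequence: str, variant: TREM2Variant) -> str:
    """Apply a variant's substitutions to a precursor sequence.

    The observed residue must match the expected wild-type residue at every
    mutated position -- a mismatch almost always means a numbering-offset
    bug, so it is rejected loudly rather than silently overwritten.
    """
    residues = list(sequence)
    for m in variant.mutations:
        if m.position < 1 or m.position > len(sequence):
            raise ValueError(f"position {m.position} outside sequence of length {len(sequence)}")
        observed = residues[m.position - 1]
        if observed != m.wt_residue:
            raise ValueError(
                f"expected {m.wt_residue} at position {m.position}, found {observed}"
            )
        residues[m.position - 1] = m.mut_residue
    return "".join(residues)


def invert_variant(variant: TREM2Variant) -> TREM2Variant:
    """The variant that undoes this one (mutant residues back to wild type)."""
    inverted = tuple(m.inverted() for m in variant.mutations)
    return TREM2Variant(
        name=format_variant_name(list(inverted)),
        mutations=inverted,
        site_class=variant.site_class,
        ad_risk=variant.ad_risk,
    )


def classify_site(positions: frozenset[int] | set[int]) -> str:
    """Binding-surface class shared by a set of mutated positions.

    Positions mapping to different surfaces yield ``"mixed"``; positions
    that sit only in the AD-risk set (87, 96) classify ``"AD-risk"``; a
    position in no configured site classifies ``"unassigned"`` with a
    warning.
    """
    if not positions:
        return "wild-type"
    classes = set()
    for pos in positions:
        for site, members in SITE_MAP.items():
            if pos in members:
                classes.add(site)
                break
        else:
            if pos in AD_RISK_POSITIONS:
                classes.add("AD-risk")
            else:
                warnings.warn(f"position {pos} is in no configured binding site")
                classes.add("unassigned")
    return classes.pop() if len(classes) == 1 else "mixed"


def parse_kd_entry(text: str | float | None) -> float | BindingSentinel | None:
    """Parse one K_D table cell: a number, a typed sentinel, or None (absent)."""
    if text is None:
        return None
    if isinstance(text, float) and pd.isna(text):
        return None
    s = str(text).strip()
    if not s:
        return None
    for sentinel in BindingSentinel:
        if s.lower() == sentinel.value.lower() or s.lower() == "no binding":
            if s.lower() == "no binding":
                return BindingSentinel.NO_BINDING
            return sentinel
    return float(s)


def load_variant_table() -> pd.DataFrame:
    """The packaged variant panel with per-ligand K_D columns.

    K_D columns are parsed into floats, :class:`BindingSentinel` members, or
    ``None`` (not measured); the printed fold-change text is kept verbatim
    in the ``*_fold_printed`` columns.
    """
    with resources.files("trem2map.data").joinpath("variant_kd.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    for col in ("apoe4_kd_nM", "c1q_kd_uM", "il34_kd_nM"):
        df[col] = df[col].map(parse_kd_entry)
    for col in ("apoe4_err_nM", "c1q_err_uM", "il34_err_nM"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
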