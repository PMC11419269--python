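"""Hydropathy-complementarity screening of protein sequence pairs.

The screen asks whether a short sequence motif (a helix, a CDR loop, a
beta strand) could pair with some window of a partner protein by
*anticomplementary* hydropathy: hydrophobic residues facing hydrophilic
ones.  Each sequence is converted to Kyte-Doolittle hydropathy indices and
binarized to a +/- map; a motif is slid over the full map of the partner in
both forward and reverse residue order, and every alignment offset is scored
with two statistics:

* **percent match** -- the percentage of aligned positions whose
  hydrophobicity signs are opposite;
* **degree of complementary hydropathy** ``C`` -- the normalized mean
  absolute index difference,

  .. math:: C = \\frac{\\sum_{i=1}^{L} |H(i) - H'(i)|}{9L},

  where ``H`` and ``H'`` are the motif and window indices and 9 is the
  largest attainable per-pair difference (Ile +4.5 vs Arg -4.5), so
  ``0 <= C <= 1``.

A hit is *good* when percent match exceeds 75 % and ``C`` exceeds 0.5
(both strict).  Good hits are clustered on the target sequence into
candidate binding regions by interval union with a small gap tolerance.

All coordinates are 1-based inclusive on the full precursor sequence
(signal peptide included) so residue labels such as R47 or R76 keep their
conventional numbering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HydropathyScale",
    "HydropathyProfile",
    "MotifDefinition",
    "ScreenHit",
    "RegionCluster",
    "ScreenThresholds",
    "kyte_doolittle",
    "binarize",
    "percent_match",
    "complementarity",
    "screen",
    "cluster",
    "run_paper_screen",
    "MAX_PAIR_DIFFERENCE",
]

#: Largest |H - H'| attainable on the Kyte-Doolittle scale (I vs R).
MAX_PAIR_DIFFERENCE = 9.0

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class HydropathyScale:
    """Per-residue hydropathy indices for the 20 standard amino acids."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(STANDARD_RESIDUES) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")
        extra = set(self.values) - set(STANDARD_RESIDUES)
        if extra:
            raise ValueError(f"scale {self.name!r} has non-standard residues: {sorted(extra)}")
        zeros = [r for r, v in self.values.items() if v == 0.0]
        if zeros:
            # A zero index has no hydrophobicity sign; the binary map would
            # be undefined there.
            raise ValueError(f"scale {self.name!r} has residues with index 0: {zeros}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


def kyte_doolittle() -> HydropathyScale:
    """The canonical Kyte-Doolittle hydropathy scale (range -4.5 to +4.5)."""
    text = resources.files("trem2map.data").joinpath("kyte_doolittle.tsv").read_text()
    values: dict[str, float] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        residue, index = line.split("\t")
        values[residue] = float(index)
    return HydropathyScale(name="kyte-doolittle", values=values)


def load_scale(path: str) -> HydropathyScale:
    """Load an alternative scale from a two-column residue/index TSV."""
    values: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip().lower() not in ("residue\tindex", ""):
            # tolerate headerless files: first line may already be data
            parts = header.split("\t")
            if len(parts) == 2 and len(parts[0].strip()) == 1:
                values[parts[0].strip()] = float(parts[1])
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            residue, index = line.split("\t")
            values[residue.strip()] = float(index)
    return HydropathyScale(name=path, values=values)


@dataclass(frozen=True)
class HydropathyProfile:
    """A sequence with per-residue hydropathy indices and binary signs.

    ``numbering_offset`` is the 1-based precursor position of the first
    residue, so sub-profiles (e.g. an Ig domain cut from a precursor) keep
    publication numbering.
    """

    sequence_id: str
    residues: str
    indices: np.ndarray
    signs: str  # one of "+-" per residue
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not (len(self.residues) == len(self.indices) == len(self.signs)):
            raise ValueError("residues, indices and signs must have equal length")
        if self.numbering_offset < 1:
            raise ValueError("numbering_offset must be >= 1 (1-based precursor coordinates)")

    def __len__(self) -> int:
        return len(self.residues)

    def subprofile(self, start: int, end: int) -> "HydropathyProfile":
        """Extract residues ``start..end`` (1-based inclusive, precursor coords)."""
        lo = start - self.numbering_offset
        hi = end - self.numbering_offset + 1
        if lo < 0 or hi > len(self) or start > end:
            raise ValueError(
                f"window {start}-{end} outside {self.sequence_id} "
                f"({self.numbering_offset}-{self.numbering_offset + len(self) - 1})"
            )
        return HydropathyProfile(
            sequence_id=self.sequence_id,
            residues=self.residues[lo:hi],
            indices=self.indices[lo:hi],
            signs=self.signs[lo:hi],
            numbering_offset=start,
        )

    def reversed(self) -> "HydropathyProfile":
        """Residue order reversed (models antiparallel backbone pairing)."""
        return HydropathyProfile(
            sequence_id=self.sequence_id,
            residues=self.residues[::-1],
            indices=self.indices[::-1],
            signs=self.signs[::-1],
            numbering_offset=self.numbering_offset,
        )


@dataclass(frozen=True)
class MotifDefinition:
    """A named motif (helix, loop, strand) on a parent sequence."""

    name: str
    parent_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"motif {self.name}: start {self.start} > end {self.end}")
        if self.length < 2:
            raise ValueError(f"motif {self.name}: length must be >= 2")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ScreenThresholds:
    """Strict lower bounds for a good hit (both exceeded, never equalled)."""

    percent_match: float = 75.0
    complementarity: float = 0.5


@dataclass(frozen=True)
class ScreenHit:
    """One motif-vs-window comparison at a single alignment offset."""

    motif: MotifDefinition
    orientation: str  # "forward" | "reverse"
    target_id: str
    target_start: int
    target_end: int
    percent_match: float
    complementarity: float
    is_good: bool


@dataclass(frozen=True)
class RegionCluster:
    """A run of target residues covered by good hits (gap-bridged union)."""

    sequence_id: str
    start: int
    end: int
    supporting_hits: int
    per_residue_hit_counts: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        if self.supporting_hits < 1:
            raise ValueError("region must be supported by at least one hit")


def binarize(
    sequence: str,
    scale: HydropathyScale | None = None,
    sequence_id: str = "",
    numbering_offset: int = 1,
) -> HydropathyProfile:
    """Convert a residue string into a hydropathy profile with binary signs.

    Ambiguity codes (X, B, Z) and anything outside the 20 standard residues
    are rejected with the offending position reported.
    """
    scale = scale or kyte_doolittle()
    sequence = sequence.upper()
    indices = np.empty(len(sequence))
    signs = []
    for i, residue in enumerate(sequence):
        if residue not in scale.values:
            raise ValueError(
                f"unknown residue {residue!r} at position "
                f"{i + numbering_offset} of {sequence_id or 'sequence'}"
            )
        indices[i] = scale[residue]
        signs.append("+" if indices[i] > 0 else "-")
    return HydropathyProfile(
        sequence_id=sequence_id,
        residues=sequence,
        indices=indices,
        signs="".join(signs),
        numbering_offset=numbering_offset,
    )


def percent_match(motif_signs: Sequence[str], window_signs: Sequence[str]) -> float:
    """Percentage of aligned positions with opposite hydrophobicity signs."""
    if len(motif_signs) != len(window_signs):
        raise ValueError(
            f"sign vectors differ in length: {len(motif_signs)} vs {len(window_signs)}"
        )
    if len(motif_signs) == 0:
        raise ValueError("empty sign vectors")
    opposite = sum(1 for a, b in zip(motif_signs, window_signs) if a != b)
    return 100.0 * opposite / len(motif_signs)


def complementarity(
    motif_indices: Sequence[float], window_indices: Sequence[float]
) -> float:
    """Degree of complementary hydropathy C = sum|H - H'| / (9 L), in [0, 1]."""
    h = np.asarray(motif_indices, dtype=float)
    hp = np.asarray(window_indices, dtype=float)
    if h.shape != hp.shape:
        raise ValueError(f"index vectors differ in length: {h.shape} vs {hp.shape}")
    if h.size == 0:
        raise ValueError("empty index vectors")
    return float(np.sum(np.abs(h - hp)) / (h.size * MAX_PAIR_DIFFERENCE))


def screen(
    motif: MotifDefinition,
    parent: HydropathyProfile,
    target: HydropathyProfile,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[ScreenHit]:
    """Slide a motif over the whole target map in both orientations.

    Every alignment offset is scored (window step 1), yielding exactly
    ``2 * (len(target) - L + 1)`` hits.  The reverse orientation reverses
    the motif's residue order before comparison.
    """
    motif_profile = parent.subprofile(motif.start, motif.end)
    L = motif.length
    if L > len(target):
        raise ValueError(
            f"motif {motif.name} (L={L}) longer than target "
            f"{target.sequence_id} (N={len(target)})"
        )
    hits: list[ScreenHit] = []
    for orientation, prof in (
        ("forward", motif_profile),
        ("reverse", motif_profile.reversed()),
    ):
        for offset in range(len(target) - L + 1):
            window_idx = target.indices[offset : offset + L]
            window_signs = target.signs[offset : offset + L]
            pm = percent_match(prof.signs, window_signs)
            c = complementarity(prof.indices, window_idx)
            hits.append(
                ScreenHit(
                    motif=motif,
                    orientation=orientation,
                    target_id=target.sequence_id,
                    target_start=target.numbering_offset + offset,
                    target_end=target.numbering_offset + offset + L - 1,
                    percent_match=pm,
                    complementarity=c,
                    is_good=(
                        pm > thresholds.percent_match
                        and c > thresholds.complementarity
                    ),
                )
            )
    return hits


def cluster(hits: Iterable[ScreenHit], gap_tolerance: int = 3) -> list[RegionCluster]:
    """Merge good-hit spans on one target into regions.

    Spans separated by at most ``gap_tolerance`` unhit residues are bridged
    into a single region.  Returns regions sorted by start, each with
    per-residue hit counts (how many good hits cover each residue).
    Empty input yields an empty list.
    """
    good = [h for h in hits if h.is_good]
    if not good:
        return []
    target_ids = {h.target_id for h in good}
    if len(target_ids) > 1:
        raise ValueError(f"hits reference multiple targets: {sorted(target_ids)}")
    spans = sorted((h.target_start, h.target_end) for h in good)
    merged: list[list[int]] = [list(spans[0])]
    for start, end in spans[1:]:
        if start <= merged[-1][1] + gap_tolerance + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    regions = []
    for start, end in merged:
        counts = [0] * (end - start + 1)
        n_hits = 0
        for h in good:
            if h.target_start <= end and h.target_end >= start:
                n_hits += 1
                for pos in range(h.target_start, h.target_end + 1):
                    counts[pos - start] += 1
        regions.append(
            RegionCluster(
                sequence_id=good[0].target_id,
                start=start,
                end=end,
                supporting_hits=n_hits,
                per_residue_hit_counts=tuple(counts),
            )
        )
    return regions


def _hit_table(hits: list[ScreenHit]) -> pd.DataFrame:
    rows = [
        {
            "motif": h.motif.name,
            "orientation": h.orientation,
            "target_id": h.target_id,
            "target_start": h.target_start,
            "target_end": h.target_end,
            "percent_match": h.percent_match,
            "complementarity": h.complementarity,
            "is_good": h.is_good,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "motif",
            "orientation",
            "target_id",
            "target_start",
            "target_end",
            "percent_match",
            "complementarity",
            "is_good",
        ],
    )


def _good_hit_counts(hits: list[ScreenHit]) -> pd.DataFrame:
    df = _hit_table(hits)
    if df.empty:
        return pd.DataFrame(columns=["motif", "orientation", "good_hits"])
    counts = (
        df[df.is_good]
        .groupby(["motif", "orientation"], sort=True)
        .size()
        .reset_index(name="good_hits")
    )
    all_pairs = df[["motif", "orientation"]].drop_duplicates()
    counts = all_pairs.merge(counts, how="left").fillna({"good_hits": 0})
    counts["good_hits"] = counts["good_hits"].astype(int)
    return counts.sort_values(["motif", "orientation"]).reset_index(drop=True)


def run_paper_screen(
    trem2_seq: str,
    il34_seq: str,
    segments: dict[str, dict[str, tuple[int, int]]],
    scale: HydropathyScale | None = None,
    thresholds: ScreenThresholds = ScreenThresholds(),
    gap_tolerance: int = 3,
    gap_sensitivity_range: range = range(0, 9),
) -> dict:
    """Run the full bidirectional TREM2 / IL-34 binding-region screen.

    The six IL-34 helices are screened against the TREM2 Ig domain and the
    seven TREM2 segments (three CDR loops, four basic-site strands) against
    the mature IL-34 sequence; good hits are clustered on each target.

    ``segments`` maps ``{"trem2": {...}, "il34": {...}}`` with a special
    ``"target"`` entry per side giving the screened span (see
    :func:`trem2map.io.load_segments`).

    Returns a dict with clustered regions per side, per-motif good-hit
    tables, all raw hits, and a gap-tolerance sensitivity table of region
    counts.
    """
    scale = scale or kyte_doolittle()
    trem2 = binarize(trem2_seq, scale, sequence_id="TREM2")
    il34 = binarize(il34_seq, scale, sequence_id="IL-34")

    trem2_segments = dict(segments["trem2"])
    il34_segments = dict(segments["il34"])
    trem2_target = trem2.subprofile(*trem2_segments.pop("target"))
    il34_target = il34.subprofile(*il34_segments.pop("target"))

    helix_hits: list[ScreenHit] = []
    for name, (start, end) in il34_segments.items():
        motif = MotifDefinition(name=name, parent_id="IL-34", start=start, end=end)
        helix_hits.extend(screen(motif, il34, trem2_target, thresholds))
    segment_hits: list[ScreenHit] = []
    for name, (start, end) in trem2_segments.items():
        motif = MotifDefinition(name=name, parent_id="TREM2", start=start, end=end)
        segment_hits.extend(screen(motif, trem2, il34_target, thresholds))

    sensitivity = pd.DataFrame(
        [
            {
                "gap_tolerance": g,
                "trem2_regions": len(cluster(helix_hits, g)),
                "il34_regions": len(cluster(segment_hits, g)),
            }
            for g in gap_sensitivity_range
        ]
    )
    return {
        "trem2_regions": cluster(helix_hits, gap_tolerance),
        "il34_regions": cluster(segment_hits, gap_tolerance),
        "helix_hit_table": _good_hit_counts(helix_hits),
        "segment_hit_table": _good_hit_counts(segment_hits),
        "trem2_hits": helix_hits,
        "il34_hits": segment_hits,
        "gap_sensitivity": sensitivity,
        "thresholds": thresholds,
        "gap_tolerance": gap_tolerance,
    }
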