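"""File formats and reporting: FASTA, segment configs, sensorgram CSV, TSV reports.

Coordinates default to the publication convention (1-based inclusive on the
full precursor); a BED-style 0-based half-open export is available behind an
explicit flag so the two conventions are never mixed silently.  Report
writers embed the resolved configuration and seed as ``#`` header comments
and render floats at fixed precision, so a rerun with the same inputs is
byte-identical.
"""

from __future__ import annotations

import datetime
import json
import re
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .hydropathy import RegionCluster, ScreenHit
from .kinetics import FitResult, Sensorgram
from .variants import BindingSentinel

__all__ = [
    "read_fasta",
    "packaged_sequences",
    "load_segments",
    "write_sensorgrams_csv",
    "read_sensorgrams_csv",
    "write_hit_table",
    "write_region_table",
    "write_fit_report",
    "write_competition_report",
    "fetch_accession",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

_ACCESSION_RE = re.compile(
    r"^[OPQ][0-9][A-Z0-9]{3}[0-9]$|^[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2}$"
)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered {id: sequence} mapping.

    Ids are the first whitespace-delimited word of each header; sequences
    are uppercased.  Empty files, duplicate ids, gap characters and
    non-amino-acid codes are rejected with the offending record and
    position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        for i, residue in enumerate(seq):
            if residue == "-" or residue == ".":
                raise ValueError(f"gap character in record {rec.id!r} at position {i + 1}")
            if residue not in STANDARD_RESIDUES:
                raise ValueError(
                    f"non-standard residue {residue!r} in record {rec.id!r} at position {i + 1}"
                )
        sequences[rec.id] = seq
    return sequences


def packaged_sequences() -> dict[str, str]:
    """The bundled TREM2 (Q9NZC2) and IL-34 (Q6ZMJ4) precursor sequences."""
    with resources.as_file(
        resources.files("trem2map.data").joinpath("sequences.fasta")
    ) as path:
        return read_fasta(path)


def load_segments(path: str | Path | None = None) -> dict[str, dict[str, tuple[int, int]]]:
    """Parse a flat ``group.name=start-end`` segment configuration.

    Returns ``{group: {name: (start, end)}}`` with 1-based inclusive
    coordinates.  With no path, the packaged TREM2/IL-34 segment table is
    loaded.
    """
    if path is None:
        text = resources.files("trem2map.data").joinpath("segments.cfg").read_text()
    else:
        text = Path(path).read_text()
    segments: dict[str, dict[str, tuple[int, int]]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line or "." not in line.split("=", 1)[0]:
            raise ValueError(f"line {lineno}: expected 'group.name=start-end', got {line!r}")
        key, value = line.split("=", 1)
        group, name = key.split(".", 1)
        m = re.fullmatch(r"(\d+)-(\d+)", value.strip())
        if m is None:
            raise ValueError(f"line {lineno}: bad span {value!r} (expected start-end)")
        start, end = int(m.group(1)), int(m.group(2))
        if start > end or start < 1:
            raise ValueError(f"line {lineno}: invalid span {start}-{end}")
        segments.setdefault(group.strip(), {})[name.strip()] = (start, end)
    return segments


def _header_lines(config: dict | None) -> list[str]:
    lines = []
    for key, value in sorted((config or {}).items()):
        lines.append(f"# {key}={value}")
    return lines


def write_sensorgrams_csv(
    sensorgrams: list[Sensorgram], path: str | Path, config: dict | None = None
) -> Path:
    """Write a sensorgram family as CSV (time_s, signal_nm, phase, conc_M, sensor_id)."""
    if not sensorgrams:
        raise ValueError("no sensorgrams to write")
    if not all(isinstance(sg, Sensorgram) for sg in sensorgrams):
        raise TypeError("write_sensorgrams_csv accepts Sensorgram objects only")
    path = Path(path)
    frames = []
    for sg in sensorgrams:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": sg.time,
                    "signal_nm": sg.signal,
                    "phase": sg.phase,
                    "conc_M": sg.analyte_conc,
                    "sensor_id": sg.sensor_id,
                }
            )
        )
    meta = dict(config or {})
    for key in ("seed", "noise_sd", "drift_slope"):
        if key in sensorgrams[0].metadata and key not in meta:
            meta[key] = sensorgrams[0].metadata[key]
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        pd.concat(frames, ignore_index=True).to_csv(fh, index=False, float_format="%.6g")
    return path


def read_sensorgrams_csv(path: str | Path) -> list[Sensorgram]:
    """Read a sensorgram-family CSV back into Sensorgram objects."""
    df = pd.read_csv(path, comment="#")
    required = {"time_s", "signal_nm", "phase", "conc_M", "sensor_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sensorgram CSV missing columns: {sorted(missing)}")
    sensorgrams = []
    for sensor_id, group in df.groupby("sensor_id", sort=False):
        concs = group["conc_M"].unique()
        if len(concs) != 1:
            raise ValueError(f"sensor {sensor_id!r} has multiple concentrations")
        sensorgrams.append(
            Sensorgram(
                time=group["time_s"].to_numpy(),
                signal=group["signal_nm"].to_numpy(),
                phase=group["phase"].to_numpy(dtype=str),
                analyte_conc=float(concs[0]),
                sensor_id=str(sensor_id),
            )
        )
    return sensorgrams


def write_hit_table(
    hits: Iterable[ScreenHit], path: str | Path, config: dict | None = None
) -> Path:
    """Tab-separated hit table (motif, orientation, span, scores, is_good)."""
    hits = list(hits)
    if hits and not all(isinstance(h, ScreenHit) for h in hits):
        raise TypeError("write_hit_table accepts ScreenHit objects only")
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        fh.write(
            "motif\torientation\ttarget_id\ttarget_start\ttarget_end\t"
            "percent_match\tcomplementarity\tis_good\n"
        )
        for h in hits:
            fh.write(
                f"{h.motif.name}\t{h.orientation}\t{h.target_id}\t"
                f"{h.target_start}\t{h.target_end}\t{h.percent_match:.3f}\t"
                f"{h.complementarity:.4f}\t{str(h.is_good).lower()}\n"
            )
    return path


def write_region_table(
    regions: Iterable[RegionCluster],
    path: str | Path,
    config: dict | None = None,
    bed: bool = False,
) -> Path:
    """Region table; ``bed=True`` switches to 0-based half-open coordinates."""
    regions = list(regions)
    if regions and not all(isinstance(r, RegionCluster) for r in regions):
        raise TypeError("write_region_table accepts RegionCluster objects only")
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines({**(config or {}), "coordinates": "bed" if bed else "1-based"}):
            fh.write(line + "\n")
        fh.write("sequence_id\tstart\tend\tsupporting_hits\n")
        for r in regions:
            start, end = (r.start - 1, r.end) if bed else (r.start, r.end)
            fh.write(f"{r.sequence_id}\t{start}\t{end}\t{r.supporting_hits}\n")
    return path


def write_fit_report(
    rows: list[dict], path: str | Path, config: dict | None = None
) -> Path:
    """Fit report mirroring the binding tables: variant, KD, SE, fold, direction, flags.

    ``rows`` are dicts with keys variant, kd, kd_stderr, fold, direction,
    flags; K_D sentinels (:class:`BindingSentinel`) render as their printed
    text.
    """
    path = Path(path)

    def render(value) -> str:
        if value is None:
            return ""
        if isinstance(value, BindingSentinel):
            return str(value)
        if isinstance(value, float):
            return "" if value != value else f"{value:.4g}"
        return str(value)

    columns = ["variant", "kd", "kd_stderr", "fold", "direction", "flags"]
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(render(row.get(col)) for col in columns) + "\n")
    return path


def write_competition_report(
    table: pd.DataFrame, path: str | Path, config: dict | None = None
) -> Path:
    """Titration block-curve table with percent decreases and classifications."""
    expected = {"conc_first", "assoc2_magnitude", "percent_decrease", "classification"}
    if not expected <= set(table.columns):
        raise TypeError(f"competition report requires columns {sorted(expected)}")
    path = Path(path)
    meta = dict(config or {})
    if "complete_block_conc" in table.attrs:
        meta["complete_block_conc"] = table.attrs["complete_block_conc"]
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.4g")
    return path


def fetch_accession(
    accession: str,
    cache_dir: str | Path = ".trem2map-cache",
    enabled: bool = False,
    timeout: float = 30.0,
) -> str:
    """Fetch a UniProt sequence by accession (network-gated; cache-first).

    The accession is validated before any network activity.  Cached entries
    are served without network; otherwise a download is attempted only when
    ``enabled=True``, and an offline failure produces an actionable message
    pointing to manual FASTA supply.
    """
    accession = accession.strip().upper()
    if not _ACCESSION_RE.match(accession):
        raise ValueError(f"malformed UniProt accession {accession!r}")
    cache_dir = Path(cache_dir)
    cached = cache_dir / f"{accession}.fasta"
    if cached.exists():
        return read_fasta(cached)[accession]
    if not enabled:
        raise ConnectionError(
            f"network fetch disabled and {accession} is not cached; either rerun "
            "with networking enabled or supply the sequence as a FASTA file "
            "(e.g. via --fasta)"
        )
    import urllib.request

    url = f"https://rest.uniprot.org/uniprotkb/{accession}.fasta"
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode()
    except OSError as exc:
        raise ConnectionError(
            f"could not download {accession} ({exc}); supply the sequence as a "
            "FASTA file instead"
        ) from exc
    cache_dir.mkdir(parents=True, exist_ok=True)
    header, _, body = text.partition("\n")
    stamp = datetime.date.today().isoformat()
    cached.write_text(f">{accession} retrieved={stamp}\n{body}")
    return read_fasta(cached)[accession]
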