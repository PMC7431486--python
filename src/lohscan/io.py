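"""TSV-first file formats, run configuration, and BED export.

All tabular artifacts are tab-separated text with a header line and
1-based inclusive coordinates (SGD convention).  Writers can prepend
``# key<TAB>value`` provenance lines (config, seed, version), which
readers skip.  BED export converts to 0-based half-open coordinates.

Schemas
-------
genome      : chrom, length, centromere
markers     : marker_id, chrom, pos, allele_W, allele_Y
roster      : isolate_id, event_class, chromosome, start, end, parent
signals     : probe_id, marker_id, target_parent, cy3, cy5   (GPR-like)
segments    : see :func:`lohscan.signal.segments_to_frame`
events      : isolate_id, event_class, subclass, chromosome, start, end,
              parent, copies_W, copies_Y
karyotypes  : isolate_id, chromosome, state, parent
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .events import Event, Karyotype
from .genome import GenomeMap, MarkerMap, RegionOfInterest, build_default_genome
from .simulate import EventSpec

__all__ = [
    "RunConfig",
    "write_tsv",
    "read_tsv",
    "write_marker_map",
    "read_marker_map",
    "write_genome",
    "read_genome",
    "write_roster",
    "read_roster",
    "write_events",
    "write_karyotypes",
    "write_bed",
]


@dataclass
class RunConfig:
    """Parameters of one pipeline run, serialized alongside every output.

    Plain ``key = value`` text; all fields are validated on load.
    """

    seed: int = 0
    sigma: float = 0.15
    min_run: int = 3
    concordance: float = 0.9
    divisions_per_isolate: int = 25
    design: str = "whole_genome"
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not (0.5 < self.concordance <= 1.0):
            raise ValueError("concordance must be in (0.5, 1]")
        if self.divisions_per_isolate <= 0:
            raise ValueError("divisions_per_isolate must be positive")
        if self.design not in ("whole_genome", "chr4_specific"):
            raise ValueError(f"unknown design {self.design!r}")

    def save(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f: t for f, t in cls.__annotations__.items()}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            k, v = (s.strip() for s in line.split("=", 1))
            if k not in types:
                raise ValueError(f"{path}:{lineno}: unknown key {k!r}")
            typ = {"int": int, "float": float, "str": str}[types[k]]
            kwargs[k] = typ(v)
        return cls(**kwargs)


def _provenance(config: RunConfig | None) -> list[str]:
    lines = [f"# lohscan\t{__version__}"]
    if config is not None:
        lines += [f"# {k}\t{v}" for k, v in asdict(config).items()]
    return lines


def write_tsv(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """Write a TSV with an optional provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance(config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def write_genome(genome: GenomeMap, path, config: RunConfig | None = None) -> None:
    write_tsv(genome.to_frame(), path, config)


def read_genome(path) -> GenomeMap:
    from .genome import Chromosome

    df = read_tsv(path)
    _require_columns(df, ["chrom", "length", "centromere"], path)
    return GenomeMap(
        tuple(
            Chromosome(str(r.chrom), int(r.length), int(r.centromere))
            for r in df.itertuples()
        )
    )


def write_marker_map(markers: MarkerMap, path, config: RunConfig | None = None) -> None:
    write_tsv(markers.table, path, config)


def read_marker_map(path, genome: GenomeMap | None = None) -> MarkerMap:
    df = read_tsv(path)
    _require_columns(df, ["marker_id", "chrom", "pos", "allele_W", "allele_Y"], path)
    return MarkerMap(df, genome or build_default_genome())


def write_roster(events: list[EventSpec], path, config: RunConfig | None = None) -> None:
    df = pd.DataFrame(
        {
            "isolate_id": [e.isolate_id for e in events],
            "event_class": [e.event_class for e in events],
            "chromosome": [e.chromosome for e in events],
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "parent": [e.parent for e in events],
        }
    )
    write_tsv(df, path, config)


def read_roster(path) -> list[EventSpec]:
    df = read_tsv(path)
    _require_columns(
        df, ["isolate_id", "event_class", "chromosome", "start", "end", "parent"], path
    )
    out = []
    for i, r in enumerate(df.itertuples(), 2):  # header is line 1
        try:
            out.append(
                EventSpec(
                    str(r.isolate_id), str(r.event_class), str(r.chromosome),
                    int(r.start), int(r.end), str(r.parent),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return out


def write_events(events: list[Event], path, config: RunConfig | None = None) -> None:
    df = pd.DataFrame(
        {
            "isolate_id": [e.isolate_id for e in events],
            "event_class": [e.event_class for e in events],
            "subclass": [e.subclass for e in events],
            "chromosome": [e.chromosome for e in events],
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "parent": [e.parent for e in events],
            "copies_W": [e.state[0] for e in events],
            "copies_Y": [e.state[1] for e in events],
        }
    )
    write_tsv(df, path, config)


def write_karyotypes(
    karyotypes: list[Karyotype], path, config: RunConfig | None = None
) -> None:
    rows = [
        {
            "isolate_id": k.isolate_id,
            "chromosome": chrom,
            "state": label,
            "parent": parent or "",
        }
        for k in karyotypes
        for chrom, (label, parent) in k.states.items()
    ]
    write_tsv(pd.DataFrame(rows), path, config)


def write_bed(regions: list[RegionOfInterest], path) -> None:
    """BED export: 0-based half-open, so start is shifted by -1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.name}\n")
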