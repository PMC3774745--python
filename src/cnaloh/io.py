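"""Tab-separated file formats and round-trip readers/writers.

All genomic coordinates in files are 1-based inclusive, except BED which
is the standard 0-based half-open convention and is converted on read and
back on write. Every file written by the pipeline starts with a header
comment declaring the tool version and, when available, the hash of the
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome import GenomeMap
from .loh import LOHEvent
from .segmentation import Segment


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _header(meta: str | None = None) -> str:
    line = f"# cnaloh {__version__}"
    if meta:
        line += f" {meta}"
    return line + "\n"


def write_tsv(df: pd.DataFrame, path: str | Path, meta: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- marker tables -----------------------------------------------------------


def marker_table(genome: GenomeMap, lrr: np.ndarray, baf: np.ndarray) -> pd.DataFrame:
    chroms = np.concatenate(
        [np.repeat(c, len(genome.positions[c])) for c in genome.chromosomes]
    )
    pos = np.concatenate([genome.positions[c] for c in genome.chromosomes])
    return pd.DataFrame(
        {
            "marker_id": genome.marker_ids(),
            "chrom": chroms,
            "pos": pos,
            "lrr": lrr,
            "baf": baf,
        }
    )


def write_marker_table(
    path: str | Path,
    genome: GenomeMap,
    lrr: np.ndarray,
    baf: np.ndarray,
    meta: str | None = None,
) -> None:
    write_tsv(marker_table(genome, lrr, baf), path, meta)


def read_marker_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    required = ["marker_id", "chrom", "pos", "lrr", "baf"]
    if list(df.columns[:5]) != required:
        raise ValueError(f"{path}: expected columns {required}, got {list(df.columns)}")
    df["chrom"] = df["chrom"].astype(str)
    return df


# -- genome map --------------------------------------------------------------


def write_genome(path: str | Path, genome: GenomeMap, meta: str | None = None) -> None:
    df = pd.DataFrame(
        {"chrom": genome.chromosomes, "length": [genome.lengths[c] for c in genome.chromosomes]}
    )
    write_tsv(df, path, meta)


def read_genome(path: str | Path, markers: pd.DataFrame) -> GenomeMap:
    """Rebuild a GenomeMap from a chromosome-length TSV plus a marker table."""
    lengths_df = read_tsv(path)
    lengths_df["chrom"] = lengths_df["chrom"].astype(str)
    chroms = tuple(lengths_df["chrom"])
    lengths = dict(zip(lengths_df["chrom"], lengths_df["length"].astype(int)))
    positions = {
        c: np.asarray(markers.loc[markers["chrom"] == c, "pos"], dtype=np.int64)
        for c in chroms
    }
    return GenomeMap(chromosomes=chroms, lengths=lengths, positions=positions)


# -- segments (SEG format + state column) ------------------------------------

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "n_markers", "mean", "state", "large"]


def segments_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_markers": s.n_markers,
                "mean": round(s.mean, 6),
                "state": s.state if s.state is not None else "",
                "large": int(s.large),
            }
            for s in segments
        ],
        columns=SEG_COLUMNS,
    )


def write_segments(path: str | Path, segments: list[Segment], meta: str | None = None) -> None:
    write_tsv(segments_frame(segments), path, meta)


def read_segments(path: str | Path) -> list[Segment]:
    df = read_tsv(path)
    out = []
    for _, r in df.iterrows():
        state = r.get("state", "")
        out.append(
            Segment(
                sample_id=str(r["sample_id"]),
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                n_markers=int(r["n_markers"]),
                mean=float(r["mean"]),
                state=None if pd.isna(state) or state == "" else str(state),
                large=bool(int(r["large"])) if "large" in df.columns else False,
            )
        )
    return out


# -- LOH events --------------------------------------------------------------

LOH_COLUMNS = ["sample_id", "chrom", "start", "end", "n_informative", "class"]


def loh_frame(events: list[LOHEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "n_informative": e.n_informative,
                "class": e.cls,
            }
            for e in events
        ],
        columns=LOH_COLUMNS,
    )


def write_loh(path: str | Path, events: list[LOHEvent], meta: str | None = None) -> None:
    write_tsv(loh_frame(events), path, meta)


def read_loh(path: str | Path) -> list[LOHEvent]:
    df = read_tsv(path)
    return [
        LOHEvent(
            sample_id=str(r["sample_id"]),
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            n_informative=int(r["n_informative"]),
            cls=str(r["class"]),
        )
        for _, r in df.iterrows()
    ]


# -- BED gene map ------------------------------------------------------------


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED gene map, converting to 1-based inclusive coordinates.

    BED interval [start, end) in 0-based half-open becomes [start+1, end]
    internally. Malformed lines raise with the file and line number.
    """
    rows = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start0 < 0 or end0 <= start0:
                raise ValueError(f"{path}:{lineno}: invalid BED interval [{start0}, {end0})")
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            rows.append({"chrom": chrom, "start": start0 + 1, "end": end0, "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(path: str | Path, genes: pd.DataFrame) -> None:
    """Write a 1-based inclusive gene table back to 0-based half-open BED."""
    with open(path, "w") as fh:
        for _, r in genes.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{r['name']}\n")


# -- ground truth / phenotypes / JSON ----------------------------------------


def write_events(path: str | Path, events: pd.DataFrame, meta: str | None = None) -> None:
    write_tsv(events, path, meta)


def read_events(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_phenotypes(path: str | Path, phenotypes: pd.DataFrame, meta: str | None = None) -> None:
    write_tsv(phenotypes, path, meta)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return read_tsv(path)


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
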