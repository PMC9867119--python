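"""Plain-text readers and writers for every pipeline input and output.

Formats: FASTA (sequences), BED4/BED6 (peaks; score column carries the
peak height), bedGraph (per-base conservation, coordinates relative to
each UTR, 0-based half-open), TSV count tables (rows features, columns
samples, first column the feature id), TSV group maps, and TSV line-scan
matrices (rows time, columns spatial positions).  Readers validate on
load and raise :class:`DataError` naming the offending record rather than
silently coercing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clip import ConservationTrack, Peak
from .diffexpr import CountMatrix
from .errors import DataError
from .readouts import CalciumTrace


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise DataError(f"{path}: duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise DataError(f"{path}: empty FASTA record {record.id!r}")
        out[record.id] = seq
    if not out:
        raise DataError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    """Write sequences as wrapped FASTA; read_fasta round-trips losslessly."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED (peaks)
# ---------------------------------------------------------------------------

def read_bed(path) -> list[Peak]:
    """Read BED4 or BED6 peak intervals (0-based half-open).

    BED6 column 5 (score) is the peak height; BED4 files get height 1.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (4, 6):
                raise DataError(
                    f"{path}:{lineno}: expected 4 or 6 BED columns, got {len(fields)}"
                )
            ref, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise DataError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            height = float(fields[4]) if len(fields) == 6 else 1.0
            peaks.append(Peak(ref, start, end, height))
    return peaks


def write_bed(peaks: list[Peak], path) -> None:
    """Write peaks as BED6 (name pk<N>, score = height, strand +)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, start=1):
            fh.write(
                f"{p.ref_id}\t{p.start}\t{p.end}\tpk{i}\t{p.height:g}\t+\n"
            )


# ---------------------------------------------------------------------------
# bedGraph (conservation)
# ---------------------------------------------------------------------------

def read_bedgraph(path, lengths: dict[str, int] | None = None) -> ConservationTrack:
    """Expand bedGraph runs into per-base scores (0-based half-open).

    ``lengths`` fixes each reference's array length; otherwise the largest
    end coordinate seen is used.  Uncovered bases score 0.
    """
    runs: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise DataError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}"
                )
            ref, start, end, score = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if start >= end:
                raise DataError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            runs.setdefault(ref, []).append((start, end, score))
    track = ConservationTrack()
    for ref, items in runs.items():
        size = lengths[ref] if lengths else max(end for _s, end, _v in items)
        arr = np.zeros(size)
        for start, end, score in items:
            arr[start : min(end, size)] = score
        track.scores[ref] = arr
    if lengths:
        for ref, size in lengths.items():
            track.scores.setdefault(ref, np.zeros(size))
    return track


def write_bedgraph(track: ConservationTrack, path, decimals: int = 4) -> None:
    """Write per-base scores as run-length-merged bedGraph lines."""
    with open(path, "w") as fh:
        for ref in track.scores:
            arr = np.round(track.scores[ref], decimals)
            if arr.size == 0:
                continue
            run_start = 0
            for i in range(1, arr.size + 1):
                if i == arr.size or arr[i] != arr[run_start]:
                    fh.write(f"{ref}\t{run_start}\t{i}\t{arr[run_start]:g}\n")
                    run_start = i


# ---------------------------------------------------------------------------
# Count tables and group maps
# ---------------------------------------------------------------------------

def read_group_map(path) -> pd.Series:
    """Read a two-column TSV (sample, group) into a Series."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise DataError(f"{path}: group map must have exactly 2 columns")
    df.columns = ["sample", "group"]
    if df["sample"].duplicated().any():
        raise DataError(f"{path}: duplicate sample in group map")
    return pd.Series(df["group"].values, index=df["sample"].values)


def write_group_map(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


def read_counts(
    path,
    group_map: pd.Series,
    lengths: pd.Series | None = None,
) -> CountMatrix:
    """Read a feature x sample TSV count table into a CountMatrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise DataError(f"{path}: missing or ragged values in count table")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: non-numeric values in count table") from exc
    if (df.to_numpy() < 0).any():
        raise DataError(f"{path}: negative values in count table")
    missing = [s for s in df.columns if s not in group_map.index]
    if missing:
        raise DataError(f"{path}: no group assigned to sample(s) {missing}")
    return CountMatrix(df, group_map.loc[df.columns], lengths)


def write_counts(m: CountMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_lengths(path) -> pd.Series:
    """Two-column TSV (feature, length in nt)."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise DataError(f"{path}: lengths table must have exactly 2 columns")
    df.columns = ["feature_id", "length"]
    return pd.Series(df["length"].astype(float).values, index=df["feature_id"].values)


def write_lengths(lengths: pd.Series, path) -> None:
    pd.DataFrame(
        {"feature_id": lengths.index, "length": lengths.values}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Line scans
# ---------------------------------------------------------------------------

def read_linescan(path, dt: float) -> CalciumTrace:
    """Read a TSV fluorescence matrix (rows time, columns positions)."""
    try:
        values = np.loadtxt(path, delimiter="\t")
    except ValueError as exc:
        raise DataError(f"{path}: malformed line-scan matrix: {exc}") from exc
    return CalciumTrace(dt=dt, values=values)


def write_linescan(trace: CalciumTrace, path) -> None:
    np.savetxt(path, trace.values, delimiter="\t", fmt="%.4f")


# ---------------------------------------------------------------------------
# Sites and truth tables
# ---------------------------------------------------------------------------

def write_sites(sites, path) -> None:
    """Write seed sites (or annotated sites) as a TSV table."""
    rows = []
    for s in sites:
        site = getattr(s, "site", s)
        row = {
            "utr_id": site.utr_id,
            "start": site.start,
            "end": site.end,
            "match_type": site.match_type,
            "mirna_id": site.mirna_id,
        }
        if hasattr(s, "ago2"):
            row.update(
                ago2=int(s.ago2),
                peak_height=s.peak_height,
                cons_score=s.cons_score,
                cons_class=s.cons_class,
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
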