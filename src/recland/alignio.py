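"""Readers and writers for the external formats the pipeline touches.

Alignment coordinate reports (MUMmer ``show-coords -r`` text), variant reports
(``show-snps`` text), BED intervals, recombination/feature/prediction CSV
tracks and BedGraph output.

All genomic coordinates are converted to 0-based half-open exactly once, at
parse time; every internal structure uses that convention.  The 1-based
inclusive convention of the aligner reports exists only in this module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A malformed row in an alignment report, carrying its line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned segment between reference and query.

    Coordinates are 0-based half-open.  ``reverse`` records that the query
    segment aligned in reverse orientation (the report listed its query start
    after its query end); ``qry_start < qry_end`` always holds internally and
    describes the covered query interval.
    """

    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    ref_chrom: str = "ref"
    qry_chrom: str = "qry"
    reverse: bool = False

    def __post_init__(self):
        if self.ref_start < 0 or self.ref_start >= self.ref_end:
            raise ValueError(
                f"invalid reference interval [{self.ref_start}, {self.ref_end})"
            )
        if self.qry_start < 0 or self.qry_start >= self.qry_end:
            raise ValueError(
                f"invalid query interval [{self.qry_start}, {self.qry_end})"
            )

    @classmethod
    def from_1based(
        cls,
        s1: int,
        e1: int,
        s2: int,
        e2: int,
        ref_chrom: str = "ref",
        qry_chrom: str = "qry",
    ) -> "AlignmentBlock":
        """Build from the aligner's 1-based inclusive coordinates.

        Reverse orientation is inferred from ``s2 > e2``.
        """
        reverse = s2 > e2
        q_lo, q_hi = (e2, s2) if reverse else (s2, e2)
        return cls(
            ref_start=s1 - 1,
            ref_end=e1,
            qry_start=q_lo - 1,
            qry_end=q_hi,
            ref_chrom=ref_chrom,
            qry_chrom=qry_chrom,
            reverse=reverse,
        )

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_span(self) -> int:
        return self.qry_end - self.qry_start


@dataclass(frozen=True)
class VariantRecord:
    """One variant row: SNP, deletion-in-query or insertion-in-query.

    ``pos`` is the 0-based reference position.  A ``'.'`` in ``ref_base``
    marks an insertion in the query; in ``qry_base`` a deletion.
    """

    pos: int
    ref_base: str
    qry_base: str
    ref_chrom: str = "ref"
    qry_chrom: str = "qry"

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative variant position {self.pos}")
        if self.ref_base == "." and self.qry_base == ".":
            raise ValueError("variant with gap in both sequences")

    @property
    def is_insertion(self) -> bool:
        return self.ref_base == "."

    @property
    def is_deletion(self) -> bool:
        return self.qry_base == "."

    @property
    def is_snp(self) -> bool:
        return self.ref_base != "." and self.qry_base != "."


@dataclass
class RecombinationTrack:
    """Observed recombination rates (cM per window) on a regular window grid."""

    window_starts: np.ndarray
    rates: np.ndarray
    chrom: str = "chr01"

    def __post_init__(self):
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.window_starts.shape != self.rates.shape:
            raise ValueError("window_starts and rates must have equal length")
        if len(self.window_starts) == 0:
            raise ValueError("empty recombination track")
        steps = np.diff(self.window_starts)
        if len(steps) and (steps <= 0).any():
            raise ValueError("window starts must be strictly increasing")
        if len(steps) and not (steps == steps[0]).all():
            raise ValueError("window starts must advance by a constant step")
        if (self.rates < 0).any():
            raise ValueError("recombination rates must be non-negative")

    @property
    def window_size(self) -> int | None:
        if len(self.window_starts) < 2:
            return None
        return int(self.window_starts[1] - self.window_starts[0])

    def __len__(self) -> int:
        return len(self.rates)


def _as_lines(stream) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    if isinstance(stream, (io.TextIOBase, io.StringIO)) or hasattr(stream, "read"):
        return stream.read().splitlines()
    return list(stream)


def _strip_header(lines: list[str]) -> list[tuple[int, str]]:
    """Drop a show-coords/show-snps preamble if present.

    The preamble, when the report was produced without ``-H``, ends in a ruler
    line of ``=`` characters; everything up to and including the ruler is
    skipped.  Headerless reports pass through untouched.  Returns (line
    number, text) pairs for the remaining non-blank lines.
    """
    body_from = 0
    for i, line in enumerate(lines[:8]):
        if line.strip().startswith("=") and set(line.strip()) == {"="}:
            body_from = i + 1
            break
    return [
        (i + 1, line)
        for i, line in enumerate(lines)
        if i >= body_from and line.strip()
    ]


def read_coords(stream) -> list[AlignmentBlock]:
    """Parse a ``show-coords -r`` report into alignment blocks.

    Accepts both the headered and the ``-H`` headerless dialect; ``|`` column
    separators are tolerated.  Blocks are returned sorted by reference start.
    An empty report body yields an empty list.
    """
    blocks: list[AlignmentBlock] = []
    for lineno, line in _strip_header(_as_lines(stream)):
        tokens = line.replace("|", " ").split()
        if len(tokens) < 9:
            raise ParseError(
                f"expected at least 9 columns, got {len(tokens)}", lineno
            )
        try:
            s1, e1, s2, e2 = (int(t) for t in tokens[:4])
        except ValueError as exc:
            raise ParseError(f"non-numeric coordinate field: {exc}", lineno) from None
        try:
            blocks.append(
                AlignmentBlock.from_1based(
                    s1, e1, s2, e2, ref_chrom=tokens[-2], qry_chrom=tokens[-1]
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
    blocks.sort(key=lambda b: (b.ref_start, b.ref_end))
    return blocks


def read_snps(stream) -> list[VariantRecord]:
    """Parse a ``show-snps`` report into variant records.

    Gap symbols ``'.'`` are preserved, distinguishing deletions in the query
    (reference base shown, query gap) from insertions (reference gap).
    """
    records: list[VariantRecord] = []
    for lineno, line in _strip_header(_as_lines(stream)):
        tokens = line.replace("|", " ").split()
        if len(tokens) < 4:
            raise ParseError(f"expected at least 4 columns, got {len(tokens)}", lineno)
        try:
            p1 = int(tokens[0])
        except ValueError:
            raise ParseError(
                f"non-numeric position field {tokens[0]!r}", lineno
            ) from None
        ref_base, qry_base = tokens[1], tokens[2]
        ref_chrom, qry_chrom = ("ref", "qry")
        if len(tokens) >= 9:
            ref_chrom, qry_chrom = tokens[-2], tokens[-1]
        try:
            records.append(
                VariantRecord(
                    pos=p1 - 1,
                    ref_base=ref_base,
                    qry_base=qry_base,
                    ref_chrom=ref_chrom,
                    qry_chrom=qry_chrom,
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
    return records


def read_bed(stream) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (0-based half-open) as (chrom, start, end) tuples."""
    out = []
    for lineno, line in enumerate(_as_lines(stream), start=1):
        if not line.strip() or line.startswith(("track", "#")):
            continue
        tokens = line.split()
        if len(tokens) < 3:
            raise ParseError("BED line needs chrom, start, end", lineno)
        try:
            start, end = int(tokens[1]), int(tokens[2])
        except ValueError:
            raise ParseError("non-numeric BED coordinates", lineno) from None
        out.append((tokens[0], start, end))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]]) -> str:
    return "".join(f"{c}\t{s}\t{e}\n" for c, s, e in intervals)


def read_recombination_csv(stream, chrom: str) -> RecombinationTrack:
    """Read an observed-recombination CSV restricted to one chromosome.

    Expects a header row and three columns: chromosome, window start (bases)
    and rate (cM per window); extra columns are ignored.
    """
    df = pd.read_csv(
        stream if not isinstance(stream, str) else io.StringIO(stream),
        float_precision="round_trip",
    )
    if df.shape[1] < 3:
        raise ValueError("recombination CSV needs chrom, window_start, rate columns")
    chrom_col, start_col, rate_col = df.columns[:3]
    available = sorted(df[chrom_col].astype(str).unique())
    sub = df[df[chrom_col].astype(str) == chrom]
    if sub.empty:
        raise ValueError(
            f"chromosome {chrom!r} not in recombination CSV; available: {available}"
        )
    sub = sub.sort_values(start_col)
    return RecombinationTrack(
        window_starts=sub[start_col].to_numpy(dtype=np.int64),
        rates=sub[rate_col].to_numpy(dtype=float),
        chrom=chrom,
    )


def write_recombination_csv(track: RecombinationTrack) -> str:
    df = pd.DataFrame(
        {
            "chrom": track.chrom,
            "window_start": track.window_starts,
            "rate": track.rates,
        }
    )
    return df.to_csv(index=False, float_format="%.17g")


def write_track_csv(values: Sequence[float], grid, value_name: str = "value") -> str:
    """One-column windowed track as CSV (chrom, window_start, <value_name>)."""
    values = np.asarray(values, dtype=float)
    if len(values) != grid.n:
        raise ValueError(f"track length {len(values)} != grid windows {grid.n}")
    df = pd.DataFrame(
        {"chrom": grid.chrom, "window_start": grid.starts, value_name: values}
    )
    return df.to_csv(index=False, float_format="%.17g")


def write_bedgraph(values: Sequence[float], grid) -> str:
    """Windowed track as BedGraph (0-based half-open; last window truncated)."""
    values = np.asarray(values, dtype=float)
    if len(values) != grid.n:
        raise ValueError(f"track length {len(values)} != grid windows {grid.n}")
    lines = ["track type=bedGraph"]
    for w, v in enumerate(values):
        start = grid.starts[w]
        end = min(start + grid.window_size, grid.chrom_length)
        lines.append(f"{grid.chrom}\t{start}\t{end}\t{v:g}")
    return "\n".join(lines) + "\n"


def write_feature_csv(track) -> str:
    grid = track.grid
    df = pd.DataFrame(
        {
            "chrom": grid.chrom,
            "window_start": grid.starts,
            "V": track.V,
            "I": track.I,
            "A": track.A,
            "Id0": track.Id0,
        }
    )
    return df.to_csv(index=False, float_format="%.17g")


def read_feature_csv(stream, grid):
    """Read a feature CSV back onto a known window grid."""
    from .features import FeatureTrack

    df = pd.read_csv(
        stream if not isinstance(stream, str) else io.StringIO(stream),
        float_precision="round_trip",
    )
    if len(df) != grid.n:
        raise ValueError(f"feature CSV has {len(df)} rows, grid has {grid.n} windows")
    df = df.sort_values("window_start")
    return FeatureTrack(
        V=df["V"].to_numpy(dtype=float),
        I=df["I"].to_numpy(dtype=float),
        A=df["A"].to_numpy(dtype=float),
        Id0=df["Id0"].to_numpy(dtype=float),
        grid=grid,
    )


def write_prediction_csv(track) -> str:
    grid = track.grid
    df = pd.DataFrame(
        {
            "chrom": grid.chrom,
            "window_start": grid.starts,
            "Id1": track.Id1,
            "Id2": track.Id2,
            "Id3": track.Id3,
            "Id4": track.Id4,
            "case_label": track.case_label,
        }
    )
    return df.to_csv(index=False, float_format="%.17g")


def read_prediction_csv(stream, grid):
    from .model import PredictionTrack

    df = pd.read_csv(
        stream if not isinstance(stream, str) else io.StringIO(stream),
        float_precision="round_trip",
    )
    if len(df) != grid.n:
        raise ValueError(
            f"prediction CSV has {len(df)} rows, grid has {grid.n} windows"
        )
    df = df.sort_values("window_start")
    return PredictionTrack(
        Id1=df["Id1"].to_numpy(dtype=float),
        Id2=df["Id2"].to_numpy(dtype=float),
        Id3=df["Id3"].to_numpy(dtype=float),
        Id4=df["Id4"].to_numpy(dtype=float),
        case_label=df["case_label"].to_numpy(dtype=object),
        grid=grid,
    )


def read_fasta_lengths(path) -> dict[str, int]:
    """Sequence lengths per record id from a FASTA file."""
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
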