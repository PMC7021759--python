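"""Genomic interval algebra and BED-family readers/writers.

All coordinates are 0-based, half-open (BED convention). Overlap means at
least one shared base pair; abutting intervals (``a.end == b.start``) do not
overlap and are not merged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "BedParseError",
    "read_intervals",
    "write_bed",
    "merge",
    "overlap_query",
]


class BedParseError(ValueError):
    """Raised for malformed interval lines; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open region ``[start, end)`` on a named sequence."""

    seq: str
    start: int
    end: int
    strand: str = "."
    payload: Mapping = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self):
        if not self.seq:
            raise ValueError("sequence name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq == other.seq
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.seq != other.seq:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """A collection of :class:`GenomicInterval` grouped by sequence.

    Intervals are kept sorted by ``(start, end)`` within each sequence.
    ``name`` records provenance (sample id, track name).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), name: str = ""):
        self.name = name
        self._by_seq: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            self._by_seq.setdefault(iv.seq, []).append(iv)
        for seq in self._by_seq:
            self._by_seq[seq].sort(key=lambda iv: (iv.start, iv.end))
        self._trees: dict[str, IntervalTree] | None = None

    # -- container protocol -------------------------------------------------

    def __iter__(self) -> Iterator[GenomicInterval]:
        for seq in sorted(self._by_seq):
            yield from self._by_seq[seq]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_seq.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    @property
    def seqs(self) -> list[str]:
        return sorted(self._by_seq)

    def on(self, seq: str) -> Sequence[GenomicInterval]:
        return tuple(self._by_seq.get(seq, ()))

    def _tree(self, seq: str) -> IntervalTree:
        if self._trees is None:
            self._trees = {}
        if seq not in self._trees:
            tree = IntervalTree()
            for iv in self._by_seq.get(seq, ()):
                tree.addi(iv.start, iv.end, iv)
            self._trees[seq] = tree
        return self._trees[seq]

    # -- algebra -------------------------------------------------------------

    def merge(self) -> "IntervalSet":
        """Union of overlapping (>=1 bp shared) intervals.

        Abutting intervals stay separate. Each merged interval's payload
        lists the contributing intervals under ``"sources"``. Idempotent.
        """
        out: list[GenomicInterval] = []
        for seq in sorted(self._by_seq):
            run_start = run_end = None
            sources: list[GenomicInterval] = []
            for iv in self._by_seq[seq]:
                if run_start is None:
                    run_start, run_end, sources = iv.start, iv.end, [iv]
                elif iv.start < run_end:  # strict: abutment does not merge
                    run_end = max(run_end, iv.end)
                    sources.append(iv)
                else:
                    out.append(
                        GenomicInterval(seq, run_start, run_end,
                                        payload={"sources": tuple(sources)})
                    )
                    run_start, run_end, sources = iv.start, iv.end, [iv]
            if run_start is not None:
                out.append(
                    GenomicInterval(seq, run_start, run_end,
                                    payload={"sources": tuple(sources)})
                )
        return IntervalSet(out, name=self.name)

    def query(self, iv: GenomicInterval) -> list[GenomicInterval]:
        """Intervals in this set sharing >=1 bp with ``iv``, sorted."""
        hits = self._tree(iv.seq).overlap(iv.start, iv.end)
        return sorted((h.data for h in hits), key=lambda x: (x.start, x.end))

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        return bool(self._tree(iv.seq).overlap(iv.start, iv.end))


def merge(iset: IntervalSet) -> IntervalSet:
    """Functional alias for :meth:`IntervalSet.merge`."""
    return iset.merge()


def overlap_query(
    query: IntervalSet, subject: IntervalSet
) -> tuple[list[bool], list[list[GenomicInterval]]]:
    """Per-query hit flags and hit lists against ``subject``.

    A query interval is flagged iff some subject interval shares >=1 bp
    with it. Results follow the iteration order of ``query``.
    """
    flags: list[bool] = []
    hits: list[list[GenomicInterval]] = []
    for iv in query:
        h = subject.query(iv)
        flags.append(bool(h))
        hits.append(h)
    return flags, hits


# -- I/O ----------------------------------------------------------------------

_NARROWPEAK_FIELDS = ("name", "score", "strand", "signalValue", "pValue",
                      "qValue", "summit")


def _parse_state(label: str, lineno: int) -> int:
    raw = label[1:] if label[:1] in ("E", "U") else label
    try:
        return int(raw)
    except ValueError:
        raise BedParseError(f"cannot parse state label {label!r}", lineno)


def _parse_line(fields: list[str], fmt: str, lineno: int) -> GenomicInterval:
    if len(fields) < 3:
        raise BedParseError(
            f"expected >=3 tab-separated columns, got {len(fields)}", lineno
        )
    seq = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise BedParseError(
            f"non-integer coordinates {fields[1]!r}, {fields[2]!r}", lineno
        )
    if start < 0:
        raise BedParseError(f"negative start {start}", lineno)
    if start >= end:
        raise BedParseError(f"start {start} >= end {end}", lineno)

    strand = "."
    payload: dict = {}
    if fmt == "narrowPeak":
        extra = fields[3:10]
        for key, value in zip(_NARROWPEAK_FIELDS, extra):
            payload[key] = value
        for key in ("signalValue", "pValue", "qValue"):
            if key in payload:
                payload[key] = float(payload[key])
        if "summit" in payload:
            payload["summit"] = int(payload["summit"])
        if payload.get("strand") in ("+", "-"):
            strand = payload["strand"]
    elif fmt == "segmentation":
        if len(fields) < 4:
            raise BedParseError("segmentation line needs a state column", lineno)
        payload["state"] = _parse_state(fields[3], lineno)
    else:  # plain bed
        if len(fields) >= 4:
            payload["name"] = fields[3]
        if len(fields) >= 6 and fields[5] in ("+", "-"):
            strand = fields[5]
    return GenomicInterval(seq, start, end, strand=strand, payload=payload)


def read_intervals(path: str | Path | io.TextIOBase,
                   fmt: str = "bed",
                   name: str = "") -> IntervalSet:
    """Read a BED3+/narrowPeak/segmentation file into an :class:`IntervalSet`.

    Header lines starting with ``track``, ``browser`` or ``#`` are skipped.
    Malformed lines raise :class:`BedParseError` naming the line number.
    """
    if fmt not in ("bed", "narrowPeak", "segmentation"):
        raise ValueError(f"unknown format {fmt!r}")
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
        if not name:
            name = Path(path).stem
    else:
        handle, close = path, False
    try:
        intervals = []
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            intervals.append(_parse_line(line.split("\t"), fmt, lineno))
    finally:
        if close:
            handle.close()
    return IntervalSet(intervals, name=name)


def write_bed(iset: IntervalSet, path: str | Path,
              fmt: str = "bed") -> None:
    """Write canonical BED: seq, start, end (+ state column for segmentations).

    Output is sorted, so read -> write -> read is byte-stable for canonical
    input.
    """
    with open(path, "w") as out:
        for iv in iset:
            if fmt == "segmentation":
                out.write(f"{iv.seq}\t{iv.start}\t{iv.end}\tE{iv.payload['state']}\n")
            elif "name" in iv.payload:
                out.write(f"{iv.seq}\t{iv.start}\t{iv.end}\t{iv.payload['name']}\n")
            else:
                out.write(f"{iv.seq}\t{iv.start}\t{iv.end}\n")
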