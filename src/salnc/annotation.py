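"""Transcript models, GTF input/output and the lncRNA candidate filter.

A long non-coding RNA candidate must look like a real lncRNA before any
expression analysis: longer than 200 bp of mature sequence, multi-exonic,
free of exon overlap with protein-coding transcripts, and without coding
potential.  :func:`filter_lncrna_candidates` applies those four criteria in
a fixed order and reports the first failing one per rejected transcript.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")
LNCRNA = "lncRNA"
MRNA = "mRNA"

#: fixed precedence of rejection reasons
REJECTION_ORDER = ("length", "exons", "overlap", "coding")


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Closed 1-based genomic interval [start, end]."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end ({self.end}) < start ({self.start})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        # closed intervals: a single shared coordinate counts
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's genomic structure.

    ``exons`` are stored sorted by start and must be pairwise
    non-overlapping.  ``coding_flag`` marks externally supplied
    protein-coding potential (True = coding).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = MRNA
    coding_flag: bool = False

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        object.__setattr__(self, "exons", exons)
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def exon_sizes(self) -> tuple[int, ...]:
        return tuple(e.width for e in self.exons)

    @property
    def intron_sizes(self) -> tuple[int, ...]:
        return tuple(
            b.start - a.end - 1 for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def transcript_length(self) -> int:
        """Mature (spliced) length: sum of exon widths."""
        return sum(self.exon_sizes)

    @property
    def span_start(self) -> int:
        return self.exons[0].start

    @property
    def span_end(self) -> int:
        return self.exons[-1].end

    @property
    def genomic_span(self) -> int:
        return self.span_end - self.span_start + 1


class TranscriptSet:
    """Collection of :class:`TranscriptModel` keyed by transcript_id."""

    def __init__(
        self,
        transcripts: Iterable[TranscriptModel] = (),
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self._transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.transcript_id in self._transcripts:
                raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
            self._transcripts[t.transcript_id] = t
        self._chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        if self._chrom_lengths is not None:
            for t in self:
                limit = self._chrom_lengths.get(t.chrom)
                if limit is None:
                    raise ValueError(
                        f"transcript {t.transcript_id} on unknown chrom {t.chrom!r}"
                    )
                if t.span_end > limit:
                    raise ValueError(
                        f"transcript {t.transcript_id} exceeds chrom "
                        f"{t.chrom} length {limit}"
                    )

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    @property
    def ids(self) -> list[str]:
        return list(self._transcripts)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        """Given lengths, or per-chrom max span end when not supplied."""
        if self._chrom_lengths is not None:
            return dict(self._chrom_lengths)
        inferred: dict[str, int] = {}
        for t in self:
            inferred[t.chrom] = max(inferred.get(t.chrom, 0), t.span_end)
        return inferred

    def subset(self, ids: Iterable[str]) -> "TranscriptSet":
        return TranscriptSet(
            (self._transcripts[i] for i in ids), self._chrom_lengths
        )

    def by_biotype(self, biotype: str) -> list[TranscriptModel]:
        return [t for t in self if t.biotype == biotype]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(
    path: str | Path,
    biotype_attr: str = "transcript_biotype",
) -> TranscriptSet:
    """Read ``exon`` rows of a 9-column GTF into a :class:`TranscriptSet`.

    Transcripts lacking the biotype attribute are treated as mRNA, so they
    contribute to the overlap mask conservatively.  Comment lines and
    non-exon features are skipped.
    """
    path = Path(path)
    records: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if start < 1 or end < start:
                raise GtfParseError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            attributes = _parse_attributes(attrs)
            tid = attributes.get("transcript_id")
            gid = attributes.get("gene_id")
            if tid is None or gid is None:
                raise GtfParseError(
                    f"{path}:{lineno}: exon lacks transcript_id/gene_id"
                )
            rec = records.setdefault(
                tid,
                {
                    "gene_id": gid,
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attributes.get(biotype_attr, MRNA),
                    "exons": [],
                },
            )
            iv = GenomicInterval(start, end)
            if iv in rec["exons"]:
                raise GtfParseError(
                    f"{path}:{lineno}: duplicate exon {start}-{end} "
                    f"for transcript {tid}"
                )
            rec["exons"].append(iv)
    transcripts = [
        TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(rec["exons"]),
            biotype=rec["biotype"],
        )
        for tid, rec in records.items()
    ]
    return TranscriptSet(transcripts)


def write_gtf(ts: TranscriptSet, path: str | Path) -> None:
    """Write exon rows; :func:`read_gtf` of the output reproduces ``ts``.

    The ``coding_flag`` is not a GTF concept and is carried in a sidecar
    table (see :func:`write_coding_flags`).
    """
    path = Path(path)
    ordered = sorted(ts, key=lambda t: (t.chrom, t.span_start, t.transcript_id))
    with open(path, "w") as fh:
        fh.write("# exon records; coordinates 1-based inclusive\n")
        for t in ordered:
            for exon in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'transcript_biotype "{t.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "salnc",
                            "exon",
                            str(exon.start),
                            str(exon.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_coding_flags(path: str | Path) -> dict[str, bool]:
    """Sidecar TSV (transcript_id, coding_flag in {0,1}) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("coding-flag table needs 2 columns")
    ids = df.iloc[:, 0]
    flags = df.iloc[:, 1]
    if not flags.isin([0, 1]).all():
        raise ValueError("coding_flag values must be 0 or 1")
    return dict(zip(ids, flags.astype(bool)))


def write_coding_flags(flags: Mapping[str, bool], path: str | Path) -> None:
    pd.DataFrame(
        {"transcript_id": list(flags), "coding_flag": [int(v) for v in flags.values()]}
    ).to_csv(path, sep="\t", index=False)


def apply_coding_flags(ts: TranscriptSet, flags: Mapping[str, bool]) -> TranscriptSet:
    """Return a new set with coding_flag replaced where the mapping has an entry.

    Absent transcripts keep their current flag (default False: a deposited
    lncRNA annotation is normally already coding-filtered upstream).
    """
    out = []
    for t in ts:
        if t.transcript_id in flags:
            t = TranscriptModel(
                t.transcript_id, t.gene_id, t.chrom, t.strand, t.exons,
                t.biotype, bool(flags[t.transcript_id]),
            )
        out.append(t)
    return TranscriptSet(out, ts._chrom_lengths)


class _ExonMask:
    """Per-chromosome mRNA exon intervals supporting O(log n) overlap queries."""

    def __init__(self, transcripts: Iterable[TranscriptModel]) -> None:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for t in transcripts:
            rows = per_chrom.setdefault(t.chrom, [])
            rows.extend((e.start, e.end) for e in t.exons)
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            # prefix running max of ends, aligned with sorted starts
            self._index[chrom] = (starts, np.maximum.accumulate(ends))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        idx = self._index.get(chrom)
        if idx is None:
            return False
        starts, max_ends = idx
        # intervals with start <= end of query; overlap iff any of their ends >= start
        k = int(np.searchsorted(starts, end, side="right"))
        return k > 0 and int(max_ends[k - 1]) >= start


def filter_lncrna_candidates(
    ts: TranscriptSet,
    min_length: int = 200,
    min_exons: int = 2,
) -> tuple[TranscriptSet, pd.DataFrame]:
    """Apply the four lncRNA candidate criteria to lncRNA-biotype transcripts.

    Criteria, in rejection-report order: mature length strictly greater than
    ``min_length``; at least ``min_exons`` exons; no exon overlapping any
    exon of any mRNA-biotype transcript (strand-agnostic, closed intervals);
    coding_flag False.  Returns the retained candidates and a rejection
    report (transcript_id, reason = first failing criterion).
    """
    if len(ts) == 0:
        logger.warning("filter_lncrna_candidates: empty transcript set")
        return TranscriptSet(), pd.DataFrame(columns=["transcript_id", "reason"])

    mask = _ExonMask(t for t in ts if t.biotype != LNCRNA)
    retained: list[str] = []
    rejected: list[tuple[str, str]] = []
    for t in ts.by_biotype(LNCRNA):
        if t.transcript_length <= min_length:
            rejected.append((t.transcript_id, "length"))
        elif t.exon_count < min_exons:
            rejected.append((t.transcript_id, "exons"))
        elif any(mask.overlaps(t.chrom, e.start, e.end) for e in t.exons):
            rejected.append((t.transcript_id, "overlap"))
        elif t.coding_flag:
            rejected.append((t.transcript_id, "coding"))
        else:
            retained.append(t.transcript_id)
    report = pd.DataFrame(rejected, columns=["transcript_id", "reason"])
    logger.info(
        "lncRNA filter: %d candidates, %d retained, %d rejected",
        len(retained) + len(rejected), len(retained), len(rejected),
    )
    return ts.subset(retained), report
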