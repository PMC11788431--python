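"""Protospacer extraction and guide counting from screen reads.

Screen reads carry a fixed vector sequence (the "anchor") immediately
upstream of the 20-nt protospacer. Extraction takes the ``guide_length``
bases following the first exact occurrence of the anchor; the extracted
sequence is then assigned to a library guide under a unique-best Hamming
contract: an assignment requires a single guide at the minimum distance
within ``max_mismatches`` (default 3); ties at the minimum distance are
discarded as ambiguous, as are exact hits to protospacers duplicated in the
library. This mirrors unique best-stratum short-read alignment with
``-m 1 --best -v 3``.

Counting is single-pass and streaming: memory is proportional to the
library, never to the number of reads.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqParseError, InputError
from .library import GuideLibrary

#: Vector sequence immediately upstream of the protospacer in a screen read.
DEFAULT_ANCHOR = "GGCTTTATATATCTTGTGGAAAGGACGAAACACCG"

_DNA_READ = frozenset("ACGTN")

# Assignment / extraction statuses
ASSIGNED = "assigned"
NO_ANCHOR = "no_anchor"
SHORT_TAIL = "short_tail"
NO_MATCH = "no_match"
AMBIGUOUS = "ambiguous"

STATUSES = (ASSIGNED, NO_ANCHOR, SHORT_TAIL, NO_MATCH, AMBIGUOUS)


@dataclass(frozen=True)
class ExtractionParams:
    """Parameters of the extraction + assignment contract."""

    anchor: str = DEFAULT_ANCHOR
    guide_length: int = 20
    max_mismatches: int = 3

    def __post_init__(self) -> None:
        if not self.anchor or not set(self.anchor) <= frozenset("ACGT"):
            raise InputError("anchor must be a non-empty A/C/G/T string")
        if self.guide_length < 1:
            raise InputError("guide_length must be >= 1")
        if not 0 <= self.max_mismatches <= 3:
            raise InputError("max_mismatches must be in 0..3")


@dataclass(frozen=True)
class ReadAssignment:
    status: str
    guide_id: str | None = None
    mismatches: int | None = None


def extract_protospacer(read: str, params: ExtractionParams) -> tuple[str, str | None]:
    """Return ``(status, protospacer)`` for one read.

    The anchor must occur as an exact substring; only its first occurrence
    is used and the read is never reverse-complemented (vector orientation
    is fixed by the assay). If fewer than ``guide_length`` bases follow the
    anchor the read is ``short_tail``.
    """
    pos = read.find(params.anchor)
    if pos < 0:
        return NO_ANCHOR, None
    start = pos + len(params.anchor)
    tail = read[start : start + params.guide_length]
    if len(tail) < params.guide_length:
        return SHORT_TAIL, None
    return ASSIGNED, tail


def hamming(a: str, b: str) -> int:
    """Hamming distance; N never matches, so it counts as a mismatch."""
    if len(a) != len(b):
        raise InputError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


class GuideIndex:
    """Exact + approximate protospacer lookup over a library.

    Mismatch search uses the pigeonhole principle: the protospacer is cut
    into ``max_mismatches + 1`` contiguous chunks; any sequence within the
    mismatch budget of a library guide must match that guide exactly in at
    least one chunk, so candidates are gathered from per-chunk hash tables
    and only those few are scored by full Hamming distance.
    """

    def __init__(self, lib: GuideLibrary, max_mismatches: int = 3) -> None:
        if max_mismatches < 0:
            raise InputError("max_mismatches must be >= 0")
        self.max_mismatches = max_mismatches
        self.guide_ids = lib.guide_ids
        self._seqs = [r.protospacer for r in lib.records]
        if self._seqs:
            lengths = {len(s) for s in self._seqs}
            if len(lengths) != 1:
                raise InputError("library protospacers have mixed lengths")
            self.guide_length = lengths.pop()
        else:
            self.guide_length = 0
        # exact map: seq -> guide index, or -1 when duplicated (ambiguous)
        self._exact: dict[str, int] = {}
        for i, s in enumerate(self._seqs):
            self._exact[s] = -1 if s in self._exact else i
        # chunk tables for approximate search
        k = max_mismatches + 1
        bounds = np.linspace(0, self.guide_length, k + 1).astype(int)
        self._chunks = list(zip(bounds[:-1], bounds[1:]))
        self._chunk_tables: list[dict[str, list[int]]] = []
        for lo, hi in self._chunks:
            table: dict[str, list[int]] = {}
            for i, s in enumerate(self._seqs):
                table.setdefault(s[lo:hi], []).append(i)
            self._chunk_tables.append(table)

    def assign(self, protospacer: str) -> ReadAssignment:
        """Assign a protospacer to a unique best guide (see module docs)."""
        if len(protospacer) != self.guide_length:
            raise InputError(
                f"protospacer length {len(protospacer)} != guide length "
                f"{self.guide_length}"
            )
        hit = self._exact.get(protospacer)
        if hit is not None:
            if hit < 0:  # duplicated protospacer: inherently ambiguous
                return ReadAssignment(AMBIGUOUS)
            return ReadAssignment(ASSIGNED, self.guide_ids[hit], 0)
        if self.max_mismatches == 0:
            return ReadAssignment(NO_MATCH)
        candidates: set[int] = set()
        for (lo, hi), table in zip(self._chunks, self._chunk_tables):
            candidates.update(table.get(protospacer[lo:hi], ()))
        best = self.max_mismatches + 1
        best_idx = -1
        tie = False
        for i in candidates:
            d = 0
            for x, y in zip(protospacer, self._seqs[i]):
                if x != y:
                    d += 1
                    if d > self.max_mismatches:
                        break
            if d < best:
                best, best_idx, tie = d, i, False
            elif d == best and d <= self.max_mismatches:
                tie = True
        if best > self.max_mismatches:
            return ReadAssignment(NO_MATCH)
        if tie:
            return ReadAssignment(AMBIGUOUS)
        return ReadAssignment(ASSIGNED, self.guide_ids[best_idx], best)


def assign_read(
    protospacer: str, lib: GuideLibrary | GuideIndex, max_mismatches: int = 3
) -> ReadAssignment:
    """One-shot assignment; builds a :class:`GuideIndex` if given a library."""
    index = (
        lib
        if isinstance(lib, GuideIndex)
        else GuideIndex(lib, max_mismatches=max_mismatches)
    )
    return index.assign(protospacer)


@dataclass
class ExtractionStats:
    reads_total: int = 0
    assigned: int = 0
    no_anchor: int = 0
    short_tail: int = 0
    no_match: int = 0
    ambiguous: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_total": self.reads_total,
            "assigned": self.assigned,
            "no_anchor": self.no_anchor,
            "short_tail": self.short_tail,
            "no_match": self.no_match,
            "ambiguous": self.ambiguous,
        }

    @property
    def anchor_bearing(self) -> int:
        return self.reads_total - self.no_anchor - self.short_tail


@dataclass
class CountTable:
    """Guide x sample matrix of read counts plus per-sample extraction stats.

    Every library guide appears (zero-filled); ``counts`` is int64 of shape
    (n_guides, n_samples).
    """

    guides: list[str]
    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    stats: dict[str, ExtractionStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.guides), len(self.samples)):
            raise InputError("counts shape does not match guides x samples")
        if (self.counts < 0).any():
            raise InputError("negative counts")

    @property
    def totals(self) -> dict[str, int]:
        sums = self.counts.sum(axis=0)
        return {s: int(t) for s, t in zip(self.samples, sums)}

    def column(self, sample: str) -> np.ndarray:
        try:
            j = self.samples.index(sample)
        except ValueError:
            raise InputError(f"no sample named {sample!r}") from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "gene", self.genes)
        df.insert(0, "guide_id", self.guides)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def stats_json(self) -> str:
        return json.dumps(
            {s: st.as_dict() for s, st in self.stats.items()}, indent=2
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        for col in ("guide_id", "gene"):
            if col not in df.columns:
                raise InputError(f"count table missing column {col!r}")
        samples = [c for c in df.columns if c not in ("guide_id", "gene")]
        if not samples:
            raise InputError("count table has no sample columns")
        return cls(
            guides=df["guide_id"].astype(str).tolist(),
            genes=df["gene"].astype(str).tolist(),
            samples=samples,
            counts=df[samples].to_numpy(dtype=np.int64),
        )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_reads(
    fastq_by_sample: Mapping[str, str | Path | Sequence[str | Path]],
    lib: GuideLibrary,
    params: ExtractionParams | None = None,
) -> CountTable:
    """Count reads per guide for one or more samples.

    ``fastq_by_sample`` maps sample name -> FASTQ path(s) (plain or gzip).
    Every read is tallied under exactly one status; quality strings are
    ignored. Malformed records raise :class:`FastqParseError` naming the
    file and the (0-based) record index.
    """
    if not fastq_by_sample:
        raise InputError("at least one sample is required")
    params = params or ExtractionParams()
    index = GuideIndex(lib, max_mismatches=params.max_mismatches)
    guide_pos = {g: i for i, g in enumerate(index.guide_ids)}
    samples = list(fastq_by_sample)
    counts = np.zeros((len(index.guide_ids), len(samples)), dtype=np.int64)
    stats: dict[str, ExtractionStats] = {}

    anchor = params.anchor
    alen = len(anchor)
    glen = params.guide_length
    exact = index._exact

    for j, sample in enumerate(samples):
        st = ExtractionStats()
        paths = fastq_by_sample[sample]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        col = counts[:, j]
        for path in paths:
            with _open_text(path) as handle:
                record_iter = FastqGeneralIterator(handle)
                i = -1
                while True:
                    i += 1
                    try:
                        item = next(record_iter)
                    except StopIteration:
                        break
                    except ValueError as exc:
                        raise FastqParseError(
                            f"{path}: malformed FASTQ record {i}: {exc}"
                        ) from exc
                    seq = item[1].upper()
                    st.reads_total += 1
                    pos = seq.find(anchor)
                    if pos < 0:
                        st.no_anchor += 1
                        continue
                    proto = seq[pos + alen : pos + alen + glen]
                    if len(proto) < glen:
                        st.short_tail += 1
                        continue
                    hit = exact.get(proto)
                    if hit is not None and hit >= 0:  # fast path: exact unique
                        col[hit] += 1
                        st.assigned += 1
                        continue
                    asg = (
                        ReadAssignment(AMBIGUOUS)
                        if hit is not None
                        else index.assign(proto)
                    )
                    if asg.status == ASSIGNED:
                        col[guide_pos[asg.guide_id]] += 1
                        st.assigned += 1
                    elif asg.status == AMBIGUOUS:
                        st.ambiguous += 1
                    else:
                        st.no_match += 1
        stats[sample] = st

    return CountTable(
        guides=index.guide_ids,
        genes=lib.genes,
        samples=samples,
        counts=counts,
        stats=stats,
    )
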