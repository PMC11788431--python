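"""Consensus motif scanning with a protected 3' core.

GLI transcription factors bind a 9-nt consensus, GACCACCCA, whose last
five residues are the most critical for binding. The scanner encodes that
asymmetry: a window is a hit when its last ``core_length`` positions match
the consensus exactly and the remaining 5' prefix carries at most
``max_prefix_mismatches`` mismatches (defaults: 5-nt core, 1 prefix
mismatch). Both strands are scanned; a minus-strand hit is a window whose
reverse complement matches, reported at its plus-strand coordinates with
the matched sequence in motif orientation.

Coordinates are 0-based half-open on the plus strand (BED convention).
Overlapping hits are all reported. Windows containing non-ACGT characters
are skipped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import InputError

#: High-affinity GLI-binding consensus.
GLI_CONSENSUS = "GACCACCCA"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """Consensus with a protected 3' core and a 5' prefix mismatch budget."""

    consensus: str = GLI_CONSENSUS
    core_length: int = 5
    max_prefix_mismatches: int = 1

    def __post_init__(self) -> None:
        if not self.consensus or not set(self.consensus) <= _DNA:
            raise InputError("consensus must be a non-empty A/C/G/T string")
        if not 0 < self.core_length <= len(self.consensus):
            raise InputError("core_length must be in 1..len(consensus)")
        if self.max_prefix_mismatches < 0:
            raise InputError("mismatch budget must be >= 0")

    @property
    def prefix(self) -> str:
        return self.consensus[: -self.core_length]

    @property
    def core(self) -> str:
        return self.consensus[-self.core_length :]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, plus-strand coordinates, half-open."""

    sequence_id: str
    start: int
    end: int
    strand: str
    matched: str  # motif-oriented sequence of the window
    mismatches: int


def _scan_oriented(seq: str, spec: MotifSpec) -> Iterable[tuple[int, int]]:
    """Yield (start, prefix_mismatches) of motif-orientation matches in seq."""
    m = len(spec.consensus)
    prefix, core = spec.prefix, spec.core
    plen = len(prefix)
    budget = spec.max_prefix_mismatches
    pos = 0
    n = len(seq)
    while True:
        pos = seq.find(core, pos)
        if pos < 0:
            break
        start = pos - plen
        if start >= 0 and pos + len(core) <= n:
            window_prefix = seq[start:pos]
            if set(window_prefix) <= _DNA:
                mm = sum(a != b for a, b in zip(window_prefix, prefix))
                if mm <= budget:
                    yield start, mm
        pos += 1


def scan_sequence(
    sequence_id: str, seq: str, spec: MotifSpec, strands: str = "both"
) -> list[MotifHit]:
    """Scan one sequence; see module docstring for the matching rule."""
    if strands not in ("both", "plus"):
        raise InputError("strands must be 'both' or 'plus'")
    seq = seq.upper()
    if not set(seq) <= _DNA:
        n_bad = sum(1 for ch in seq if ch not in _DNA)
        warnings.warn(
            f"{sequence_id}: {n_bad} non-ACGT position(s); windows covering "
            "them are skipped",
            stacklevel=2,
        )
    m = len(spec.consensus)
    hits = [
        MotifHit(sequence_id, s, s + m, "+", seq[s : s + m], mm)
        for s, mm in _scan_oriented(seq, spec)
    ]
    if strands == "both":
        rc = reverse_complement(seq)
        n = len(seq)
        for s, mm in _scan_oriented(rc, spec):
            start = n - s - m  # map back to plus-strand coordinates
            hits.append(
                MotifHit(sequence_id, start, start + m, "-", rc[s : s + m], mm)
            )
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.strand))
    return hits


def scan_motif(
    sequences: str | Path | Sequence[tuple[str, str]],
    spec: MotifSpec | None = None,
    strands: str = "both",
) -> list[MotifHit]:
    """Scan a FASTA file (path) or ``[(id, sequence), ...]`` pairs."""
    spec = spec or MotifSpec()
    if isinstance(sequences, (str, Path)):
        pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(sequences), "fasta")]
    else:
        pairs = list(sequences)
    if not pairs:
        raise InputError("no sequences to scan")
    hits: list[MotifHit] = []
    for sid, seq in pairs:
        hits.extend(scan_sequence(sid, seq, spec, strands=strands))
    return hits


def expected_exact_hits(seq_length: int, consensus_length: int = 9) -> float:
    """Expected exact-match count (both strands) in uniform random DNA:
    ``2 * (L - m + 1) * 4**-m`` for a non-palindromic consensus."""
    windows = max(0, seq_length - consensus_length + 1)
    return 2.0 * windows * 4.0 ** (-consensus_length)


def write_bed(hits: Iterable[MotifHit], path: str | Path) -> None:
    """BED6: name = matched (motif-oriented) sequence, score = mismatches."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.matched}\t"
                f"{h.mismatches}\t{h.strand}\n"
            )
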