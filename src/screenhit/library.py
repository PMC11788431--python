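"""Guide-library annotation tables.

A pooled knockout screen is defined against a reference universe of guides:
each guide has a unique identifier, a target gene symbol, and a 20-nt
protospacer (the programmable targeting sequence). Brunello-style annotation
files ship as delimited text with one row per guide; this module parses and
validates them, summarises library composition, and round-trips a canonical
TSV representation.

Non-targeting control guides are kept in the library under a reserved gene
label (:data:`CONTROL_GENE`); gene-level hit calling excludes them.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, InputError

#: Reserved gene label for non-targeting control guides.
CONTROL_GENE = "NON_TARGETING_CONTROL"

#: Expected protospacer length (nt).
GUIDE_LENGTH = 20

_DNA = frozenset("ACGT")

#: Default column names looked up in annotation tables. Values are tried in
#: order; the first present column wins.
DEFAULT_COLUMN_MAP: Mapping[str, Sequence[str]] = {
    "guide_id": ("guide_id", "sgRNA", "sgRNA Target Sequence ID", "id"),
    "gene": ("gene", "Gene", "Target Gene Symbol", "gene_symbol"),
    "protospacer": ("protospacer", "sequence", "sgRNA Target Sequence", "seq"),
}


@dataclass(frozen=True)
class GuideRecord:
    """One guide: identifier, target gene symbol, 20-nt protospacer."""

    guide_id: str
    gene: str
    protospacer: str

    def validate(self) -> None:
        if len(self.protospacer) != GUIDE_LENGTH:
            raise InputError(
                f"protospacer of {self.guide_id!r} has length "
                f"{len(self.protospacer)}, expected {GUIDE_LENGTH}"
            )
        if not set(self.protospacer) <= _DNA:
            raise InputError(
                f"protospacer of {self.guide_id!r} contains non-ACGT characters"
            )


@dataclass
class GuideLibrary:
    """Ordered collection of guides with a protospacer lookup.

    Duplicate protospacers are legal (Brunello contains a handful) but are
    recorded in :attr:`duplicate_protospacers` because an exact sequencing
    read of such a sequence cannot be assigned to a unique guide.
    """

    records: list[GuideRecord]
    by_sequence: dict[str, list[str]] = field(default_factory=dict)
    duplicate_protospacers: list[str] = field(default_factory=list)
    n_rejected: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.by_sequence:
            self._build_index()

    def _build_index(self) -> None:
        ids = {}
        for rec in self.records:
            if rec.guide_id in ids:
                raise InputError(f"duplicate guide_id {rec.guide_id!r}")
            ids[rec.guide_id] = True
            self.by_sequence.setdefault(rec.protospacer, []).append(rec.guide_id)
        self.duplicate_protospacers = sorted(
            seq for seq, gids in self.by_sequence.items() if len(gids) > 1
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        return [r.gene for r in self.records]

    def targeting_records(self) -> list[GuideRecord]:
        """Records excluding non-targeting controls."""
        return [r for r in self.records if r.gene != CONTROL_GENE]

    @classmethod
    def from_records(cls, records: Iterable[GuideRecord]) -> "GuideLibrary":
        recs = list(records)
        for r in recs:
            r.validate()
        return cls(records=recs)


@dataclass(frozen=True)
class LibrarySummary:
    n_guides: int
    n_genes: int
    guides_per_gene: dict[int, int]
    n_duplicate_protospacers: int
    n_control_guides: int = 0

    def to_json(self) -> str:
        d = {
            "n_guides": self.n_guides,
            "n_genes": self.n_genes,
            "guides_per_gene": {str(k): v for k, v in sorted(self.guides_per_gene.items())},
            "n_duplicate_protospacers": self.n_duplicate_protospacers,
            "n_control_guides": self.n_control_guides,
        }
        return json.dumps(d, indent=2)


def _resolve_column(columns: Sequence[str], candidates: str | Sequence[str], role: str) -> str:
    if isinstance(candidates, str):
        candidates = (candidates,)
    for cand in candidates:
        if cand in columns:
            return cand
    raise ConfigurationError(
        f"no column for {role!r}: tried {list(candidates)}, file has {list(columns)}"
    )


def parse_library(
    path: str | Path,
    column_map: Mapping[str, str | Sequence[str]] | None = None,
) -> GuideLibrary:
    """Parse a delimited guide annotation table into a :class:`GuideLibrary`.

    The delimiter is sniffed (comma or tab); a header row is required.
    Rows whose sequence is not a 20-nt A/C/G/T string are rejected and
    counted in ``library.n_rejected`` with per-row reasons in
    ``library.rejections`` (0-based data row index).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"library file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise InputError(f"empty or undelimited library file: {path}") from exc
    if df.empty:
        raise InputError(f"library file has a header but no rows: {path}")

    id_col = _resolve_column(df.columns, cmap["guide_id"], "guide_id")
    gene_col = _resolve_column(df.columns, cmap["gene"], "gene")
    seq_col = _resolve_column(df.columns, cmap["protospacer"], "protospacer")

    records: list[GuideRecord] = []
    rejections: list[tuple[int, str]] = []
    for i, (gid, gene, seq) in enumerate(
        zip(df[id_col], df[gene_col], df[seq_col])
    ):
        seq = str(seq).strip().upper()
        if len(seq) != GUIDE_LENGTH:
            rejections.append((i, f"length {len(seq)} != {GUIDE_LENGTH}"))
            continue
        if not set(seq) <= _DNA:
            rejections.append((i, "non-ACGT characters"))
            continue
        records.append(GuideRecord(str(gid).strip(), str(gene).strip(), seq))

    lib = GuideLibrary(records=records)
    lib.n_rejected = len(rejections)
    lib.rejections = rejections
    return lib


def library_summary(lib: GuideLibrary) -> LibrarySummary:
    """Summarise a library: guide/gene counts and a guides-per-gene histogram.

    Gene symbols are compared case-sensitively (annotation files are already
    normalized). The histogram maps guides-per-gene -> number of genes and
    sums to ``n_genes``. Control guides count toward ``n_guides`` and the
    control label counts as one gene symbol.
    """
    if len(lib) == 0:
        raise InputError("cannot summarise an empty library")
    per_gene = Counter(r.gene for r in lib.records)
    hist = Counter(per_gene.values())
    n_controls = sum(1 for r in lib.records if r.gene == CONTROL_GENE)
    return LibrarySummary(
        n_guides=len(lib),
        n_genes=len(per_gene),
        guides_per_gene=dict(hist),
        n_duplicate_protospacers=len(lib.duplicate_protospacers),
        n_control_guides=n_controls,
    )


def write_library(lib: GuideLibrary, path: str | Path) -> None:
    """Write the canonical TSV (guide_id, gene, protospacer)."""
    df = pd.DataFrame(
        {
            "guide_id": [r.guide_id for r in lib.records],
            "gene": [r.gene for r in lib.records],
            "protospacer": [r.protospacer for r in lib.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
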