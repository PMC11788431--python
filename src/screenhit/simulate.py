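"""Synthetic sorted-screen generator with planted hit genes.

The generator emulates the statistical structure of a single-pool
fluorescence-sorted knockout screen at the count level:

* library skew — per-guide relative abundances in the unsorted pool are
  log-normal(0, ``abundance_dispersion``), normalized to sum to one
  (lentiviral library representation is heavy-tailed);
* selection — guides targeting the planted hit genes have their relative
  abundance multiplied by ``enrichment_factor`` in the sorted pool, after
  which abundances are renormalized (sorting enriches, it does not create
  reads);
* sequencing — counts per sample are a single multinomial draw of
  ``reads_per_sample`` over the guide abundances, conditioning on total
  depth exactly as a sequencing lane does.

Reads can be emitted as FASTQ: a random 0-5 nt stagger prefix, the fixed
vector anchor, the guide protospacer, and a constant scaffold suffix, with
optional per-base substitution error everywhere except the anchor (so
extraction failures stay under explicit control). All randomness flows from
a single integer seed; identical configurations give identical output.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .counting import DEFAULT_ANCHOR, CountTable
from .errors import InputError
from .library import CONTROL_GENE, GUIDE_LENGTH, GuideLibrary, GuideRecord

#: Constant tracrRNA scaffold appended after the protospacer in emitted reads.
SCAFFOLD_SUFFIX = "GTTTTAGAGCTAGAAATAGC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated screen.

    Defaults are the desk-scale screen used throughout: 1000 genes x 4
    guides with 50 hit genes enriched 8-fold, log-normal dispersion 1.0,
    and 2x10^6 reads per sample.
    """

    n_genes: int = 1000
    guides_per_gene: int = 4
    n_control_guides: int = 0
    n_hit_genes: int = 50
    enrichment_factor: float = 8.0
    abundance_dispersion: float = 1.0
    reads_per_sample: int = 2_000_000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hit_genes > self.n_genes:
            raise InputError("n_hit_genes cannot exceed n_genes")
        if self.enrichment_factor <= 1:
            raise InputError("enrichment_factor must be > 1")
        if not 0 <= self.error_rate < 1:
            raise InputError("error_rate must be in [0, 1)")
        if self.abundance_dispersion <= 0:
            raise InputError("abundance_dispersion must be positive")


@dataclass
class SimTruth:
    """Planted ground truth of a simulated screen."""

    hit_genes: set[str]
    guide_factors: dict[str, float]
    unsorted_abundance: np.ndarray
    sorted_abundance: np.ndarray


def _random_distinct_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    if n > 4**k:
        raise InputError(f"cannot draw {n} distinct {k}-mers")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = _BASES[rng.integers(0, 4, size=(n - len(out), k))]
        for row in batch:
            s = row.tobytes().decode("ascii")
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def simulate_library(
    n_genes: int,
    guides_per_gene: int = 4,
    n_control_guides: int = 0,
    seed: int | np.random.SeedSequence = 0,
) -> GuideLibrary:
    """Random library: ``n_genes x guides_per_gene`` targeting guides plus
    optional non-targeting controls, all with distinct random protospacers."""
    if n_genes < 1 or guides_per_gene < 1 or n_control_guides < 0:
        raise InputError("library dimensions must be positive")
    rng = np.random.default_rng(seed)
    n_total = n_genes * guides_per_gene + n_control_guides
    seqs = _random_distinct_kmers(rng, n_total, GUIDE_LENGTH)
    width = len(str(n_genes))
    records = []
    i = 0
    for g in range(n_genes):
        gene = f"GENE{g + 1:0{width}d}"
        for j in range(guides_per_gene):
            records.append(GuideRecord(f"{gene}_sg{j + 1}", gene, seqs[i]))
            i += 1
    for j in range(n_control_guides):
        records.append(GuideRecord(f"CTRL_sg{j + 1}", CONTROL_GENE, seqs[i]))
        i += 1
    return GuideLibrary.from_records(records)


def simulate_screen_counts(
    lib: GuideLibrary,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountTable, SimTruth]:
    """Draw sorted/unsorted counts for a library with planted hit genes.

    Hit genes are sampled uniformly from the targeting genes; every guide
    of a hit gene carries the full enrichment factor, every other guide
    (controls included) has factor 1.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes = np.array(lib.genes)
    targeting = sorted(set(g for g in lib.genes if g != CONTROL_GENE))
    if config.n_hit_genes > len(targeting):
        raise InputError("more hit genes requested than targeting genes present")
    hit_genes = set(
        rng.choice(np.array(targeting), size=config.n_hit_genes, replace=False)
    )
    factors = np.where(
        np.isin(genes, sorted(hit_genes)), config.enrichment_factor, 1.0
    )

    n = len(lib)
    unsorted_ab = rng.lognormal(0.0, config.abundance_dispersion, size=n)
    unsorted_ab /= unsorted_ab.sum()
    sorted_ab = unsorted_ab * factors
    sorted_ab /= sorted_ab.sum()

    counts = np.column_stack(
        [
            rng.multinomial(config.reads_per_sample, unsorted_ab),
            rng.multinomial(config.reads_per_sample, sorted_ab),
        ]
    )
    table = CountTable(
        guides=lib.guide_ids,
        genes=list(genes),
        samples=["unsorted", "sorted"],
        counts=counts,
    )
    truth = SimTruth(
        hit_genes=hit_genes,
        guide_factors={
            r.guide_id: float(f) for r, f in zip(lib.records, factors)
        },
        unsorted_abundance=unsorted_ab,
        sorted_abundance=sorted_ab,
    )
    return table, truth


def simulate_screen(
    config: SimConfig,
) -> tuple[GuideLibrary, CountTable, SimTruth]:
    """Library + counts in one call, fully determined by ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    lib_seed, counts_seed = ss.spawn(2)
    lib = simulate_library(
        config.n_genes,
        config.guides_per_gene,
        config.n_control_guides,
        seed=lib_seed,
    )
    counts, truth = simulate_screen_counts(
        lib, config, rng=np.random.default_rng(counts_seed)
    )
    return lib, counts, truth


def write_synthetic_fastq(
    counts: CountTable,
    sample: str,
    lib: GuideLibrary,
    path: str | Path,
    anchor: str = DEFAULT_ANCHOR,
    error_rate: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> int:
    """Emit one FASTQ read per counted unit of ``sample``; returns the read count.

    Read layout: 0-5 nt random prefix + anchor + protospacer + scaffold.
    Substitution errors are applied at ``error_rate`` per base everywhere
    except the anchor. Reads are emitted in shuffled order; gzip output is
    selected by a ``.gz`` suffix.
    """
    if not 0 <= error_rate < 1:
        raise InputError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    col = counts.column(sample)
    seqs = {r.guide_id: r.protospacer for r in lib.records}
    try:
        protos = [seqs[g] for g in counts.guides]
    except KeyError as exc:
        raise InputError(f"guide {exc.args[0]!r} not in library") from None

    order = rng.permutation(np.repeat(np.arange(len(col)), col))
    n_reads = order.size
    prefix_lens = rng.integers(0, 6, size=n_reads)
    prefix_bases = _BASES[rng.integers(0, 4, size=int(prefix_lens.sum()))]
    alen = len(anchor)
    glen = len(protos[0]) if protos else GUIDE_LENGTH
    mut_len = prefix_lens + glen + len(SCAFFOLD_SUFFIX)
    n_errors = (
        rng.binomial(mut_len, error_rate) if error_rate > 0
        else np.zeros(n_reads, dtype=np.int64)
    )

    opener = gzip.open if str(path).endswith(".gz") else open
    pb_off = 0
    with opener(path, "wt") as fh:
        buf: list[str] = []
        for i in range(n_reads):
            plen = int(prefix_lens[i])
            prefix = prefix_bases[pb_off : pb_off + plen].tobytes().decode("ascii")
            pb_off += plen
            read = prefix + anchor + protos[order[i]] + SCAFFOLD_SUFFIX
            ne = int(n_errors[i])
            if ne:
                # positions index the mutable region: prefix, then post-anchor
                pos = rng.choice(int(mut_len[i]), size=ne, replace=False)
                shifts = rng.integers(1, 4, size=ne)
                arr = bytearray(read, "ascii")
                for p, sh in zip(pos, shifts):
                    rp = p if p < plen else p + alen
                    base = b"ACGT".index(arr[rp])
                    arr[rp] = b"ACGT"[(base + sh) % 4]
                read = arr.decode("ascii")
            buf.append(f"@sim_{i}\n{read}\n+\n{'I' * len(read)}\n")
            if len(buf) >= 10000:
                fh.write("".join(buf))
                buf.clear()
        fh.write("".join(buf))
    return n_reads


def inject_junk_reads(
    path: str | Path,
    n_reads: int,
    read_length: int = 75,
    seed: int | np.random.SeedSequence = 0,
    append: bool = True,
) -> int:
    """Append anchor-free random reads (extraction-failure controls)."""
    rng = np.random.default_rng(seed)
    opener = gzip.open if str(path).endswith(".gz") else open
    mode = "at" if append else "wt"
    with opener(path, mode) as fh:
        for i in range(n_reads):
            seq = _BASES[rng.integers(0, 4, size=read_length)].tobytes().decode()
            fh.write(f"@junk_{i}\n{seq}\n+\n{'I' * read_length}\n")
    return n_reads
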