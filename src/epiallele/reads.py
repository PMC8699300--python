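"""Raw amplicon reads -> per-sample methylation pattern tables.

The stages mirror a targeted bisulfite-amplicon workflow: merge read pairs,
demultiplex on the dual 8-bp barcodes (excluding chimeric pairs never used
in library construction), call per-CpG methylation states against the
in-silico converted reference, and filter reads on bisulfite conversion
rate and unrecognized sites.

Disposition precedence is UNASSIGNED > CHIMERA > CONVERSION > UNRECOGNIZED,
so every read is counted exactly once and input read count always equals
retained + sum of exclusions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .design import BarcodeScheme, LocusSpec, revcomp

logger = logging.getLogger(__name__)

RETAINED = "retained"
EXCLUDED_UNASSIGNED = "excluded_unassigned"
EXCLUDED_CHIMERA = "excluded_chimera"
EXCLUDED_CONVERSION = "excluded_conversion"
EXCLUDED_UNRECOGNIZED = "excluded_unrecognized"
EXCLUDED_UNMERGED = "excluded_unmerged"

DISPOSITIONS = (
    RETAINED,
    EXCLUDED_UNASSIGNED,
    EXCLUDED_CHIMERA,
    EXCLUDED_CONVERSION,
    EXCLUDED_UNRECOGNIZED,
    EXCLUDED_UNMERGED,
)

METH, UNMETH, UNRECOGNIZED = "C", "T", "N"


@dataclass
class ProcessedRead:
    """One demultiplexed, methylation-called read."""

    sample: str | None
    locus: str | None
    states: str | None  # over {C, T, N}, length = locus CpG count
    conversion_rate: float | None
    disposition: str


class MethylationPatternTable:
    """Per (sample, locus) counts of full-length CpG state patterns.

    ``counts[(sample, locus)]`` maps a pattern string over {C, T} to the
    number of retained molecules carrying it; ``exclusions[(sample, locus)]``
    tallies excluded reads by disposition (sample/locus may be None when a
    read could not be attributed).
    """

    def __init__(self) -> None:
        self.counts: dict[tuple[str, str], Counter] = {}
        self.exclusions: dict[tuple[str | None, str | None], Counter] = {}

    def add_pattern(self, sample: str, locus: str, pattern: str, n: int = 1) -> None:
        self.counts.setdefault((sample, locus), Counter())[pattern] += int(n)

    def add_exclusion(
        self, sample: str | None, locus: str | None, disposition: str, n: int = 1
    ) -> None:
        self.exclusions.setdefault((sample, locus), Counter())[disposition] += int(n)

    def patterns(self, sample: str, locus: str) -> Counter:
        return self.counts.get((sample, locus), Counter())

    def retained_total(self, sample: str, locus: str) -> int:
        return sum(self.patterns(sample, locus).values())

    def total_retained(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def total_excluded(self) -> Counter:
        out: Counter = Counter()
        for c in self.exclusions.values():
            out.update(c)
        return out

    def total_reads(self) -> int:
        return self.total_retained() + sum(self.total_excluded().values())

    def samples(self) -> list[str]:
        return sorted({s for s, _ in self.counts})

    def loci(self) -> list[str]:
        return sorted({l for _, l in self.counts})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationPatternTable):
            return NotImplemented
        mine = {k: {p: n for p, n in c.items() if n} for k, c in self.counts.items()}
        theirs = {k: {p: n for p, n in c.items() if n} for k, c in other.counts.items()}
        return mine == theirs

    def exclusion_summary(self) -> dict:
        return {
            "total_reads": self.total_reads(),
            "retained": self.total_retained(),
            "excluded": dict(self.total_excluded()),
        }

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tlocus\tpattern\tcount\n")
            for (sample, locus) in sorted(self.counts):
                for pattern, n in sorted(self.counts[(sample, locus)].items()):
                    if n:
                        fh.write(f"{sample}\t{locus}\t{pattern}\t{n}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MethylationPatternTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("sample\t"):
                raise ValueError(f"unexpected header in {path}: {header!r}")
            for line in fh:
                sample, locus, pattern, n = line.rstrip("\n").split("\t")
                table.add_pattern(sample, locus, pattern, int(n))
        return table


# ---------------------------------------------------------------------------
# Pair merging

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def merge_pairs(
    read1: str,
    read2: str,
    qual1: str | None = None,
    qual2: str | None = None,
    min_overlap: int = 10,
) -> str | None:
    """Merge overlapping mates into one insert sequence.

    ``read2`` is given in the same orientation as read1 (callers reverse-
    complement the raw R2 first).  The longest overlap with at most 10%
    mismatches (minimum 1) is used; overlap mismatches are resolved by the
    higher base quality, ties by read1.  Returns None when no acceptable
    overlap of at least ``min_overlap`` exists.
    """
    max_k = min(len(read1), len(read2))
    for k in range(max_k, min_overlap - 1, -1):
        tail, head = read1[-k:], read2[:k]
        if _hamming(tail, head) <= max(1, k // 10):
            merged = list(read1[: len(read1) - k])
            q1 = qual1[-k:] if qual1 else "I" * k
            q2 = qual2[:k] if qual2 else "I" * k
            for i in range(k):
                if tail[i] == head[i] or q1[i] >= q2[i]:
                    merged.append(tail[i])
                else:
                    merged.append(head[i])
            merged.append(read2[k:])
            return "".join(merged)
    return None


# ---------------------------------------------------------------------------
# Demultiplexing

class DemuxIndex:
    """Precomputed lookups for fast demultiplexing against a design."""

    def __init__(self, loci: list[LocusSpec], scheme: BarcodeScheme, max_primer_mismatch: int = 2):
        self.scheme = scheme
        self.max_primer_mismatch = max_primer_mismatch
        self.x_inv = {seq: label for label, seq in scheme.x_codes.items()}
        self.y_inv = {seq: label for label, seq in scheme.y_codes.items()}
        self.pair_to_sample = scheme.pair_lookup()
        self.by_length: dict[int, list[tuple[LocusSpec, str, str]]] = {}
        for loc in loci:
            entry = (loc, loc.primer_forward, revcomp(loc.primer_reverse))
            self.by_length.setdefault(16 + loc.insert_length_bp, []).append(entry)


@dataclass
class DemuxResult:
    disposition: str  # RETAINED here means "assigned"; filtering happens later
    sample: str | None
    locus: LocusSpec | None
    insert: str | None  # barcode-trimmed, reference-sense orientation


def _match_layout(s: str, pf: str, rc_pr: str, max_mm: int) -> bool:
    region5 = s[8 : 8 + len(pf)]
    if region5 != pf and _hamming(region5, pf) > max_mm:
        return False
    region3 = s[-8 - len(rc_pr) : -8]
    return region3 == rc_pr or _hamming(region3, rc_pr) <= max_mm


def demultiplex(seq: str, index: DemuxIndex) -> DemuxResult:
    """Assign a merged read to (sample, locus) or an exclusion disposition.

    Both orientations are tried; the 8-mers at the two ends are matched
    exactly against the X and Y lists in the locus's configured orientation.
    A pair of known codes never used in library construction is a chimera;
    an unknown code or unmatched primer layout leaves the read unassigned.
    """
    candidates = index.by_length.get(len(seq))
    if not candidates:
        return DemuxResult(EXCLUDED_UNASSIGNED, None, None, None)
    for loc, pf, rc_pr in candidates:
        for oriented in (seq, revcomp(seq)):
            if not _match_layout(oriented, pf, rc_pr, index.max_primer_mismatch):
                continue
            bc5, bc3 = oriented[:8], revcomp(oriented[-8:])
            x_seq, y_seq = (bc5, bc3) if loc.x_on == "forward" else (bc3, bc5)
            x = index.x_inv.get(x_seq)
            y = index.y_inv.get(y_seq)
            insert = oriented[8:-8]
            if x is None or y is None:
                return DemuxResult(EXCLUDED_UNASSIGNED, None, loc, insert)
            sample = index.pair_to_sample.get((x, y))
            if sample is None:
                return DemuxResult(EXCLUDED_CHIMERA, None, loc, insert)
            return DemuxResult(RETAINED, sample, loc, insert)
    return DemuxResult(EXCLUDED_UNASSIGNED, None, None, None)


# ---------------------------------------------------------------------------
# Methylation calling

def call_methylation(
    insert: str, locus: LocusSpec, max_mismatch_frac: float = 0.10
) -> tuple[str | None, float | None]:
    """Call per-CpG states and the bisulfite conversion rate for one insert.

    Fast path: gapless per-position comparison against the converted
    reference (amplicons are fixed-length; sequencing substitutions leave
    the frame intact).  If the insert length differs or the non-CpG
    mismatch fraction exceeds ``max_mismatch_frac``, falls back to a global
    alignment with CpG positions wildcarded.  Returns (None, None) when
    alignment fails (identity below floor) — callers treat that read as
    unassignable.

    At each CpG: C -> methylated, T -> unmethylated, anything else (or a
    gap) -> unrecognized.  Conversion rate = fraction of reference non-CpG
    cytosine positions read as T.
    """
    ref = locus.converted_reference()
    cpg_idx = [p - 1 for p in locus.cpg_positions]
    noncpg_c_idx = [p - 1 for p in locus.non_cpg_c_positions]
    if len(insert) == len(ref):
        insert = insert.upper()
        cpg_set = set(cpg_idx)
        mism = sum(
            1 for i, (a, b) in enumerate(zip(insert, ref)) if i not in cpg_set and a != b
        )
        if mism <= max_mismatch_frac * (len(ref) - len(cpg_idx)):
            states = "".join(
                METH if insert[i] == "C" else UNMETH if insert[i] == "T" else UNRECOGNIZED
                for i in cpg_idx
            )
            rate = (
                sum(insert[i] == "T" for i in noncpg_c_idx) / len(noncpg_c_idx)
                if noncpg_c_idx
                else 1.0
            )
            return states, rate
    return _call_aligned(insert, locus)


def _call_aligned(
    insert: str, locus: LocusSpec, min_identity: float = 0.7
) -> tuple[str | None, float | None]:
    """Global alignment fallback for inserts with indels or heavy mismatch."""
    from Bio import Align

    ref = locus.converted_reference()
    cpg_idx = [p - 1 for p in locus.cpg_positions]
    target = "".join("N" if i in set(cpg_idx) else b for i, b in enumerate(ref))
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-2,
        wildcard="N",
    )
    try:
        aln = aligner.align(target, insert.upper())[0]
    except (ValueError, IndexError):
        return None, None
    read_at = [""] * len(ref)  # read base aligned to each reference position
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            read_at[t0 + k] = insert[q0 + k].upper()
    cpg_set = set(cpg_idx)
    matches = sum(
        1
        for i, b in enumerate(read_at)
        if b and (b == ref[i] or (i in cpg_set and b in "CT"))
    )
    if matches / len(ref) < min_identity:
        return None, None
    states = "".join(
        METH if read_at[i] == "C" else UNMETH if read_at[i] == "T" else UNRECOGNIZED
        for i in cpg_idx
    )
    aligned_c = [i for i in (p - 1 for p in locus.non_cpg_c_positions) if read_at[i]]
    rate = sum(read_at[i] == "T" for i in aligned_c) / len(aligned_c) if aligned_c else 1.0
    return states, rate


# ---------------------------------------------------------------------------
# Filtering / aggregation

def filter_reads(
    reads: list[ProcessedRead], min_conversion: float = 0.95
) -> MethylationPatternTable:
    """Aggregate called reads into a pattern table with exclusion tallies.

    A read is retained iff its conversion rate is at least ``min_conversion``
    (inclusive boundary) and no CpG state is unrecognized.
    """
    table = MethylationPatternTable()
    for read in reads:
        if read.disposition in (EXCLUDED_UNASSIGNED, EXCLUDED_CHIMERA, EXCLUDED_UNMERGED):
            table.add_exclusion(read.sample, read.locus, read.disposition)
        elif read.states is None:
            table.add_exclusion(read.sample, read.locus, EXCLUDED_UNASSIGNED)
        elif read.conversion_rate < min_conversion:
            table.add_exclusion(read.sample, read.locus, EXCLUDED_CONVERSION)
        elif UNRECOGNIZED in read.states:
            table.add_exclusion(read.sample, read.locus, EXCLUDED_UNRECOGNIZED)
        else:
            table.add_pattern(read.sample, read.locus, read.states)
    return table


def process_reads(
    seqs,
    loci: list[LocusSpec],
    scheme: BarcodeScheme,
    min_conversion: float = 0.95,
) -> MethylationPatternTable:
    """Reference per-read pipeline: demultiplex, call, filter one read at a time."""
    index = DemuxIndex(loci, scheme)
    processed: list[ProcessedRead] = []
    for seq in seqs:
        d = demultiplex(seq, index)
        if d.disposition != RETAINED:
            processed.append(
                ProcessedRead(d.sample, d.locus.name if d.locus else None, None, None, d.disposition)
            )
            continue
        states, rate = call_methylation(d.insert, d.locus)
        processed.append(ProcessedRead(d.sample, d.locus.name, states, rate, RETAINED))
    return filter_reads(processed, min_conversion)


# ---------------------------------------------------------------------------
# Vectorized FASTQ pipeline

def _call_batch(
    inserts: list[str], locus: LocusSpec, max_mismatch_frac: float = 0.10
) -> tuple[list[str | None], list[float | None]]:
    """Vectorized gapless calling over same-length inserts, with per-read fallback."""
    ref = locus.converted_reference()
    L = len(ref)
    cpg_idx = np.array([p - 1 for p in locus.cpg_positions])
    noncpg_c = np.array([p - 1 for p in locus.non_cpg_c_positions])
    gapless_rows = [i for i, s in enumerate(inserts) if len(s) == L]
    states_out: list[str | None] = [None] * len(inserts)
    rates_out: list[float | None] = [None] * len(inserts)

    if gapless_rows:
        arr = np.frombuffer(
            "".join(inserts[i] for i in gapless_rows).upper().encode(), dtype=np.uint8
        ).reshape(len(gapless_rows), L)
        ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
        non_cpg_mask = np.ones(L, dtype=bool)
        non_cpg_mask[cpg_idx] = False
        mism = ((arr != ref_arr) & non_cpg_mask).sum(axis=1)
        ok = mism <= max_mismatch_frac * non_cpg_mask.sum()
        cpg_bases = arr[:, cpg_idx]
        state_codes = np.full(cpg_bases.shape, ord("N"), dtype=np.uint8)
        state_codes[cpg_bases == ord("C")] = ord("C")
        state_codes[cpg_bases == ord("T")] = ord("T")
        if noncpg_c.size:
            rates = (arr[:, noncpg_c] == ord("T")).mean(axis=1)
        else:
            rates = np.ones(len(gapless_rows))
        for j, i in enumerate(gapless_rows):
            if ok[j]:
                states_out[i] = state_codes[j].tobytes().decode()
                rates_out[i] = float(rates[j])
    for i, s in enumerate(inserts):
        if states_out[i] is None and rates_out[i] is None:
            states_out[i], rates_out[i] = _call_aligned(s, locus)
    return states_out, rates_out


def process_fastq(
    fastq_path: str | Path,
    loci: list[LocusSpec],
    scheme: BarcodeScheme,
    min_conversion: float = 0.95,
    chunk_size: int = 250_000,
) -> MethylationPatternTable:
    """Full pipeline over a (possibly large) merged-read FASTQ file.

    Equivalent to :func:`process_reads` but demultiplexes in a streaming
    loop and vectorizes methylation calling per (sample, locus) batch.
    """
    import pysam

    index = DemuxIndex(loci, scheme)
    loci_by_name = {loc.name: loc for loc in loci}
    table = MethylationPatternTable()

    def flush(buffers: dict[tuple[str, str], list[str]]) -> None:
        for (sample, locus_name), inserts in buffers.items():
            locus = loci_by_name[locus_name]
            states_list, rates = _call_batch(inserts, locus)
            for states, rate in zip(states_list, rates):
                if states is None:
                    table.add_exclusion(sample, locus_name, EXCLUDED_UNASSIGNED)
                elif rate < min_conversion:
                    table.add_exclusion(sample, locus_name, EXCLUDED_CONVERSION)
                elif UNRECOGNIZED in states:
                    table.add_exclusion(sample, locus_name, EXCLUDED_UNRECOGNIZED)
                else:
                    table.add_pattern(sample, locus_name, states)
        buffers.clear()

    buffers: dict[tuple[str, str], list[str]] = {}
    pending = 0
    with pysam.FastxFile(str(fastq_path)) as fh:
        for entry in fh:
            d = demultiplex(entry.sequence, index)
            if d.disposition != RETAINED:
                table.add_exclusion(d.sample, d.locus.name if d.locus else None, d.disposition)
                continue
            buffers.setdefault((d.sample, d.locus.name), []).append(d.insert)
            pending += 1
            if pending >= chunk_size:
                flush(buffers)
                pending = 0
    flush(buffers)

    for sample in scheme.samples:
        for loc in loci:
            total = table.retained_total(sample, loc.name)
            if total:
                logger.info("%s %s: retained %d reads", sample, loc.name, total)
    return table
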