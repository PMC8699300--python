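"""Synthetic cfDNA cohort generator with known ground-truth epiallele mixtures.

Each (group, locus) is a finite mixture of epiallele classes — per-CpG
methylation probability vectors with mixture weights — emulating
heterogeneous methylation: different molecules of the same locus carry
different methylation patterns, and the tumor- or hyperplasia-specific
patterns are rare (0.1–1% scale) against a background of fully
unmethylated molecules.  Per-sample biological variability is modeled as
lognormal jitter on the non-background class weights.

Reads are emitted as merged full-amplicon sequences: 8-bp barcode, primer
footprint, bisulfite-converted insert, reverse primer footprint, 8-bp
barcode (reverse-complemented), with three independent per-base noise
processes: conversion failure (a non-CpG C stays C), inappropriate
conversion (a methylated CpG C reads T) and sequencing substitution.
A configurable fraction of reads receives a barcode pair never used in
library construction (PCR chimeras).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .design import BarcodeScheme, LocusSpec, enumerate_chimeric_pairs, revcomp
from .reads import MethylationPatternTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class EpialleleClass:
    """One epiallele class: a per-CpG methylation probability vector."""

    name: str
    meth_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.meth_probs):
            raise ValueError(f"class {self.name}: probabilities outside [0, 1]")


@dataclass
class EpialleleModel:
    """Generative mixture over methylation patterns per (group, locus).

    ``mixtures[(group, locus_name)]`` is a list of (class, weight) pairs
    whose weights sum to 1.  The first class of each mixture is treated as
    the background; per-sample dispersion multiplies the other weights by
    lognormal(0, dispersion_sigma) factors and the background absorbs the
    remainder.
    """

    mixtures: dict[tuple[str, str], list[tuple[EpialleleClass, float]]]
    conversion_failure_rate: float = 0.01
    inappropriate_conversion_rate: float = 0.005
    sequencing_error_rate: float = 0.001
    coverage_range: tuple[int, int] = (5000, 20000)
    chimera_rate: float = 0.01
    dispersion_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (
            self.conversion_failure_rate,
            self.inappropriate_conversion_rate,
            self.sequencing_error_rate,
            self.chimera_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("noise rates must lie in [0, 1]")
        for key, mix in self.mixtures.items():
            total = sum(w for _, w in mix)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture weights for {key} sum to {total}, not 1")
            if any(w < 0 for _, w in mix):
                raise ValueError(f"negative mixture weight for {key}")
        if self.coverage_range[0] < 1 or self.coverage_range[1] < self.coverage_range[0]:
            raise ValueError("coverage_range must be positive and ordered")

    def expected_variable(self, group: str, spec) -> float:
        """Exact model expectation of a variable's proportion (pre-noise).

        ``spec`` is a :class:`~epiallele.variables.VariableSpec` (or a name
        parseable by :func:`~epiallele.variables.parse_variable`).
        """
        from .variables import parse_variable

        if isinstance(spec, str):
            spec = parse_variable(spec)
        mix = self.mixtures[(group, spec.locus)]
        total = 0.0
        for cls, w in mix:
            prod = 1.0
            for pos, status in zip(spec.positions, spec.statuses):
                p = cls.meth_probs[pos - 1]
                prod *= p if status == "C" else 1.0 - p
            total += w * prod
        return total

    def sample_weights(self, group: str, locus_name: str, rng: np.random.Generator):
        """Per-sample jittered mixture weights (background class absorbs)."""
        mix = self.mixtures[(group, locus_name)]
        base = np.array([w for _, w in mix])
        if self.dispersion_sigma <= 0 or len(base) == 1:
            return base
        w = base.copy()
        w[1:] = w[1:] * np.exp(self.dispersion_sigma * rng.standard_normal(len(w) - 1))
        rest = w[1:].sum()
        if rest >= 0.99:
            w[1:] *= 0.99 / rest
            rest = 0.99
        w[0] = 1.0 - rest
        return w


@dataclass
class TruthTable:
    """Exact pre-noise pattern counts per (sample, locus), with group labels."""

    pattern_table: MethylationPatternTable
    groups: dict[str, str]

    def to_tsv(self, path: str | Path) -> None:
        self.pattern_table.to_tsv(path)


def default_calibrated_model(
    loci: list[LocusSpec], scheme: BarcodeScheme | None = None, seed: int = 0, **overrides
) -> EpialleleModel:
    """The default cohort model, calibrated to the study's group-level anchors.

    GSTP1 carries a fully methylated tumor class (~8.35% of molecules in
    PCa, ~0.16% elsewhere, driving C9) and a hyperplasia class methylated
    at CpGs 3, 13 and 16 (~10% in BPH), so healthy donors keep ~99.7% of
    molecules unmethylated at positions 3 and 13 while both tumor groups
    drop to ~90%.  RNF219 methylation is nearly absent in BPH (pairwise-CC
    frequencies in the 0.005% range) but present at ~0.13–0.20% in the
    other groups.  KIAA1539 does not differ between groups.
    """
    by_name = {loc.name: loc for loc in loci}

    def cls(name: str, n: int, positions: tuple[int, ...] = (), full: bool = False) -> EpialleleClass:
        probs = [1.0] * n if full else [0.0] * n
        for p in positions:
            probs[p - 1] = 1.0
        return EpialleleClass(name, tuple(probs))

    mixtures: dict[tuple[str, str], list[tuple[EpialleleClass, float]]] = {}

    n = by_name["GSTP1"].n_cpg
    u, m = cls("unmethylated", n), cls("fully_methylated", n, full=True)
    b = cls("bph_3_13_16", n, positions=(3, 13, 16))
    for group, (wm, wb) in {
        "HD": (0.0016, 0.001),
        "BPH": (0.0016, 0.10),
        "PCa": (0.0835, 0.01),
    }.items():
        mixtures[(group, "GSTP1")] = [(u, 1.0 - wm - wb), (m, wm), (b, wb)]

    n = by_name["RNF219"].n_cpg
    u, m = cls("unmethylated", n), cls("fully_methylated", n, full=True)
    r = cls("half_methylated_1_8", n, positions=tuple(range(1, 9)))
    for group, (wm, wr) in {
        "HD": (0.0013, 0.0007),
        "PCa": (0.0013, 0.0007),
        "BPH": (0.00003, 0.00002),
    }.items():
        mixtures[(group, "RNF219")] = [(u, 1.0 - wm - wr), (m, wm), (r, wr)]

    n = by_name["KIAA1539"].n_cpg
    u, m = cls("unmethylated", n), cls("fully_methylated", n, full=True)
    for group in ("HD", "BPH", "PCa"):
        mixtures[(group, "KIAA1539")] = [(u, 0.99), (m, 0.01)]

    return EpialleleModel(mixtures=mixtures, seed=seed, **overrides)


def default_wgbs_tissue_model(loci: list[LocusSpec], seed: int = 0) -> EpialleleModel:
    """Tissue-scale methylation model for the WGBS binary re-screen.

    Prostate biopsies and primary epithelial cells carry discrete
    methylation at far higher molecule fractions than cfDNA: roughly half
    of normal-group reads and ~80% of cancer-group reads are methylated at
    the GSTP1 locus in the screened public datasets.  The model therefore
    mixes fully methylated and fully unmethylated molecules at those
    weights (normal ~52%, cancer ~80% methylated).
    """
    gstp1 = next(l for l in loci if l.name == "GSTP1")
    n = gstp1.n_cpg
    u = EpialleleClass("unmethylated", (0.0,) * n)
    m = EpialleleClass("fully_methylated", (1.0,) * n)
    mixtures = {
        ("HD", "GSTP1"): [(u, 0.482), (m, 0.518)],
        ("PCa", "GSTP1"): [(u, 0.201), (m, 0.799)],
    }
    return EpialleleModel(mixtures=mixtures, dispersion_sigma=0.15, seed=seed)


def null_model(model: EpialleleModel, reference_group: str = "HD", seed: int | None = None) -> EpialleleModel:
    """A copy of ``model`` with identical mixtures in every group.

    Under this model no variable differs between groups, so any
    significant screen hit is a false positive — the null-calibration
    condition for the comparison machinery.
    """
    groups = sorted({g for g, _ in model.mixtures})
    locus_names = sorted({l for _, l in model.mixtures})
    mixtures = {
        (g, l): list(model.mixtures[(reference_group, l)]) for g in groups for l in locus_names
    }
    return replace(model, mixtures=mixtures, seed=model.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# Pattern drawing

def _draw_patterns(
    cls: EpialleleClass, count: int, rng: np.random.Generator
) -> dict[str, int]:
    """Realized methylation patterns (strings over {C, T}) for one class."""
    probs = np.array(cls.meth_probs)
    if np.all((probs == 0.0) | (probs == 1.0)):
        pattern = "".join("C" if p else "T" for p in probs)
        return {pattern: count}
    draws = rng.random((count, len(probs))) < probs
    out: dict[str, int] = {}
    for row in draws:
        key = "".join("C" if v else "T" for v in row)
        out[key] = out.get(key, 0) + 1
    return out


def _pattern_reads(
    pattern: str,
    count: int,
    locus: LocusSpec,
    model: EpialleleModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noisy converted-read byte matrix (count x insert length) for one pattern."""
    template = np.frombuffer(locus.converted_reference().encode(), dtype=np.uint8).copy()
    cpg_idx = np.array([p - 1 for p in locus.cpg_positions])
    meth_mask = np.frombuffer(pattern.encode(), dtype=np.uint8) == ord("C")
    template[cpg_idx[~meth_mask]] = ord("T")
    arr = np.tile(template, (count, 1))

    noncpg_c = np.array([p - 1 for p in locus.non_cpg_c_positions])
    if model.conversion_failure_rate > 0 and noncpg_c.size:
        fail = rng.random((count, noncpg_c.size)) < model.conversion_failure_rate
        rows, cols = np.nonzero(fail)
        arr[rows, noncpg_c[cols]] = ord("C")
    meth_pos = cpg_idx[meth_mask]
    if model.inappropriate_conversion_rate > 0 and meth_pos.size:
        flip = rng.random((count, meth_pos.size)) < model.inappropriate_conversion_rate
        rows, cols = np.nonzero(flip)
        arr[rows, meth_pos[cols]] = ord("T")
    if model.sequencing_error_rate > 0:
        err = rng.random(arr.shape) < model.sequencing_error_rate
        rows, cols = np.nonzero(err)
        if rows.size:
            # substitute with a uniformly random *different* base
            cur = arr[rows, cols]
            idx = np.searchsorted(_BASES, cur)
            idx = np.clip(idx, 0, 3)
            shift = rng.integers(1, 4, size=rows.size)
            arr[rows, cols] = _BASES[(idx + shift) % 4]
    return arr


def _sample_rng(model: EpialleleModel, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(model.seed, spawn_key=key))


def simulate_cohort(
    model: EpialleleModel,
    loci: list[LocusSpec],
    scheme: BarcodeScheme,
    out_dir: str | Path,
    reads_per_sample: int | None = None,
) -> tuple[Path, TruthTable]:
    """Generate a cohort FASTQ plus the exact pre-noise truth table.

    Returns the FASTQ path and a :class:`TruthTable` whose counts are the
    generated pattern counts before conversion/sequencing noise, excluding
    injected chimeric reads.  Fully reproducible from ``model.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fastq_path = out_dir / "cohort.fastq"
    truth = TruthTable(MethylationPatternTable(), dict(scheme.group_assignment))
    chimeric_pairs = sorted(enumerate_chimeric_pairs(scheme))

    read_counter = 0
    with open(fastq_path, "w") as fh:
        for si, sample in enumerate(scheme.sample_assignment):
            group = scheme.group_assignment[sample]
            x_label, y_label = scheme.sample_assignment[sample]
            for li, locus in enumerate(loci):
                rng = _sample_rng(model, si, li)
                if reads_per_sample is not None:
                    n_reads = int(reads_per_sample)
                else:
                    lo, hi = model.coverage_range
                    n_reads = int(rng.integers(lo, hi + 1))
                n_chim = rng.binomial(n_reads, model.chimera_rate) if model.chimera_rate else 0
                n_real = n_reads - n_chim

                mix = model.mixtures[(group, locus.name)]
                weights = model.sample_weights(group, locus.name, rng)
                class_counts = rng.multinomial(n_real, weights)

                chunks: list[str] = []
                for (cls_obj, _), cnt in zip(mix, class_counts):
                    if cnt == 0:
                        continue
                    for pattern, pcount in sorted(_draw_patterns(cls_obj, cnt, rng).items()):
                        truth.pattern_table.add_pattern(sample, locus.name, pattern, pcount)
                        arr = _pattern_reads(pattern, pcount, locus, model, rng)
                        chunks.extend(
                            _format_reads(arr, locus, scheme, x_label, y_label, read_counter)
                        )
                        read_counter += arr.shape[0]
                if n_chim:
                    pat = "T" * locus.n_cpg
                    arr = _pattern_reads(pat, n_chim, locus, model, rng)
                    cx, cy = chimeric_pairs[int(rng.integers(len(chimeric_pairs)))]
                    chunks.extend(_format_reads(arr, locus, scheme, cx, cy, read_counter))
                    read_counter += n_chim
                fh.write("".join(chunks))
    return fastq_path, truth


def _format_reads(
    arr: np.ndarray,
    locus: LocusSpec,
    scheme: BarcodeScheme,
    x_label: str,
    y_label: str,
    start_id: int,
) -> list[str]:
    x_seq = scheme.x_codes[x_label]
    y_seq = scheme.y_codes[y_label]
    if locus.x_on == "forward":
        bc5, bc3 = x_seq, revcomp(y_seq)
    else:
        bc5, bc3 = y_seq, revcomp(x_seq)
    qual = "I" * (16 + arr.shape[1])
    out = []
    for i in range(arr.shape[0]):
        seq = bc5 + arr[i].tobytes().decode() + bc3
        out.append(f"@r{start_id + i}\n{seq}\n+\n{qual}\n")
    return out


def simulate_pattern_tables(
    model: EpialleleModel,
    loci: list[LocusSpec],
    scheme: BarcodeScheme,
    reads_per_sample: int | None = None,
) -> TruthTable:
    """Fast path: draw pattern counts directly, skipping reads and noise.

    Produces the same kind of table the full FASTQ pipeline recovers in the
    noiseless limit; used for statistical studies where read-level noise is
    not the object (e.g. null-calibration runs).
    """
    truth = TruthTable(MethylationPatternTable(), dict(scheme.group_assignment))
    for si, sample in enumerate(scheme.sample_assignment):
        group = scheme.group_assignment[sample]
        for li, locus in enumerate(loci):
            rng = _sample_rng(model, si, li)
            if reads_per_sample is not None:
                n_reads = int(reads_per_sample)
            else:
                lo, hi = model.coverage_range
                n_reads = int(rng.integers(lo, hi + 1))
            weights = model.sample_weights(group, locus.name, rng)
            mix = model.mixtures[(group, locus.name)]
            class_counts = rng.multinomial(n_reads, weights)
            for (cls_obj, _), cnt in zip(mix, class_counts):
                if cnt == 0:
                    continue
                for pattern, pcount in sorted(_draw_patterns(cls_obj, cnt, rng).items()):
                    truth.pattern_table.add_pattern(sample, locus.name, pattern, pcount)
    return truth


def simulate_wgbs_reads(
    model: EpialleleModel,
    locus: LocusSpec,
    read_length_bp: int = 70,
    n_fragments: int = 40,
    n_samples: tuple[int, int] = (7, 11),
    group_map: dict[str, str] | None = None,
):
    """Short-read WGBS-style per-read call table over one locus.

    Each fragment covers a ``read_length_bp`` window at a uniform random
    offset, so only the CpG subset inside the window is observed — the
    low-coverage, missing-data regime of genome-wide bisulfite data.
    Returns a list of :class:`~epiallele.wgbs.WgbsObservation` rows,
    ``n_fragments`` per sample, groups labeled normal/cancer.
    """
    from .wgbs import WgbsObservation

    group_map = group_map or {"normal": "HD", "cancer": "PCa"}
    positions = locus.cpg_positions
    L = locus.insert_length_bp
    observations: list[WgbsObservation] = []
    rid = 0
    for gi, (wgbs_group, model_group) in enumerate(sorted(group_map.items())):
        n_samp = n_samples[0] if wgbs_group == "normal" else n_samples[1]
        mix = model.mixtures[(model_group, locus.name)]
        for si in range(n_samp):
            rng = _sample_rng(model, 1000 + gi, si)
            weights = model.sample_weights(model_group, locus.name, rng)
            for _ in range(n_fragments):
                cls_idx = int(rng.choice(len(mix), p=weights / weights.sum()))
                pattern = next(iter(_draw_patterns(mix[cls_idx][0], 1, rng)))
                for _try in range(100):
                    start = int(rng.integers(1, max(L - read_length_bp + 1, 2)))
                    covered = [
                        k + 1
                        for k, p in enumerate(positions)
                        if start <= p <= start + read_length_bp - 1
                    ]
                    if covered:
                        break
                states = "".join(pattern[k - 1] for k in covered)
                observations.append(
                    WgbsObservation(f"w{rid}", wgbs_group, tuple(covered), states)
                )
                rid += 1
    return observations
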