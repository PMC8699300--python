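"""Single and joint methylation-status variables over pattern tables.

A locus with n CpGs defines n single-position variables (GENE.Ci = the
proportion of retained molecules methylated at CpG i) and 4·n(n−1)/2
joint variables over unordered position pairs (GENE.Ci.Cj, GENE.Ci.Tj,
GENE.Ti.Cj, GENE.Ti.Tj — the proportions of molecules carrying that joint
status).  For the three-locus design (17, 17, 5 CpGs) the full family
counts 2·(17 + 4·17·16/2) + 5 + 4·(5·4/2) = 1167 variables.

All variables at a locus share a single denominator — the sample's
retained read count — because reads with any unrecognized site are
excluded upstream.  Proportions are kept as exact count/total pairs
alongside floats so that downstream cutoff rules can compare tiny
proportions without float ties.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .design import BarcodeScheme, LocusSpec
from .reads import MethylationPatternTable

logger = logging.getLogger(__name__)

PAIR_STATUSES = ("CC", "CT", "TC", "TT")

_NAME_RE = re.compile(r"^(?P<locus>[A-Za-z0-9_]+)\.(?P<s1>[CT])(?P<p1>\d+)(?:\.(?P<s2>[CT])(?P<p2>\d+))?$")


class VariableNameError(ValueError):
    """A variable name does not parse as GENE.Ci or GENE.Si.Sj."""


class UndefinedVariableError(ValueError):
    """A proportion is requested for a sample with no retained reads."""


@dataclass(frozen=True)
class VariableSpec:
    """A single- or pair-status variable: locus, positions, per-position status."""

    locus: str
    positions: tuple[int, ...]
    statuses: str  # 'C' (methylated) / 'T' (unmethylated), one per position

    def __post_init__(self) -> None:
        if len(self.positions) not in (1, 2) or len(self.statuses) != len(self.positions):
            raise VariableNameError(f"malformed variable spec: {self}")
        if len(self.positions) == 2 and not self.positions[0] < self.positions[1]:
            raise VariableNameError(f"pair positions must satisfy i < j: {self}")

    @property
    def name(self) -> str:
        parts = [f"{s}{p}" for s, p in zip(self.statuses, self.positions)]
        return f"{self.locus}." + ".".join(parts)

    @property
    def kind(self) -> str:
        return "single" if len(self.positions) == 1 else "pair"


def parse_variable(name: str) -> VariableSpec:
    m = _NAME_RE.match(name)
    if not m:
        raise VariableNameError(f"cannot parse variable name {name!r}")
    positions = [int(m["p1"])]
    statuses = m["s1"]
    if m["s2"]:
        positions.append(int(m["p2"]))
        statuses += m["s2"]
    return VariableSpec(m["locus"], tuple(positions), statuses)


def n_variables(n_cpg: int) -> int:
    """Enumeration size for one locus: n singles + 4·C(n, 2) pairs."""
    return n_cpg + 2 * n_cpg * (n_cpg - 1)


def enumerate_variables(loci: list[LocusSpec]) -> list[VariableSpec]:
    """The deterministic variable enumeration: per locus, singles C1..Cn then
    pairs lexicographic by (i, j, status) with statuses CC, CT, TC, TT."""
    out: list[VariableSpec] = []
    for loc in loci:
        n = loc.n_cpg
        for i in range(1, n + 1):
            out.append(VariableSpec(loc.name, (i,), "C"))
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                for st in PAIR_STATUSES:
                    out.append(VariableSpec(loc.name, (i, j), st))
    return out


def compute_variable_counts(
    table: MethylationPatternTable, sample: str, spec: VariableSpec
) -> tuple[int, int]:
    """(matching reads, retained total) for one sample and variable."""
    patterns = table.patterns(sample, spec.locus)
    total = sum(patterns.values())
    if total == 0:
        raise UndefinedVariableError(f"no retained reads for {sample} at {spec.locus}")
    num = 0
    for pattern, count in patterns.items():
        if all(pattern[p - 1] == s for p, s in zip(spec.positions, spec.statuses)):
            num += count
    return num, total


def compute_variable(
    table: MethylationPatternTable, sample: str, spec: VariableSpec
) -> float:
    num, total = compute_variable_counts(table, sample, spec)
    return num / total


@dataclass
class VariableMatrix:
    """Samples × variables proportion matrix with group labels and exact counts.

    ``values`` holds float proportions; ``counts`` the integer numerators and
    ``denominators`` the per (sample, locus) retained totals, so any entry can
    be recovered exactly as a rational.  ``covariates`` holds extra numeric
    columns (e.g. PSA) that are not proportions.
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    denominators: pd.DataFrame
    groups: pd.Series
    specs: list[VariableSpec]
    covariates: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    def locus_of(self, name: str) -> str:
        return parse_variable(name).locus

    def column_fractions(self, name: str) -> list[Fraction]:
        """Exact rational proportions for one variable column."""
        locus = self.locus_of(name)
        nums = self.counts[name]
        dens = self.denominators[locus]
        return [Fraction(int(n), int(d)) for n, d in zip(nums, dens)]

    def resolve(self, name: str) -> np.ndarray:
        """Numeric column for a variable, covariate, or single-T alias.

        ``GENE.Ti`` is accepted in model formulas and resolves to
        ``1 − GENE.Ci`` (single-T variables are not part of the enumeration).
        """
        if name in self.values.columns:
            return self.values[name].to_numpy()
        if self.covariates is not None and name in self.covariates.columns:
            return self.covariates[name].to_numpy(dtype=float)
        spec = parse_variable(name)
        if spec.kind == "single" and spec.statuses == "T":
            comp = spec.locus + f".C{spec.positions[0]}"
            if comp in self.values.columns:
                return 1.0 - self.values[comp].to_numpy()
        raise KeyError(name)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample")


def _locus_block(patterns: dict[str, int], n: int) -> tuple[np.ndarray, int]:
    """Vectorized numerators for one (sample, locus): singles then pair block."""
    pats = list(patterns)
    w = np.array([patterns[p] for p in pats], dtype=np.int64)
    M = np.array([[c == "C" for c in p] for p in pats], dtype=np.int64)
    total = int(w.sum())
    singles = w @ M  # (n,)
    CC = M.T @ (M * w[:, None])
    CT = M.T @ ((1 - M) * w[:, None])  # CT[i, j] = sum_k w_k M_ki (1 - M_kj)
    TC = CT.T
    TT = (1 - M).T @ ((1 - M) * w[:, None])
    iu = np.triu_indices(n, 1)
    block = np.stack([CC[iu], CT[iu], TC[iu], TT[iu]], axis=1).ravel()
    return np.concatenate([singles, block]), total


def build_variable_matrix(
    table: MethylationPatternTable,
    loci: list[LocusSpec],
    scheme: BarcodeScheme,
    covariates: pd.DataFrame | None = None,
) -> VariableMatrix:
    """Assemble the full samples × variables matrix from a pattern table.

    Samples with no retained reads at some locus are dropped with a logged
    warning; a duplicated sample id raises.
    """
    specs = enumerate_variables(loci)
    names = [s.name for s in specs]
    all_samples = list(scheme.sample_assignment)
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("duplicate sample id in design")

    kept: list[str] = []
    for sample in all_samples:
        if all(table.retained_total(sample, loc.name) > 0 for loc in loci):
            kept.append(sample)
        else:
            logger.warning("dropping sample %s: no retained reads at some locus", sample)
    if not kept:
        raise ValueError("no samples with retained reads at every locus")

    count_rows = np.zeros((len(kept), len(names)), dtype=np.int64)
    denom = np.zeros((len(kept), len(loci)), dtype=np.int64)
    value_rows = np.zeros((len(kept), len(names)))
    for si, sample in enumerate(kept):
        col = 0
        for li, loc in enumerate(loci):
            nums, total = _locus_block(dict(table.patterns(sample, loc.name)), loc.n_cpg)
            width = n_variables(loc.n_cpg)
            count_rows[si, col : col + width] = nums
            value_rows[si, col : col + width] = nums / total
            denom[si, li] = total
            col += width

    values = pd.DataFrame(value_rows, index=kept, columns=names)
    counts = pd.DataFrame(count_rows, index=kept, columns=names)
    denominators = pd.DataFrame(denom, index=kept, columns=[l.name for l in loci])
    groups = pd.Series({s: scheme.group_assignment[s] for s in kept}, name="group").loc[kept]
    cov = None
    if covariates is not None:
        if covariates.index.has_duplicates:
            raise ValueError("duplicate sample id in covariates")
        cov = covariates.reindex(kept)
    return VariableMatrix(values, counts, denominators, groups, specs, cov)


def summarize_groups(matrix: VariableMatrix) -> dict:
    """Per-variable group quartiles and per-group log2 correlations of singles.

    Correlations are Pearson, computed on binary logarithms of the
    single-position variables with non-finite values (log2 of zero
    proportions) excluded pairwise; groups with fewer than two finite
    values for a pair yield an undefined (NaN) correlation.
    """
    quart_records = []
    for name in matrix.variable_names:
        for group, sub in matrix.values.groupby(matrix.groups):
            col = sub[name]
            quart_records.append(
                {
                    "variable": name,
                    "group": group,
                    "median": col.median(),
                    "q1": col.quantile(0.25),
                    "q3": col.quantile(0.75),
                }
            )
    quartiles = pd.DataFrame(quart_records)

    correlations: dict[tuple[str, str], pd.DataFrame] = {}
    loci = sorted({s.locus for s in matrix.specs})
    for locus in loci:
        single_names = [s.name for s in matrix.specs if s.locus == locus and s.kind == "single"]
        logs = np.log2(matrix.values[single_names].where(matrix.values[single_names] > 0))
        for group in matrix.groups.unique():
            sub = logs[matrix.groups == group]
            n_nonfinite = int(sub.isna().sum().sum())
            if n_nonfinite:
                logger.info(
                    "%s/%s: excluding %d non-finite log2 values pairwise", locus, group, n_nonfinite
                )
            correlations[(group, locus)] = sub.corr(min_periods=2)
    return {"quartiles": quartiles, "correlations": correlations}
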