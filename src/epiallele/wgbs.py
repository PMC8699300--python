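"""Binary re-screen of the variable family on low-coverage per-read data.

Whole-genome bisulfite reads are short and sparse: each read covers only a
subset of a locus's CpGs.  Variables keep their names but become binary —
the presence of the specified methylation status(es) in one read.  A read
is evaluable for a variable iff it covers all the variable's positions;
evaluable reads are pooled across samples into the normal and cancer
groups, and each 2×2 table is tested with Pearson's chi-square (no
continuity correction) when all expected counts are at least 5, otherwise
with the two-sided Fisher exact test.  P-values are adjusted by the
locus's own enumeration size (561 for a 17-CpG locus), capped at 1.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .design import LocusSpec
from .variables import VariableSpec, enumerate_variables, n_variables


class WgbsObservation(NamedTuple):
    """One sequencing read restricted to a locus: covered CpG indices + states."""

    read_id: str
    group: str  # "normal" or "cancer"
    positions: tuple[int, ...]  # CpG indices (1-based) covered by the read
    states: str  # over {C, T}, one per covered position

    def state_at(self, position: int) -> str | None:
        try:
            return self.states[self.positions.index(position)]
        except ValueError:
            return None


def evaluate_binary_variable(
    observations: Iterable[WgbsObservation], spec: VariableSpec, groups=("normal", "cancer")
) -> np.ndarray:
    """2×2 counts: rows pattern present/absent, columns the two groups.

    Reads not covering every position of ``spec`` are not evaluable and are
    excluded from both rows.
    """
    counts = np.zeros((2, 2), dtype=np.int64)
    gidx = {g: j for j, g in enumerate(groups)}
    for obs in observations:
        j = gidx.get(obs.group)
        if j is None:
            continue
        states = [obs.state_at(p) for p in spec.positions]
        if any(s is None for s in states):
            continue
        present = all(s == want for s, want in zip(states, spec.statuses))
        counts[0 if present else 1, j] += 1
    return counts


def test_association(counts: np.ndarray) -> tuple[str, float]:
    """(test used, raw two-sided p) for a 2×2 table.

    Chi-square (Pearson, no continuity correction) when all four expected
    counts are >= 5, Fisher exact otherwise; a zero margin yields p = 1
    with a "degenerate" label.
    """
    counts = np.asarray(counts, dtype=np.int64)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    total = counts.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        return "degenerate", 1.0
    expected = np.outer(row, col) / total
    if (expected >= 5).all():
        _, p, _, _ = chi2_contingency(counts, correction=False)
        return "chi-square", float(min(max(p, np.nextafter(0, 1)), 1.0))
    _, p = fisher_exact(counts, alternative="two-sided")
    return "fisher", float(min(p, 1.0))


def screen_locus(
    observations: Iterable[WgbsObservation],
    locus: LocusSpec,
    groups=("normal", "cancer"),
) -> pd.DataFrame:
    """One association result per enumerated variable of the locus.

    The Bonferroni family is the locus's own enumeration (n + 2n(n−1)
    variables); significance at adjusted p < 0.05.
    """
    observations = list(observations)
    specs = enumerate_variables([locus])
    m = n_variables(locus.n_cpg)
    assert len(specs) == m
    rows = []
    for spec in specs:
        counts = evaluate_binary_variable(observations, spec, groups)
        test, p = test_association(counts)
        rows.append(
            {
                "variable": spec.name,
                "present_normal": int(counts[0, 0]),
                "present_cancer": int(counts[0, 1]),
                "absent_normal": int(counts[1, 0]),
                "absent_cancer": int(counts[1, 1]),
                "evaluable_normal": int(counts[:, 0].sum()),
                "evaluable_cancer": int(counts[:, 1].sum()),
                "test": test,
                "p_raw": p,
                "p_adj": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: per-read call tables

def write_observations(observations: Iterable[WgbsObservation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgroup\tcovered_positions\tstates\n")
        for obs in observations:
            pos = ",".join(str(p) for p in obs.positions)
            fh.write(f"{obs.read_id}\t{obs.group}\t{pos}\t{obs.states}\n")


def read_observations(path: str | Path) -> list[WgbsObservation]:
    out: list[WgbsObservation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["read_id", "group", "covered_positions", "states"]:
            raise ValueError(f"unexpected WGBS table header in {path}")
        for line in fh:
            rid, group, pos, states = line.rstrip("\n").split("\t")
            positions = tuple(int(p) for p in pos.split(",")) if pos else ()
            if not positions or len(positions) != len(states):
                raise ValueError(f"malformed WGBS row for read {rid}")
            out.append(WgbsObservation(rid, group, positions, states))
    return out
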