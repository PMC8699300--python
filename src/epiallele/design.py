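"""Experimental design objects: amplicon loci and the dual 8-bp barcode scheme.

A targeted bisulfite-amplicon experiment is described by a set of loci
(each an amplicon with an ordered list of CpG sites) and a barcode scheme
that assigns one (X, Y) pair of 8-mers to every sample.  Barcode pairs that
were never used in library construction identify PCR chimeras, so the
scheme also fixes which read barcode combinations are valid.

Coordinates are 1-based, inclusive, on the genomic sense strand of the
amplicon; CpG index ``k`` in variable names always means the k-th CpG in
5'->3' order.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

GROUPS = ("HD", "BPH", "PCa")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class DesignError(ValueError):
    """Base class for design-validation failures."""


class DesignSchemaError(DesignError):
    """The configuration file does not match the documented schema."""


class DuplicateBarcodeError(DesignError):
    """The same 8-mer appears twice within one code list."""


class DuplicateAssignmentError(DesignError):
    """One (X, Y) pair is assigned to two different samples."""


class CpGSiteError(DesignError):
    """A declared CpG position does not sit on a C-G dinucleotide."""


@dataclass(frozen=True)
class LocusSpec:
    """One amplicon locus.

    ``reference_sequence`` is the genomic-sense insert without barcodes
    (primer footprints included); ``cpg_positions`` are 1-based offsets of
    the CpG cytosines, strictly increasing in 5'->3' order.  ``x_on`` says
    which primer end carries the X codes ("forward" or "reverse"); the
    other end carries the Y codes.
    """

    name: str
    reference_sequence: str
    cpg_positions: tuple[int, ...]
    primer_forward: str
    primer_reverse: str
    x_on: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpg_positions", tuple(self.cpg_positions))
        self.validate()

    def validate(self) -> None:
        ref = self.reference_sequence.upper()
        if self.x_on not in ("forward", "reverse"):
            raise DesignSchemaError(
                f"{self.name}: x_on must be 'forward' or 'reverse', got {self.x_on!r}"
            )
        pos = self.cpg_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise CpGSiteError(f"{self.name}: cpg_positions must be strictly increasing")
        for p in pos:
            if not (1 <= p < len(ref)) or ref[p - 1 : p + 1] != "CG":
                raise CpGSiteError(
                    f"{self.name}: position {p} is not a CG dinucleotide in the reference"
                )

    @property
    def insert_length_bp(self) -> int:
        return len(self.reference_sequence)

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    @property
    def non_cpg_c_positions(self) -> tuple[int, ...]:
        """1-based positions of cytosines outside CpG context (conversion-rate sites)."""
        cpg = set(self.cpg_positions)
        return tuple(
            i + 1
            for i, b in enumerate(self.reference_sequence.upper())
            if b == "C" and (i + 1) not in cpg
        )

    def converted_reference(self) -> str:
        """In-silico bisulfite-converted sense strand with CpG cytosines kept as C.

        Non-CpG cytosines read as T after full conversion; CpG cytosines read
        C (methylated) or T (unmethylated), so the returned template carries C
        at CpG sites and callers treat those positions as {C, T} wildcards.
        """
        seq = list(self.reference_sequence.upper())
        cpg = set(self.cpg_positions)
        for i, b in enumerate(seq):
            if b == "C" and (i + 1) not in cpg:
                seq[i] = "T"
        return "".join(seq)


@dataclass
class BarcodeScheme:
    """Dual-index barcode design: X codes, Y codes, and the per-sample assignment.

    ``sample_assignment`` maps sample id -> (X label, Y label); the same pair is
    used for every locus of that sample (which end of the amplicon carries the
    X code is a per-locus property of :class:`LocusSpec`).  The X/Y code
    subsets used by the PCa group and the HD group must be disjoint so that
    tumor/healthy cross-contamination cannot masquerade as a valid pair.
    """

    x_codes: dict[str, str]
    y_codes: dict[str, str]
    sample_assignment: dict[str, tuple[str, str]]
    group_assignment: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for side, codes in (("X", self.x_codes), ("Y", self.y_codes)):
            for label, seq in codes.items():
                if len(seq) != 8:
                    raise DesignSchemaError(f"{side} code {label} is not 8 bp: {seq!r}")
            if len(set(codes.values())) != len(codes):
                raise DuplicateBarcodeError(f"duplicate 8-mer within the {side} code list")
        seen: dict[tuple[str, str], str] = {}
        for sample, (x, y) in self.sample_assignment.items():
            if x not in self.x_codes or y not in self.y_codes:
                raise DesignSchemaError(f"sample {sample} references unknown code ({x}, {y})")
            if (x, y) in seen:
                raise DuplicateAssignmentError(
                    f"pair ({x}, {y}) assigned to both {seen[(x, y)]} and {sample}"
                )
            seen[(x, y)] = sample
        for sample in self.sample_assignment:
            group = self.group_assignment.get(sample)
            if group not in GROUPS:
                raise DesignSchemaError(f"sample {sample} has invalid group {group!r}")
        # Tumor and healthy libraries must not share any barcode.
        pca = self._codes_of_group("PCa")
        hd = self._codes_of_group("HD")
        common = pca & hd
        if common:
            raise DesignSchemaError(f"PCa and HD groups share barcodes: {sorted(common)}")

    def _codes_of_group(self, group: str) -> set[str]:
        out: set[str] = set()
        for sample, (x, y) in self.sample_assignment.items():
            if self.group_assignment[sample] == group:
                out.update((x, y))
        return out

    @property
    def samples(self) -> list[str]:
        return list(self.sample_assignment)

    def sample_of_pair(self, x: str, y: str) -> str | None:
        for sample, pair in self.sample_assignment.items():
            if pair == (x, y):
                return sample
        return None

    def pair_lookup(self) -> dict[tuple[str, str], str]:
        return {pair: sample for sample, pair in self.sample_assignment.items()}


def enumerate_valid_pairs(scheme: BarcodeScheme) -> set[tuple[str, str]]:
    """The (X, Y) label pairs actually used in library construction."""
    return set(scheme.sample_assignment.values())


def enumerate_chimeric_pairs(scheme: BarcodeScheme) -> set[tuple[str, str]]:
    """Complement of the valid pairs within the full X x Y grid."""
    grid = set(itertools.product(scheme.x_codes, scheme.y_codes))
    return grid - enumerate_valid_pairs(scheme)


# ---------------------------------------------------------------------------
# Configuration I/O

def _loci_to_obj(loci: list[LocusSpec]) -> list[dict]:
    return [
        {
            "name": loc.name,
            "reference_sequence": loc.reference_sequence,
            "cpg_positions": list(loc.cpg_positions),
            "primer_forward": loc.primer_forward,
            "primer_reverse": loc.primer_reverse,
            "x_on": loc.x_on,
        }
        for loc in loci
    ]


def design_to_obj(loci: list[LocusSpec], scheme: BarcodeScheme) -> dict:
    return {
        "loci": _loci_to_obj(loci),
        "barcodes": {"X": dict(scheme.x_codes), "Y": dict(scheme.y_codes)},
        "samples": {
            sample: {
                "group": scheme.group_assignment[sample],
                "x": scheme.sample_assignment[sample][0],
                "y": scheme.sample_assignment[sample][1],
            }
            for sample in scheme.sample_assignment
        },
    }


def design_from_obj(obj: dict) -> tuple[list[LocusSpec], BarcodeScheme]:
    try:
        loci = [
            LocusSpec(
                name=l["name"],
                reference_sequence=l["reference_sequence"],
                cpg_positions=tuple(l["cpg_positions"]),
                primer_forward=l["primer_forward"],
                primer_reverse=l["primer_reverse"],
                x_on=l["x_on"],
            )
            for l in obj["loci"]
        ]
        scheme = BarcodeScheme(
            x_codes=dict(obj["barcodes"]["X"]),
            y_codes=dict(obj["barcodes"]["Y"]),
            sample_assignment={s: (v["x"], v["y"]) for s, v in obj["samples"].items()},
            group_assignment={s: v["group"] for s, v in obj["samples"].items()},
        )
    except (KeyError, TypeError) as exc:
        raise DesignSchemaError(f"malformed design configuration: {exc}") from exc
    return loci, scheme


def load_design(config_file: str | Path) -> tuple[list[LocusSpec], BarcodeScheme]:
    """Load and validate a design from a JSON or YAML configuration file."""
    path = Path(config_file)
    text = path.read_text()
    if path.suffix in (".json",):
        obj = json.loads(text)
    else:
        obj = yaml.safe_load(text)
    if not isinstance(obj, dict):
        raise DesignSchemaError("design configuration must be a mapping")
    return design_from_obj(obj)


def save_design(loci: list[LocusSpec], scheme: BarcodeScheme, path: str | Path) -> None:
    path = Path(path)
    obj = design_to_obj(loci, scheme)
    if path.suffix == ".json":
        path.write_text(json.dumps(obj, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))


def export_fasta(loci: list[LocusSpec], path: str | Path) -> None:
    """Write reference inserts as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(loc.reference_sequence), id=loc.name, description=f"{loc.n_cpg} CpGs")
        for loc in loci
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Bundled demo design
#
# The published primer sequences, amplicon lengths, CpG counts and barcode
# lists are real design constants; the reference inserts between the primer
# footprints are synthetic stand-ins (the true amplicon sequences are not
# published), fabricated to the printed lengths and CpG counts.

X_CODES = {
    "X1": "TAGATCGC", "X2": "CTCTCTAT", "X3": "TATCCTCT", "X4": "AGAGTAGA",
    "X5": "ACTGCATA", "X6": "AAGGAGTA", "X7": "CTAAGCCT", "X8": "CCTCTCTG",
}
Y_CODES = {
    "Y1": "TCGCCTTA", "Y2": "CTAGTACG", "Y3": "TTCTGCCT", "Y4": "GCTCAGGA",
    "Y5": "AGGAGTCC", "Y6": "CATGCCTA", "Y7": "GTAGAGAG", "Y8": "CCTCTCTG",
    "Y9": "AGCGTAGC", "Y10": "CAGCCTCG", "Y11": "TGCCTCTT", "Y12": "TCCTCTAC",
}

_PRIMERS = {
    # name: (forward, reverse, insert length without barcodes, n CpGs, x_on)
    "GSTP1": ("ATTTGGGAAAGAGGGAAAGGTT", "CTCTTCTAAAAAATCC", 142, 17, "reverse"),
    "RNF219": ("GTGATTGTGGGTATAGTTATAAAA", "ACTACCCCCATCTCCCAAAA", 161, 17, "reverse"),
    "KIAA1539": ("AGGAAGGAGGAGATAAAGTGAT", "CCCCTCTAAACTTATCATCACA", 89, 5, "forward"),
}


def _fabricate_core(length: int, cpg_offsets: list[int], seed: int) -> str:
    """Deterministic synthetic core with CpGs exactly at ``cpg_offsets`` (0-based).

    No CG dinucleotide is created outside the designated sites, so the
    declared CpG list is exhaustive; free positions draw from {A, C, G, T}
    with G suppressed after C.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    seq: list[str] = [""] * length
    designated = set(cpg_offsets)
    for p in cpg_offsets:
        seq[p] = "C"
        seq[p + 1] = "G"
    for i in range(length):
        if seq[i]:
            continue
        prev = seq[i - 1] if i > 0 else ""
        bases = ["A", "C", "T"] if prev == "C" else ["A", "C", "G", "T"]
        # never place C immediately before a G that is already fixed
        if i + 1 < length and seq[i + 1] == "G" and "C" in bases:
            bases.remove("C")
        seq[i] = bases[int(rng.integers(len(bases)))]
    out = "".join(seq)
    assert all(out[p : p + 2] == "CG" for p in cpg_offsets)
    assert sum(out[i : i + 2] == "CG" for i in range(length - 1)) == len(cpg_offsets)
    return out


def _demo_locus(name: str, seed: int) -> LocusSpec:
    fwd, rev, total_len, n_cpg, x_on = _PRIMERS[name]
    rc_rev = revcomp(rev)
    core_len = total_len - len(fwd) - len(rc_rev)
    # spread the CpGs evenly across the core
    span = core_len - 2
    offsets = [round(i * span / max(n_cpg - 1, 1)) for i in range(n_cpg)]
    # enforce >= 2 bp spacing
    for i in range(1, len(offsets)):
        offsets[i] = max(offsets[i], offsets[i - 1] + 2)
    core = _fabricate_core(core_len, offsets, seed)
    if rc_rev.startswith("G") and core.endswith("C"):
        core = core[:-1] + "T"  # avoid an undeclared CG at the core/primer junction
    ref = fwd + core + rc_rev
    cpg_positions = tuple(len(fwd) + o + 1 for o in offsets)  # 1-based on full insert
    return LocusSpec(
        name=name,
        reference_sequence=ref,
        cpg_positions=cpg_positions,
        primer_forward=fwd,
        primer_reverse=rev,
        x_on=x_on,
    )


def demo_scheme() -> BarcodeScheme:
    """55-sample assignment (20 PCa, 17 BPH, 18 HD) with PCa/HD code disjointness."""
    assignment: dict[str, tuple[str, str]] = {}
    groups: dict[str, str] = {}

    pca_pairs = [(f"X{i}", f"Y{j}") for i in range(1, 5) for j in range(1, 6)]  # 20
    hd_pairs = [(f"X{i}", f"Y{j}") for i in range(5, 9) for j in range(6, 11)][:18]
    bph_pairs = [(f"X{i}", "Y11") for i in range(1, 9)] + [
        (f"X{i}", "Y12") for i in range(1, 9)
    ] + [("X1", "Y6")]  # 17

    for k, pair in enumerate(pca_pairs, 1):
        sample = f"PCa_{k:02d}"
        assignment[sample] = pair
        groups[sample] = "PCa"
    for k, pair in enumerate(bph_pairs, 1):
        sample = f"BPH_{k:02d}"
        assignment[sample] = pair
        groups[sample] = "BPH"
    for k, pair in enumerate(hd_pairs, 1):
        sample = f"HD_{k:02d}"
        assignment[sample] = pair
        groups[sample] = "HD"

    return BarcodeScheme(
        x_codes=dict(X_CODES),
        y_codes=dict(Y_CODES),
        sample_assignment=assignment,
        group_assignment=groups,
    )


def demo_design() -> tuple[list[LocusSpec], BarcodeScheme]:
    """The bundled three-locus demo design (synthetic reference inserts)."""
    loci = [_demo_locus("GSTP1", 11), _demo_locus("RNF219", 12), _demo_locus("KIAA1539", 13)]
    return loci, demo_scheme()
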