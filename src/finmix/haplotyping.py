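"""Amplicon merging, haplotype definition, and baseline assignment.

Market mitochondrial control-region (mtCR) sequences are recovered as two
short overlapping amplicons (the target DNA is degraded).  This module merges
the two fragments into the full-length fragment, collapses equal-length
sequences into haplotypes, and assigns market sequences to a reference
haplotype table using exact matching with ``N`` treated as a wildcard.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "read_fasta",
    "write_fasta",
    "MtcrSequence",
    "HaplotypeTable",
    "NOVEL",
    "UNRESOLVABLE",
    "AmpliconMergeError",
    "merge_amplicons",
    "define_haplotypes",
    "assign_to_baseline",
    "assign_many",
]

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

#: Sentinel returned when a sequence matches no baseline haplotype.
NOVEL = "NOVEL"
#: Sentinel returned when a sequence has too many ambiguous bases to assign.
UNRESOLVABLE = "UNRESOLVABLE"


class AmpliconMergeError(ValueError):
    """Raised when two amplicons disagree in their implied overlap."""


@dataclass(frozen=True)
class MtcrSequence:
    """A single mtCR sequence (IUPAC upper-case nucleotides)."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        bad = set(bases) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass
class HaplotypeTable:
    """Distinct sequences with observation counts.

    ``ids`` preserves first-occurrence order; all representative sequences are
    pairwise distinct and equal length.
    """

    ids: list[str] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def sequence_length(self) -> int | None:
        if not self.ids:
            return None
        return len(self.sequences[self.ids[0]])

    def __len__(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        seqs = [self.sequences[i] for i in self.ids]
        if len(set(seqs)) != len(seqs):
            raise ValueError("representative sequences are not pairwise distinct")
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("representative sequences differ in length")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["haplotype_id", "sequence", "count"])
            for hid in self.ids:
                writer.writerow([hid, self.sequences[hid], self.counts[hid]])

    @classmethod
    def from_csv(cls, path) -> "HaplotypeTable":
        table = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                hid = row["haplotype_id"]
                table.ids.append(hid)
                table.sequences[hid] = row["sequence"].upper()
                table.counts[hid] = int(row["count"])
        table.validate()
        return table


def read_fasta(path) -> list[MtcrSequence]:
    from Bio import SeqIO

    return [
        MtcrSequence(id=rec.id, bases=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[MtcrSequence], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    seqio_write(records, str(path), "fasta")


def _bases_compatible(a: str, b: str) -> bool:
    return a == b or a == "N" or b == "N"


def _resolve(a: str, b: str) -> str:
    # N yields to the concrete base observed on the other fragment.
    if a == "N":
        return b
    return a


def merge_amplicons(
    frag_a: MtcrSequence, frag_b: MtcrSequence, expected_length: int
) -> MtcrSequence:
    """Merge two overlapping amplicons into a sequence of ``expected_length``.

    The overlap length is implied: ``k = len(a) + len(b) - expected_length``.
    The last ``k`` bases of ``frag_a`` must agree with the first ``k`` bases of
    ``frag_b`` position by position, where ``N`` is compatible with anything
    and resolves toward the concrete base.  Any concrete disagreement raises
    :class:`AmpliconMergeError` naming the offending positions (1-based in the
    merged coordinate system).

    Parameters
    ----------
    frag_a, frag_b
        The upstream and downstream amplicons.
    expected_length
        Length of the merged product, e.g. 535 for 388 + 168 bp fragments
        overlapping by 21 bp.
    """
    if not frag_a.bases or not frag_b.bases:
        raise ValueError("amplicons must be non-empty")
    la, lb = len(frag_a), len(frag_b)
    k = la + lb - expected_length
    if k < 0:
        raise ValueError(
            f"expected_length {expected_length} exceeds combined fragment "
            f"length {la + lb}"
        )
    if k > min(la, lb):
        raise ValueError(
            f"implied overlap {k} exceeds a fragment length ({la}, {lb})"
        )
    a_tail = frag_a.bases[la - k :] if k else ""
    b_head = frag_b.bases[:k]
    mismatches = [
        la - k + i + 1  # 1-based position in merged sequence
        for i, (x, y) in enumerate(zip(a_tail, b_head))
        if not _bases_compatible(x, y)
    ]
    if mismatches:
        raise AmpliconMergeError(
            f"fragments {frag_a.id!r}/{frag_b.id!r} disagree in overlap at "
            f"merged positions {mismatches} (possible chimera)"
        )
    overlap = "".join(_resolve(x, y) for x, y in zip(a_tail, b_head))
    merged = frag_a.bases[: la - k] + overlap + frag_b.bases[k:]
    assert len(merged) == expected_length
    return MtcrSequence(id=frag_a.id, bases=merged)


def define_haplotypes(
    seqs: Iterable[MtcrSequence], id_prefix: str = "H"
) -> HaplotypeTable:
    """Collapse equal-length sequences into a haplotype table.

    One haplotype per distinct sequence string; IDs are assigned in order of
    first occurrence (``H1``, ``H2``, ...).  Sequences of heterogeneous length
    are rejected with a per-record report.
    """
    seqs = list(seqs)
    table = HaplotypeTable()
    if not seqs:
        return table
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        offenders = [(s.id, len(s)) for s in seqs]
        raise ValueError(
            f"sequences are not all the same length: {sorted(lengths)}; "
            f"records: {offenders}"
        )
    seen: dict[str, str] = {}
    for s in seqs:
        hid = seen.get(s.bases)
        if hid is None:
            hid = f"{id_prefix}{len(seen) + 1}"
            seen[s.bases] = hid
            table.ids.append(hid)
            table.sequences[hid] = s.bases
            table.counts[hid] = 0
        table.counts[hid] += 1
    table.validate()
    return table


def assign_to_baseline(
    seq: MtcrSequence, baseline: HaplotypeTable, max_ambiguous: int = 5
) -> str:
    """Assign a sequence to a baseline haplotype by exact match with N-wildcard.

    Returns the haplotype ID on a unique wildcard match, :data:`NOVEL` when
    the sequence differs from every baseline haplotype at one or more resolved
    positions (or matches more than one haplotype ambiguously), and
    :data:`UNRESOLVABLE` when the sequence carries more than ``max_ambiguous``
    ``N`` bases.  No record is ever silently dropped.
    """
    if not len(baseline):
        raise ValueError("baseline haplotype table is empty")
    ref_len = baseline.sequence_length
    if len(seq) != ref_len:
        raise ValueError(
            f"sequence {seq.id!r} has length {len(seq)}, baseline is {ref_len} bp"
        )
    if seq.bases.count("N") > max_ambiguous:
        return UNRESOLVABLE
    matches = [
        hid
        for hid in baseline.ids
        if all(
            _bases_compatible(a, b)
            for a, b in zip(seq.bases, baseline.sequences[hid])
        )
    ]
    if len(matches) == 1:
        return matches[0]
    return NOVEL


def assign_many(
    seqs: Sequence[MtcrSequence], baseline: HaplotypeTable, max_ambiguous: int = 5
) -> tuple[dict[str, str], dict[str, int]]:
    """Assign a batch of sequences; returns (per-record assignment, tallies).

    The tally dict counts ``assigned``, ``novel`` and ``unresolvable`` records
    so that downstream attrition is auditable.
    """
    out: dict[str, str] = {}
    tally = {"assigned": 0, "novel": 0, "unresolvable": 0}
    for s in seqs:
        hid = assign_to_baseline(s, baseline, max_ambiguous=max_ambiguous)
        out[s.id] = hid
        if hid == NOVEL:
            tally["novel"] += 1
        elif hid == UNRESOLVABLE:
            tally["unresolvable"] += 1
        else:
            tally["assigned"] += 1
    return out, tally
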