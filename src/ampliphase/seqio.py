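"""Sequence I/O and the core read/reference types.

All internal coordinates are 0-based, half-open. Conversion to and from the
1-based conventions of SAM/BED happens only at the format boundary, never
inside the pipeline.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam
from Bio import SeqIO as _BioSeqIO

#: IUPAC nucleotide alphabet accepted in reference sequences.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

#: Plain (unambiguous) bases counted in pileups and genotype tallies.
PLAIN_DNA = frozenset("ACGT")

SHORT = "short"
LONG = "long"

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN" + "ACGTRYSWKMBDHVN".lower(),
    "TGCAYRSWMKVHDBN" + "TGCAYRSWMKVHDBN".lower(),
)


def revcomp(bases: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSeq:
    """A named uppercase DNA sequence (generic, sample-specific, or haplotype
    reference)."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError(f"reference {self.id!r} is empty")
        bad = set(self.bases) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"reference {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Read:
    """A sequencing read; quality scores are optional (Phred+33 string)."""

    id: str
    bases: str
    quals: Optional[str] = None
    platform: str = LONG

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: quality string length {len(self.quals)} "
                f"!= sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadSet:
    """An ordered collection of reads from a single platform."""

    reads: list[Read] = field(default_factory=list)
    platform: str = LONG

    def __post_init__(self) -> None:
        for r in self.reads:
            r.platform = self.platform

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def subset(self, ids: Iterable[str]) -> "ReadSet":
        wanted = set(ids)
        return ReadSet([r for r in self.reads if r.id in wanted], self.platform)


def _open_text(path) -> object:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[ReferenceSeq]:
    """Parse a FASTA file into :class:`ReferenceSeq` records.

    Sequences are uppercased and U is mapped to T. An empty file or a record
    with non-IUPAC characters is an error naming the offending record.
    """
    records = []
    with _open_text(path) as handle:
        for rec in _BioSeqIO.parse(handle, "fasta"):
            bases = str(rec.seq).upper().replace("U", "T")
            try:
                records.append(ReferenceSeq(rec.id, bases))
            except ValueError as exc:
                raise ValueError(f"invalid FASTA record {rec.id!r}: {exc}") from exc
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[ReferenceSeq], path, wrap: int = 60) -> None:
    """Write sequences as wrapped FASTA. Round-trips losslessly through
    :func:`read_fasta` (IUPAC ambiguity codes are written unchanged)."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "wt") as out:
        for s in seqs:
            out.write(f">{s.id}\n")
            for i in range(0, len(s.bases), wrap):
                out.write(s.bases[i : i + wrap] + "\n")


def read_fastq(path, platform: str = LONG) -> ReadSet:
    """Parse a (possibly gzipped) Phred+33 FASTQ file into a :class:`ReadSet`.

    Truncated records raise an error carrying the record index. An empty file
    yields an empty ReadSet; downstream stages reject empty inputs themselves.
    """
    reads: list[Read] = []
    with _open_text(path) as handle:
        idx = 0
        while True:
            header = handle.readline()
            if not header:
                break
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"truncated or malformed FASTQ record #{idx} in {path}")
            rid = header[1:].split()[0]
            if len(qual) != len(seq):
                raise ValueError(
                    f"FASTQ record #{idx} ({rid!r}): quality length != sequence length"
                )
            reads.append(Read(rid, seq.upper(), qual, platform))
            idx += 1
    return ReadSet(reads, platform)


def write_fastq(readset: ReadSet, path) -> None:
    with open(path, "wt") as out:
        for r in readset:
            qual = r.quals if r.quals is not None else "I" * len(r.bases)
            out.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def read_sam(path, reference: ReferenceSeq) -> list:
    """Import aligned reads from a SAM file produced by an external mapper.

    CIGAR operations M/=/X/I/D/S/H are converted to the internal edit-operation
    list; soft/hard-clipped bases are excluded from pileups. Unmapped and
    secondary/supplementary records are skipped. SAM's 1-based POS becomes the
    internal 0-based offset.
    """
    from .align import AlignedRead  # deferred: align depends on seqio types

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name != reference.id:
                raise ValueError(
                    f"SAM record {rec.query_name!r} is aligned to "
                    f"{rec.reference_name!r}, expected {reference.id!r}"
                )
            seq = (rec.query_sequence or "").upper()
            ops = []
            cig = rec.cigartuples or []
            query_start = cig[0][1] if cig and cig[0][0] == 4 else 0
            qpos = 0
            rpos = rec.reference_start
            for op, length in cig:
                if op in (0, 7, 8):  # M / = / X: compare to reference
                    for k in range(length):
                        refbase = reference.bases[rpos + k]
                        kind = "match" if seq[qpos + k] == refbase else "mismatch"
                        if ops and ops[-1][0] == kind:
                            ops[-1] = (kind, ops[-1][1] + 1, None)
                        else:
                            ops.append((kind, 1, None))
                    qpos += length
                    rpos += length
                elif op == 1:  # I
                    ops.append(("ins", length, seq[qpos : qpos + length]))
                    qpos += length
                elif op == 2:  # D
                    ops.append(("del", length, None))
                    rpos += length
                elif op == 4:  # S: consumes query only
                    qpos += length
                elif op == 5:  # H: consumes nothing
                    continue
                else:
                    raise ValueError(
                        f"unsupported CIGAR op {op} in record {rec.query_name!r}"
                    )
            read = Read(
                rec.query_name,
                seq,
                pysam.qualities_to_qualitystring(rec.query_qualities)
                if rec.query_qualities is not None
                else None,
            )
            out.append(
                AlignedRead(
                    read=read,
                    ref_offset=rec.reference_start,
                    ops=ops,
                    score=float(rec.mapping_quality),
                    # SAM stores the sequence already in reference
                    # orientation, so no re-complementing is needed
                    reverse=False,
                    query_start=query_start,
                )
            )
    return out
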