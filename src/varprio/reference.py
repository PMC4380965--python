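"""Reference sequence accessors.

Every consumer in the package talks to a minimal accessor interface:
``fetch(chrom, start, end)`` with 1-based inclusive coordinates and
``length(chrom)``. Two implementations are provided: an indexed-FASTA
accessor backed by pyfaidx, and an in-memory dict accessor used heavily by
the fixture generator and the test suite.
"""

from __future__ import annotations

from typing import Mapping, Protocol, runtime_checkable

from pyfaidx import Fasta

from .errors import ValidationError


@runtime_checkable
class SequenceAccessor(Protocol):
    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the uppercase sequence for [start, end], 1-based inclusive."""
        ...

    def length(self, chrom: str) -> int: ...

    def contigs(self) -> list[str]: ...


class DictReference:
    """Accessor over plain in-memory chromosome strings."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs.get(chrom)
        if seq is None:
            raise ValidationError(f"unknown contig {chrom!r}")
        if start < 1 or end > len(seq):
            raise ValidationError(
                f"coordinates {chrom}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start - 1 : end]

    def length(self, chrom: str) -> int:
        try:
            return len(self._seqs[chrom])
        except KeyError:
            raise ValidationError(f"unknown contig {chrom!r}") from None

    def contigs(self) -> list[str]:
        return list(self._seqs)


class FastaReference:
    """Accessor over an indexed FASTA file (index built on first open)."""

    def __init__(self, path: str):
        self._fasta = Fasta(path, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise ValidationError(f"unknown contig {chrom!r}")
        if start < 1 or end > len(self._fasta[chrom]):
            raise ValidationError(f"coordinates {chrom}:{start}-{end} outside contig")
        return str(self._fasta[chrom][start - 1 : end])

    def length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise ValidationError(f"unknown contig {chrom!r}")
        return len(self._fasta[chrom])

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())
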