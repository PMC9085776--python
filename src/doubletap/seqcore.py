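"""Sequence primitives: loci, protospacers, PAM patterns, FASTA/FASTQ I/O.

Conventions used throughout the package:

* coordinates are 0-based, half-open, always on the stored (forward) strand;
* cut sites are *gap* coordinates, i.e. they sit between two bases;
* SpCas9 makes a blunt cut 3 nt 5' of the PAM, between spacer positions
  17 and 18 counted from the PAM-distal end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

SPACER_LENGTH = 20
#: distance of the blunt cut from the PAM-proximal end of the spacer
CUT_OFFSET_FROM_PAM = 3

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_SEQ = re.compile(r"^[ACGTN]+$")

#: IUPAC nucleotide code -> set of concrete bases it matches.
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}


class SequenceFormatError(ValueError):
    """Raised when a record does not satisfy the expected format."""


@dataclass(frozen=True)
class LocusSequence:
    """A named reference (amplicon) sequence over the {A,C,G,T,N} alphabet."""

    id: str
    seq: str
    quality: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.seq:
            raise SequenceFormatError(f"locus {self.id!r}: empty sequence")
        if not _VALID_SEQ.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise SequenceFormatError(
                f"locus {self.id!r}: invalid characters {bad}"
            )
        if self.quality is not None and len(self.quality) != len(self.seq):
            raise SequenceFormatError(
                f"locus {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PamPattern:
    """An IUPAC PAM pattern such as NGG (SpCas9) or NG (Cas9-NG).

    Matching is case-insensitive; N in the pattern matches any concrete
    base.  An N in the *sequence* never matches (ambiguous base calls are
    not trusted in PAM comparisons).
    """

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        for c in pat:
            if c not in IUPAC_SETS:
                raise ValueError(f"non-IUPAC character {c!r} in PAM pattern")

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, site: str) -> bool:
        """True if ``site`` (concrete bases) matches this pattern."""
        if len(site) != len(self.pattern):
            return False
        for pat_c, seq_c in zip(self.pattern, site.upper()):
            if seq_c not in "ACGT" or seq_c not in IUPAC_SETS[pat_c]:
                return False
        return True


NGG = PamPattern("NGG")
NG = PamPattern("NG")


@dataclass(frozen=True)
class Protospacer:
    """A 20-nt spacer plus PAM on a named locus.

    ``spacer_start`` is the forward-strand coordinate of the spacer's
    leftmost base regardless of strand; ``cut_index`` is the forward-strand
    gap coordinate of the blunt cut.
    """

    locus_id: str
    spacer: str
    pam: str
    strand: str
    spacer_start: int

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LENGTH:
            raise ValueError(
                f"spacer must be {SPACER_LENGTH} nt, got {len(self.spacer)}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.spacer_start < 0:
            raise ValueError("spacer_start must be non-negative")

    @property
    def cut_index(self) -> int:
        """Forward-strand gap coordinate of the blunt cut."""
        if self.strand == "+":
            return self.spacer_start + SPACER_LENGTH - CUT_OFFSET_FROM_PAM
        return self.spacer_start + CUT_OFFSET_FROM_PAM

    @property
    def site(self) -> str:
        """spacer+PAM in protospacer-strand orientation."""
        return self.spacer + self.pam

    def pam_interval(self) -> tuple[int, int]:
        """Forward-strand half-open interval occupied by the PAM."""
        if self.strand == "+":
            start = self.spacer_start + SPACER_LENGTH
            return start, start + len(self.pam)
        return self.spacer_start - len(self.pam), self.spacer_start

    def validate(self, locus: LocusSequence) -> None:
        """Check spacer and PAM against the locus sequence; raise if wrong."""
        if locus.id != self.locus_id:
            raise ValueError(
                f"protospacer belongs to {self.locus_id!r}, not {locus.id!r}"
            )
        s, e = self.spacer_start, self.spacer_start + SPACER_LENGTH
        ps, pe = self.pam_interval()
        if ps < 0 or pe > len(locus) or s < 0 or e > len(locus):
            raise ValueError("protospacer extends past locus bounds")
        spacer_fwd = locus.seq[s:e]
        pam_fwd = locus.seq[ps:pe]
        if self.strand == "+":
            found_spacer, found_pam = spacer_fwd, pam_fwd
        else:
            found_spacer = reverse_complement(spacer_fwd)
            found_pam = reverse_complement(pam_fwd)
        if found_spacer != self.spacer:
            raise ValueError(
                f"spacer mismatch at {self.spacer_start}{self.strand}: "
                f"{found_spacer} != {self.spacer}"
            )
        if found_pam != self.pam:
            raise ValueError(
                f"PAM mismatch at {self.spacer_start}{self.strand}: "
                f"{found_pam} != {self.pam}"
            )


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    seq = seq.upper()
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"cannot reverse-complement characters {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def load_sequences(
    path: str | Path, format: str = "fasta"
) -> list[LocusSequence]:
    """Read FASTA or FASTQ (Phred+33) into LocusSequence records.

    Sequences are uppercased and U is converted to T.  Record order is
    preserved; ids are taken up to the first whitespace.  An empty file
    yields an empty list.
    """
    fmt = format.lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    records = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            seq = str(rec.seq).upper().replace("U", "T")
            qual = None
            if fmt == "fastq":
                phred = rec.letter_annotations.get("phred_quality", [])
                qual = "".join(chr(q + 33) for q in phred)
            try:
                records.append(LocusSequence(id=rec.id, seq=seq, quality=qual))
            except SequenceFormatError as exc:
                raise SequenceFormatError(f"record {i}: {exc}") from exc
    except ValueError as exc:
        if isinstance(exc, SequenceFormatError):
            raise
        raise SequenceFormatError(
            f"malformed {fmt} record ~{len(records)} in {path}: {exc}"
        ) from exc
    return records


def write_fasta(records: Iterable[LocusSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def write_fastq(records: Iterable[LocusSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def find_protospacers(
    locus: LocusSequence, pam: PamPattern = NGG
) -> list[Protospacer]:
    """All protospacers (both strands) for ``pam`` on ``locus``.

    Every position with >= 20 concrete nt immediately 5' of a PAM match
    yields one candidate.  Windows containing N are skipped (N never
    matches in spacer/PAM comparisons).  Output is sorted by
    (spacer_start, strand).
    """
    hits: list[Protospacer] = []
    n, plen = len(locus), len(pam)
    fwd = locus.seq
    rev = reverse_complement(fwd)
    for strand, seq in (("+", fwd), ("-", rev)):
        for pam_start in range(SPACER_LENGTH, n - plen + 1):
            site_pam = seq[pam_start : pam_start + plen]
            if not pam.matches(site_pam):
                continue
            spacer = seq[pam_start - SPACER_LENGTH : pam_start]
            if "N" in spacer:
                continue
            if strand == "+":
                spacer_start = pam_start - SPACER_LENGTH
            else:
                spacer_start = n - pam_start
            hits.append(
                Protospacer(
                    locus_id=locus.id,
                    spacer=spacer,
                    pam=site_pam,
                    strand=strand,
                    spacer_start=spacer_start,
                )
            )
    hits.sort(key=lambda p: (p.spacer_start, p.strand))
    return hits


def cut_index_of(p: Protospacer) -> int:
    """Forward-strand gap coordinate of the blunt Cas9 cut for ``p``."""
    return p.cut_index


def iter_sites(seq: str, length: int) -> Iterator[tuple[int, str, str]]:
    """Yield (forward_start, strand, window) for every window of ``length``
    on both strands of ``seq``; a convenience for naive scans."""
    n = len(seq)
    rc = reverse_complement(seq)
    for i in range(n - length + 1):
        yield i, "+", seq[i : i + length]
    for i in range(n - length + 1):
        yield n - i - length, "-", rc[i : i + length]
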