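"""Indel allele construction, canonical keys, and microhomology-mediated
deletion (MMEJ) enumeration and scoring.

Cas9 double-strand breaks are repaired by end joining, which leaves
insertions (typically 1 bp, templated from the base 5' of the cut) and
deletions.  Where the two sides of the break share a repeat of >= 2 nt
(a microhomology), MMEJ collapses the repeat and deletes the intervening
bases.  Enumerating and scoring those products predicts the indel
spectrum of a cut site before any sequencing data exist; observed NGS
data always override the enumeration.

Canonical indel keys left-align each indel inside repeats (as in VCF
variant normalisation) so that replicates and different aligners
aggregate identical repair products under one key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .seqcore import LocusSequence

DEFAULT_MIN_MH = 2
DEFAULT_MAX_DEL = 60
#: decay length (nt) of the deletion-size penalty in the MMEJ score
MMEJ_DECAY_NT = 20.0
#: top-3 indel share (percent of repair products) above which a
#: protospacer counts as "high precision"
HIGH_PRECISION_TOP3_PCT = 40.0


@dataclass(frozen=True)
class IndelSpec:
    """A concrete insertion or deletion anchored to a cut site.

    ``anchor_cut`` is the gap coordinate of the causative cut.  Insertions
    are placed at ``anchor_cut`` unless ``ins_pos`` overrides the placement
    (needed when reconstructing a left-normalised key).  Deletions remove
    ``[del_start, del_start + length)``, which must contain or abut the
    cut.
    """

    kind: str  # "insertion" | "deletion"
    length: int
    anchor_cut: int
    inserted: str = ""
    del_start: int = -1
    ins_pos: int | None = None
    #: a left-normalised representation may sit left of the causative cut
    #: inside a repeat; the containment check is waived for those
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError("indel length must be positive (no null indels)")
        if self.kind == "insertion":
            if len(self.inserted) != self.length:
                raise ValueError(
                    "inserted bases must match the stated insertion length"
                )
        else:
            if self.del_start < 0:
                raise ValueError("deletion requires del_start >= 0")
            if not self.normalized and not (
                self.del_start <= self.anchor_cut <= self.del_start + self.length
            ):
                raise ValueError(
                    "deletion interval must contain or abut the cut"
                )

    @property
    def position(self) -> int:
        """Leftmost reference coordinate the indel acts at."""
        if self.kind == "insertion":
            return self.anchor_cut if self.ins_pos is None else self.ins_pos
        return self.del_start


@dataclass(frozen=True)
class IndelAllele:
    """A concrete locus variant produced by one indel."""

    key: str
    seq: str
    spec: IndelSpec
    provenance: str = "enumerated"  # observed | mmej_predicted | enumerated
    frequency: float | None = None
    frequency_sd: float | None = None
    n_replicates: int | None = None


@dataclass(frozen=True)
class MicrohomologyDeletion:
    """A deletion whose junction is spanned by one surviving copy of a
    repeated sequence (``mh_seq``) that flanked the cut."""

    mh_seq: str
    mh_length: int
    deletion_length: int
    del_start: int
    pattern_score: float = 0.0
    normalized_frequency: float = 0.0


def apply_indel(reference: LocusSequence, spec: IndelSpec) -> IndelAllele:
    """Splice ``spec`` into ``reference`` and return the resulting allele."""
    ref = reference.seq
    if spec.kind == "insertion":
        p = spec.position
        if not 0 <= p <= len(ref):
            raise ValueError("insertion position outside reference")
        seq = ref[:p] + spec.inserted + ref[p:]
    else:
        s, e = spec.del_start, spec.del_start + spec.length
        if not 0 <= s < e <= len(ref):
            raise ValueError("deletion extends past sequence bounds")
        seq = ref[:s] + ref[e:]
    return IndelAllele(
        key=canonical_key(spec, reference),
        seq=seq,
        spec=spec,
        provenance="enumerated",
    )


def _left_normalize(spec: IndelSpec, ref: str) -> tuple[int, str]:
    """Leftmost equivalent placement: returns (position, inserted_bases).

    The shifted placement is only a representation of the same product;
    it need not itself contain the causative cut.
    """
    if spec.kind == "deletion":
        s, L = spec.del_start, spec.length
        while s > 0 and ref[s - 1] == ref[s + L - 1]:
            s -= 1
        return s, ""
    p, bases = spec.position, spec.inserted
    while p > 0 and ref[p - 1] == bases[-1]:
        bases = ref[p - 1] + bases[:-1]
        p -= 1
    return p, bases


def _right_normalize(spec: IndelSpec, ref: str) -> tuple[int, str]:
    """Rightmost equivalent placement (used for ambiguity intervals)."""
    if spec.kind == "deletion":
        s, L = spec.del_start, spec.length
        while s + L < len(ref) and ref[s] == ref[s + L]:
            s += 1
        return s, ""
    p, bases = spec.position, spec.inserted
    while p < len(ref) and ref[p] == bases[0]:
        bases = bases[1:] + ref[p]
        p += 1
    return p, bases


def canonical_key(spec: IndelSpec, reference: LocusSequence) -> str:
    """Canonical string key for an indel, unique per product sequence.

    Format: ``ins:<len>:<offset-from-cut>:<bases>`` or
    ``del:<len>:<offset-from-cut>``, after left-normalisation inside
    repeats.  Two specs producing the same allele sequence always get the
    same key.
    """
    pos, bases = _left_normalize(spec, reference.seq)
    off = pos - spec.anchor_cut
    if spec.kind == "insertion":
        return f"ins:{spec.length}:{off}:{bases}"
    return f"del:{spec.length}:{off}"


def parse_indel_key(key: str, anchor_cut: int) -> IndelSpec:
    """Reconstruct an IndelSpec from a canonical key and its cut site."""
    parts = key.split(":")
    try:
        if parts[0] == "ins" and len(parts) == 4:
            length, off, bases = int(parts[1]), int(parts[2]), parts[3]
            return IndelSpec(
                kind="insertion",
                length=length,
                anchor_cut=anchor_cut,
                inserted=bases,
                ins_pos=anchor_cut + off,
            )
        if parts[0] == "del" and len(parts) == 3:
            length, off = int(parts[1]), int(parts[2])
            return IndelSpec(
                kind="deletion",
                length=length,
                anchor_cut=anchor_cut,
                del_start=anchor_cut + off,
                normalized=True,
            )
    except ValueError as exc:
        raise ValueError(f"malformed indel key {key!r}") from exc
    raise ValueError(f"malformed indel key {key!r}")


def altered_interval(spec: IndelSpec, reference: LocusSequence) -> tuple[int, int]:
    """Half-open interval on the *allele* sequence that differs from the
    reference, widened to the full repeat-ambiguity range.

    For insertions this covers every placement of the inserted bases;
    for deletions it covers the bases flanking every equivalent junction.
    """
    ref = reference.seq
    left_pos, _ = _left_normalize(spec, ref)
    right_pos, _ = _right_normalize(spec, ref)
    if spec.kind == "insertion":
        return left_pos, right_pos + spec.length
    # deletion: junctions on the allele run from the leftmost del_start to
    # the rightmost; include one flanking base each side
    lo = max(0, left_pos - 1)
    hi = min(len(ref) - spec.length, right_pos + 1)
    return lo, hi


def enumerate_mmej_deletions(
    reference: LocusSequence,
    cut_index: int,
    min_mh: int = DEFAULT_MIN_MH,
    max_del: int = DEFAULT_MAX_DEL,
) -> list[MicrohomologyDeletion]:
    """Enumerate deletions producible by collapsing a repeat that flanks
    the cut.

    Every pair of identical substrings (length >= ``min_mh``), one ending
    at or before the cut and one starting at or after it, whose collapse
    deletes <= ``max_del`` bases yields a candidate.  Candidates giving
    the same product sequence are reported once, with the longest
    microhomology and the leftmost (left-normalised) deletion placement.
    Sorted by descending pattern score.
    """
    ref = reference.seq
    if not 0 < cut_index < len(ref):
        raise ValueError("cut_index must be interior to the reference")
    left_arm, right_arm = ref[:cut_index], ref[cut_index:]
    best: dict[str, MicrohomologyDeletion] = {}
    max_k = min(len(left_arm), len(right_arm))
    for k in range(min_mh, max_k + 1):
        for i in range(0, cut_index - k + 1):
            mh = ref[i : i + k]
            start = 0
            while True:
                j_rel = right_arm.find(mh, start)
                if j_rel == -1:
                    break
                start = j_rel + 1
                j = cut_index + j_rel
                d = j - i
                if d < 1 or d > max_del:
                    continue
                spec = IndelSpec(
                    kind="deletion", length=d, anchor_cut=cut_index, del_start=i
                )
                key = canonical_key(spec, reference)
                norm_start, _ = _left_normalize(spec, ref)
                cand = MicrohomologyDeletion(
                    mh_seq=mh,
                    mh_length=k,
                    deletion_length=d,
                    del_start=norm_start,
                )
                prev = best.get(key)
                if (
                    prev is None
                    or cand.mh_length > prev.mh_length
                    or (
                        cand.mh_length == prev.mh_length
                        and cand.del_start < prev.del_start
                    )
                ):
                    best[key] = cand
    scored = [
        replace(d, pattern_score=mmej_pattern_score(d)) for d in best.values()
    ]
    total = sum(d.pattern_score for d in scored)
    if total > 0:
        scored = [
            replace(d, normalized_frequency=d.pattern_score / total)
            for d in scored
        ]
    scored.sort(
        key=lambda d: (-d.pattern_score, d.deletion_length, d.del_start)
    )
    return scored


def mmej_pattern_score(d: MicrohomologyDeletion) -> float:
    """GC-weighted, length-penalised microhomology score.

    ``S = 100 * (L + G) * exp(-D / 20)`` where L is the microhomology
    length, G its G/C count and D the deletion length.  Longer deletions
    score lower at fixed (L, G); GC-rich microhomologies anneal more
    stably and score higher.  A transparent stand-in for machine-learned
    indel predictors, swappable via configuration.
    """
    if d.mh_length < DEFAULT_MIN_MH:
        raise ValueError(f"microhomology shorter than {DEFAULT_MIN_MH} nt")
    gc = sum(1 for c in d.mh_seq if c in "GC")
    return 100.0 * (d.mh_length + gc) * math.exp(-d.deletion_length / MMEJ_DECAY_NT)


def enumerate_one_bp_insertions(
    reference: LocusSequence, cut_index: int
) -> list[IndelAllele]:
    """All four 1-bp insertions at the cut, the templated duplication of
    the base immediately 5' of the cut ranked first.

    End joining most often duplicates the nucleotide just 5' of the blunt
    cut; the other three bases are enumerated after it.  Used only when no
    sequencing data are available — observed spectra always take priority.
    """
    if not 0 < cut_index < len(reference):
        raise ValueError("cut_index must be interior to the reference")
    templated = reference.seq[cut_index - 1]
    order = [templated] + [b for b in "ACGT" if b != templated]
    alleles = []
    for base in order:
        spec = IndelSpec(
            kind="insertion", length=1, anchor_cut=cut_index, inserted=base
        )
        alleles.append(replace(apply_indel(reference, spec), provenance="enumerated"))
    return alleles


def is_high_precision(
    frequencies: Sequence[float] | Iterable[float],
) -> tuple[bool, float]:
    """Whether the top three indel products exceed 40% of repair products.

    ``frequencies`` are per-allele percentages of all repair (indel)
    products.  Returns (verdict, top-3 cumulative percentage); the 40%
    threshold is strict.
    """
    freqs = sorted(frequencies, reverse=True)
    if not freqs:
        raise ValueError("empty indel table: precision undefined")
    top3 = float(sum(freqs[:3]))
    return top3 > HIGH_PRECISION_TOP3_PCT, top3
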