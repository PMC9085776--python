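"""Amplicon read classification and indel quantification.

Reads are classified against the reference amplicon (and optionally the
HDR-edited amplicon) into WT, perfect-HDR, INDEL or DISCARD within a
quantification window around the cut.  Frequencies follow the amplicon
sequencing convention: reads carrying an allele divided by all
QC-passing reads, as percentages.  Reads that carry the HDR edit *and*
an indel count as INDEL — perfect HDR means no indels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .indel_model import IndelAllele, IndelSpec, apply_indel, canonical_key, parse_indel_key
from .seqcore import LocusSequence

logger = logging.getLogger(__name__)

#: read categories
WT, HDR_PERFECT, INDEL, DISCARD = "WT", "HDR_perfect", "INDEL", "DISCARD"

ZYGOSITY_CATEGORIES = (
    "homozygous",      # all copies carry the HDR edit, no indels
    "heterozygous",    # WT + HDR mixture, no indels
    "HDR_indel",       # HDR edits mixed with indels
    "indel_mixture",   # all copies carry indels
    "WT_indel",        # WT mixed with indels
    "WT",              # all copies unedited
)


@dataclass(frozen=True)
class QuantifyParams:
    """Alignment and QC settings for read classification.

    Alignment is global with free gaps at read ends (truncated reads are
    not penalised); scores are standard amplicon settings.  Mismatches and
    gaps outside the quantification window are tolerated as sequencing
    error.
    """

    window: int = 10
    match: int = 5
    mismatch: int = -4
    gap_open: int = -10
    gap_extend: int = -1
    min_mean_quality: float = 20.0
    min_length_fraction: float = 0.8
    min_identity: float = 0.6


@dataclass(frozen=True)
class ReadClassification:
    category: str
    indel_keys: tuple[str, ...] = ()
    alignment_score: float = 0.0

    def __post_init__(self) -> None:
        if (self.category == INDEL) != bool(self.indel_keys):
            raise ValueError("indel_keys non-empty iff category is INDEL")


@dataclass(frozen=True)
class Stat:
    """Mean and standard deviation (sample sd, n-1) across replicates."""

    mean: float
    sd: float
    n: int

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "Stat":
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(mean=float(arr.mean()), sd=sd, n=arr.size)


@dataclass
class IndelTable:
    """Per-allele indel frequencies with replicate statistics.

    Frequencies are percentages of all QC-passing reads (the "initial
    indel rates" of a primary-gRNA-only experiment).  Per replicate,
    wt + hdr + total_indel + discard = 100 within rounding.
    """

    locus_id: str
    cut_index: int
    total_reads: int
    n_replicates: int
    alleles: list[IndelAllele]
    wt_pct: Stat
    hdr_pct: Stat
    total_indel_pct: Stat
    discard_pct: Stat
    per_replicate: pd.DataFrame = field(repr=False, default=None)

    def allele_frequencies(self) -> dict[str, float]:
        return {a.key: a.frequency for a in self.alleles}

    def indel_product_percentages(self) -> list[float]:
        """Allele frequencies renormalised to percent of indel products."""
        total = sum(a.frequency for a in self.alleles)
        if total == 0:
            return []
        return [a.frequency / total * 100.0 for a in self.alleles]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.alleles:
            spec = a.spec
            offset = bases = None
            kind = None
            if spec is not None:
                kind = "ins" if spec.kind == "insertion" else "del"
                offset = spec.position - spec.anchor_cut
                bases = spec.inserted or None
            rows.append(
                {
                    "key": a.key,
                    "kind": kind,
                    "length": spec.length if spec else None,
                    "offset": offset,
                    "bases": bases,
                    "frequency_pct": a.frequency,
                    "sd_pct": a.frequency_sd,
                    "n": a.n_replicates,
                    "provenance": a.provenance,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "key", "kind", "length", "offset", "bases",
                "frequency_pct", "sd_pct", "n", "provenance",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "cut_index": self.cut_index,
            "total_reads": self.total_reads,
            "n_replicates": self.n_replicates,
            "wt_pct": {"mean": self.wt_pct.mean, "sd": self.wt_pct.sd},
            "hdr_pct": {"mean": self.hdr_pct.mean, "sd": self.hdr_pct.sd},
            "total_indel_pct": {
                "mean": self.total_indel_pct.mean,
                "sd": self.total_indel_pct.sd,
            },
            "discard_pct": {
                "mean": self.discard_pct.mean,
                "sd": self.discard_pct.sd,
            },
            "n_alleles": len(self.alleles),
        }


@dataclass(frozen=True)
class ComparisonStats:
    """Double-tap vs non-targeting comparison.

    fold_change = mean(DT HDR) / mean(NT HDR), sd by quotient error
    propagation; percent_decrease_indels = (NT - DT)/NT * 100 on mean
    total indel rates.
    """

    fold_change: float | None
    fold_change_sd: float | None
    percent_decrease_indels: float
    percent_decrease_sd: float
    hdr_to_indel_ratio_change: float | None
    targeted_rate_nt: float
    targeted_rate_dt: float
    fold_undefined: bool = False


@dataclass(frozen=True)
class ZygosityCall:
    clone_id: str
    ploidy: int
    category: str
    fractions: Mapping[str, float] = field(default_factory=dict)


def _mean_phred(quality: str) -> float:
    if not quality:
        return math.inf
    return sum(ord(c) - 33 for c in quality) / len(quality)


def _make_aligner(params: QuantifyParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=params.match,
        mismatch_score=params.mismatch,
        open_gap_score=params.gap_open,
        extend_gap_score=params.gap_extend,
    )
    # free gaps at read ends: a truncated read is not an indel
    aligner.end_deletion_score = 0
    return aligner


def _alignment_ops(
    aln, ref: str, read: str
) -> tuple[list[IndelSpec], list[int], int]:
    """Extract gaps (as cut-less IndelSpecs with anchor_cut=-1 placeholder),
    mismatch reference positions, and match count from a pairwise alignment."""
    tgt_blocks, qry_blocks = aln.aligned
    gaps: list[tuple[str, int, int, str]] = []  # (kind, ref_pos, length, bases)
    mismatches: list[int] = []
    matches = 0
    for bi, ((ts, te), (qs, qe)) in enumerate(zip(tgt_blocks, qry_blocks)):
        for k in range(te - ts):
            if ref[ts + k] == read[qs + k]:
                matches += 1
            else:
                mismatches.append(ts + k)
        if bi + 1 < len(tgt_blocks):
            nts, _ = tgt_blocks[bi + 1]
            nqs, _ = qry_blocks[bi + 1]
            dt, dq = nts - te, nqs - qe
            if dt > 0:
                gaps.append(("deletion", te, dt, ""))
            if dq > 0:
                gaps.append(("insertion", te if dt == 0 else nts, dq, read[qe:nqs]))
    specs = []
    for kind, pos, length, bases in gaps:
        specs.append((kind, pos, length, bases))
    return specs, mismatches, matches


def _window_bounds(cut_index: int, window: int) -> tuple[int, int]:
    return cut_index - window, cut_index + window


def _classify_against(
    read: str,
    amplicon: str,
    cut_index: int,
    params: QuantifyParams,
    aligner: Align.PairwiseAligner,
) -> dict:
    """Alignment of ``read`` to ``amplicon`` summarised relative to the
    quantification window."""
    lo, hi = _window_bounds(cut_index, params.window)
    if read == amplicon:
        return {
            "gaps_in_window": [], "mismatch_in_window": False,
            "identity": 1.0, "score": params.match * len(read),
        }
    if len(read) == len(amplicon):
        diff = [i for i, (a, b) in enumerate(zip(read, amplicon)) if a != b]
        identity = 1 - len(diff) / len(amplicon)
        if identity >= params.min_identity:
            return {
                "gaps_in_window": [],
                "mismatch_in_window": any(lo <= i < hi for i in diff),
                "identity": identity,
                "score": float(
                    params.match * (len(read) - len(diff))
                    + params.mismatch * len(diff)
                ),
            }
    aln = aligner.align(amplicon, read)[0]
    gaps, mismatches, matches = _alignment_ops(aln, amplicon, read)
    gaps_in_window = []
    for kind, pos, length, bases in gaps:
        if kind == "deletion":
            touches = pos <= hi and pos + length >= lo
        else:
            touches = lo <= pos <= hi
        if touches:
            gaps_in_window.append((kind, pos, length, bases))
    aln_span = matches + len(mismatches) + sum(g[2] for g in gaps)
    identity = matches / aln_span if aln_span else 0.0
    return {
        "gaps_in_window": gaps_in_window,
        "mismatch_in_window": any(lo <= i < hi for i in mismatches),
        "identity": identity,
        "score": float(aln.score),
    }


def classify_read(
    read: str,
    quality: str | None,
    ref_amplicon: LocusSequence,
    hdr_amplicon: LocusSequence | None,
    cut_index: int,
    params: QuantifyParams = QuantifyParams(),
    hdr_cut_index: int | None = None,
    _aligner: Align.PairwiseAligner | None = None,
) -> ReadClassification:
    """Classify one amplicon read as WT / HDR_perfect / INDEL / DISCARD.

    HDR_perfect: aligns to the HDR amplicon with no mismatch or gap inside
    the quantification window.  WT: same against the reference.  INDEL:
    best alignment to the reference has >= 1 gap touching the window
    (canonical keys reported).  Everything else — low identity, QC
    failure, window mismatches without a gap — is DISCARD.
    """
    read = read.upper()
    if quality is not None and _mean_phred(quality) < params.min_mean_quality:
        return ReadClassification(category=DISCARD)
    if len(read) < params.min_length_fraction * len(ref_amplicon):
        return ReadClassification(category=DISCARD)
    aligner = _aligner if _aligner is not None else _make_aligner(params)

    if hdr_amplicon is not None:
        hc = hdr_cut_index if hdr_cut_index is not None else cut_index
        res = _classify_against(read, hdr_amplicon.seq, hc, params, aligner)
        if (
            not res["gaps_in_window"]
            and not res["mismatch_in_window"]
            and res["identity"] >= params.min_identity
        ):
            return ReadClassification(
                category=HDR_PERFECT, alignment_score=res["score"]
            )

    res = _classify_against(read, ref_amplicon.seq, cut_index, params, aligner)
    if res["identity"] < params.min_identity:
        return ReadClassification(category=DISCARD)
    if res["gaps_in_window"]:
        # a read whose only indel reconstructs the HDR allele exactly is an
        # errored HDR read, not a novel byproduct: ambiguous, discard
        if hdr_amplicon is not None and len(res["gaps_in_window"]) == 1:
            kind, pos, length, bases = res["gaps_in_window"][0]
            ref = ref_amplicon.seq
            if kind == "insertion":
                product = ref[:pos] + bases + ref[pos:]
            else:
                product = ref[:pos] + ref[pos + length:]
            if product == hdr_amplicon.seq:
                return ReadClassification(
                    category=DISCARD, alignment_score=res["score"]
                )
        keys = []
        for kind, pos, length, bases in res["gaps_in_window"]:
            if kind == "insertion":
                spec = IndelSpec(
                    kind="insertion", length=length, anchor_cut=cut_index,
                    inserted=bases, ins_pos=pos,
                )
            else:
                # anchor the spec at the gap itself so validation holds even
                # for gaps at the window edge
                anchor = min(max(cut_index, pos), pos + length)
                spec = IndelSpec(
                    kind="deletion", length=length, anchor_cut=anchor,
                    del_start=pos,
                )
            key = canonical_key(spec, ref_amplicon)
            if spec.kind == "deletion":
                # re-express the offset relative to the true cut
                off = int(key.split(":")[2]) + (anchor - cut_index)
                key = f"del:{length}:{off}"
            if key not in keys:
                keys.append(key)
        return ReadClassification(
            category=INDEL, indel_keys=tuple(keys),
            alignment_score=res["score"],
        )
    if not res["mismatch_in_window"]:
        return ReadClassification(category=WT, alignment_score=res["score"])
    return ReadClassification(category=DISCARD, alignment_score=res["score"])


def _classify_replicate(
    reads: Sequence[tuple[str, str | None]],
    ref: LocusSequence,
    hdr: LocusSequence | None,
    cut_index: int,
    params: QuantifyParams,
    hdr_cut_index: int | None,
    cache: dict,
    aligner: Align.PairwiseAligner,
) -> tuple[dict, dict[str, int], int]:
    counts = {WT: 0, HDR_PERFECT: 0, INDEL: 0, DISCARD: 0}
    key_counts: dict[str, int] = {}
    n_pass = 0
    for seq, qual in reads:
        if qual is not None and _mean_phred(qual) < params.min_mean_quality:
            continue  # QC failure: excluded from the denominator
        if len(seq) < params.min_length_fraction * len(ref):
            continue
        n_pass += 1
        cls = cache.get(seq)
        if cls is None:
            cls = classify_read(
                seq, None, ref, hdr, cut_index, params,
                hdr_cut_index=hdr_cut_index, _aligner=aligner,
            )
            cache[seq] = cls
        counts[cls.category] += 1
        for key in cls.indel_keys:
            key_counts[key] = key_counts.get(key, 0) + 1
    return counts, key_counts, n_pass


def build_indel_table(
    replicates: Sequence[Sequence[tuple[str, str | None]]],
    ref: LocusSequence,
    hdr: LocusSequence | None,
    cut_index: int,
    params: QuantifyParams = QuantifyParams(),
    hdr_cut_index: int | None = None,
    reporting_floor_pct: float = 0.1,
) -> IndelTable:
    """Quantify indel alleles across replicate read sets.

    Each replicate is a sequence of (sequence, quality-or-None) reads.
    Frequencies are per-replicate percentages of QC-passing reads,
    averaged across replicates; alleles with mean frequency below
    ``reporting_floor_pct`` are pooled under the key ``other``.
    """
    if not replicates or any(len(r) == 0 for r in replicates):
        raise ValueError("each replicate needs at least one read")
    cache: dict = {}
    aligner = _make_aligner(params)
    per_rep = []
    all_keys: set[str] = set()
    total_reads = 0
    for rep in replicates:
        counts, key_counts, n_pass = _classify_replicate(
            rep, ref, hdr, cut_index, params, hdr_cut_index, cache, aligner
        )
        if n_pass == 0:
            raise ValueError("no classifiable reads (all failed QC)")
        total_reads += n_pass
        row = {
            "n_reads": n_pass,
            "wt_pct": counts[WT] / n_pass * 100,
            "hdr_pct": counts[HDR_PERFECT] / n_pass * 100,
            "total_indel_pct": counts[INDEL] / n_pass * 100,
            "discard_pct": counts[DISCARD] / n_pass * 100,
        }
        for key, c in key_counts.items():
            row[key] = c / n_pass * 100
            all_keys.add(key)
        per_rep.append(row)
    if all(r["wt_pct"] + r["hdr_pct"] + r["total_indel_pct"] == 0 for r in per_rep):
        raise ValueError("no classifiable reads")
    df = pd.DataFrame(per_rep).fillna(0.0)

    alleles: list[IndelAllele] = []
    pooled = 0.0
    pooled_var = 0.0
    n_rep = len(replicates)
    for key in sorted(all_keys):
        stat = Stat.from_values(df[key].tolist())
        if stat.mean < reporting_floor_pct:
            pooled += stat.mean
            pooled_var += stat.sd ** 2
            continue
        try:
            spec = parse_indel_key(key, cut_index)
            seq = apply_indel(ref, spec).seq
        except ValueError:
            spec, seq = None, ""
        alleles.append(
            IndelAllele(
                key=key, seq=seq, spec=spec, provenance="observed",
                frequency=stat.mean, frequency_sd=stat.sd, n_replicates=n_rep,
            )
        )
    alleles.sort(key=lambda a: (-a.frequency, a.key))
    if pooled > 0:
        alleles.append(
            IndelAllele(
                key="other", seq="", spec=None, provenance="observed",
                frequency=pooled, frequency_sd=math.sqrt(pooled_var),
                n_replicates=n_rep,
            )
        )
    return IndelTable(
        locus_id=ref.id,
        cut_index=cut_index,
        total_reads=total_reads,
        n_replicates=n_rep,
        alleles=alleles,
        wt_pct=Stat.from_values(df["wt_pct"].tolist()),
        hdr_pct=Stat.from_values(df["hdr_pct"].tolist()),
        total_indel_pct=Stat.from_values(df["total_indel_pct"].tolist()),
        discard_pct=Stat.from_values(df["discard_pct"].tolist()),
        per_replicate=df,
    )


def _quotient_sd(a: float, sa: float, b: float, sb: float) -> float:
    """SD of b/a by first-order propagation of uncertainty."""
    f = b / a
    return abs(f) * math.sqrt((sa / a) ** 2 + (sb / b) ** 2) if b != 0 else 0.0


def compare_conditions(
    nt: IndelTable, dt: IndelTable, targeted_keys: Sequence[str] = ()
) -> ComparisonStats:
    """Fold-change in perfect HDR and percent decrease in total indels
    between a non-targeting (NT) control and a double-tap (DT) sample.

    fold = mean(DT HDR)/mean(NT HDR) with sd by quotient propagation;
    percent decrease = (mean NT indels - mean DT indels)/mean NT indels x 100.
    """
    if nt.locus_id != dt.locus_id:
        raise ValueError("tables must come from the same locus")
    a, sa = nt.hdr_pct.mean, nt.hdr_pct.sd
    b, sb = dt.hdr_pct.mean, dt.hdr_pct.sd
    if a == 0:
        fold, fold_sd, undefined = None, None, True
        logger.warning("NT HDR mean is 0: fold-change undefined")
    else:
        fold = b / a
        fold_sd = _quotient_sd(a, sa, b, sb)
        undefined = False
    ti_nt, s_nt = nt.total_indel_pct.mean, nt.total_indel_pct.sd
    ti_dt, s_dt = dt.total_indel_pct.mean, dt.total_indel_pct.sd
    if ti_nt == 0:
        pct_dec, pct_sd = 0.0, 0.0
    else:
        pct_dec = (ti_nt - ti_dt) / ti_nt * 100.0
        pct_sd = 100.0 * _quotient_sd(ti_nt, s_nt, ti_dt, s_dt)
    ratio_change = None
    if not undefined and ti_nt > 0 and ti_dt > 0 and a > 0:
        ratio_change = (b / ti_dt) / (a / ti_nt)
    nt_freqs = nt.allele_frequencies()
    dt_freqs = dt.allele_frequencies()
    return ComparisonStats(
        fold_change=fold,
        fold_change_sd=fold_sd,
        percent_decrease_indels=pct_dec,
        percent_decrease_sd=pct_sd,
        hdr_to_indel_ratio_change=ratio_change,
        targeted_rate_nt=sum(nt_freqs.get(k, 0.0) for k in targeted_keys),
        targeted_rate_dt=sum(dt_freqs.get(k, 0.0) for k in targeted_keys),
        fold_undefined=undefined,
    )


def genotype_clones(
    clones: Sequence[tuple[str, Sequence[tuple[str, str | None]]]],
    ref: LocusSequence,
    hdr: LocusSequence | None,
    cut_index: int,
    ploidy: int = 3,
    params: QuantifyParams = QuantifyParams(),
    hdr_cut_index: int | None = None,
    min_reads: int = 100,
    presence_threshold: float = 0.10,
) -> tuple[list[ZygosityCall], dict[str, int]]:
    """Genotype clonal isolates from their read sets and summarise
    zygosity categories.

    An allele class (HDR / WT / indel) is present in a clone when its
    fraction of classified reads reaches ``presence_threshold`` (default
    10%, ~ detection of one allele of a triploid with noise).  Category
    mapping: {HDR} -> homozygous; {HDR, WT} -> heterozygous; HDR with any
    indel -> HDR_indel; {indel} -> indel_mixture; {WT, indel} -> WT_indel;
    {WT} -> WT.  The summary reports each category as percent of called
    clones, rounded to integers.
    """
    calls: list[ZygosityCall] = []
    cache: dict = {}
    aligner = _make_aligner(params)
    for clone_id, reads in clones:
        counts, _keys, n_pass = _classify_replicate(
            reads, ref, hdr, cut_index, params, hdr_cut_index, cache, aligner
        )
        classified = counts[WT] + counts[HDR_PERFECT] + counts[INDEL]
        if n_pass < min_reads or classified == 0:
            logger.info(
                "clone %s excluded: %d reads below minimum %d",
                clone_id, n_pass, min_reads,
            )
            continue
        fractions = {
            "HDR": counts[HDR_PERFECT] / classified,
            "WT": counts[WT] / classified,
            "indel": counts[INDEL] / classified,
        }
        present = {k for k, f in fractions.items() if f >= presence_threshold}
        if present == {"HDR"}:
            cat = "homozygous"
        elif present == {"HDR", "WT"}:
            cat = "heterozygous"
        elif "HDR" in present:
            cat = "HDR_indel"
        elif present == {"indel"}:
            cat = "indel_mixture"
        elif present == {"WT", "indel"}:
            cat = "WT_indel"
        elif present == {"WT"}:
            cat = "WT"
        else:  # nothing reaches the threshold: dominant class decides
            cat = "WT" if fractions["WT"] >= fractions["indel"] else "indel_mixture"
        calls.append(
            ZygosityCall(
                clone_id=clone_id, ploidy=ploidy, category=cat,
                fractions=fractions,
            )
        )
    summary = {cat: 0 for cat in ZYGOSITY_CATEGORIES}
    if calls:
        for cat in ZYGOSITY_CATEGORIES:
            n_cat = sum(1 for c in calls if c.category == cat)
            summary[cat] = round(n_cat / len(calls) * 100)
    return calls, summary
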