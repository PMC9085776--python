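"""Secondary gRNA design: enumerate guides on indel alleles, filter
against wild-type and HDR products, screen off-targets, and predict the
HDR improvement with the linear fold-change model.

A secondary gRNA targets a specific indel byproduct of the primary cut,
giving those alleles a "second chance" at HDR.  A safe secondary guide
must span the indel junction and must not occur in the wild-type locus
(it would cut at an unwanted alternate site) or in the HDR-edited
product (it would destroy the desired outcome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .indel_model import IndelAllele, altered_interval
from .quantify import IndelTable
from .seqcore import (
    SPACER_LENGTH,
    IUPAC_SETS,
    LocusSequence,
    NGG,
    PamPattern,
    Protospacer,
    find_protospacers,
    reverse_complement,
)

logger = logging.getLogger(__name__)

BLOCKED, NOT_BLOCKED = "blocked", "not_blocked"

#: rejection reasons
REASON_WT = "alternate_cut_site_on_wildtype"
REASON_HDR = "cuts_hdr_product"


@dataclass(frozen=True)
class OfftargetHit:
    seq_id: str
    position: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class GuideCandidate:
    """A secondary gRNA candidate against one indel allele."""

    spacer: str
    pam: str
    strand: str
    position: int  # spacer start on the indel allele (forward coords)
    target_allele_key: str
    junction_overlap: int
    flags: frozenset[str] = frozenset()
    offtarget_full_matches: tuple[OfftargetHit, ...] = ()
    offtarget_1mm: tuple[OfftargetHit, ...] = ()

    @property
    def site(self) -> str:
        return self.spacer + self.pam


@dataclass(frozen=True)
class ImprovementModel:
    """Linear model: HDR fold-change vs summed initial rate (in
    percentage points) of the indels targeted by secondary gRNAs.

    The published fit over eleven genomic loci is
    fold = 0.966 + 0.0167 * rate with r^2 = 0.81.
    """

    intercept: float = 0.966
    slope: float = 0.0167
    r_squared: float = 0.81

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("a usable improvement model has slope >= 0")

    def rate_for_fold(self, fold: float) -> float:
        """Targeted initial rate (pct points) needed for a given fold."""
        if self.slope == 0:
            raise ValueError("slope 0: fold does not depend on rate")
        return (fold - self.intercept) / self.slope


@dataclass(frozen=True)
class Prediction:
    fold_change: float
    absolute_hdr_pct: float | None = None
    warning: str | None = None


@dataclass
class DesignReport:
    """Ranked secondary-guide designs for the top indel alleles."""

    table: pd.DataFrame
    targeted_rate_pct: float
    predicted_fold: float
    predicted_hdr_pct: float | None
    selected_keys: tuple[str, ...]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self) -> dict:
        return {
            "selected_alleles": list(self.selected_keys),
            "targeted_rate_pct": self.targeted_rate_pct,
            "predicted_fold_change": self.predicted_fold,
            "predicted_hdr_pct": self.predicted_hdr_pct,
            "candidates": self.table.to_dict(orient="records"),
        }


def _occurs(site: str, seq: str) -> bool:
    """Exact substring on either strand."""
    return site in seq or reverse_complement(site) in seq


def _project_to_allele(pos: int, allele: IndelAllele) -> int | None:
    """Map a wild-type coordinate onto the allele, or None if it falls
    inside the altered region."""
    spec = allele.spec
    if spec.kind == "insertion":
        p = spec.position
        if pos < p:
            return pos
        return pos + spec.length
    s, e = spec.del_start, spec.del_start + spec.length
    if pos < s:
        return pos
    if pos >= e:
        return pos - spec.length
    return None


def enumerate_secondary_guides(
    wt: LocusSequence,
    hdr: LocusSequence | None,
    allele: IndelAllele,
    pams: Sequence[PamPattern] = (NGG,),
    primary: Protospacer | None = None,
    keep_flagged: bool = False,
) -> tuple[list[GuideCandidate], list[tuple[GuideCandidate, str]]]:
    """Secondary gRNA candidates on ``allele`` that span the indel.

    Scans both strands of the allele with each PAM pattern; a candidate's
    spacer must overlap the indel-altered region by >= 1 nt.  Candidates
    whose spacer+PAM occurs in the wild-type locus (either strand) are
    rejected — they would cut the original sequence at an alternate site.
    Candidates occurring in the HDR product are rejected — they would
    destroy the desired edit.  With ``keep_flagged`` the rejects are
    returned in the accepted list, carrying their flags.
    """
    if allele.seq == wt.seq:
        raise ValueError("allele is identical to wild type: nothing to target")
    if allele.spec is None:
        raise ValueError(f"allele {allele.key!r} has no indel spec")
    alt_lo, alt_hi = altered_interval(allele.spec, wt)
    allele_locus = LocusSequence(id=f"{wt.id}|{allele.key}", seq=allele.seq)

    primary_pam_on_allele: tuple[int, int] | None = None
    if primary is not None:
        ps, pe = primary.pam_interval()
        a_ps = _project_to_allele(ps, allele)
        a_pe_last = _project_to_allele(pe - 1, allele)
        if a_ps is not None and a_pe_last is not None and a_pe_last - a_ps == pe - 1 - ps:
            primary_pam_on_allele = (a_ps, a_pe_last + 1)

    accepted: list[GuideCandidate] = []
    rejected: list[tuple[GuideCandidate, str]] = []
    seen: set[tuple[str, str, str, int]] = set()
    for pam in pams:
        for proto in find_protospacers(allele_locus, pam):
            ident = (proto.spacer, proto.pam, proto.strand, proto.spacer_start)
            if ident in seen:
                continue
            s, e = proto.spacer_start, proto.spacer_start + SPACER_LENGTH
            overlap = min(e, alt_hi) - max(s, alt_lo)
            if overlap < 1:
                continue
            seen.add(ident)
            flags = set()
            site = proto.site
            if _occurs(site, wt.seq):
                flags.add("matches_wildtype")
            if hdr is not None and _occurs(site, hdr.seq):
                flags.add("matches_hdr_allele")
            if primary_pam_on_allele is not None and (
                proto.pam_interval() == primary_pam_on_allele
                and proto.strand == primary.strand
            ):
                flags.add("uses_original_pam")
            else:
                flags.add("uses_alternate_pam")
            cand = GuideCandidate(
                spacer=proto.spacer,
                pam=proto.pam,
                strand=proto.strand,
                position=proto.spacer_start,
                target_allele_key=allele.key,
                junction_overlap=overlap,
                flags=frozenset(flags),
            )
            if "matches_wildtype" in flags and not keep_flagged:
                rejected.append((cand, REASON_WT))
            elif "matches_hdr_allele" in flags and not keep_flagged:
                rejected.append((cand, REASON_HDR))
            else:
                accepted.append(cand)
    return accepted, rejected


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def screen_offtargets(
    spacer: str,
    pam: PamPattern,
    background: Iterable[LocusSequence],
    max_mismatches: int = 1,
) -> list[OfftargetHit]:
    """Naive exact / 1-mismatch off-target scan of background sequences.

    A hit is a window on either strand where the PAM matches its pattern
    exactly and the spacer matches with <= ``max_mismatches``
    substitutions; N in the background never matches.  Complexity is
    O(total background length x site length) — a vectorised sliding
    comparison, adequate for user-provided FASTA, not a genome index.

    Hit positions are forward-strand start coordinates of the full
    spacer+PAM site.
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    spacer = spacer.upper()
    w = len(spacer) + len(pam)
    spacer_arr = _encode(spacer)
    pam_allowed = [
        np.array([ord(b) for b in sorted(IUPAC_SETS[c] & set("ACGT"))], dtype=np.uint8)
        for c in pam.pattern
    ]
    hits: list[OfftargetHit] = []
    for bg in background:
        n = len(bg)
        if n < w:
            continue
        for strand, seq in (("+", bg.seq), ("-", reverse_complement(bg.seq))):
            arr = _encode(seq)
            n_win = n - w + 1
            mism = np.zeros(n_win, dtype=np.int32)
            for j in range(len(spacer)):
                mism += arr[j : j + n_win] != spacer_arr[j]
            pam_ok = np.ones(n_win, dtype=bool)
            for j, allowed in enumerate(pam_allowed):
                col = arr[len(spacer) + j : len(spacer) + j + n_win]
                pam_ok &= np.isin(col, allowed)
            for i in np.nonzero(pam_ok & (mism <= max_mismatches))[0]:
                i = int(i)
                fwd_pos = i if strand == "+" else n - i - w
                hits.append(
                    OfftargetHit(
                        seq_id=bg.id, position=fwd_pos, strand=strand,
                        mismatches=int(mism[i]),
                    )
                )
    hits.sort(key=lambda h: (h.seq_id, h.position, h.strand))
    return hits


def attach_offtargets(
    candidate: GuideCandidate,
    background: Sequence[LocusSequence],
    pam: PamPattern,
) -> GuideCandidate:
    """Return the candidate with full-match and 1-mismatch hits attached."""
    hits = screen_offtargets(candidate.spacer, pam, background, max_mismatches=1)
    full = tuple(h for h in hits if h.mismatches == 0)
    onemm = tuple(h for h in hits if h.mismatches == 1)
    return replace(
        candidate, offtarget_full_matches=full, offtarget_1mm=onemm
    )


def check_blocking(hdr: LocusSequence, primary: Protospacer) -> str:
    """Whether the HDR product still contains the primary spacer+PAM.

    ``blocked`` means the primary site is destroyed in the HDR allele so
    Cas9 cannot re-cut the desired product.  Exact-substring rule: any
    single change inside spacer or PAM counts as blocking (a documented
    simplification — PAM-distal spacer mismatches may in reality still
    permit cutting).
    """
    if _occurs(primary.site, hdr.seq):
        logger.warning(
            "primary protospacer intact in the HDR product: consider adding "
            "silent blocking mutations in the PAM or PAM-proximal spacer"
        )
        return NOT_BLOCKED
    return BLOCKED


def predict_improvement(
    model: ImprovementModel,
    targeted_rate: float,
    baseline_hdr: float | None = None,
) -> Prediction:
    """Predicted HDR fold-change for a summed targeted initial indel rate
    (percentage points, 0-100); absolute HDR when a baseline is given."""
    if targeted_rate < 0:
        raise ValueError("targeted rate cannot be negative")
    if targeted_rate > 100:
        raise ValueError("targeted rate is a percentage (0-100)")
    fold = model.intercept + model.slope * targeted_rate
    warning = None
    if fold < 1:
        warning = (
            f"predicted fold {fold:.3f} < 1: targeted rate too low for a "
            "net improvement"
        )
    absolute = baseline_hdr * fold if baseline_hdr is not None else None
    return Prediction(fold_change=fold, absolute_hdr_pct=absolute, warning=warning)


def fit_improvement_model(
    points: Sequence[tuple[float, float]]
) -> ImprovementModel:
    """Ordinary least squares fit of fold-change against targeted rate.

    Closed form: slope = cov(x, y)/var(x).  Requires >= 2 distinct rates.
    """
    if len(points) < 2:
        raise ValueError("need at least two points to fit a line")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("all rates identical: degenerate design")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ImprovementModel(intercept=intercept, slope=slope, r_squared=r2)


def rank_candidates(cands: Sequence[GuideCandidate]) -> list[GuideCandidate]:
    """Deterministic ranking: fewest full off-target matches, then fewest
    1-mismatch hits, then greatest junction overlap, then spacer."""
    return sorted(
        cands,
        key=lambda c: (
            len(c.offtarget_full_matches),
            len(c.offtarget_1mm),
            -c.junction_overlap,
            c.spacer,
        ),
    )


def design_report(
    table: IndelTable,
    candidates_per_allele: dict[str, tuple[list[GuideCandidate], list[tuple[GuideCandidate, str]]]],
    model: ImprovementModel = ImprovementModel(),
    k: int = 3,
    baseline_hdr: float | None = None,
) -> DesignReport:
    """Greedy design: take the top-``k`` alleles by initial rate, sum
    their rates, rank candidates per allele, and predict the fold-change.

    Alleles without any accepted candidate produce explicit
    "no design possible" rows.  Ranks are unique and deterministic.
    """
    real = [a for a in table.alleles if a.key != "other" and a.spec is not None]
    if not real:
        raise ValueError("quantified table has no indel alleles")
    selected = sorted(real, key=lambda a: (-a.frequency, a.key))[:k]
    targeted_rate = sum(a.frequency for a in selected)
    pred = predict_improvement(model, targeted_rate, baseline_hdr)
    rows = []
    for allele in selected:
        accepted, rejected = candidates_per_allele.get(allele.key, ([], []))
        ranked = rank_candidates(accepted)
        if not ranked:
            rows.append(
                {
                    "allele_key": allele.key,
                    "initial_rate_pct": allele.frequency,
                    "rank": None,
                    "status": "no design possible",
                    "spacer": None, "pam": None, "strand": None,
                    "position": None, "junction_overlap": None,
                    "flags": None, "n_offtarget_0mm": None,
                    "n_offtarget_1mm": None, "reason": None,
                }
            )
        for rank, cand in enumerate(ranked, start=1):
            rows.append(
                {
                    "allele_key": allele.key,
                    "initial_rate_pct": allele.frequency,
                    "rank": rank,
                    "status": "accepted",
                    "spacer": cand.spacer,
                    "pam": cand.pam,
                    "strand": cand.strand,
                    "position": cand.position,
                    "junction_overlap": cand.junction_overlap,
                    "flags": ";".join(sorted(cand.flags)),
                    "n_offtarget_0mm": len(cand.offtarget_full_matches),
                    "n_offtarget_1mm": len(cand.offtarget_1mm),
                    "reason": None,
                }
            )
        for cand, reason in rejected:
            rows.append(
                {
                    "allele_key": allele.key,
                    "initial_rate_pct": allele.frequency,
                    "rank": None,
                    "status": "rejected",
                    "spacer": cand.spacer,
                    "pam": cand.pam,
                    "strand": cand.strand,
                    "position": cand.position,
                    "junction_overlap": cand.junction_overlap,
                    "flags": ";".join(sorted(cand.flags)),
                    "n_offtarget_0mm": None,
                    "n_offtarget_1mm": None,
                    "reason": reason,
                }
            )
    df = pd.DataFrame(rows)
    df["targeted_rate_pct"] = targeted_rate
    df["predicted_fold"] = pred.fold_change
    if baseline_hdr is not None:
        df["predicted_hdr_pct"] = pred.absolute_hdr_pct
    return DesignReport(
        table=df,
        targeted_rate_pct=targeted_rate,
        predicted_fold=pred.fold_change,
        predicted_hdr_pct=pred.absolute_hdr_pct,
        selected_keys=tuple(a.key for a in selected),
    )
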