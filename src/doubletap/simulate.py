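"""Synthetic amplicon data: random loci, editing-outcome mixtures, and
sequencing reads.

The simulator emulates the NGS readout of a Cas9 HDR experiment: each
read is drawn from a stated mixture of wild-type, perfect-HDR and indel
alleles, then per-base substitution errors are applied.  It also builds
paired non-targeting / double-tap read sets in which a fraction of each
targeted indel's probability mass is converted to HDR (and optionally to
new secondary indels), so the configured fold-change is recoverable by
quantification.  Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .indel_model import apply_indel, parse_indel_key
from .seqcore import (
    LocusSequence,
    NGG,
    PamPattern,
    Protospacer,
    find_protospacers,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimRead:
    id: str
    seq: str
    quality: str

    def as_pair(self) -> tuple[str, str]:
        return self.seq, self.quality


@dataclass(frozen=True)
class OutcomeDistribution:
    """Mixture of editing outcomes: WT, perfect HDR, and indel alleles
    (by canonical key).  Fractions are non-negative and sum to 1."""

    wt_fraction: float
    hdr_fraction: float
    indel_fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fracs = [self.wt_fraction, self.hdr_fraction, *self.indel_fractions.values()]
        if any(f < -1e-12 for f in fracs):
            raise ValueError("fractions must be non-negative")
        total = sum(fracs)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"fractions must sum to 1, got {total}")

    def categories(self) -> list[tuple[str, float]]:
        cats = [("WT", self.wt_fraction), ("HDR", self.hdr_fraction)]
        cats.extend(sorted(self.indel_fractions.items()))
        return cats


@dataclass(frozen=True)
class SimConfig:
    """Read-generation settings; identical config + seed means
    byte-identical output."""

    seed: int
    n_reads: int
    error_rate: float = 0.0
    exact_counts: bool = False  # deterministic composition (largest remainder)

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def _phred_char(error_rate: float) -> str:
    if error_rate <= 0:
        q = 40
    else:
        q = int(round(-10 * math.log10(error_rate)))
        q = max(2, min(40, q))
    return chr(q + 33)


def make_locus(
    seed: int,
    length: int,
    gc_fraction: float = 0.5,
    require_pam: PamPattern = NGG,
) -> tuple[LocusSequence, Protospacer]:
    """Random locus of the given length and GC content guaranteed to host
    a protospacer for ``require_pam``; returns the protospacer whose cut
    lies closest to the centre (most room for indels and the
    quantification window)."""
    if length < 30:
        raise ValueError("length must be >= 30 to host a spacer and PAM")
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    for attempt in range(1000):
        seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
        locus = LocusSequence(id=f"synthetic_locus_{seed}", seq=seq)
        protos = find_protospacers(locus, require_pam)
        interior = [
            pr for pr in protos if 25 <= pr.cut_index <= length - 25
        ] or protos
        if interior:
            best = min(
                interior,
                key=lambda pr: (abs(pr.cut_index - length // 2), pr.spacer_start, pr.strand),
            )
            return locus, best
    raise RuntimeError(
        f"could not place a {require_pam.pattern} protospacer in 1000 attempts"
    )


def _mixture_counts(
    dist: OutcomeDistribution, cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[str, int]]:
    cats = dist.categories()
    fracs = np.array([f for _, f in cats])
    if cfg.exact_counts:
        raw = fracs * cfg.n_reads
        counts = np.floor(raw).astype(int)
        short = cfg.n_reads - counts.sum()
        for i in np.argsort(-(raw - counts))[:short]:
            counts[i] += 1
    else:
        counts = rng.multinomial(cfg.n_reads, fracs)
    return [(name, int(c)) for (name, _), c in zip(cats, counts)]


def _apply_errors(
    template: str, n: int, error_rate: float, rng: np.random.Generator
) -> list[str]:
    if n == 0:
        return []
    if error_rate <= 0:
        return [template] * n
    arr = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
    out = []
    for _ in range(n):
        mask = rng.random(arr.size) < error_rate
        if not mask.any():
            out.append(template)
            continue
        read = arr.copy()
        for i in np.nonzero(mask)[0]:
            choices = _BASES[_BASES != read[i]]
            read[i] = rng.choice(choices)
        out.append(read.tobytes().decode("ascii"))
    return out


def _templates(
    locus: LocusSequence,
    protospacer: Protospacer,
    hdr_allele: LocusSequence | None,
    dist: OutcomeDistribution,
) -> dict[str, str]:
    cut = protospacer.cut_index
    templates = {"WT": locus.seq}
    if dist.hdr_fraction > 0:
        if hdr_allele is None:
            raise ValueError("distribution includes HDR but no HDR allele given")
        templates["HDR"] = hdr_allele.seq
    for key in dist.indel_fractions:
        try:
            spec = parse_indel_key(key, cut)
            templates[key] = apply_indel(locus, spec).seq
        except ValueError as exc:
            raise ValueError(f"indel key {key!r} not constructible: {exc}") from exc
    return templates


def simulate_reads(
    locus: LocusSequence,
    protospacer: Protospacer,
    hdr_allele: LocusSequence | None,
    dist: OutcomeDistribution,
    cfg: SimConfig,
    read_prefix: str = "sim",
) -> list[SimRead]:
    """Draw full-amplicon reads from the outcome mixture and apply
    uniform per-base substitution errors.

    Quality strings are constant at the Phred score encoding the
    configured error rate.  Reads are shuffled so category blocks do not
    leak ordering information.
    """
    rng = np.random.default_rng(cfg.seed)
    templates = _templates(locus, protospacer, hdr_allele, dist)
    counts = _mixture_counts(dist, cfg, rng)
    seqs: list[str] = []
    for name, n in counts:
        if n == 0:
            continue
        seqs.extend(_apply_errors(templates[name], n, cfg.error_rate, rng))
    order = rng.permutation(len(seqs))
    reads = []
    for out_i, src_i in enumerate(order):
        seq = seqs[src_i]
        reads.append(
            SimRead(
                id=f"{read_prefix}_{out_i:06d}",
                seq=seq,
                quality=_phred_char(cfg.error_rate) * len(seq),
            )
        )
    return reads


def write_fastq(reads: Sequence[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.quality}\n")


def double_tap_distribution(
    nt_dist: OutcomeDistribution,
    conversion: float,
    targeted_keys: Sequence[str],
    hdr_share: float = 1.0,
    secondary_keys: Sequence[str] = (),
) -> OutcomeDistribution:
    """Reassign a fraction ``conversion`` (q) of each targeted indel's
    mass: a share ``hdr_share`` (h) goes to HDR, the rest is split evenly
    among ``secondary_keys`` (new low-frequency indels created by the
    secondary cut).  Untargeted indels keep their mass."""
    if not 0 <= conversion <= 1:
        raise ValueError("conversion must be in [0, 1]")
    if not 0 <= hdr_share <= 1:
        raise ValueError("hdr_share must be in [0, 1]")
    missing = [k for k in targeted_keys if k not in nt_dist.indel_fractions]
    if missing:
        raise ValueError(f"targeted keys not in distribution: {missing}")
    if hdr_share < 1 and not secondary_keys:
        raise ValueError("hdr_share < 1 requires secondary_keys")
    moved = sum(nt_dist.indel_fractions[k] * conversion for k in targeted_keys)
    indels = dict(nt_dist.indel_fractions)
    for k in targeted_keys:
        indels[k] = indels[k] * (1 - conversion)
    to_secondary = moved * (1 - hdr_share)
    for k in secondary_keys:
        indels[k] = indels.get(k, 0.0) + to_secondary / len(secondary_keys)
    indels = {k: v for k, v in indels.items() if v > 0}
    return OutcomeDistribution(
        wt_fraction=nt_dist.wt_fraction,
        hdr_fraction=nt_dist.hdr_fraction + moved * hdr_share,
        indel_fractions=indels,
    )


def simulate_double_tap_experiment(
    locus: LocusSequence,
    protospacer: Protospacer,
    hdr_allele: LocusSequence,
    nt_dist: OutcomeDistribution,
    conversion: float,
    targeted_keys: Sequence[str],
    cfg: SimConfig,
    hdr_share: float = 1.0,
    secondary_keys: Sequence[str] = (),
) -> tuple[list[SimRead], list[SimRead], OutcomeDistribution]:
    """Paired non-targeting and double-tap read sets.

    The double-tap distribution moves ``conversion`` of the targeted
    indel mass to HDR (share ``hdr_share``) and to secondary indel keys;
    the implied fold-change mean(DT HDR)/mean(NT HDR) is recoverable by
    quantification within sampling error.
    """
    dt_dist = double_tap_distribution(
        nt_dist, conversion, targeted_keys, hdr_share, secondary_keys
    )
    nt_reads = simulate_reads(
        locus, protospacer, hdr_allele, nt_dist,
        replace(cfg, seed=cfg.seed), read_prefix="nt",
    )
    dt_reads = simulate_reads(
        locus, protospacer, hdr_allele, dt_dist,
        replace(cfg, seed=cfg.seed + 1), read_prefix="dt",
    )
    return nt_reads, dt_reads, dt_dist
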