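"""Independent brute-force oracles used to cross-check the package.

Deliberately naive implementations, structured differently from the
library code they verify.
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def pam_matches(pattern: str, site: str) -> bool:
    return len(site) == len(pattern) and all(
        s in "ACGT" and s in IUPAC[p] for p, s in zip(pattern, site)
    )


def oracle_protospacers(seq: str, pam: str) -> set[tuple[str, str, str, int]]:
    """All (spacer, pam_site, strand, forward_spacer_start) windows of
    length 20+|pam| on both strands whose tail matches the PAM."""
    n, plen, out = len(seq), len(pam), set()
    w = 20 + plen
    for strand, s in (("+", seq), ("-", rc(seq))):
        for i in range(n - w + 1):
            window = s[i : i + w]
            spacer, pam_site = window[:20], window[20:]
            if "N" in spacer or not pam_matches(pam, pam_site):
                continue
            fwd_start = i if strand == "+" else n - i - w + plen
            out.add((spacer, pam_site, strand, fwd_start))
    return out


def oracle_mmej_products(
    ref: str, cut: int, min_mh: int = 2, max_del: int = 60
) -> set[str]:
    """Product sequences of every microhomology-collapse deletion, found
    by scanning deletion intervals rather than substring pairs."""
    products = set()
    n = len(ref)
    for s in range(0, cut):
        for d in range(1, max_del + 1):
            if s + d < cut or s + d > n:
                continue  # right copy must start at or after the cut
            for k in range(min_mh, n + 1):
                if s + k > cut or s + d + k > n:
                    break
                if ref[s : s + k] == ref[s + d : s + d + k]:
                    products.add(ref[:s] + ref[s + d :])
                    break
    return products


def oracle_offtargets(
    spacer: str, pam: str, sequences: list[tuple[str, str]], max_mm: int
) -> set[tuple[str, int, str, int]]:
    """(seq_id, forward_position, strand, mismatches) for every window
    where the PAM matches and the spacer has <= max_mm substitutions."""
    hits = set()
    w = len(spacer) + len(pam)
    for seq_id, seq in sequences:
        n = len(seq)
        for strand, s in (("+", seq), ("-", rc(seq))):
            for i in range(n - w + 1):
                site = s[i : i + w]
                if not pam_matches(pam, site[len(spacer):]):
                    continue
                mm = sum(
                    1
                    for a, b in zip(spacer, site[: len(spacer)])
                    if b not in "ACGT" or a != b
                )
                if mm <= max_mm:
                    fwd = i if strand == "+" else n - i - w
                    hits.add((seq_id, fwd, strand, mm))
    return hits


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(length))
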