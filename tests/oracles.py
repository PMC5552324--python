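"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: equivalence
of variant spellings is decided by applying each spelling to the context
sequence and comparing resulting haplotypes; consensus, interval and
pair-enumeration oracles are naive scans.
"""

from __future__ import annotations

from itertools import combinations


def apply_spelling(seq: str, pos: int, ref: str, alt: str) -> str:
    """Haplotype produced by substituting ref->alt at 1-based pos in seq."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def enumerate_equivalent_spellings(
    seq: str, pos: int, ref: str, alt: str, max_allele: int = 8
) -> set[tuple[int, str, str]]:
    """All trimmed (pos', ref', alt') spellings over ``seq`` producing the
    same haplotype as (pos, ref, alt). Exhaustive over positions and
    reference-allele lengths; the alternate allele is implied by requiring
    prefix/suffix identity with the haplotype."""
    target = apply_spelling(seq, pos, ref, alt)
    delta = len(target) - len(seq)
    out: set[tuple[int, str, str]] = set()
    for p in range(1, len(seq) + 1):
        if seq[: p - 1] != target[: p - 1]:
            break
        for ref_len in range(0, max_allele + 1):
            if p - 1 + ref_len > len(seq):
                continue
            alt_len = ref_len + delta
            if alt_len < 0 or p - 1 + alt_len > len(target):
                continue
            cand_ref = seq[p - 1 : p - 1 + ref_len]
            cand_alt = target[p - 1 : p - 1 + alt_len]
            if seq[p - 1 + ref_len :] != target[p - 1 + alt_len :]:
                continue
            # VCF-valid spelling: non-empty alleles, not identical
            if not cand_ref or not cand_alt or cand_ref == cand_alt:
                continue
            # trimmed: no shared trailing base; leading share only if min len 1
            if cand_ref[-1] == cand_alt[-1] and (len(cand_ref) > 1 or len(cand_alt) > 1):
                continue
            if cand_ref[0] == cand_alt[0] and len(cand_ref) > 1 and len(cand_alt) > 1:
                continue
            out.add((p, cand_ref, cand_alt))
    return out


def oracle_normalize(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Canonical spelling = the minimal-position trimmed equivalent
    spelling (ties broken by shortest ref allele)."""
    spellings = enumerate_equivalent_spellings(seq, pos, ref, alt)
    assert spellings, "no valid trimmed spelling found"
    return min(spellings, key=lambda s: (s[0], len(s[1])))


def brute_force_consensus(callsets: dict, k: int) -> set[tuple[str, tuple]]:
    """(sample, variant key) pairs supported by >= k callers with a
    carrier genotype."""
    support: dict[tuple[str, tuple], set[str]] = {}
    for caller, observations in callsets.items():
        for o in observations:
            if o.genotype.value in ("het", "hom_alt", "hemi"):
                support.setdefault((o.sample, o.variant.key), set()).add(caller)
    return {key for key, callers in support.items() if len(callers) >= k}


def brute_force_in_targets(positions, intervals) -> set:
    """Point-in-interval scan: (chrom, pos 1-based) vs half-open intervals."""
    kept = set()
    for chrom, pos in positions:
        for ichrom, s, e in intervals:
            if ichrom == chrom and s <= pos - 1 < e:
                kept.add((chrom, pos))
                break
    return kept


def brute_force_splice_distance(p0: int, exons) -> int | None:
    """Minimum distance from an intronic 0-based position to any exon
    boundary, scanning every boundary; None for exonic positions."""
    for s, e in exons:
        if s <= p0 < e:
            return None
    best = None
    for s, e in exons:
        for boundary_dist in (
            (s - p0) if p0 < s else None,
            (p0 - e + 1) if p0 >= e else None,
        ):
            if boundary_dist is not None and boundary_dist > 0:
                if best is None or boundary_dist < best:
                    best = boundary_dist
    return best


def brute_force_compound_pairs(carried_by_sample: dict, kinds: dict) -> dict:
    """Enumerate all unordered candidate pairs per sample with one
    'exonic_plp' and one 'intronic_tier1' member."""
    out = {}
    for sample, carried in carried_by_sample.items():
        pairs = []
        for a, b in combinations(sorted(carried), 2):
            if {kinds[a], kinds[b]} == {"exonic_plp", "intronic_tier1"}:
                pairs.append(frozenset((a, b)))
        out[sample] = set(pairs)
    return out
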