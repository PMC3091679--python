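"""Independent oracles and generators used across the test suite.

The scanning oracle here deliberately re-derives everything from first
principles — its own IUPAC base-set table, its own complement table, and a
position-by-position set-membership check — so it shares no code path with
the package's regex-based scanner.
"""

from __future__ import annotations

import numpy as np

# Independent IUPAC base-set table (not imported from the package).
ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(ORACLE_COMPLEMENT[b] for b in reversed(seq))


def oracle_scan_strand(seq: str, expanded: str, strand: str) -> list[int]:
    """1-based starts where the flat IUPAC pattern matches on one strand.

    A minus-strand match at forward start s means the reverse complement
    of the forward window [s, s+m-1] realizes the pattern, i.e. forward
    base at offset m-1-k must lie in the complemented base set of pattern
    letter k.  Membership is evaluated position by position.
    """
    n, m = len(seq), len(expanded)
    if m > n:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    ok = np.ones(n - m + 1, dtype=bool)
    for k, letter in enumerate(expanded):
        bases = ORACLE_IUPAC[letter]
        if strand == "+":
            offset, allowed = k, bases
        else:
            offset = m - 1 - k
            allowed = "".join(ORACLE_COMPLEMENT[b] for b in bases)
        window = arr[offset : offset + n - m + 1]
        ok &= np.isin(window, np.frombuffer(allowed.encode(), dtype=np.uint8))
    return [int(i) + 1 for i in np.flatnonzero(ok)]


def oracle_scan(seq: str, expanded: str, strands: str = "both") -> set[tuple[int, str]]:
    """Full oracle hit set {(start, strand)} for one sequence × one pattern."""
    hits = {(s, "+") for s in oracle_scan_strand(seq, expanded, "+")}
    if strands == "both":
        hits |= {(s, "-") for s in oracle_scan_strand(seq, expanded, "-")}
    return hits


def random_pattern(rng: np.random.Generator,
                   min_len: int = 4, max_len: int = 12) -> tuple[str, str]:
    """Random degenerate pattern as (raw-with-quantifiers, known expansion).

    Tokens are built as (letter, count) pairs so the expansion is known by
    construction, independent of the package's quantifier parser.  Letters
    are biased toward concrete bases so matches stay informative.
    """
    letters = list(ORACLE_IUPAC)
    weights = np.array([4.0 if c in "ACGT" else 1.0 for c in letters])
    weights /= weights.sum()
    target = int(rng.integers(min_len, max_len + 1))
    raw_parts: list[str] = []
    expanded_parts: list[str] = []
    total = 0
    while total < target:
        letter = str(rng.choice(letters, p=weights))
        if rng.random() < 0.2:
            count = int(rng.integers(2, min(5, target - total) + 1)) \
                if target - total >= 2 else 1
        else:
            count = 1
        if count == 1:
            raw_parts.append(letter)
        else:
            raw_parts.append(f"[{letter}]{count}")
        expanded_parts.append(letter * count)
        total += count
    return "".join(raw_parts), "".join(expanded_parts)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def naive_venn(calls: dict[tuple[str, str], str],
               comparisons: list[str]) -> dict[tuple[str, ...], set[str]]:
    """Exhaustive set-algebra Venn oracle over explicit signature enumeration."""
    from itertools import product

    genes = sorted({g for g, _ in calls})
    cells: dict[tuple[str, ...], set[str]] = {}
    for sig in product(["up", "down", "neither"], repeat=len(comparisons)):
        members = set()
        for g in genes:
            observed = tuple(
                calls[(g, c)] if calls[(g, c)] in ("up", "down") else "neither"
                for c in comparisons
            )
            if observed == sig:
                members.add(g)
        if members:
            cells[sig] = members
    return cells


def pooled_t_pvalue(a, b) -> float:
    """Textbook pooled-variance two-sample t-test, written out longhand."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_stat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return float(2 * t_dist.sf(abs(t_stat), df=na + nb - 2))
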