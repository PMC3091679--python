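"""Degenerate cis-element scanning over promoter sets.

PLACE-style consensus patterns are written in the IUPAC nucleotide alphabet
(W = A/T, M = A/C, Y = C/T, R = A/G, ... N = any base) extended with a
bracketed repeat quantifier ``[X]k`` meaning the code X repeated k times
(``CC[W]6GG`` expands to ``CCWWWWWWGG``).  Scanning reports every match
position on both strands of a promoter; minus-strand sites are reported at
the forward-coordinate (1-based) start of the reverse-complemented site.
Presence frequencies count promoters carrying at least one hit, as a
nearest-integer percentage of the promoter universe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

#: IUPAC degenerate nucleotide codes mapped to the set of bases they stand for.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Alphabet accepted in promoter sequences. N is allowed in the input but
#: matches no pattern letter (conservative handling of ambiguous calls).
SEQUENCE_ALPHABET = frozenset("ACGTN")

# token := plain IUPAC letter | "[X]k" | "[X]_k_"  (k >= 1)
_TOKEN_RE = re.compile(r"([A-Za-z])|\[([A-Za-z])\]_?(\d+)_?")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a sequence (IUPAC-aware; N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=4096)
def _compiled_regex(expanded: str) -> re.Pattern[str]:
    classes = "".join(f"[{IUPAC_CODES[c]}]" for c in expanded)
    return re.compile(f"(?={classes})")


class MotifPatternError(ValueError):
    """Raised for malformed degenerate patterns (bad letter or quantifier)."""


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate motif.

    Attributes
    ----------
    name : str
        Motif identifier (e.g. ``GARE``).
    raw_pattern : str
        Pattern as written, possibly with ``[X]k`` quantifiers.
    expanded : str
        Flat IUPAC string with all quantifiers expanded.
    """

    name: str
    raw_pattern: str
    expanded: str

    @property
    def length(self) -> int:
        return len(self.expanded)

    def base_sets(self) -> list[str]:
        """Per-position allowed bases, in pattern order."""
        return [IUPAC_CODES[c] for c in self.expanded]

    def regex(self) -> re.Pattern[str]:
        """Overlap-reporting regex for the forward orientation."""
        return _compiled_regex(self.expanded)


@dataclass(frozen=True, order=True)
class MotifHit:
    """One match of a motif inside a promoter.

    ``start`` is the 1-based forward-strand coordinate of the leftmost base
    of the matched site; minus-strand sites keep forward coordinates.
    """

    promoter_id: str
    start: int
    strand: str
    motif: str


@dataclass
class FrequencyTable:
    """Presence/absence frequency of motifs over a promoter universe."""

    counts: pd.DataFrame  # columns: motif, promoters_with_hit, total, percent
    total: int

    def percent(self, motif: str) -> int:
        row = self.counts.loc[self.counts["motif"] == motif]
        if row.empty:
            raise KeyError(motif)
        return int(row["percent"].iloc[0])


def compile_motif(name: str, raw_pattern: str) -> MotifPattern:
    """Compile a degenerate pattern, expanding ``[X]k`` quantifiers.

    Raises :class:`MotifPatternError` naming the offending position for
    unknown letters, malformed quantifiers, or a zero repeat count.
    """
    if not raw_pattern:
        raise MotifPatternError(f"motif {name!r}: empty pattern")
    expanded: list[str] = []
    pos = 0
    while pos < len(raw_pattern):
        m = _TOKEN_RE.match(raw_pattern, pos)
        if m is None:
            raise MotifPatternError(
                f"motif {name!r}: unparseable token at position {pos} "
                f"in {raw_pattern!r}"
            )
        if m.group(1) is not None:
            letter, count = m.group(1).upper(), 1
        else:
            letter, count = m.group(2).upper(), int(m.group(3))
            if count == 0:
                raise MotifPatternError(
                    f"motif {name!r}: zero repeat count at position {pos}"
                )
        if letter not in IUPAC_CODES:
            raise MotifPatternError(
                f"motif {name!r}: unknown IUPAC letter {letter!r} at position {pos}"
            )
        expanded.extend(letter * count)
        pos = m.end()
    return MotifPattern(name=name, raw_pattern=raw_pattern, expanded="".join(expanded))


def load_motif_table(path=None) -> list[MotifPattern]:
    """Read a tab-separated motif definition file (name, pattern[, description]).

    Without ``path`` the packaged PLACE-selection fixture is loaded: the ten
    hormone- and MADS-box-related elements scanned in the 1000-bp windows
    upstream of the peroxidase genes.
    """
    if path is None:
        ref = resources.files("prxarray.data") / "place_motifs.tsv"
        with resources.as_file(ref) as p:
            return load_motif_table(p)
    table = pd.read_csv(path, sep="\t", comment="#")
    if not {"name", "pattern"} <= set(table.columns):
        raise ValueError(f"{path}: motif table needs 'name' and 'pattern' columns")
    return [compile_motif(r["name"], r["pattern"]) for _, r in table.iterrows()]


def _validate_sequence(promoter_id: str, seq: str) -> None:
    for offset, base in enumerate(seq):
        if base not in SEQUENCE_ALPHABET:
            raise ValueError(
                f"promoter {promoter_id!r}: illegal character {base!r} "
                f"at offset {offset}"
            )


def scan(
    promoters: Mapping[str, str],
    motifs: Iterable[MotifPattern],
    strands: str = "both",
) -> list[MotifHit]:
    """Scan promoters for every motif occurrence.

    Overlapping and repeated matches are all reported.  With
    ``strands="both"`` the reverse strand is scanned by matching the
    reverse complement and mapping positions back to forward coordinates
    (a site covering forward bases [s, s+len-1] is reported at start s
    with strand ``-``).  Output is sorted by (promoter, start, strand).
    """
    if strands not in ("both", "forward"):
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    motifs = list(motifs)
    hits: list[MotifHit] = []
    for pid, seq in promoters.items():
        seq = seq.upper()
        _validate_sequence(pid, seq)
        length = len(seq)
        rc = reverse_complement(seq)
        for motif in motifs:
            if motif.length > length:
                continue
            rx = motif.regex()
            for m in rx.finditer(seq):
                hits.append(MotifHit(pid, m.start() + 1, "+", motif.name))
            if strands == "both":
                for m in rx.finditer(rc):
                    start = length - m.start() - motif.length + 1
                    hits.append(MotifHit(pid, start, "-", motif.name))
    hits.sort(key=lambda h: (h.promoter_id, h.start, h.strand, h.motif))
    return hits


def frequency(
    hits: Iterable[MotifHit],
    promoter_ids: Iterable[str],
    motifs: Iterable[MotifPattern],
) -> FrequencyTable:
    """Presence frequency per motif over the promoter universe.

    A promoter counts once per motif regardless of its number of hits;
    ``percent`` rounds to the nearest integer with ties away from zero
    (2 of 73 promoters → 2.74% → 3).
    """
    universe = list(dict.fromkeys(promoter_ids))
    if not universe:
        raise ValueError("promoter universe is empty")
    known = set(universe)
    present: dict[str, set[str]] = {m.name: set() for m in motifs}
    for h in hits:
        if h.promoter_id not in known:
            raise ValueError(
                f"hit references promoter {h.promoter_id!r} outside the universe"
            )
        present.setdefault(h.motif, set()).add(h.promoter_id)
    total = len(universe)
    rows = [
        {
            "motif": name,
            "promoters_with_hit": len(carriers),
            "total": total,
            # int(x + 0.5) == round-half-away-from-zero for non-negative x
            "percent": int(100 * len(carriers) / total + 0.5),
        }
        for name, carriers in sorted(present.items())
    ]
    return FrequencyTable(counts=pd.DataFrame(rows), total=total)


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    """Tabular view of a hit list (promoter_id, motif, start, strand)."""
    return pd.DataFrame(
        [
            {"promoter_id": h.promoter_id, "motif": h.motif,
             "start": h.start, "strand": h.strand}
            for h in hits
        ],
        columns=["promoter_id", "motif", "start", "strand"],
    )
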