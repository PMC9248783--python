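"""In-silico PCR with IUPAC-degenerate primers.

Implements the assay-design side of the pipeline: expanding degenerate
primers into their concrete variants, locating binding sites on both
strands of a template with an exact 3' anchor, and predicting PCR products
(amplicons) for primer pairs, including multiplex panels.

Conventions
-----------
* Coordinates are 0-based half-open internally; human-readable report
  writers convert to 1-based inclusive and say so in their headers.
* Product length includes both primer footprints (standard PCR convention).
* A template ``N`` matches nothing by default (conservative for assay
  specificity); set ``permissive_n=True`` to resolve primer-vs-template
  ambiguity by IUPAC set intersection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

from Bio.Seq import reverse_complement
from Bio.SeqUtils import gc_fraction

__all__ = [
    "IUPAC",
    "DegeneratePrimer",
    "BindingSite",
    "Amplicon",
    "expand_degenerate",
    "degeneracy",
    "enumerate_variants",
    "find_binding_sites",
    "predict_amplicon",
    "multiplex_predict",
]

#: IUPAC nucleotide codes -> the set of concrete bases each permits.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_MIN_PRIMER_LEN = 10


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named IUPAC DNA primer, written 5'->3'."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace(" ", "")
        object.__setattr__(self, "sequence", seq)
        for pos, base in enumerate(seq):
            if base not in IUPAC:
                raise ValueError(
                    f"primer {self.name!r}: invalid IUPAC symbol {base!r} at position {pos}"
                )
        if len(seq) < _MIN_PRIMER_LEN:
            raise ValueError(f"primer {self.name!r}: length {len(seq)} < {_MIN_PRIMER_LEN}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """A primer footprint on a template (+ strand coordinates)."""

    template_id: str
    start: int
    end: int  # half-open; end - start == primer length
    strand: str  # '+' forward primer, '-' reverse primer
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product spanning fwd-primer start to rev-primer end."""

    template_id: str
    start: int
    end: int
    sequence: str
    fwd_len: int
    rev_len: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def core(self) -> str:
        """Inter-primer subsequence (both primer footprints removed)."""
        return self.sequence[self.fwd_len:len(self.sequence) - self.rev_len]

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.sequence)


def degeneracy(primer: DegeneratePrimer) -> int:
    """Number of concrete sequences the degenerate primer encodes."""
    n = 1
    for base in primer.sequence:
        n *= len(IUPAC[base])
    return n


def enumerate_variants(primer: DegeneratePrimer) -> Iterator[str]:
    """Lazily enumerate all concrete variants, lexicographically."""
    choices = [sorted(IUPAC[base]) for base in primer.sequence]
    for combo in itertools.product(*choices):
        yield "".join(combo)


def expand_degenerate(primer: DegeneratePrimer, enumerate_all: bool = False):
    """Variant count, optionally with the full lexicographic enumeration.

    Returns the count, or ``(count, iterator)`` when ``enumerate_all``.
    """
    count = degeneracy(primer)
    if enumerate_all:
        return count, enumerate_variants(primer)
    return count


def _match(primer_seq: str, window: str, max_mismatch: int, anchor3_positions: range,
           permissive_n: bool) -> int | None:
    """Mismatch count of a primer against an equal-length template window.

    ``anchor3_positions`` are primer indices that must match exactly.
    Returns None when the window fails the anchor rule or exceeds
    ``max_mismatch``.
    """
    mismatches = 0
    for i, (p, t) in enumerate(zip(primer_seq, window)):
        allowed = IUPAC[p]
        if t in "ACGT":
            ok = t in allowed
        elif permissive_n and t in IUPAC:
            ok = bool(allowed & IUPAC[t])
        else:
            ok = False  # template N (or other ambiguity) matches nothing
        if not ok:
            if i in anchor3_positions:
                return None
            mismatches += 1
            if mismatches > max_mismatch:
                return None
    return mismatches


def find_binding_sites(template: str, primer: DegeneratePrimer,
                       max_mismatch: int = 0, anchor3: int = 3,
                       template_id: str = "", permissive_n: bool = False) -> list[BindingSite]:
    """Locate primer binding sites on both strands of a template.

    The + strand scan matches the primer directly; the - strand scan matches
    the primer's reverse complement (a reverse primer priming leftwards).
    The ``anchor3`` 3'-terminal bases of the primer must match exactly;
    mismatches elsewhere are tolerated up to ``max_mismatch``.  Hits are
    sorted by coordinate.  A template shorter than the primer yields an
    empty list.
    """
    template = template.upper()
    n, k = len(template), len(primer)
    if n < k:
        return []
    fwd = primer.sequence
    # On the + strand the primer's 3' end is its last base; on the - strand
    # the reverse-complemented primer's 3' end is the leftmost base.
    fwd_anchor = range(k - anchor3, k)
    rev = reverse_complement(fwd)
    rev_anchor = range(0, anchor3)
    hits: list[BindingSite] = []
    for start in range(n - k + 1):
        window = template[start:start + k]
        m = _match(fwd, window, max_mismatch, fwd_anchor, permissive_n)
        if m is not None:
            hits.append(BindingSite(template_id, start, start + k, "+", m))
        m = _match(rev, window, max_mismatch, rev_anchor, permissive_n)
        if m is not None:
            hits.append(BindingSite(template_id, start, start + k, "-", m))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def predict_amplicon(template: str, fwd: DegeneratePrimer, rev: DegeneratePrimer,
                     max_product: int = 2000, max_mismatch: int = 0, anchor3: int = 3,
                     template_id: str = "", permissive_n: bool = False) -> list[Amplicon]:
    """Predict PCR products for one primer pair on one template.

    Every + strand forward hit is paired with every downstream - strand
    reverse hit within ``max_product``; product length includes both primer
    footprints.  Amplicons are sorted by start, then length.
    """
    template = template.upper()
    fwd_hits = [h for h in find_binding_sites(template, fwd, max_mismatch, anchor3,
                                              template_id, permissive_n) if h.strand == "+"]
    rev_hits = [h for h in find_binding_sites(template, rev, max_mismatch, anchor3,
                                              template_id, permissive_n) if h.strand == "-"]
    products: list[Amplicon] = []
    for f in fwd_hits:
        for r in rev_hits:
            if r.start < f.end:  # reverse site must lie downstream of the forward footprint
                continue
            length = r.end - f.start
            if length > max_product:
                continue
            products.append(Amplicon(
                template_id=template_id, start=f.start, end=r.end,
                sequence=template[f.start:r.end], fwd_len=len(fwd), rev_len=len(rev),
            ))
    products.sort(key=lambda a: (a.start, a.length))
    return products


def multiplex_predict(templates: Mapping[str, str],
                      pairs: Sequence[tuple[DegeneratePrimer, DegeneratePrimer]],
                      **kwargs) -> dict[str, dict[str, list[int]]]:
    """Amplification matrix: template x primer pair -> product lengths.

    ``templates`` maps label -> sequence (labels must be unique, which a
    mapping enforces; passing a sequence of (label, seq) pairs with
    duplicates raises).  Cells hold the list of predicted product lengths,
    possibly empty; off-target amplification shows up as extra lengths
    rather than being hidden.
    """
    if not isinstance(templates, Mapping):
        items = list(templates)
        labels = [lab for lab, _ in items]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate template labels: {dupes}")
        templates = dict(items)
    matrix: dict[str, dict[str, list[int]]] = {}
    for label, seq in templates.items():
        row: dict[str, list[int]] = {}
        for f, r in pairs:
            key = f"{f.name}x{r.name}"
            row[key] = [a.length for a in
                        predict_amplicon(seq, f, r, template_id=label, **kwargs)]
        matrix[label] = row
    return matrix
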