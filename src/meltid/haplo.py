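"""COI subregion haplotypes: extraction, collapsing, distances, trees.

Workflow: extract the primer-amplified subregion from each full-length COI
sequence with the in-silico PCR engine (default primer pair EW_COI_F2 x
EW_COI_R1, 158 bp product), collapse the inter-primer cores to exact-match
haplotypes, compute pairwise p-distances, build a UPGMA tree, and score
concordance between melt-curve groups and sequence haplotypes.

No multiple sequence alignment is performed: primer anchoring plus
equal-length enforcement replaces alignment for this short subregion.
Cores whose length differs (indel-bearing) are reported as extraction
failures rather than aligned.

Haplotypes are defined on the inter-primer core by default, because in a
real amplicon the primer footprints are overwritten by the primers and
carry no specimen information; ``mode="full"`` keeps the whole amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .assign import ClusterResult
from .insilico import DegeneratePrimer, predict_amplicon
from . import primers as _primers

__all__ = [
    "ExtractionFailure",
    "HaplotypeTable",
    "DistanceTree",
    "extract_subregion",
    "collapse_haplotypes",
    "p_distance_matrix",
    "upgma_tree",
    "concordance",
]


@dataclass(frozen=True)
class ExtractionFailure:
    """Per-sequence record of a failed subregion extraction."""

    seq_id: str
    reason: str
    n_amplicons: int


@dataclass
class HaplotypeTable:
    """Exact-identity haplotypes: id -> (core sequence, members, count).

    Ids ``h1, h2, ...`` follow first occurrence in the input.  Member sets
    partition the input samples; counts sum to the number of inputs.
    """

    haplotypes: dict[str, str]            # haplotype_id -> core sequence
    members: dict[str, list[str]]         # haplotype_id -> sample ids
    sample_to_haplotype: dict[str, str]   # sample id -> haplotype_id

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def counts(self) -> dict[str, int]:
        return {h: len(m) for h, m in self.members.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype_id": list(self.haplotypes),
                "count": [len(self.members[h]) for h in self.haplotypes],
                "members": [";".join(self.members[h]) for h in self.haplotypes],
                "sequence": [self.haplotypes[h] for h in self.haplotypes],
            }
        )


@dataclass
class DistanceTree:
    """An ultrametric UPGMA tree with its Newick serialization."""

    leaves: list[str]
    newick: str
    method: str = "UPGMA"
    root: object = None  # scipy ClusterNode

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (all equal for an ultrametric tree)."""
        depths: dict[str, float] = {}

        def walk(node, acc: float) -> None:
            if node.is_leaf():
                depths[self.leaves[node.id]] = acc
                return
            for child in (node.left, node.right):
                walk(child, acc + (node.dist - child.dist) / 2.0)

        walk(self.root, 0.0)
        return depths


def extract_subregion(seqs: Mapping[str, str],
                      fwd: DegeneratePrimer | str | None = None,
                      rev: DegeneratePrimer | str | None = None,
                      mode: str = "core",
                      max_mismatch: int = 0) -> tuple[dict[str, str], list[ExtractionFailure]]:
    """Extract the primer-amplified subregion from each sequence.

    Returns ``(extracted, failures)``.  A sequence yielding zero or multiple
    amplicons produces a failure record and the run continues; if every
    sequence fails, an error is raised.  ``mode="core"`` (default) strips
    both primer footprints; ``mode="full"`` keeps the whole amplicon.
    """
    if mode not in ("core", "full"):
        raise ValueError(f"mode must be 'core' or 'full', got {mode!r}")
    fwd = _primers.get_primer(fwd) if isinstance(fwd, str) else (fwd or _primers.get_primer(_primers.DEFAULT_PAIR[0]))
    rev = _primers.get_primer(rev) if isinstance(rev, str) else (rev or _primers.get_primer(_primers.DEFAULT_PAIR[1]))
    extracted: dict[str, str] = {}
    failures: list[ExtractionFailure] = []
    for seq_id, seq in seqs.items():
        amps = predict_amplicon(seq, fwd, rev, max_mismatch=max_mismatch, template_id=seq_id)
        if len(amps) != 1:
            reason = "no amplicon" if not amps else f"{len(amps)} amplicons"
            failures.append(ExtractionFailure(seq_id, reason, len(amps)))
            continue
        amp = amps[0]
        extracted[seq_id] = amp.core if mode == "core" else amp.sequence
    if not extracted:
        raise ValueError(
            f"subregion extraction failed for all {len(failures)} sequences "
            f"({fwd.name} x {rev.name}, max_mismatch={max_mismatch})"
        )
    return extracted, failures


def collapse_haplotypes(seqs: Mapping[str, str]) -> HaplotypeTable:
    """Collapse equal-length sequences to exact-identity haplotypes.

    Case-insensitive; mixed lengths are an error listing the offenders
    (length differences indicate failed primer-anchored extraction, not an
    alignment problem).
    """
    if not seqs:
        raise ValueError("no sequences to collapse")
    lengths = {sid: len(s) for sid, s in seqs.items()}
    distinct = set(lengths.values())
    if len(distinct) > 1:
        common = max(distinct, key=lambda L: sum(v == L for v in lengths.values()))
        offenders = sorted(sid for sid, L in lengths.items() if L != common)
        raise ValueError(f"mixed sequence lengths {sorted(distinct)}; offenders: {offenders}")
    haplotypes: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    by_core: dict[str, str] = {}
    sample_to_h: dict[str, str] = {}
    for sid, seq in seqs.items():
        core = seq.upper()
        if core not in by_core:
            hid = f"h{len(by_core) + 1}"
            by_core[core] = hid
            haplotypes[hid] = core
            members[hid] = []
        hid = by_core[core]
        members[hid].append(sid)
        sample_to_h[sid] = hid
    return HaplotypeTable(haplotypes=haplotypes, members=members, sample_to_haplotype=sample_to_h)


def p_distance_matrix(seqs: Mapping[str, str] | HaplotypeTable) -> pd.DataFrame:
    """Pairwise p-distance: proportion of differing comparable positions.

    Positions where either sequence carries ``N`` are excluded from both
    numerator and denominator.  A pair with zero comparable positions is
    NaN, never 0.
    """
    if isinstance(seqs, HaplotypeTable):
        seqs = dict(seqs.haplotypes)
    ids = list(seqs)
    arr = {sid: np.frombuffer(seqs[sid].upper().encode(), dtype="S1") for sid in ids}
    lengths = {len(a) for a in arr.values()}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        a = arr[ids[i]]
        for j in range(i + 1, n):
            b = arr[ids[j]]
            comparable = (a != b"N") & (b != b"N")
            denom = int(comparable.sum())
            if denom == 0:
                mat[i, j] = mat[j, i] = np.nan
            else:
                diff = int(((a != b) & comparable).sum())
                mat[i, j] = mat[j, i] = diff / denom
    return pd.DataFrame(mat, index=ids, columns=ids)


def upgma_tree(dist: pd.DataFrame) -> DistanceTree:
    """UPGMA (average-linkage on cluster sizes) tree from a distance matrix.

    The input must be symmetric with a zero diagonal.  Leaves are processed
    in sorted-label order so ties resolve deterministically toward the
    smallest labels.  Node heights are half the linkage merge distances, so
    the tree is ultrametric; Newick branch lengths carry those heights.
    """
    mat = dist.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, equal_nan=True):
        raise ValueError("distance matrix is not symmetric")
    if np.isnan(mat).any():
        raise ValueError("distance matrix contains missing (NaN) entries")
    if np.any(np.diag(mat) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    order = sorted(range(len(dist.index)), key=lambda i: str(dist.index[i]))
    labels = [str(dist.index[i]) for i in order]
    mat = mat[np.ix_(order, order)]
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    z = linkage(squareform(mat, checks=False), method="average")
    root = to_tree(z)

    def min_leaf(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return min(min_leaf(node.left), min_leaf(node.right))

    def newick(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        children = sorted((node.left, node.right), key=min_leaf)
        parts = []
        for child in children:
            # branch length = parent height - child height, heights = dist/2
            bl = (node.dist - child.dist) / 2.0
            parts.append(f"{newick(child)}:{bl:.10g}")
        return f"({','.join(parts)})"

    return DistanceTree(leaves=labels, newick=newick(root) + ";", root=root)


def concordance(groups: ClusterResult, haps: HaplotypeTable) -> dict:
    """Cross-tabulate melt-curve groups against sequence haplotypes.

    Returns a dict with the group x haplotype contingency table, the
    haplotype -> group mapping, whether the partitions are *consistent*
    (every haplotype maps to exactly one group), and the list of haplotypes
    split across groups.
    """
    shared = set(groups.groups) & set(haps.sample_to_haplotype)
    if not shared:
        raise ValueError("cluster result and haplotype table share no sample ids")
    rows = []
    for sid in shared:
        rows.append({"sample_id": sid, "group": groups.groups[sid],
                     "haplotype": haps.sample_to_haplotype[sid]})
    df = pd.DataFrame(rows)
    table = pd.crosstab(df["group"], df["haplotype"])
    hap_to_groups = df.groupby("haplotype")["group"].agg(lambda s: sorted(set(s)))
    violations = sorted(h for h, gs in hap_to_groups.items() if len(gs) > 1)
    mapping = {h: gs[0] for h, gs in hap_to_groups.items() if len(gs) == 1}
    return {
        "table": table,
        "haplotype_to_group": mapping,
        "consistent": not violations,
        "split_haplotypes": violations,
        "n_groups": int(df["group"].nunique()),
        "n_haplotypes": int(df["haplotype"].nunique()),
    }
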