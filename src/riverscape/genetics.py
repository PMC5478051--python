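"""Sequence-level computations.

Alignments of mitochondrial fragments, haplotype collapsing, pairwise
p-distances with pairwise deletion of ambiguous sites, a deterministic
Saitou–Nei neighbor-joining builder, patristic (tip-to-tip path length)
distances from Newick trees, and nucleotide diversity.

The genetic distance used throughout the pipeline is the patristic
distance: the sum of the branch lengths separating two samples in a
phylogenetic tree, which integrates all the divergence accumulated
between the corresponding sequences. The tree itself may come from any
external inference tool (the pipeline accepts Newick input); the
neighbor-joining builder provided here is a fast distance-based
stand-in so the pipeline is self-contained.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DistanceMatrix
from .errors import ArgumentError, ComputationError, FormatError

_VALID_CHARS = set("ACGTN-")

# byte codes for A, C, G, T in the uint8 encoding used below
_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Alignment:
    """Equal-length uppercase nucleotide sequences keyed by sample id.

    Allowed characters are A, C, G, T, N and the gap character ``-``;
    N and ``-`` are treated as missing data by the distance and
    diversity computations.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.seqs = [s.upper() for s in self.seqs]
        if len(self.ids) != len(self.seqs):
            raise ArgumentError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - _VALID_CHARS
            if bad:
                raise FormatError(f"invalid characters {sorted(bad)} in sequence {sid!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def subset(self, ids) -> "Alignment":
        pos = {sid: k for k, sid in enumerate(self.ids)}
        try:
            keep = [pos[i] for i in ids]
        except KeyError as e:
            raise ArgumentError(f"unknown sequence id {e.args[0]!r}") from e
        return Alignment([self.ids[k] for k in keep], [self.seqs[k] for k in keep])

    def codes(self) -> np.ndarray:
        """(n, L) uint8 view of the sequences as ASCII codes."""
        return np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype=np.uint8
        ).reshape(self.n, self.length)


@dataclass
class HaplotypeAssignment:
    """Map from sample id to haplotype index (0-based, order of first
    appearance); two samples share an index iff their sequences are
    strictly identical strings."""

    assignment: dict[str, int]
    n_haplotypes: int


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment; records must be unique ids of equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def concat_alignments(a: Alignment, b: Alignment) -> Alignment:
    """Concatenate two fragment alignments over the same samples.

    Sample order is taken from ``a``; the output length is the sum of
    the two fragment lengths (e.g. a 724 bp cytochrome-b fragment plus
    a 342 bp D-loop fragment gives 1,066 bp).
    """
    if set(a.ids) != set(b.ids):
        missing = set(a.ids) ^ set(b.ids)
        raise ArgumentError(f"alignments cover different samples: {sorted(missing)[:5]}")
    b_seq = dict(zip(b.ids, b.seqs))
    return Alignment(list(a.ids), [sa + b_seq[i] for i, sa in zip(a.ids, a.seqs)])


def find_haplotypes(aln: Alignment) -> HaplotypeAssignment:
    """Collapse strictly identical sequences into haplotype classes."""
    if aln.n == 0:
        raise ArgumentError("empty alignment")
    index: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        if seq not in index:
            index[seq] = len(index)
        assignment[sid] = index[seq]
    return HaplotypeAssignment(assignment, len(index))


def _diff_and_valid(codes: np.ndarray):
    """Per-pair counts of differing and comparable sites.

    A site is comparable for a pair when both characters are one of
    A/C/G/T (pairwise deletion of N and gaps).
    """
    valid = np.isin(codes, _ACGT_CODES)
    n = codes.shape[0]
    diffs = np.zeros((n, n), dtype=np.int64)
    comps = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diffs_i = ((codes[i] != codes[i + 1 :]) & both).sum(axis=1)
        comps_i = both.sum(axis=1)
        diffs[i, i + 1 :] = diffs_i
        comps[i, i + 1 :] = comps_i
    diffs += diffs.T
    comps += comps.T
    return diffs, comps


def pairwise_p_distances(aln: Alignment) -> DistanceMatrix:
    """Per-site proportion of differences with pairwise deletion.

    d_ij = (# sites where both sequences have an unambiguous base and
    the bases differ) / (# sites where both have an unambiguous base).
    """
    if aln.n < 2:
        raise ArgumentError("need at least two sequences")
    diffs, comps = _diff_and_valid(aln.codes())
    np.fill_diagonal(comps, 1)  # diagonal is 0/1 = 0
    zero = np.argwhere(comps == 0)
    if len(zero):
        i, j = zero[0]
        raise ComputationError(
            f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    return DistanceMatrix(list(aln.ids), diffs / comps)


def nucleotide_diversity(
    aln: Alignment, deletion: Literal["pairwise", "complete"] = "pairwise"
) -> float:
    """Nucleotide diversity π: the mean per-site pairwise difference.

    With ``deletion="pairwise"`` each pair is compared over its own set
    of unambiguous sites; with ``"complete"`` the columns containing
    any N or gap are removed once for all pairs. Both conventions
    appear in the literature; pairwise deletion is the default because
    it retains more information from N-rich noninvasive-sample data.
    """
    if aln.n < 2:
        raise ArgumentError("nucleotide diversity requires at least two sequences")
    if deletion == "complete":
        codes = aln.codes()
        keep = np.all(np.isin(codes, _ACGT_CODES), axis=0)
        if not keep.any():
            raise ComputationError("no fully unambiguous columns for complete deletion")
        codes = codes[:, keep]
        sub = Alignment(
            list(aln.ids),
            ["".join(chr(c) for c in row) for row in codes],
        )
        return nucleotide_diversity(sub, deletion="pairwise")
    d = pairwise_p_distances(aln)
    iu = np.triu_indices(aln.n, k=1)
    return float(d.values[iu].mean())


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted Newick string.

    Deterministic: ties in the Q criterion are broken by the smallest
    (i, j) index pair in the current matrix order, and negative branch
    lengths are clamped to zero. Consistent on additive matrices: the
    patristic distances of the output reproduce the input exactly.
    """
    if not d.is_complete():
        raise ArgumentError("neighbor joining requires a complete distance matrix")
    n = d.n
    if n < 3:
        raise ArgumentError("neighbor joining requires at least three taxa")

    labels = list(d.ids)
    D = d.values.astype(float).copy()
    nodes = [_quote_newick(l) for l in labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; scan order gives the (i, j) tie-break
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        merged = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [merged]

    # terminal three-point formulas
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.5 * (d01 + d02 - d12), 0.0)
    l1 = max(0.5 * (d01 + d12 - d02), 0.0)
    l2 = max(0.5 * (d02 + d12 - d01), 0.0)
    return f"({nodes[0]}:{l0:.10g},{nodes[1]}:{l1:.10g},{nodes[2]}:{l2:.10g});"


def _quote_newick(label: str) -> str:
    if any(c in label for c in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# patristic distances
# ---------------------------------------------------------------------------

def parse_tree(newick: str) -> dendropy.Tree:
    """Parse Newick text (not a path) preserving underscores in labels."""
    try:
        return dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as e:  # dendropy raises various parser errors
        raise FormatError(f"could not parse Newick tree: {e}") from e


def patristic_distances(newick: str) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distances from a Newick tree.

    Every edge below the root must carry a branch length; tip labels
    must be unique. The id order of the result follows the order of
    first appearance of the tips in the Newick text.
    """
    tree = parse_tree(newick)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(tips) != len(set(tips)):
        raise FormatError("duplicate tip labels in tree")
    if len(tips) < 2:
        raise FormatError("tree must have at least two labelled tips")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError("tree edge without a branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(tips)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.patristic_distance(taxa[tips[i]], taxa[tips[j]])
    return DistanceMatrix(tips, vals)
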