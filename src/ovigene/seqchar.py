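"""Cloned-cDNA characterization: ORF, protein properties, identity, NJ tree.

Covers the bioinformatic workup of a cloned coding sequence: longest open
reading frame (ATG..stop, forward frames), translation with the standard
genetic code, protein molecular weight (average residue masses) and
isoelectric point, pairwise percent-identity matrices from global
alignments, and a Saitou–Nei neighbor-joining tree with Newick export.

The isoelectric point uses a fixed Henderson–Hasselbalch pKa table
(:data:`DEFAULT_PKA`, EMBOSS-style values) and bisection on pH 0–14; the
table is a module-level constant precisely because published pKa sets differ
and the choice must be explicit and reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

__all__ = [
    "OrfResult",
    "ProteinProperties",
    "DistanceMatrix",
    "Node",
    "DEFAULT_PKA",
    "find_longest_orf",
    "translate",
    "protein_mw",
    "isoelectric_point",
    "protein_properties",
    "identity_matrix",
    "nj_tree",
    "to_newick",
    "parse_newick",
    "leaf_distance_matrix",
    "read_fasta",
    "characterize_fasta",
]

logger = logging.getLogger(__name__)

DNA_CHARS = set("ACGTRYSWKMBDHVN")
AA_CHARS = set("ACDEFGHIKLMNPQRSTVWY")
STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Henderson–Hasselbalch pKa values used for pI (termini + ionizable side chains)
DEFAULT_PKA: Mapping[str, float] = {
    "n_term": 7.50,
    "c_term": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.00,
    "Y": 10.00,
    "H": 5.98,
    "K": 10.00,
    "R": 12.00,
}

WATER_DA = 18.0153


# ---------------------------------------------------------------------------
# ORF detection and translation


@dataclass(frozen=True)
class OrfResult:
    """Longest ATG..stop open reading frame on the scanned strand.

    Coordinates are 0-based half-open on the scanned sequence; ``nt_length``
    includes the stop codon, so the peptide has ``nt_length / 3 - 1``
    residues.
    """

    start: int
    end: int
    frame: int
    peptide: str
    strand: str = "+"

    @property
    def nt_length(self) -> int:
        return self.end - self.start


def find_longest_orf(cdna: str, include_revcomp: bool = False) -> OrfResult | None:
    """Longest complete ORF over the three forward frames.

    Ties are broken toward the 5'-most start.  Returns ``None`` when no
    ATG..stop frame exists (an explicit no-ORF outcome, not an error).  With
    ``include_revcomp`` the reverse complement is also scanned and the better
    of the two strands returned (tie goes to the forward strand).
    """
    seq = _clean_dna(cdna)
    if len(seq) < 6:
        raise ValueError("sequence shorter than one codon pair")
    best = _scan_forward(seq, "+")
    if include_revcomp:
        rc_best = _scan_forward(str(Seq(seq).reverse_complement()), "-")
        if rc_best is not None and (
                best is None or rc_best.nt_length > best.nt_length):
            best = rc_best
    return best


def _scan_forward(seq: str, strand: str) -> OrfResult | None:
    best: tuple[int, int, int] | None = None  # (length, start, frame)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - start
                candidate = (length, -start, frame)
                if best is None or candidate[:2] > (best[0], -best[1]):
                    best = (length, start, frame)
                start = None
    if best is None:
        return None
    length, start, frame = best
    orf_nt = seq[start:start + length]
    return OrfResult(start=start, end=start + length, frame=frame,
                     peptide=translate(orf_nt), strand=strand)


def _clean_dna(seq: str) -> str:
    text = str(seq).strip().upper().replace("U", "T")
    bad = set(text) - DNA_CHARS
    if bad:
        raise ValueError(f"non-IUPAC DNA symbol(s) {sorted(bad)}")
    return text


def translate(orf_nt: str) -> str:
    """Translate with the standard code; a trailing stop is removed.

    An internal stop codon raises, since the input is expected to be a clean
    open reading frame.
    """
    seq = _clean_dna(orf_nt)
    if len(seq) % 3:
        raise ValueError(f"length {len(seq)} is not a multiple of 3")
    peptide = str(Seq(seq).translate())
    if peptide.endswith("*"):
        peptide = peptide[:-1]
    if "*" in peptide:
        raise ValueError(f"internal stop codon at residue {peptide.index('*') + 1}")
    return peptide


# ---------------------------------------------------------------------------
# Protein properties


@dataclass(frozen=True)
class ProteinProperties:
    length: int
    mw_kda: float
    pi: float


def protein_mw(peptide: str) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    pep = str(peptide).strip().upper()
    if not pep:
        raise ValueError("empty peptide")
    bad = set(pep) - AA_CHARS
    if bad:
        raise ValueError(f"unknown residue symbol(s) {sorted(bad)}")
    return molecular_weight(pep, seq_type="protein", monoisotopic=False) / 1000.0


def _net_charge(pep: str, ph: float, pka: Mapping[str, float]) -> float:
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    for residue in pep:
        value = pka.get(residue)
        if value is None:
            continue
        if residue in ("H", "K", "R"):
            charge += 1.0 / (1.0 + 10.0 ** (ph - value))
        else:  # D, E, C, Y
            charge -= 1.0 / (1.0 + 10.0 ** (value - ph))
    return charge


def isoelectric_point(peptide: str,
                      pka: Mapping[str, float] = DEFAULT_PKA,
                      tol: float = 1e-4) -> float:
    """pH at which the Henderson–Hasselbalch net charge crosses zero.

    The net charge is strictly decreasing in pH and positive at 0, negative
    at 14 (the termini alone guarantee it), so bisection always converges.
    """
    pep = str(peptide).strip().upper()
    if not pep:
        raise ValueError("empty peptide")
    bad = set(pep) - AA_CHARS
    if bad:
        raise ValueError(f"unknown residue symbol(s) {sorted(bad)}")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        charge = _net_charge(pep, mid, pka)
        if abs(charge) < tol:
            return mid
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def protein_properties(peptide: str) -> ProteinProperties:
    return ProteinProperties(length=len(peptide), mw_kda=protein_mw(peptide),
                             pi=isoelectric_point(peptide))


# ---------------------------------------------------------------------------
# Pairwise identity


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix over named taxa; ``values`` holds distances."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} taxa")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.names),
                            columns=list(self.names))


def _alphabet_of(seq: str) -> str:
    chars = set(seq.upper())
    if chars <= DNA_CHARS:
        return "dna"
    if chars <= AA_CHARS:
        return "protein"
    raise ValueError(f"unrecognized alphabet: {sorted(chars - AA_CHARS)[:5]}")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def identity_matrix(seqs: Mapping[str, str] | Sequence[tuple[str, str]],
                    ) -> tuple[pd.DataFrame, DistanceMatrix]:
    """Pairwise percent identity and the matching 1 - identity distances.

    Identity is matched columns over alignment length in a global alignment
    (match +1, mismatch -1, gap -2).  All sequences must share one alphabet
    (DNA or protein).
    """
    records = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    names = [name for name, _ in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence names")
    alphabets = {_alphabet_of(s) for _, s in records}
    if len(alphabets) > 1:
        raise ValueError(f"mixed alphabets {sorted(alphabets)}")

    aligner = _make_aligner()
    n = len(records)
    ident = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        a, b = records[i][1].upper(), records[j][1].upper()
        alignment = aligner.align(a, b)[0]
        counts = alignment.counts()
        ident[i, j] = ident[j, i] = 100.0 * counts.identities / alignment.length
    distance = 1.0 - ident / 100.0
    np.fill_diagonal(distance, 0.0)
    identity_frame = pd.DataFrame(ident, index=names, columns=names)
    return identity_frame, DistanceMatrix(names=tuple(names), values=distance)


# ---------------------------------------------------------------------------
# Neighbor joining and Newick


@dataclass
class Node:
    """Tree node; ``branch_length`` is the edge to the parent (None at root)."""

    name: str | None = None
    branch_length: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]


def nj_tree(dm: DistanceMatrix) -> tuple[Node, str]:
    """Saitou–Nei neighbor joining; returns the tree and its Newick string.

    The root is the final unresolved trifurcation (bifurcation for 3 taxa is
    the same thing), so the tree is effectively unrooted.  Negative branch
    lengths — possible on non-additive input — are clamped to zero and the
    clamped deficit logged.
    """
    d = np.array(dm.values, dtype=float)
    nodes: list[Node] = [Node(name=name) for name in dm.names]
    if len(nodes) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    active = list(range(len(nodes)))

    def clamp(value: float, context: str) -> float:
        if value < 0.0:
            logger.warning("clamped negative branch length %.3g (%s)",
                           value, context)
            return 0.0
        return value

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]

        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        li = clamp(li, f"join of {nodes[i].name or i}")
        lj = clamp(lj, f"join of {nodes[j].name or j}")

        parent = Node(children=[nodes[i], nodes[j]])
        nodes[i].branch_length = li
        nodes[j].branch_length = lj

        new_index = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k_loc, k in enumerate(active):
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - dij)
            d[new_index, k] = d[k, new_index] = dk
        active = [k for k in active if k not in (i, j)] + [new_index]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    nodes[a].branch_length = clamp(la, "final join")
    nodes[b].branch_length = clamp(lb, "final join")
    nodes[c].branch_length = clamp(lc, "final join")
    return root, to_newick(root)


def to_newick(root: Node) -> str:
    """Newick serialization with full-precision branch lengths."""

    def render(node: Node) -> str:
        if node.is_leaf:
            label = node.name or ""
        else:
            label = "(" + ",".join(render(c) for c in node.children) + ")"
            label += node.name or ""
        if node.branch_length is not None:
            label += f":{float(node.branch_length)!r}"
        return label

    return render(root) + ";"


def parse_newick(text: str) -> Node:
    """Minimal Newick parser (unquoted labels, decimal branch lengths)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    stream = text[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(stream) and stream[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while pos < len(stream) and stream[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if pos >= len(stream) or stream[pos] != ")":
                raise ValueError(f"expected ')' at position {pos}")
            pos += 1
        start = pos
        while pos < len(stream) and stream[pos] not in "(),:;":
            pos += 1
        if pos > start:
            node.name = stream[start:pos]
        if pos < len(stream) and stream[pos] == ":":
            pos += 1
            start = pos
            while pos < len(stream) and stream[pos] not in "(),:;":
                pos += 1
            node.branch_length = float(stream[start:pos])
        return node

    root = parse_node()
    if pos != len(stream):
        raise ValueError(f"trailing characters at position {pos}")
    return root


def leaf_distance_matrix(root: Node) -> DistanceMatrix:
    """Path-length (patristic) distances between all leaf pairs."""
    names = [leaf.name or "" for leaf in root.leaves()]
    index = {name: i for i, name in enumerate(names)}
    n = len(names)
    d = np.zeros((n, n))

    def descend(node: Node) -> dict[str, float]:
        if node.is_leaf:
            return {node.name or "": 0.0}
        maps = []
        for child in node.children:
            sub = descend(child)
            bl = child.branch_length or 0.0
            maps.append({name: dist + bl for name, dist in sub.items()})
        for m1, m2 in itertools.combinations(maps, 2):
            for name1, d1 in m1.items():
                for name2, d2 in m2.items():
                    i, j = index[name1], index[name2]
                    d[i, j] = d[j, i] = d1 + d2
        merged: dict[str, float] = {}
        for m in maps:
            merged.update(m)
        return merged

    descend(root)
    return DistanceMatrix(names=tuple(names), values=d)


# ---------------------------------------------------------------------------
# FASTA IO and the characterization table


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Read a FASTA file into (name, sequence) pairs."""
    records = [(record.id, str(record.seq))
               for record in SeqIO.parse(path, "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def characterize_fasta(records: Iterable[tuple[str, str]],
                       include_revcomp: bool = False) -> pd.DataFrame:
    """Per-sequence ORF and protein-property table for nucleotide input."""
    rows = []
    for name, seq in records:
        orf = find_longest_orf(seq, include_revcomp=include_revcomp)
        if orf is None:
            rows.append({"name": name, "orf_start": pd.NA, "orf_end": pd.NA,
                         "orf_len": 0, "aa_len": 0,
                         "mw_kda": np.nan, "pi": np.nan})
            continue
        props = protein_properties(orf.peptide)
        rows.append({"name": name, "orf_start": orf.start, "orf_end": orf.end,
                     "orf_len": orf.nt_length, "aa_len": props.length,
                     "mw_kda": round(props.mw_kda, 2), "pi": round(props.pi, 2)})
    return pd.DataFrame(rows)
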