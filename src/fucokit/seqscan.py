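"""GH107-oriented protein sequence utilities.

Degenerate motif scanning (with catalytic-residue marking), global pairwise
alignment with percent identity, pairwise identity/distance matrices, and a
neighbor-joining tree builder with a Newick writer.

The family's catalytic (beta/alpha)8-barrel D1 domain carries two conserved
motifs: motif I, canonically ``RxxxxxDxxxxD`` (``VxxxxxDxxxxD`` in some
members, hence the shipped pattern ``[RV]xxxxxDxxxxD``), whose aspartate is
the predicted catalytic nucleophile, and motif II ``DxxxGH`` whose histidine
is the predicted acid/base.  Coordinates are 1-based throughout, matching
residue numbering conventions such as Asp182/His260.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinSequence",
    "MotifPattern",
    "MotifHit",
    "DistanceMatrix",
    "PhyloNode",
    "PhyloTree",
    "read_fasta",
    "write_fasta",
    "compile_motif",
    "scan_motif",
    "global_align",
    "Alignment",
    "pairwise_identity_matrix",
    "nj_tree",
    "MOTIF_I",
    "MOTIF_II",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        canon = self.residues.upper()
        bad = set(canon) - _AA
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters {sorted(bad)}"
            )
        object.__setattr__(self, "residues", canon)

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences; uppercases residues, rejects duplicate ids."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seqs = [ProteinSequence(rec.id, str(rec.seq)) for rec in records]
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids: {dupes}")
    return seqs


def write_fasta(seqs: list[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Degenerate motif scanning

_TOKEN_RE = re.compile(r"\[([A-Z]+)\]|([A-Zx])")


@dataclass(frozen=True)
class MotifPattern:
    """Tokenized degenerate motif: exact residue, wildcard, or residue class."""

    name: str
    text: str
    tokens: tuple[frozenset | None, ...]  # None = wildcard 'x'

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class MotifHit:
    pattern: str
    start: int  # 1-based
    span: str
    marked: dict[str, int] = field(default_factory=dict)  # role -> 1-based position

    @property
    def end(self) -> int:
        return self.start + len(self.span) - 1


def compile_motif(name: str, text: str) -> MotifPattern:
    """Compile a motif string: exact letters, ``x`` wildcard, ``[..]`` class."""
    tokens: list[frozenset | None] = []
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed motif {text!r} at offset {pos}")
        pos = m.end()
        if m.group(1) is not None:
            tokens.append(frozenset(m.group(1)))
        elif m.group(2) == "x":
            tokens.append(None)
        else:
            tokens.append(frozenset(m.group(2)))
    if pos != len(text) or not tokens:
        raise ValueError(f"malformed motif {text!r}")
    return MotifPattern(name=name, text=text, tokens=tuple(tokens))


def scan_motif(
    seq: ProteinSequence,
    pattern: MotifPattern,
    mark_residues: frozenset[str] = frozenset("DH"),
) -> list[MotifHit]:
    """All occurrences of a motif (every start position tested; overlaps allowed).

    Exact single-residue tokens whose letter is in ``mark_residues`` are
    reported in ``MotifHit.marked`` under roles like ``catalytic-D`` (numbered
    ``catalytic-D1``, ``catalytic-D2``, ... when the motif holds several).
    """
    s = seq.residues
    k = len(pattern)
    # Offsets within the motif of exact tokens to mark, with their roles.
    mark_offsets: list[tuple[str, int]] = []
    counts: dict[str, int] = {}
    for off, tok in enumerate(pattern.tokens):
        if tok is not None and len(tok) == 1:
            (letter,) = tok
            if letter in mark_residues:
                counts[letter] = counts.get(letter, 0) + 1
                mark_offsets.append((letter, off))
    totals = dict(counts)
    hits: list[MotifHit] = []
    for start in range(len(s) - k + 1):
        window = s[start : start + k]
        if all(tok is None or window[i] in tok for i, tok in enumerate(pattern.tokens)):
            marked: dict[str, int] = {}
            seen: dict[str, int] = {}
            for letter, off in mark_offsets:
                seen[letter] = seen.get(letter, 0) + 1
                role = f"catalytic-{letter}"
                if totals[letter] > 1:
                    role += str(seen[letter])
                marked[role] = start + off + 1
            hits.append(
                MotifHit(pattern=pattern.name, start=start + 1, span=window, marked=marked)
            )
    return hits


MOTIF_I = compile_motif("motif-I", "[RV]xxxxxDxxxxD")
MOTIF_II = compile_motif("motif-II", "DxxxGH")


# ---------------------------------------------------------------------------
# Global alignment (Needleman-Wunsch, linear gap penalty)


@dataclass(frozen=True)
class Alignment:
    aligned1: str
    aligned2: str
    score: float
    identity: float  # percent of identical columns over the alignment length


def global_align(
    s1: str | ProteinSequence,
    s2: str | ProteinSequence,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> Alignment:
    """Optimal global alignment under linear gap scoring.

    Deterministic traceback ties: prefer diagonal, then up (gap in the second
    sequence), then left.  Identity = identical columns / alignment length.
    """
    a = s1.residues if isinstance(s1, ProteinSequence) else str(s1)
    b = s2.residues if isinstance(s2, ProteinSequence) else str(s2)
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    m, n = len(a), len(b)
    F = np.empty((m + 1, n + 1))
    F[0, :] = gap * np.arange(n + 1)
    F[:, 0] = gap * np.arange(m + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            diag = F[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = F[i - 1, j] + gap
            left = F[i, j - 1] + gap
            F[i, j] = max(diag, up, left)
    # Traceback with the stated preference order.
    out1: list[str] = []
    out2: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out1.append(a[i - 1])
            out2.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and F[i, j] == F[i - 1, j] + gap:
            out1.append(a[i - 1])
            out2.append("-")
            i -= 1
        else:
            out1.append("-")
            out2.append(b[j - 1])
            j -= 1
    al1 = "".join(reversed(out1))
    al2 = "".join(reversed(out2))
    ident = sum(1 for x, y in zip(al1, al2) if x == y and x != "-")
    return Alignment(
        aligned1=al1,
        aligned2=al2,
        score=float(F[m, n]),
        identity=100.0 * ident / len(al1),
    )


# ---------------------------------------------------------------------------
# Distance matrices and neighbor joining


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate taxon labels")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(vals < -1e-12):
            raise ValueError("distances must be nonnegative")

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])


def pairwise_identity_matrix(
    seqs: list[ProteinSequence],
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> DistanceMatrix:
    """Distance matrix with distance = 100 - percent identity."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j], match=match, mismatch=mismatch, gap=gap)
            d[i, j] = d[j, i] = 100.0 - aln.identity
    return DistanceMatrix(tuple(ids), d)


@dataclass
class PhyloNode:
    name: str | None = None
    children: list[tuple["PhyloNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal junction as root."""

    root: PhyloNode

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: PhyloNode) -> None:
            if node.is_leaf():
                out.append(node.name)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return sorted(out)

    def leaf_distances(self) -> DistanceMatrix:
        """Path lengths (sum of branch lengths) between every leaf pair."""
        paths: dict[str, list[tuple[int, float]]] = {}

        def walk(node: PhyloNode, trail: list[tuple[int, float]]) -> None:
            if node.is_leaf():
                paths[node.name] = list(trail)
            for child, length in node.children:
                walk(child, trail + [(id(child), length)])

        walk(self.root, [])
        labels = sorted(paths)
        n = len(labels)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pi = paths[labels[i]]
                pj = paths[labels[j]]
                shared = 0
                for (u, _), (v, _) in zip(pi, pj):
                    if u == v:
                        shared += 1
                    else:
                        break
                dist = sum(l for _, l in pi[shared:]) + sum(l for _, l in pj[shared:])
                vals[i, j] = vals[j, i] = dist
        return DistanceMatrix(tuple(labels), vals)

    def to_newick(self) -> str:
        def render(node: PhyloNode) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(
                f"{render(child)}:{length:.10g}" for child, length in node.children
            )
            return f"({inner})"

        return render(self.root) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Neighbor joining with Q-matrix pair selection.

    Branch lengths use the canonical closed form; ties in the Q matrix are
    broken by the lexicographically smallest (label, label) pair so the
    result is deterministic.  On an additive (tree-metric) input the
    generating topology and path lengths are recovered exactly.
    """
    labels = list(dist.labels)
    if len(labels) < 2:
        raise ValueError("need at least two taxa")
    D: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                D[_key(a, b)] = float(dist.values[i, j])
    nodes: dict[str, PhyloNode] = {lab: PhyloNode(name=lab) for lab in labels}
    active = sorted(labels)

    if len(active) == 2:
        a, b = active
        half = D[_key(a, b)] / 2.0
        return PhyloTree(PhyloNode(children=[(nodes[a], half), (nodes[b], half)]))

    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[_key(a, b)] for b in active if b != a) for a in active}
        best = None
        best_q = np.inf
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = active[ii], active[jj]
                q = (n - 2) * D[_key(a, b)] - r[a] - r[b]
                if q < best_q - 1e-15 or (
                    abs(q - best_q) <= 1e-15 and best is not None and (a, b) < best
                ):
                    best_q = q
                    best = (a, b)
        a, b = best
        dab = D[_key(a, b)]
        va = 0.5 * dab + (r[a] - r[b]) / (2.0 * (n - 2))
        vb = dab - va
        new = f"@{counter}"
        counter += 1
        nodes[new] = PhyloNode(children=[(nodes[a], va), (nodes[b], vb)])
        for c in active:
            if c in (a, b):
                continue
            D[_key(new, c)] = 0.5 * (D[_key(a, c)] + D[_key(b, c)] - dab)
        active = sorted(set(active) - {a, b} | {new})

    a, b, c = active
    dab, dac, dbc = D[_key(a, b)], D[_key(a, c)], D[_key(b, c)]
    va = (dab + dac - dbc) / 2.0
    vb = (dab + dbc - dac) / 2.0
    vc = (dac + dbc - dab) / 2.0
    root = PhyloNode(children=[(nodes[a], va), (nodes[b], vb), (nodes[c], vc)])
    return PhyloTree(root)


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)
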