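"""Sulfated/acetylated fucan and galactofucan oligosaccharide structures.

Data model, notation parser, and computed properties for the oligosaccharide
products released by endo-fucoidanase digestion of brown-algal fucoidans.
A structure is a tree of pyranose residues rooted at the reducing end; every
other residue is joined through its anomeric carbon (position 1) to a ring
position (2, 3, 4 or 6) of its parent, and ring positions may carry one
O-sulfate or O-acetyl substituent.

Notation grammar (plain-ASCII; written non-reducing end -> reducing end)::

    residue   := anomer '-' enantiomer '-' sugar 'p' [ '(' subst {',' subst} ')' ] { branch }
    anomer    := 'a' | 'b' | 'ab'        (alpha, beta, mixed reducing end)
    sugar     := 'Fuc' | 'Gal'
    subst     := pos ('S' | 'Ac')        e.g. 2S = 2-O-sulfate, 3Ac = 3-O-acetyl
                 (pos 'OSO3' ['-'] accepted as an alias for pos 'S')
    branch    := '[' chain '-(1,' pos ')' ']'    attached to the preceding residue
    chain     := residue { '-(1,' pos ')-' residue }

Example -- the branched octasaccharide OF1 (see :func:`of1_octasaccharide`)::

    a-L-Fucp(4S)-(1,3)-a-L-Fucp(2S)[a-L-Fucp(4S)-(1,4)]-(1,3)-a-L-Fucp-(1,3)-
    a-L-Fucp(4S)-(1,3)-a-L-Fucp(2S)[a-L-Fucp(4S)-(1,4)]-(1,3)-ab-L-Fucp

The module also ships the assigned NMR chemical-shift tables for the
digestion products (the OF1 octasaccharide spin systems and the
medium-molecular-weight galactofucan repeating units) as packaged
delimited-text fixtures; see :func:`load_shift_table`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GlycanResidue",
    "Linkage",
    "Oligosaccharide",
    "GlycanBuilder",
    "GlycanParseError",
    "GlycanViolation",
    "ShiftAssignment",
    "parse_glycan",
    "to_text",
    "degree_of_polymerization",
    "sulfate_count",
    "acetyl_count",
    "linkage_census",
    "molecular_mass",
    "net_charge",
    "validate",
    "load_shift_table",
    "shift_lookup",
    "of1_octasaccharide",
    "ffa2_dp4_standard",
    "OF1_STRING",
]

SUGARS = ("Fuc", "Gal")
ANOMERS = ("alpha", "beta", "mixed")
SULFATE = "sulfate"
ACETYL = "acetyl"

# Ring positions bearing a free hydroxyl that can be substituted or
# glycosylated.  Fucose is 6-deoxy, so O6 does not exist.
_FREE_OH = {"Fuc": (2, 3, 4), "Gal": (2, 3, 4, 6)}
_LINKABLE = {"Fuc": (2, 3, 4), "Gal": (2, 3, 4, 6)}


@dataclass(frozen=True)
class GlycanResidue:
    label: str
    sugar: str = "Fuc"
    enantiomer: str = "L"
    anomer: str = "alpha"
    ring: str = "pyranose"
    substituents: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sugar not in SUGARS:
            raise ValueError(f"unknown sugar {self.sugar!r}")
        if self.enantiomer not in ("L", "D"):
            raise ValueError(f"enantiomer must be 'L' or 'D', got {self.enantiomer!r}")
        if self.anomer not in ANOMERS:
            raise ValueError(f"unknown anomer {self.anomer!r}")
        subs = dict(self.substituents)
        for pos, kind in subs.items():
            if not 2 <= int(pos) <= 6:
                raise ValueError(
                    f"substituent position {pos} out of range 2..6 on {self.label}"
                )
            if kind not in (SULFATE, ACETYL):
                raise ValueError(f"unknown substituent {kind!r}")
        object.__setattr__(self, "substituents", subs)


@dataclass(frozen=True)
class Linkage:
    """child anomeric C1 -> parent ring position."""

    child: str
    child_pos: int
    parent: str
    parent_pos: int


@dataclass(frozen=True)
class GlycanViolation:
    residue: str
    position: int | None
    rule: str


class GlycanParseError(ValueError):
    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


@dataclass(frozen=True)
class Oligosaccharide:
    residues: tuple[GlycanResidue, ...]
    linkages: tuple[Linkage, ...]
    reducing_end: str | None

    def __post_init__(self) -> None:
        labels = [r.label for r in self.residues]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate residue labels")
        if self.residues and self.reducing_end not in labels:
            raise ValueError(f"reducing end {self.reducing_end!r} not among residues")

    def residue(self, label: str) -> GlycanResidue:
        for r in self.residues:
            if r.label == label:
                return r
        raise KeyError(label)

    def children(self, label: str) -> list[Linkage]:
        """Linkages whose parent is ``label``, in declaration order."""
        return [lk for lk in self.linkages if lk.parent == label]

    def canonical_signature(self):
        """Structure signature invariant under relabeling (for isomorphism)."""

        def sig(label: str):
            r = self.residue(label)
            subs = tuple(sorted(r.substituents.items()))
            kids = tuple(
                sorted((lk.parent_pos, sig(lk.child)) for lk in self.children(label))
            )
            return (r.sugar, r.enantiomer, r.anomer, subs, kids)

        if not self.residues:
            return ()
        return sig(self.reducing_end)

    def isomorphic_to(self, other: "Oligosaccharide") -> bool:
        return self.canonical_signature() == other.canonical_signature()


class GlycanBuilder:
    """Programmatic construction of an Oligosaccharide tree."""

    def __init__(self) -> None:
        self._residues: list[GlycanResidue] = []
        self._linkages: list[Linkage] = []

    def add(self, label: str, **kwargs) -> "GlycanBuilder":
        self._residues.append(GlycanResidue(label=label, **kwargs))
        return self

    def link(self, child: str, parent: str, parent_pos: int) -> "GlycanBuilder":
        self._linkages.append(Linkage(child, 1, parent, int(parent_pos)))
        return self

    def build(self, reducing_end: str) -> Oligosaccharide:
        return Oligosaccharide(
            tuple(self._residues), tuple(self._linkages), reducing_end
        )


# ---------------------------------------------------------------------------
# Parsing

_ANOMER_TOKENS = {"ab": "mixed", "a": "alpha", "b": "beta", "α": "alpha", "β": "beta"}
_SUBST_RE = re.compile(r"^([1-9])(S|Ac|OSO3[-−]?)$")


class _Node:
    __slots__ = ("residue_kwargs", "children", "offset")

    def __init__(self, residue_kwargs: dict, offset: int):
        self.residue_kwargs = residue_kwargs
        self.children: list[tuple["_Node", int]] = []
        self.offset = offset


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.i = 0

    def error(self, msg: str, offset: int | None = None):
        raise GlycanParseError(msg, self.i if offset is None else offset)

    def peek(self) -> str:
        return self.text[self.i] if self.i < len(self.text) else ""

    def expect(self, s: str) -> None:
        if not self.text.startswith(s, self.i):
            self.error(f"expected {s!r}")
        self.i += len(s)

    def parse(self) -> _Node:
        node, attach = self.parse_chain(in_branch=False)
        if self.i != len(self.text):
            self.error("unexpected trailing text")
        return node

    def parse_chain(self, in_branch: bool) -> tuple[_Node, int | None]:
        node = self.parse_residue()
        while True:
            if not self.text.startswith("-(1,", self.i):
                if in_branch:
                    self.error("branch must end with its attachment linkage '-(1,p)'")
                return node, None
            start = self.i
            self.i += len("-(1,")
            pos = self.parse_position()
            self.expect(")")
            if self.peek() == "-":
                self.i += 1
                parent = self.parse_residue()
                parent.children.append((node, pos))
                node = parent
            else:
                if not in_branch:
                    self.error("dangling linkage at end of chain", start)
                return node, pos

    def parse_position(self) -> int:
        ch = self.peek()
        if not ch.isdigit():
            self.error("expected a linkage position digit")
        self.i += 1
        pos = int(ch)
        if pos not in (2, 3, 4, 6):
            self.error(f"linkage position {pos} out of range {{2,3,4,6}}", self.i - 1)
        return pos

    def parse_residue(self) -> _Node:
        start = self.i
        anomer = None
        for tok in ("ab", "a", "b", "α", "β"):  # longest first
            if self.text.startswith(tok + "-", self.i):
                anomer = _ANOMER_TOKENS[tok]
                self.i += len(tok) + 1
                break
        if anomer is None:
            self.error("expected anomer token 'a-', 'b-' or 'ab-'")
        enant = self.peek()
        if enant not in ("L", "D"):
            self.error("expected enantiomer 'L' or 'D'")
        self.i += 1
        self.expect("-")
        sugar = None
        for s in SUGARS:
            if self.text.startswith(s + "p", self.i):
                sugar = s
                self.i += len(s) + 1
                break
        if sugar is None:
            self.error("unknown sugar code (expected 'Fucp' or 'Galp')")
        substituents: dict[int, str] = {}
        if self.peek() == "(":
            close = self.text.find(")", self.i)
            if close < 0:
                self.error("unterminated substituent group")
            body = self.text[self.i + 1 : close]
            for item in body.split(","):
                m = _SUBST_RE.match(item.strip())
                if not m:
                    self.error(f"malformed substituent {item.strip()!r}")
                pos = int(m.group(1))
                if pos < 2 or pos > 6:
                    self.error(f"substituent position {pos} out of range 2..6")
                kind = ACETYL if m.group(2) == "Ac" else SULFATE
                if pos in substituents:
                    self.error(f"duplicate substituent at position {pos}")
                substituents[pos] = kind
            self.i = close + 1
        node = _Node(
            dict(
                sugar=sugar,
                enantiomer=enant,
                anomer=anomer,
                substituents=substituents,
            ),
            start,
        )
        while self.peek() == "[":
            self.i += 1
            child, pos = self.parse_chain(in_branch=True)
            self.expect("]")
            node.children.append((child, pos))
        return node


def _labels() -> Iterable[str]:
    import string

    for ch in string.ascii_uppercase:
        yield ch
    i = 1
    while True:
        yield f"R{i}"
        i += 1


def parse_glycan(text: str) -> Oligosaccharide:
    """Parse the notation grammar into an Oligosaccharide tree.

    The text is written non-reducing end -> reducing end, so the last
    backbone residue becomes the reducing end (the tree root).  Residue
    labels are assigned A, B, C, ... in order of appearance in the text.
    """
    root = _Parser(text.strip()).parse()

    # Assign labels in textual (offset) order.
    nodes: list[_Node] = []

    def collect(n: _Node) -> None:
        nodes.append(n)
        for child, _ in n.children:
            collect(child)

    collect(root)
    nodes.sort(key=lambda n: n.offset)
    names = {}
    for node, label in zip(nodes, _labels()):
        names[id(node)] = label

    builder = GlycanBuilder()
    for node in nodes:
        builder.add(names[id(node)], **node.residue_kwargs)

    def link_all(n: _Node) -> None:
        for child, pos in n.children:
            builder.link(names[id(child)], names[id(n)], pos)
            link_all(child)

    link_all(root)
    return builder.build(reducing_end=names[id(root)])


def to_text(olig: Oligosaccharide) -> str:
    """Canonical notation string; ``parse_glycan(to_text(x))`` is isomorphic to x."""
    if not olig.residues:
        return ""

    def subtree_size(label: str) -> int:
        return 1 + sum(subtree_size(lk.child) for lk in olig.children(label))

    def residue_token(r: GlycanResidue) -> str:
        anomer = {"alpha": "a", "beta": "b", "mixed": "ab"}[r.anomer]
        tok = f"{anomer}-{r.enantiomer}-{r.sugar}p"
        if r.substituents:
            items = []
            for pos in sorted(r.substituents):
                items.append(f"{pos}{'S' if r.substituents[pos] == SULFATE else 'Ac'}")
            tok += "(" + ",".join(items) + ")"
        return tok

    def render(label: str) -> str:
        kids = olig.children(label)
        backbone = None
        if kids:
            backbone = max(kids, key=lambda lk: subtree_size(lk.child))
        prefix = ""
        branches = ""
        for lk in kids:
            if lk is backbone:
                prefix = f"{render(lk.child)}-(1,{lk.parent_pos})-"
            else:
                branches += f"[{render(lk.child)}-(1,{lk.parent_pos})]"
        return prefix + residue_token(olig.residue(label)) + branches

    return render(olig.reducing_end)


# ---------------------------------------------------------------------------
# Computed properties


def degree_of_polymerization(olig: Oligosaccharide) -> int:
    return len(olig.residues)


def sulfate_count(olig: Oligosaccharide) -> int:
    return sum(
        1 for r in olig.residues for kind in r.substituents.values() if kind == SULFATE
    )


def acetyl_count(olig: Oligosaccharide) -> int:
    return sum(
        1 for r in olig.residues for kind in r.substituents.values() if kind == ACETYL
    )


def linkage_census(olig: Oligosaccharide) -> dict[tuple[int, int], int]:
    """Counts of linkage types keyed by (child anomeric pos, parent pos)."""
    census: dict[tuple[int, int], int] = {}
    for lk in olig.linkages:
        key = (lk.child_pos, lk.parent_pos)
        census[key] = census.get(key, 0) + 1
    return census


# Standard atomic masses (average, monoisotopic).
_ATOMIC = {
    "C": (12.011, 12.0),
    "H": (1.008, 1.0078250319),
    "O": (15.999, 15.9949146221),
    "S": (32.06, 31.97207069),
}

# Free monosaccharide formulas; fucose is 6-deoxygalactose (C6H12O5).
_SUGAR_FORMULA = {"Fuc": {"C": 6, "H": 12, "O": 5}, "Gal": {"C": 6, "H": 12, "O": 6}}
_WATER = {"H": 2, "O": 1}
_SULFATE_INC = {"S": 1, "O": 3}  # O-sulfation adds SO3 to a hydroxyl
_ACETYL_INC = {"C": 2, "H": 2, "O": 1}  # O-acetylation adds C2H2O


def _formula_mass(formula: Mapping[str, int], kind: str) -> float:
    idx = 0 if kind == "average" else 1
    return sum(_ATOMIC[el][idx] * n for el, n in formula.items())


def molecular_mass(olig: Oligosaccharide, kind: str = "average") -> float:
    """Molecular mass in Da (neutral, fully protonated sulfate esters).

    Sum of free-monosaccharide masses, minus one water per glycosidic bond,
    plus an SO3 increment per sulfate and a C2H2O increment per acetyl.
    """
    if kind not in ("average", "monoisotopic"):
        raise ValueError("kind must be 'average' or 'monoisotopic'")
    mass = sum(_formula_mass(_SUGAR_FORMULA[r.sugar], kind) for r in olig.residues)
    mass -= len(olig.linkages) * _formula_mass(_WATER, kind)
    mass += sulfate_count(olig) * _formula_mass(_SULFATE_INC, kind)
    mass += acetyl_count(olig) * _formula_mass(_ACETYL_INC, kind)
    return mass


def net_charge(olig: Oligosaccharide, assume_full_deprotonation: bool = True) -> int:
    """Net charge; -1 per sulfate ester when fully deprotonated."""
    if not assume_full_deprotonation:
        warnings.warn(
            "net_charge without full deprotonation returns 0; sulfate pKa "
            "modeling is out of scope",
            stacklevel=2,
        )
        return 0
    return -sulfate_count(olig)


def validate(olig: Oligosaccharide) -> list[GlycanViolation]:
    """Chemistry/topology checks; returns an empty list for a sound structure."""
    violations: list[GlycanViolation] = []
    labels = {r.label for r in olig.residues}
    if not olig.residues:
        return violations

    parents_of: dict[str, int] = {}
    occupied: dict[str, dict[int, str]] = {r.label: {} for r in olig.residues}
    for lk in olig.linkages:
        if lk.child not in labels or lk.parent not in labels:
            violations.append(
                GlycanViolation(lk.child, None, "linkage references unknown residue")
            )
            continue
        if lk.child_pos != 1:
            violations.append(
                GlycanViolation(lk.child, lk.child_pos, "child must link through C1")
            )
        parents_of[lk.child] = parents_of.get(lk.child, 0) + 1
        slot = occupied[lk.parent]
        if lk.parent_pos in slot:
            violations.append(
                GlycanViolation(
                    lk.parent, lk.parent_pos, "two children on the same parent position"
                )
            )
        else:
            slot[lk.parent_pos] = lk.child
        linkable = _LINKABLE[olig.residue(lk.parent).sugar]
        if lk.parent_pos not in linkable:
            violations.append(
                GlycanViolation(
                    lk.parent,
                    lk.parent_pos,
                    f"position {lk.parent_pos} not glycosylatable on "
                    f"{olig.residue(lk.parent).sugar}",
                )
            )

    for r in olig.residues:
        free = _FREE_OH[r.sugar]
        for pos, kind in r.substituents.items():
            if pos == 1:
                violations.append(
                    GlycanViolation(r.label, 1, "position 1 never carries a substituent")
                )
            elif pos not in free:
                violations.append(
                    GlycanViolation(
                        r.label, pos, f"no free hydroxyl at position {pos} on {r.sugar}"
                    )
                )
            if pos in occupied[r.label]:
                violations.append(
                    GlycanViolation(
                        r.label, pos, "position simultaneously linked and substituted"
                    )
                )

    # Tree rooted at the reducing end: every non-root residue has exactly one
    # parent edge, the root none, and all residues are reachable.
    for label in labels:
        n_parents = parents_of.get(label, 0)
        if label == olig.reducing_end:
            if n_parents != 0:
                violations.append(
                    GlycanViolation(label, None, "reducing end must not link outward")
                )
        elif n_parents != 1:
            violations.append(
                GlycanViolation(
                    label, None, f"residue has {n_parents} parent linkages, expected 1"
                )
            )
    seen: set[str] = set()
    stack = [olig.reducing_end]
    while stack:
        lab = stack.pop()
        if lab in seen:
            violations.append(GlycanViolation(lab, None, "cycle in linkage graph"))
            break
        seen.add(lab)
        stack.extend(lk.child for lk in olig.children(lab))
    for label in labels - seen:
        violations.append(
            GlycanViolation(label, None, "residue unreachable from reducing end")
        )
    return violations


# ---------------------------------------------------------------------------
# Published structures


# OF1: branched sulfated octasaccharide released from S. latissima fucoidans.
# alpha(1,3)-linked L-fucose backbone (A-B-C-D-E-F, non-reducing -> reducing),
# with alpha(1,4)-linked 4-O-sulfated fucosyl branches G on B and H on E.
OF1_STRING = (
    "a-L-Fucp(4S)-(1,3)-a-L-Fucp(2S)[a-L-Fucp(4S)-(1,4)]-(1,3)-a-L-Fucp-(1,3)-"
    "a-L-Fucp(4S)-(1,3)-a-L-Fucp(2S)[a-L-Fucp(4S)-(1,4)]-(1,3)-ab-L-Fucp"
)


def of1_octasaccharide() -> Oligosaccharide:
    """The OF1 octasaccharide with its assignment labels A-H.

    Residues A-F form the alpha(1,3) backbone from the non-reducing end (A)
    to the reducing end (F, anomeric mixture); G and H are the
    alpha(1,4)-linked 4-O-sulfated fucosyl branches on B and E.  Six of the
    eight residues carry one sulfate each.
    """
    b = GlycanBuilder()
    b.add("A", substituents={4: SULFATE})
    b.add("B", substituents={2: SULFATE})
    b.add("C")
    b.add("D", substituents={4: SULFATE})
    b.add("E", substituents={2: SULFATE})
    b.add("F", anomer="mixed")
    b.add("G", substituents={4: SULFATE})
    b.add("H", substituents={4: SULFATE})
    b.link("A", "B", 3)
    b.link("G", "B", 4)
    b.link("B", "C", 3)
    b.link("C", "D", 3)
    b.link("D", "E", 3)
    b.link("H", "E", 4)
    b.link("E", "F", 3)
    return b.build(reducing_end="F")


def ffa2_dp4_standard() -> Oligosaccharide:
    """The DP4 electrophoresis standard: a tetrasaccharide of alternating
    (1,4)- and (1,3)-linked alpha-L-fucosyls, each sulfated at C2."""
    return parse_glycan(
        "a-L-Fucp(2S)-(1,3)-a-L-Fucp(2S)-(1,4)-a-L-Fucp(2S)-(1,3)-ab-L-Fucp(2S)"
    )


# ---------------------------------------------------------------------------
# NMR chemical-shift tables (packaged fixtures)


@dataclass(frozen=True)
class ShiftAssignment:
    """1H/13C chemical shifts (ppm) for one spin system, positions 1-6.

    ``shifts[pos] = (delta_1H, delta_13C)``; a diastereotopic proton pair
    (e.g. H6/H6' of galactose) is stored as a tuple of two 1H shifts.
    """

    label: str
    descriptor: str
    shifts: Mapping[int, tuple]


_TABLE_FILES = {
    "of1": "of1_shifts.tsv",  # low-MW octasaccharide OF1, spin systems A-H
    "mmp": "mmp_shifts.tsv",  # deacetylated medium-MW galactofucan units I-K
}


def load_shift_table(name: str) -> list[ShiftAssignment]:
    """Load a packaged shift table: ``'of1'`` (spin systems A, B, C, D, Ea,
    Eb, Fa, Fb, G, H) or ``'mmp'`` (repeating units I, J, K)."""
    if name not in _TABLE_FILES:
        raise KeyError(f"unknown shift table {name!r}; expected 'of1' or 'mmp'")
    with resources.files("fucokit.data").joinpath(_TABLE_FILES[name]).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    out = []
    for (label, descriptor), grp in df.groupby(["label", "descriptor"], sort=False):
        shifts = {}
        for _, row in grp.iterrows():
            pos = int(row["position"])
            h = row["h1"]
            h_val: tuple | float
            if "/" in h:
                h_val = tuple(float(x) for x in h.split("/"))
            else:
                h_val = float(h)
            shifts[pos] = (h_val, float(row["c13"]))
        out.append(ShiftAssignment(label=label, descriptor=descriptor, shifts=shifts))
    return out


def shift_lookup(table: list[ShiftAssignment], label: str, position: int):
    """Return the stored (delta_1H, delta_13C) pair for a residue position."""
    for assignment in table:
        if assignment.label == label:
            try:
                return assignment.shifts[int(position)]
            except KeyError:
                raise KeyError(
                    f"no assignment at position {position} of residue {label}"
                ) from None
    raise KeyError(f"no residue labeled {label!r} in table")
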