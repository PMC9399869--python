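"""Parsimony analysis of aligned SL exon sequences, gaps as a fifth state.

SL exons from different species differ by substitutions *and* short
indels, so alignment gaps are treated as an ordinary fifth character state
rather than missing data: a gap shared by two taxa is shared evidence.
Scores are computed with the Fitch algorithm per alignment column over the
{A, C, G, T, -} alphabet, and for the small taxon sets involved (a handful
of consensus SL exons) the search enumerates every unrooted binary
topology exhaustively, returning all equally parsimonious trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .align import needleman_wunsch_global

STATES = "ACGT-"

# A topology is a nested structure: a leaf is a taxon label (str); an
# internal node is a tuple of children.  Unrooted trees are canonically
# held with a trifurcating root (the unrooted form of a binary tree).


@dataclass(frozen=True)
class CharacterAlignment:
    """Equal-length character rows over {A, C, G, T, -} with taxon labels."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        if len(self.taxa) < 3:
            raise ValueError("need >= 3 taxa")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows must have equal length")
        for r in self.rows:
            bad = set(r) - set(STATES)
            if bad:
                raise ValueError(f"invalid characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row_of(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass(frozen=True)
class UnrootedTree:
    """An unrooted binary topology with its parsimony score."""

    topology: tuple
    score: int
    branch_changes: dict[frozenset, int]

    def newick(self, with_score: bool = True) -> str:
        def render(node):
            if isinstance(node, str):
                return node
            return "(" + ",".join(render(c) for c in node) + ")"
        comment = f"[&score={self.score}]" if with_score else ""
        return render(self.topology) + comment + ";"


def _leaves(node):
    if isinstance(node, str):
        return [node]
    out = []
    for c in node:
        out.extend(_leaves(c))
    return out


def _canonical(node):
    """Sort children recursively so equal topologies compare equal."""
    if isinstance(node, str):
        return node
    kids = tuple(sorted((_canonical(c) for c in node),
                        key=lambda x: min(_leaves(x))))
    return kids


def _binary_rooting(topology):
    """Root an unrooted (trifurcating-root) topology along one edge."""
    if len(topology) == 3:
        a, b, c = topology
        return (a, (b, c))
    return topology


def _fitch_site(node, char_of):
    """Bottom-up Fitch pass for one site; returns (state set, changes)."""
    if isinstance(node, str):
        return frozenset(char_of[node]), 0
    sets, costs = [], 0
    for child in node:
        s, c = _fitch_site(child, char_of)
        sets.append(s)
        costs += c
    inter = frozenset.intersection(*sets)
    if inter:
        return inter, costs
    return frozenset.union(*sets), costs + 1


def fitch_score(topology, alignment: CharacterAlignment) -> int:
    """Parsimony score of a topology: summed per-site Fitch union events."""
    if sorted(_leaves(topology)) != sorted(alignment.taxa):
        raise ValueError("topology leaves do not match alignment taxa")
    rooted = _binary_rooting(topology)
    score = 0
    for j in range(alignment.length):
        char_of = {t: alignment.row_of(t)[j] for t in alignment.taxa}
        _, changes = _fitch_site(rooted, char_of)
        score += changes
    return score


def _branch_changes(topology, alignment: CharacterAlignment) -> dict:
    """Per-branch change counts from one most-parsimonious assignment.

    The assignment is not unique; states are resolved top-down taking the
    lexicographically smallest admissible state, which is deterministic.
    Branches are keyed by the leaf set of the clade below them (in the
    arbitrary binary rooting used for scoring).
    """
    rooted = _binary_rooting(topology)
    changes: dict[frozenset, int] = {}

    def down(node, char_of):
        if isinstance(node, str):
            return (frozenset(char_of[node]), ())
        parts = tuple(down(c, char_of) for c in node)
        sets = [p[0] for p in parts]
        inter = frozenset.intersection(*sets)
        return (inter if inter else frozenset.union(*sets), parts)

    def up(node, info, parent_state, char_of):
        state_set, parts = info
        state = parent_state if parent_state in state_set \
            else min(state_set)
        if parent_state is not None and state != parent_state:
            key = frozenset(_leaves(node))
            changes[key] = changes.get(key, 0) + 1
        if not isinstance(node, str):
            for child, cinfo in zip(node, parts):
                up(child, cinfo, state, char_of)

    for j in range(alignment.length):
        char_of = {t: alignment.row_of(t)[j] for t in alignment.taxa}
        info = down(rooted, char_of)
        up(rooted, info, None, char_of)
    return changes


def _insertions(tree, leaf):
    """All topologies obtained by attaching ``leaf`` on each edge."""
    out = []
    for i, child in enumerate(tree):
        new = list(tree)
        new[i] = (child, leaf)
        out.append(tuple(new))
        if not isinstance(child, str):
            for sub in _insertions(child, leaf):
                new = list(tree)
                new[i] = sub
                out.append(tuple(new))
    return out


def enumerate_topologies(taxa):
    """All unrooted binary topologies over the taxa ((2n-5)!! of them)."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    trees = [tuple(taxa[:3])]
    for leaf in taxa[3:]:
        trees = [t for tree in trees for t in _insertions(tree, leaf)]
    return trees


def exhaustive_parsimony_search(alignment: CharacterAlignment
                                ) -> list[UnrootedTree]:
    """Score every unrooted topology; return all minimum-score trees.

    Limited to 3-8 taxa (up to 10395 topologies).  Output order is the
    deterministic sort of canonicalised newick strings.
    """
    n = len(alignment.taxa)
    if not 3 <= n <= 8:
        raise ValueError("exhaustive search supports 3 to 8 taxa")
    scored = [(fitch_score(t, alignment), t)
              for t in enumerate_topologies(alignment.taxa)]
    best = min(s for s, _ in scored)
    winners = [_canonical(t) for s, t in scored if s == best]
    winners = sorted(set(winners), key=lambda t: UnrootedTree(t, 0, {}).newick())
    return [UnrootedTree(t, best, _branch_changes(t, alignment))
            for t in winners]


def align_sl_set(sequences: dict[str, str] | list[tuple[str, str]]
                 ) -> CharacterAlignment:
    """Progressively align SL exon sequences into a character alignment.

    Pre-aligned inputs (equal lengths containing ``-``) pass through
    unchanged.  Otherwise sequences are added in input order, each aligned
    to the current first row's column structure with global alignment and
    gap columns propagated to all previous rows.
    """
    items = list(sequences.items()) if isinstance(sequences, dict) \
        else list(sequences)
    if len(items) < 3:
        raise ValueError("need >= 3 sequences")
    taxa = [t for t, _ in items]
    seqs = [s.upper() for _, s in items]
    lengths = {len(s) for s in seqs}
    if any("-" in s for s in seqs):
        if len(lengths) != 1:
            raise ValueError("pre-aligned input must have equal lengths")
        return CharacterAlignment(tuple(taxa), tuple(seqs))
    rows = [seqs[0]]
    for s in seqs[1:]:
        ref = rows[0]
        core = ref.replace("-", "")
        a_core, a_new, _ = needleman_wunsch_global(core, s)
        # re-expand: walk ref columns and the core alignment in parallel
        new_rows = [""] * len(rows)
        new_row = ""
        ri = 0          # ref column index
        for ca, cb in zip(a_core, a_new):
            if ca == "-":
                # insertion relative to the existing alignment: gap column
                for k in range(len(rows)):
                    new_rows[k] += "-"
                new_row += cb
            else:
                # consume ref columns up to and incl. the next non-gap
                while ref[ri] == "-":
                    for k in range(len(rows)):
                        new_rows[k] += rows[k][ri]
                    new_row += "-"
                    ri += 1
                for k in range(len(rows)):
                    new_rows[k] += rows[k][ri]
                new_row += cb
                ri += 1
        while ri < len(ref):
            for k in range(len(rows)):
                new_rows[k] += rows[k][ri]
            new_row += "-"
            ri += 1
        rows = new_rows + [new_row]
    return CharacterAlignment(tuple(taxa), tuple(rows))


def branch_changes_table(tree: UnrootedTree) -> pd.DataFrame:
    rows = [dict(clade=";".join(sorted(k)), changes=v)
            for k, v in sorted(tree.branch_changes.items(),
                               key=lambda kv: ";".join(sorted(kv[0])))]
    return pd.DataFrame(rows, columns=["clade", "changes"])
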