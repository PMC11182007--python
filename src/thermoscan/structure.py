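"""Lightweight secondary-structure checks and stabilizing-mutation design.

A weighted Nussinov-style folder (pair weights G:C=3, A:U=2, G:U=1, minimum
loop 3) stands in for a thermodynamic folder when verifying that candidate
regions can form the expected hairpin; externally computed dot-bracket
structures can be imported through :func:`parse_dot_bracket`.

Mutation design converts weak G•U wobble pairs in the fourU/SD helix to
canonical G-C pairs (U→C on the uracil side), the classic stabilizing edit
that abolishes thermometer behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .descriptor import RNA_BASES


class StructureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Base-pair classification
# ---------------------------------------------------------------------------

WATSON_CRICK = frozenset({frozenset("AU"), frozenset("GC")})
WOBBLE = frozenset({frozenset("GU")})


def classify_pair(b1: str, b2: str) -> str:
    """Classify an (unordered) base pair: watson_crick, wobble, or none."""
    for b in (b1, b2):
        if b not in RNA_BASES:
            raise StructureError(f"not a nucleotide: {b!r}")
    key = frozenset((b1, b2))
    if key in WATSON_CRICK:
        return "watson_crick"
    if key in WOBBLE:
        return "wobble"
    return "none"


def helix_pairs(strand5: str, strand3: str) -> list[tuple[str, str]]:
    """Antiparallel pairing: position i of ``strand5`` against position
    L+1-i of ``strand3`` (1-based)."""
    if len(strand5) != len(strand3):
        raise StructureError("helix strands must have equal length")
    L = len(strand5)
    return [(strand5[i], strand3[L - 1 - i]) for i in range(L)]


def wobble_count(strand5: str, strand3: str) -> int:
    return sum(1 for a, b in helix_pairs(strand5, strand3)
               if classify_pair(a, b) == "wobble")


# ---------------------------------------------------------------------------
# Folding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldConfig:
    min_loop: int = 3
    pair_weights: tuple[tuple[str, int], ...] = (("GC", 3), ("AU", 2), ("GU", 1))
    traceback_tiebreak: str = "pair_first_smallest_inner"

    def weight(self, b1: str, b2: str) -> int:
        key = frozenset((b1, b2))
        for bases, w in self.pair_weights:
            if frozenset(bases) == key:
                if w <= 0:
                    raise StructureError("pair weights must be positive")
                return w
        return 0


@dataclass(frozen=True)
class SecondaryStructure:
    dot_bracket: str
    pairs: tuple[tuple[int, int], ...]   # 0-based, i < j, nested

    @property
    def pair_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.pairs)


def structure_from_pairs(n: int, pairs: list[tuple[int, int]],
                         min_loop: int = 0) -> SecondaryStructure:
    chars = ["."] * n
    seen: set[int] = set()
    ordered = tuple(sorted(tuple(sorted(p)) for p in pairs))
    for i, j in ordered:
        if not (0 <= i < j < n):
            raise StructureError(f"pair ({i},{j}) out of range")
        if j - i - 1 < min_loop:
            raise StructureError(f"pair ({i},{j}) violates min loop {min_loop}")
        if i in seen or j in seen:
            raise StructureError("position paired twice")
        seen.update((i, j))
        chars[i], chars[j] = "(", ")"
    # nesting check
    stack: list[int] = []
    by_open = {i: j for i, j in ordered}
    for idx, ch in enumerate(chars):
        if ch == "(":
            stack.append(by_open[idx])
        elif ch == ")":
            if not stack or stack[-1] != idx:
                raise StructureError("pairs are pseudoknotted (crossing)")
            stack.pop()
    return SecondaryStructure("".join(chars), ordered)


def parse_dot_bracket(db: str) -> SecondaryStructure:
    """Import an externally produced dot-bracket string."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError("unbalanced brackets")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise StructureError(f"unexpected character {ch!r} in dot-bracket")
    if stack:
        raise StructureError("unbalanced brackets")
    return structure_from_pairs(len(db), pairs)


def nussinov_fold(seq: str, cfg: FoldConfig | None = None) -> SecondaryStructure:
    """Maximum-weight nested structure of ``seq``.

    Dynamic program over intervals with a fixed deterministic traceback:
    whenever pairing the interval's last base achieves the optimum, it is
    paired (with the smallest admissible partner index); otherwise the last
    base is left unpaired.
    """
    cfg = cfg or FoldConfig()
    s = seq.upper().replace("T", "U")
    n = len(s)
    if n == 0:
        raise StructureError("empty sequence")
    for ch in s:
        if ch not in RNA_BASES:
            raise StructureError(f"invalid base {ch!r}")
    ml = cfg.min_loop
    W = [[0] * n for _ in range(n)]
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i][j - 1]
            for k in range(i, j - ml):
                w = cfg.weight(s[k], s[j])
                if w <= 0:
                    continue
                left = W[i][k - 1] if k > i else 0
                inner = W[k + 1][j - 1] if k + 1 <= j - 1 else 0
                cand = left + w + inner
                if cand > best:
                    best = cand
            W[i][j] = best
    pairs: list[tuple[int, int]] = []

    def trace(i: int, j: int) -> None:
        while j > i:
            target = W[i][j]
            paired = False
            for k in range(i, j - ml):
                w = cfg.weight(s[k], s[j])
                if w <= 0:
                    continue
                left = W[i][k - 1] if k > i else 0
                inner = W[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + w + inner == target:
                    pairs.append((k, j))
                    trace(k + 1, j - 1)
                    j = k - 1
                    if k == i:
                        return
                    paired = True
                    break
            if not paired:
                j -= 1

    trace(0, n - 1)
    return structure_from_pairs(n, pairs, min_loop=ml)


def structure_score(seq: str, s: SecondaryStructure, cfg: FoldConfig | None = None) -> int:
    cfg = cfg or FoldConfig()
    seq = seq.upper().replace("T", "U")
    return sum(cfg.weight(seq[i], seq[j]) for i, j in s.pairs)


def hairpin_support(implied_pairs: list[tuple[int, int]],
                    s: SecondaryStructure) -> float:
    """Fraction of the expected helix pairs present in a folded structure."""
    if not implied_pairs:
        return 0.0
    want = {tuple(sorted(p)) for p in implied_pairs}
    return len(want & set(s.pair_set)) / len(want)


# ---------------------------------------------------------------------------
# Stabilizing mutations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationProposal:
    """A U→C edit set at wobble-paired positions.

    ``positions`` are 1-based within the candidate construct sequence; the
    name concatenates before-bases, positions, after-bases (e.g. UU2930CC for
    a double U→C edit at construct positions 29 and 30).
    """

    positions: tuple[int, ...]
    before: tuple[str, ...]
    after: tuple[str, ...]
    delta_stability: float

    @property
    def name(self) -> str:
        return ("".join(self.before)
                + "".join(str(p) for p in self.positions)
                + "".join(self.after))


def propose_wobble_mutations(strand5: str, strand3: str, strand5_offset: int,
                             cfg: FoldConfig | None = None) -> list[MutationProposal]:
    """Propose converting every wobble-paired U of the 5' strand to C.

    ``strand5_offset`` is the 0-based offset of the 5' strand within the
    construct; returned positions are 1-based construct coordinates.  Returns
    an empty list when the helix has no wobble-paired U on the 5' strand.
    """
    cfg = cfg or FoldConfig()
    targets: list[int] = []
    delta = 0.0
    for i, (b5, b3) in enumerate(helix_pairs(strand5, strand3)):
        if classify_pair(b5, b3) == "wobble" and b5 == "U":
            targets.append(i)
            delta += cfg.weight("G", "C") - cfg.weight("G", "U")
    if not targets:
        return []
    positions = tuple(strand5_offset + i + 1 for i in targets)
    return [MutationProposal(positions=positions,
                             before=tuple("U" for _ in targets),
                             after=tuple("C" for _ in targets),
                             delta_stability=delta)]


def apply_mutation(seq: str, proposal: MutationProposal) -> str:
    """Apply an edit set to a construct sequence (1-based positions)."""
    chars = list(seq)
    for pos, before, after in zip(proposal.positions, proposal.before, proposal.after):
        if not (1 <= pos <= len(chars)):
            raise StructureError(f"position {pos} outside sequence of length {len(chars)}")
        if chars[pos - 1] != before:
            raise StructureError(
                f"position {pos}: expected {before!r}, found {chars[pos - 1]!r}")
        chars[pos - 1] = after
    return "".join(chars)


__all__ = [
    "classify_pair", "helix_pairs", "wobble_count",
    "FoldConfig", "SecondaryStructure", "structure_from_pairs",
    "parse_dot_bracket", "nussinov_fold", "structure_score", "hairpin_support",
    "MutationProposal", "propose_wobble_mutations", "apply_mutation",
    "StructureError",
]
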