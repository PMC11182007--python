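"""Motif descriptor language: parsing, validation, and sampling.

A descriptor is a small text file.  The first non-comment line is the *map*,
an ordered list of element ids.  Single-stranded elements appear once
(``s1``); each helix appears twice, once for its 5' strand (``h1``) and once
for its 3' strand (``h1'``), and the two occurrences must nest like
parentheses.  Each element id on the map is then defined by one line:

    s1 0   NNN***
    h1 0:0 *NNNNN:NNNNN*

Pattern symbols: ``A C G U`` are literals (``T`` is normalised to ``U``),
``N`` is any nucleotide, and ``*`` marks an optional position ("a nucleotide
may or may not be present") whose symbol is always ``N``.  The integer on a
single-strand line is the number of tolerated mismatches at literal
positions; the ``a:b`` field of a helix gives the tolerated non-complementary
pairs (``a``) and insertions (``b``; must be 0, insertions are unsupported).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

RNA_BASES = ("A", "C", "G", "U")

#: IUPAC nucleotide codes accepted in subject sequences.
IUPAC_CODES = frozenset("ACGUNRYSWKMBDHV")

#: The fourU thermometer search descriptor (terminal-hairpin scaffold with the
#: four consecutive U's opposite the Shine-Dalgarno block and an AUG anchor).
FOURU_DESCRIPTOR = """\
s1 h1 s2 h2 s3 h2' s4 h1' s5
s1 0  NNN******
h1 0:0 *NNNNN:NNNNN*
s2 0  N*
h2 0:0 *CUUUUNNNN*:*NNNNAGGAG*
s3 0  NNN****
s4 0  N*
s5 0  NAUG***
"""


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class DescriptorError(ValueError):
    """Base class for descriptor parse/validation failures."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyDescriptorError(DescriptorError):
    """No map line / no elements, or a descriptor that can match zero length."""


class MapDefinitionError(DescriptorError):
    """A map id lacks a definition line, or a definition is not on the map."""


class HelixStrandCountError(DescriptorError):
    """A helix id does not appear exactly twice on the map (5' then 3')."""


class CrossingHelixError(DescriptorError):
    """Helix occurrences on the map are not properly nested."""


class UnknownSymbolError(DescriptorError):
    """A pattern contains a symbol outside the descriptor alphabet."""


class AllowanceError(DescriptorError):
    """A mismatch allowance exceeds the number of fixed positions."""


class UnsupportedFeatureError(DescriptorError):
    """A descriptor feature outside the supported subset (e.g. insertions)."""


class UnsatisfiablePairError(DescriptorError):
    """Literal positions forced to pair cannot form an allowed base pair."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternPosition:
    """One position of a strand pattern.

    ``optional`` positions always carry symbol ``N``: an optional position may
    be occupied by any nucleotide or absent altogether.
    """

    symbol: str
    optional: bool = False

    def __post_init__(self):
        if self.symbol not in ("A", "C", "G", "U", "N"):
            raise UnknownSymbolError(f"unknown pattern symbol {self.symbol!r}")
        if self.optional and self.symbol != "N":
            raise UnknownSymbolError("optional positions must have symbol N")

    @property
    def is_literal(self) -> bool:
        return self.symbol != "N"


@dataclass(frozen=True)
class StrandPattern:
    """An ordered run of pattern positions for one strand."""

    positions: tuple[PatternPosition, ...]

    def __post_init__(self):
        if not self.positions:
            raise EmptyDescriptorError("empty strand pattern")

    @classmethod
    def from_text(cls, text: str, line: int | None = None) -> "StrandPattern":
        positions = []
        for ch in text.strip().upper().replace("T", "U"):
            if ch == "*":
                positions.append(PatternPosition("N", optional=True))
            elif ch in ("A", "C", "G", "U", "N"):
                positions.append(PatternPosition(ch))
            else:
                raise UnknownSymbolError(f"unknown pattern symbol {ch!r}", line)
        if not positions:
            raise EmptyDescriptorError("empty strand pattern", line)
        return cls(tuple(positions))

    @property
    def text(self) -> str:
        return "".join("*" if p.optional else p.symbol for p in self.positions)

    @property
    def n_fixed(self) -> int:
        return sum(not p.optional for p in self.positions)

    @property
    def n_optional(self) -> int:
        return sum(p.optional for p in self.positions)

    @property
    def optional_indices(self) -> tuple[int, ...]:
        return tuple(i for i, p in enumerate(self.positions) if p.optional)

    def length_range(self) -> tuple[int, int]:
        return self.n_fixed, self.n_fixed + self.n_optional

    def variant(self, present: Sequence[bool]) -> str:
        """Symbol string for one choice of present optional positions."""
        it = iter(present)
        out = []
        for p in self.positions:
            if p.optional:
                if next(it):
                    out.append(p.symbol)
            else:
                out.append(p.symbol)
        return "".join(out)

    def variants(self) -> dict[str, tuple[bool, ...]]:
        """All distinct realizable symbol strings, mapped to a canonical
        present-mask (first mask in lexicographic True>False order)."""
        out: dict[str, tuple[bool, ...]] = {}
        k = self.n_optional
        for bits in _masks(k):
            v = self.variant(bits)
            if v and v not in out:
                out[v] = bits
        return out


def _masks(k: int) -> Iterator[tuple[bool, ...]]:
    """All k-bit masks, all-present first (stable canonical order)."""
    for code in range(2 ** k):
        yield tuple(not (code >> (k - 1 - i)) & 1 for i in range(k))


@dataclass(frozen=True)
class SingleStrandSpec:
    name: str
    max_mismatches: int
    pattern: StrandPattern

    def __post_init__(self):
        if not self.name.startswith("s"):
            raise MapDefinitionError(f"single-strand id must start with 's': {self.name}")
        if self.max_mismatches < 0:
            raise AllowanceError(f"{self.name}: negative mismatch allowance")
        if self.max_mismatches > self.pattern.n_fixed:
            raise AllowanceError(
                f"{self.name}: mismatch allowance {self.max_mismatches} exceeds "
                f"{self.pattern.n_fixed} fixed positions")


@dataclass(frozen=True)
class HelixSpec:
    """A helical element: antiparallel 5' and 3' strand patterns.

    ``mispair_allowance`` is the tolerated count of non-complementary realized
    pairs; ``insertion_allowance`` is accepted in the format but must be 0.
    Optional positions come in corresponding outside-in pairs and are jointly
    present or absent, so the two realized strands always have equal length.
    """

    name: str
    mispair_allowance: int
    insertion_allowance: int
    pattern5: StrandPattern
    pattern3: StrandPattern

    def __post_init__(self):
        if not self.name.startswith("h"):
            raise MapDefinitionError(f"helix id must start with 'h': {self.name}")
        if self.insertion_allowance != 0:
            raise UnsupportedFeatureError(
                f"{self.name}: insertion allowance {self.insertion_allowance} unsupported (must be 0)")
        if self.mispair_allowance < 0:
            raise AllowanceError(f"{self.name}: negative mispair allowance")
        if len(self.pattern5.positions) != len(self.pattern3.positions):
            raise UnsupportedFeatureError(
                f"{self.name}: strand patterns must have equal length")
        if self.pattern5.n_optional != self.pattern3.n_optional:
            raise UnsupportedFeatureError(
                f"{self.name}: optional position counts differ between strands")
        n_pairs = min(self.pattern5.n_fixed, self.pattern3.n_fixed)
        if self.mispair_allowance > n_pairs:
            raise AllowanceError(
                f"{self.name}: mispair allowance {self.mispair_allowance} exceeds "
                f"{n_pairs} paired fixed positions")

    @property
    def joint_optionals(self) -> tuple[tuple[int, int], ...]:
        """Corresponding optional index pairs, outside-in.

        The k-th optional of the 5' strand counted from its 5' end (outside of
        the helix) corresponds to the k-th optional of the 3' strand counted
        from its 3' end (also outside).
        """
        five = self.pattern5.optional_indices
        three = tuple(reversed(self.pattern3.optional_indices))
        return tuple(zip(five, three))

    def strand_variants(self) -> list[tuple[str, str, tuple[bool, ...]]]:
        """All joint realizations: (variant5, variant3, present-mask)."""
        out = []
        seen = set()
        five = self.pattern5.optional_indices
        three = tuple(reversed(self.pattern3.optional_indices))
        k = len(five)
        for bits in _masks(k):
            m5 = {five[i]: bits[i] for i in range(k)}
            m3 = {three[i]: bits[i] for i in range(k)}
            v5 = "".join(p.symbol for i, p in enumerate(self.pattern5.positions)
                         if not p.optional or m5[i])
            v3 = "".join(p.symbol for i, p in enumerate(self.pattern3.positions)
                         if not p.optional or m3[i])
            if v5 and (v5, v3) not in seen:
                seen.add((v5, v3))
                out.append((v5, v3, bits))
        return out


@dataclass(frozen=True)
class PairingRules:
    """Allowed base pairs; G:U wobble may be switched off."""

    wobble_enabled: bool = True
    extra_pairs: frozenset[frozenset[str]] = frozenset()

    @property
    def allowed_pairs(self) -> frozenset[frozenset[str]]:
        pairs = {frozenset("AU"), frozenset("GC")}
        if self.wobble_enabled:
            pairs.add(frozenset("GU"))
        return frozenset(pairs) | self.extra_pairs

    def allows(self, b1: str, b2: str) -> bool:
        return frozenset((b1, b2)) in self.allowed_pairs


def _canonical_id(token: str) -> str:
    """Normalise primed-strand spellings (h2', h2′, h2\") to h2'."""
    return re.sub("[′’\"']+$", "'", token)


@dataclass(frozen=True)
class MotifDescriptor:
    """A validated map + element definitions + pairing rules."""

    map_order: tuple[str, ...]
    elements: Mapping[str, SingleStrandSpec | HelixSpec]
    pairing: PairingRules = field(default_factory=PairingRules)

    def __post_init__(self):
        _validate(self)

    @property
    def helix_names(self) -> tuple[str, ...]:
        return tuple(n for n in dict.fromkeys(t.rstrip("'") for t in self.map_order)
                     if isinstance(self.elements[n], HelixSpec))

    @property
    def ss_names(self) -> tuple[str, ...]:
        return tuple(t for t in self.map_order
                     if isinstance(self.elements.get(t), SingleStrandSpec))

    def element_for_token(self, token: str) -> SingleStrandSpec | HelixSpec:
        return self.elements[token.rstrip("'")]

    def to_text(self) -> str:
        """Serialise back to the descriptor file format (round-trippable)."""
        lines = [" ".join(self.map_order)]
        for name in dict.fromkeys(t.rstrip("'") for t in self.map_order):
            el = self.elements[name]
            if isinstance(el, SingleStrandSpec):
                lines.append(f"{el.name} {el.max_mismatches} {el.pattern.text}")
            else:
                lines.append(f"{el.name} {el.mispair_allowance}:{el.insertion_allowance} "
                             f"{el.pattern5.text}:{el.pattern3.text}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _validate(d: MotifDescriptor) -> None:
    if not d.map_order:
        raise EmptyDescriptorError("empty map")
    seen_ss: set[str] = set()
    stack: list[str] = []
    opened: set[str] = set()
    closed: set[str] = set()
    for token in d.map_order:
        base = token.rstrip("'")
        if base not in d.elements:
            raise MapDefinitionError(f"map id {token!r} has no definition")
        el = d.elements[base]
        if isinstance(el, SingleStrandSpec):
            if token.endswith("'"):
                raise MapDefinitionError(f"single-strand id {token!r} cannot be primed")
            if token in seen_ss:
                raise MapDefinitionError(f"single-strand id {token!r} appears twice on map")
            seen_ss.add(token)
        else:
            if token.endswith("'"):
                if base in closed or base not in opened:
                    raise HelixStrandCountError(
                        f"helix {base!r}: primed strand without matching open strand")
                if not stack or stack[-1] != base:
                    raise CrossingHelixError(
                        f"helix {base!r} crosses helix {stack[-1] if stack else '?'!r}")
                stack.pop()
                closed.add(base)
            else:
                if base in opened:
                    raise HelixStrandCountError(f"helix {base!r} opened twice")
                stack.append(base)
                opened.add(base)
    if stack:
        raise HelixStrandCountError(f"helix {stack[-1]!r} never closed")
    for name, el in d.elements.items():
        if isinstance(el, SingleStrandSpec):
            if name not in seen_ss:
                raise MapDefinitionError(f"defined element {name!r} missing from map")
        elif name not in closed:
            raise HelixStrandCountError(f"helix {name!r} does not appear exactly twice on map")
    lo, _ = descriptor_span_range(d)
    if lo < 1:
        raise EmptyDescriptorError("descriptor admits empty matches (min span 0)")
    # literal-vs-literal pairing in the all-optionals-present alignment
    for name in d.helix_names:
        h = d.elements[name]
        assert isinstance(h, HelixSpec)
        n = len(h.pattern5.positions)
        for i in range(n):
            p5 = h.pattern5.positions[i]
            p3 = h.pattern3.positions[n - 1 - i]
            if p5.is_literal and p3.is_literal and not d.pairing.allows(p5.symbol, p3.symbol):
                raise UnsatisfiablePairError(
                    f"helix {name!r}: literal pair {p5.symbol}:{p3.symbol} "
                    f"at position {i + 1} is not an allowed base pair")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_SS_RE = re.compile(r"^(?P<name>s\S*)\s+(?P<mm>\d+)\s+(?P<pat>\S+)$")
_HX_RE = re.compile(r"^(?P<name>h\S*)\s+(?P<a>\d+):(?P<b>\d+)\s+(?P<p5>\S+):(?P<p3>\S+)$")


def parse_descriptor(text: str, pairing: PairingRules | None = None) -> MotifDescriptor:
    """Parse descriptor-file contents into a validated :class:`MotifDescriptor`.

    Accepts ``#`` comment lines and blank lines; both ASCII apostrophe and the
    Unicode prime mark primed helix strands; ``T`` in patterns is normalised
    to ``U``.
    """
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(text.splitlines())]
    lines = [(i, ln) for i, ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise EmptyDescriptorError("descriptor has no content lines")
    map_line_no, map_line = lines[0]
    map_order = tuple(_canonical_id(tok) for tok in map_line.split())
    if not map_order:
        raise EmptyDescriptorError("empty map line", map_line_no)
    for tok in map_order:
        if not tok.rstrip("'").startswith(("s", "h")):
            raise MapDefinitionError(f"map id {tok!r} must start with 's' or 'h'", map_line_no)

    elements: dict[str, SingleStrandSpec | HelixSpec] = {}
    for line_no, ln in lines[1:]:
        m = _HX_RE.match(ln)
        if m:
            name = _canonical_id(m["name"]).rstrip("'")
            if name in elements:
                raise MapDefinitionError(f"element {name!r} defined twice", line_no)
            try:
                elements[name] = HelixSpec(
                    name=name,
                    mispair_allowance=int(m["a"]),
                    insertion_allowance=int(m["b"]),
                    pattern5=StrandPattern.from_text(m["p5"], line_no),
                    pattern3=StrandPattern.from_text(m["p3"], line_no),
                )
            except DescriptorError as e:
                raise type(e)(str(e), line_no) if e.line is None else e
            continue
        m = _SS_RE.match(ln)
        if m:
            name = _canonical_id(m["name"]).rstrip("'")
            if name in elements:
                raise MapDefinitionError(f"element {name!r} defined twice", line_no)
            try:
                elements[name] = SingleStrandSpec(
                    name=name,
                    max_mismatches=int(m["mm"]),
                    pattern=StrandPattern.from_text(m["pat"], line_no),
                )
            except DescriptorError as e:
                raise type(e)(str(e), line_no) if e.line is None else e
            continue
        raise MapDefinitionError(f"cannot parse element line {ln!r}", line_no)

    map_bases = {t.rstrip("'") for t in map_order}
    for name in elements:
        if name not in map_bases:
            raise MapDefinitionError(f"defined element {name!r} missing from map")
    for tok in map_order:
        if tok.rstrip("'") not in elements:
            raise MapDefinitionError(f"map id {tok!r} has no definition", map_line_no)

    return MotifDescriptor(map_order=map_order, elements=elements,
                           pairing=pairing or PairingRules())


def fouru_descriptor(pairing: PairingRules | None = None) -> MotifDescriptor:
    """The built-in fourU terminal-hairpin search descriptor."""
    return parse_descriptor(FOURU_DESCRIPTOR, pairing=pairing)


# ---------------------------------------------------------------------------
# Length accounting
# ---------------------------------------------------------------------------

def element_length_range(spec: SingleStrandSpec | HelixSpec) -> tuple[int, int]:
    """Per-strand realized length range (min, max) of an element."""
    if isinstance(spec, SingleStrandSpec):
        return spec.pattern.length_range()
    return spec.pattern5.length_range()


def descriptor_span_range(d: MotifDescriptor) -> tuple[int, int]:
    """Total realized span range; each helix strand counts once per map entry."""
    lo = hi = 0
    for token in d.map_order:
        el = d.element_for_token(token)
        if isinstance(el, HelixSpec):
            pat = el.pattern3 if token.endswith("'") else el.pattern5
            a, b = pat.length_range()
        else:
            a, b = el.pattern.length_range()
        lo, hi = lo + a, hi + b
    return lo, hi


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _base_probs(background_rules: Mapping[str, float] | None) -> np.ndarray:
    if background_rules is None:
        return np.full(4, 0.25)
    p = np.array([float(background_rules.get(b, 0.0)) for b in RNA_BASES])
    if p.sum() <= 0:
        raise ValueError("background distribution must have positive mass")
    return p / p.sum()


def sample_instance(
    d: MotifDescriptor,
    rng: np.random.Generator | int | None = None,
    background_rules: Mapping[str, float] | None = None,
) -> tuple[str, dict[str, tuple[int, int, str]]]:
    """Draw one random sequence realizing the descriptor.

    Returns ``(sequence, truth)`` where ``truth`` maps each map token to its
    ``(start, end, realized)`` span within the sequence.  ``N`` positions are
    filled from the background distribution, helix 3' strands are filled with
    allowed partners of the 5' realization subject to both strands' literals,
    and optional positions are present with probability 0.5 (jointly for the
    corresponding optional pairs of a helix).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    probs = _base_probs(background_rules)

    def draw_base(allowed: Sequence[str]) -> str:
        idx = [RNA_BASES.index(b) for b in allowed]
        p = probs[idx]
        if p.sum() <= 0:
            p = np.full(len(idx), 1.0 / len(idx))
        else:
            p = p / p.sum()
        return allowed[rng.choice(len(allowed), p=p)]

    helix_real: dict[str, tuple[str, str]] = {}
    for name in d.helix_names:
        h = d.elements[name]
        assert isinstance(h, HelixSpec)
        k = len(h.joint_optionals)
        present = tuple(bool(rng.random() < 0.5) for _ in range(k))
        five_idx = [i for i in h.pattern5.optional_indices]
        three_idx = list(reversed(h.pattern3.optional_indices))
        keep5 = {five_idx[i]: present[i] for i in range(k)}
        keep3 = {three_idx[i]: present[i] for i in range(k)}
        pos5 = [p for i, p in enumerate(h.pattern5.positions) if not p.optional or keep5[i]]
        pos3 = [p for i, p in enumerate(h.pattern3.positions) if not p.optional or keep3[i]]
        L = len(pos5)
        s5, s3 = [""] * L, [""] * L
        for i in range(L):
            p5, p3 = pos5[i], pos3[L - 1 - i]
            cand = []
            for b5 in RNA_BASES:
                if p5.is_literal and b5 != p5.symbol:
                    continue
                for b3 in RNA_BASES:
                    if p3.is_literal and b3 != p3.symbol:
                        continue
                    if d.pairing.allows(b5, b3):
                        cand.append((b5, b3))
            if not cand:
                raise UnsatisfiablePairError(
                    f"helix {name!r}: no allowed pair satisfies "
                    f"{p5.symbol}:{p3.symbol} at stack position {i + 1}")
            b5, b3 = cand[rng.choice(len(cand))]
            s5[i], s3[L - 1 - i] = b5, b3
        helix_real[name] = ("".join(s5), "".join(s3))

    seq_parts: list[str] = []
    truth: dict[str, tuple[int, int, str]] = {}
    pos = 0
    for token in d.map_order:
        el = d.element_for_token(token)
        if isinstance(el, HelixSpec):
            realized = helix_real[el.name][1 if token.endswith("'") else 0]
        else:
            out = []
            for p in el.pattern.positions:
                if p.optional and rng.random() >= 0.5:
                    continue
                out.append(p.symbol if p.is_literal else draw_base(RNA_BASES))
            realized = "".join(out)
        seq_parts.append(realized)
        truth[token] = (pos, pos + len(realized), realized)
        pos += len(realized)
    return "".join(seq_parts), truth


__all__ = [
    "FOURU_DESCRIPTOR", "RNA_BASES", "IUPAC_CODES",
    "PatternPosition", "StrandPattern", "SingleStrandSpec", "HelixSpec",
    "PairingRules", "MotifDescriptor",
    "parse_descriptor", "fouru_descriptor",
    "element_length_range", "descriptor_span_range", "sample_instance",
    "DescriptorError", "EmptyDescriptorError", "MapDefinitionError",
    "HelixStrandCountError", "CrossingHelixError", "UnknownSymbolError",
    "AllowanceError", "UnsupportedFeatureError", "UnsatisfiablePairError",
]
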