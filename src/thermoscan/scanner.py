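"""Locate descriptor occurrences in nucleotide sequences.

Two implementations with an identical output contract:

* :func:`scan_sequence` — anchored backtracking over the descriptor map with
  literal-run prefiltering; the production path.
* :func:`brute_force_scan` — exhaustive enumeration over start positions and
  per-element pattern variants; the testing oracle for small inputs.

Coordinates are 0-based half-open on the forward reference.  Minus-strand
matches are found on the reverse complement and reported in forward
coordinates with strand ``-``; their spans keep descriptor (map) order, so on
the minus strand span coordinates descend along the forward axis while the
realized strings read 5'→3' along the motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .descriptor import (
    IUPAC_CODES,
    HelixSpec,
    MotifDescriptor,
    SingleStrandSpec,
)

_COMPLEMENT = str.maketrans("ACGUNRYSWKMBDHV", "UGCANYRSWMKVHDB")


class ScanError(ValueError):
    pass


class InvalidSequenceError(ScanError):
    """Subject contains characters outside the IUPAC nucleotide alphabet."""


class InvalidMatchError(ScanError):
    """A MotifMatch is structurally inconsistent with its sequence/descriptor."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, DNA→RNA (T→U); reject non-IUPAC characters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - IUPAC_CODES
    if bad:
        raise InvalidSequenceError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _symbol_matches(sym: str, subject: str) -> bool:
    # pattern N matches any subject code; literals require an exact letter
    return sym == "N" or subject == sym


def _mismatches(variant: str, window: str) -> int:
    return sum(1 for s, w in zip(variant, window) if not _symbol_matches(s, w))


@dataclass(frozen=True)
class ElementSpan:
    """One realized element (or helix strand) of a match."""

    element_id: str
    start: int
    end: int
    realized: str
    mask: tuple[bool, ...] = ()   # which optional positions are present

    def __post_init__(self):
        if self.end < self.start:
            raise InvalidMatchError(f"{self.element_id}: end < start")


@dataclass(frozen=True)
class MotifMatch:
    sequence_id: str
    strand: str
    start: int
    end: int
    spans: tuple[ElementSpan, ...]

    @property
    def score(self) -> int:
        """Total realized length."""
        return self.end - self.start

    @property
    def realized(self) -> str:
        """Motif sequence 5'→3' (reverse-complement side for minus strand)."""
        return "".join(s.realized for s in self.spans)

    def span_for(self, token: str) -> ElementSpan:
        for s in self.spans:
            if s.element_id == token:
                return s
        raise KeyError(token)

    def sort_key(self):
        return (self.start, self.end - self.start,
                tuple((s.start, s.end, s.realized) for s in self.spans))


@dataclass(frozen=True)
class ScanConfig:
    strand_mode: str = "both"                 # {forward, both}
    overlap_policy: str = "report_all"        # {report_all, leftmost_shortest_per_start}
    max_matches: int | None = None

    def __post_init__(self):
        if self.strand_mode not in ("forward", "both"):
            raise ScanError(f"unknown strand_mode {self.strand_mode!r}")
        if self.overlap_policy not in ("report_all", "leftmost_shortest_per_start"):
            raise ScanError(f"unknown overlap_policy {self.overlap_policy!r}")


# ---------------------------------------------------------------------------
# Shared variant tables
# ---------------------------------------------------------------------------

def _element_options(d: MotifDescriptor):
    """Per-helix joint variants and per-ss variants, keyed by element name."""
    ss_opts: dict[str, list[tuple[str, tuple[bool, ...]]]] = {}
    hx_opts: dict[str, list[tuple[str, str, tuple[bool, ...]]]] = {}
    for name, el in d.elements.items():
        if isinstance(el, SingleStrandSpec):
            ss_opts[name] = [(v, m) for v, m in el.pattern.variants().items()]
        else:
            hx_opts[name] = el.strand_variants()
    return ss_opts, hx_opts


def _pair_violations(d: MotifDescriptor, w5: str, w3: str) -> int:
    L = len(w5)
    return sum(1 for i in range(L) if not d.pairing.allows(w5[i], w3[L - 1 - i]))


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_scan(seq: str, d: MotifDescriptor, cfg: ScanConfig | None = None,
                     sequence_id: str = "seq") -> list[MotifMatch]:
    """Exhaustive reference scan: every start × every per-element variant
    combination is materialised and checked independently.  Intended for
    sequences up to a few hundred nucleotides."""
    cfg = cfg or ScanConfig()
    s = normalize_sequence(seq)
    matches = _bf_one_strand(s, d, "+", sequence_id)
    if cfg.strand_mode == "both":
        rc = revcomp(s)
        matches += [_flip_match(m, len(s)) for m in _bf_one_strand(rc, d, "-", sequence_id)]
    return _finalize(matches, cfg)


def _bf_one_strand(s: str, d: MotifDescriptor, strand: str, sequence_id: str) -> list[MotifMatch]:
    ss_opts, hx_opts = _element_options(d)
    helix_order = [t for t in d.map_order if t.rstrip("'") != t or
                   isinstance(d.element_for_token(t), HelixSpec)]
    helices = list(dict.fromkeys(t.rstrip("'") for t in helix_order))
    out: list[MotifMatch] = []

    def combos(idx: int, choice: dict[str, int]):
        if idx == len(helices):
            yield dict(choice)
            return
        name = helices[idx]
        for i in range(len(hx_opts[name])):
            choice[name] = i
            yield from combos(idx + 1, choice)

    ss_names = [t for t in d.map_order if t in ss_opts]

    def ss_combos(idx: int, choice: dict[str, int]):
        if idx == len(ss_names):
            yield dict(choice)
            return
        name = ss_names[idx]
        for i in range(len(ss_opts[name])):
            choice[name] = i
            yield from ss_combos(idx + 1, choice)

    n = len(s)
    for hx_choice in combos(0, {}):
        for ss_choice in ss_combos(0, {}):
            # fully determined segmentation lengths
            lengths = []
            for token in d.map_order:
                base = token.rstrip("'")
                if base in hx_opts:
                    v5, v3, _ = hx_opts[base][hx_choice[base]]
                    lengths.append(len(v3) if token.endswith("'") else len(v5))
                else:
                    lengths.append(len(ss_opts[base][ss_choice[base]][0]))
            total = sum(lengths)
            for start in range(0, n - total + 1):
                spans = []
                pos = start
                ok = True
                realized5: dict[str, str] = {}
                for token, L in zip(d.map_order, lengths):
                    base = token.rstrip("'")
                    window = s[pos:pos + L]
                    if base in hx_opts:
                        v5, v3, mask = hx_opts[base][hx_choice[base]]
                        el = d.elements[base]
                        if token.endswith("'"):
                            if _mismatches(v3, window) > 0:
                                ok = False
                                break
                            if _pair_violations(d, realized5[base], window) > el.mispair_allowance:
                                ok = False
                                break
                        else:
                            if _mismatches(v5, window) > 0:
                                ok = False
                                break
                            realized5[base] = window
                        spans.append(ElementSpan(token, pos, pos + L, window, mask))
                    else:
                        variant, mask = ss_opts[base][ss_choice[base]]
                        if _mismatches(variant, window) > d.elements[base].max_mismatches:
                            ok = False
                            break
                        spans.append(ElementSpan(token, pos, pos + L, window, mask))
                    pos += L
                if ok:
                    out.append(MotifMatch(sequence_id, strand, start, start + total,
                                          tuple(spans)))
    return out


# ---------------------------------------------------------------------------
# Anchored backtracking scanner
# ---------------------------------------------------------------------------

def _best_anchor(d: MotifDescriptor):
    """Longest fixed literal run that every match must contain verbatim.

    Only elements that cannot mismatch qualify (helix literals are always
    exact; single strands only when max_mismatches == 0).  Returns
    ``(literal, min_offset, max_offset)`` where the offsets bound the distance
    from a match start to the run start, or None when no run of length >= 3
    exists.
    """
    best = None  # (length, literal, token_index, run_start_in_pattern)
    for ti, token in enumerate(d.map_order):
        el = d.element_for_token(token)
        if isinstance(el, SingleStrandSpec):
            if el.max_mismatches > 0:
                continue
            pat = el.pattern
        else:
            pat = el.pattern3 if token.endswith("'") else el.pattern5
        run = []
        for i, p in enumerate(pat.positions):
            if p.is_literal and not p.optional:
                run.append((i, p.symbol))
            else:
                run = []
            if run and (best is None or len(run) > best[0]):
                best = (len(run), "".join(sym for _, sym in run), ti, run[0][0])
    if best is None or best[0] < 3:
        return None
    _, literal, ti, pat_idx = best
    lo = hi = 0
    for token in d.map_order[:ti]:
        el = d.element_for_token(token)
        if isinstance(el, HelixSpec):
            a, b = (el.pattern3 if token.endswith("'") else el.pattern5).length_range()
        else:
            a, b = el.pattern.length_range()
        lo, hi = lo + a, hi + b
    token = d.map_order[ti]
    el = d.element_for_token(token)
    pat = (el.pattern3 if token.endswith("'") else el.pattern5) \
        if isinstance(el, HelixSpec) else el.pattern
    n_opt_before = sum(1 for p in pat.positions[:pat_idx] if p.optional)
    n_fixed_before = pat_idx - n_opt_before
    return literal, lo + n_fixed_before, hi + n_fixed_before + n_opt_before


def _candidate_starts(s: str, d: MotifDescriptor) -> list[int] | None:
    anchor = _best_anchor(d)
    if anchor is None:
        return None
    literal, off_lo, off_hi = anchor
    starts: set[int] = set()
    for m in re.finditer("(?=" + literal + ")", s):
        p = m.start()
        starts.update(range(max(0, p - off_hi), p - off_lo + 1))
    return sorted(starts)


def scan_sequence(seq: str, d: MotifDescriptor, cfg: ScanConfig | None = None,
                  sequence_id: str = "seq") -> list[MotifMatch]:
    """Find every descriptor occurrence in ``seq`` (see module docstring)."""
    cfg = cfg or ScanConfig()
    if not seq:
        raise InvalidSequenceError("empty sequence")
    if not d.map_order:
        raise ScanError("empty descriptor")
    s = normalize_sequence(seq)
    matches = _scan_one_strand(s, d, "+", sequence_id)
    if cfg.strand_mode == "both":
        rc = revcomp(s)
        matches += [_flip_match(m, len(s)) for m in _scan_one_strand(rc, d, "-", sequence_id)]
    return _finalize(matches, cfg)


def _scan_one_strand(s: str, d: MotifDescriptor, strand: str, sequence_id: str) -> list[MotifMatch]:
    ss_opts, hx_opts = _element_options(d)
    n = len(s)
    order = d.map_order
    out: list[MotifMatch] = []

    def extend(ei: int, pos: int, spans: list[ElementSpan],
               hx_choice: dict[str, tuple[str, str, tuple[bool, ...], str]]):
        if ei == len(order):
            out.append(MotifMatch(sequence_id, strand, spans[0].start, pos, tuple(spans)))
            return
        token = order[ei]
        base = token.rstrip("'")
        el = d.elements[base]
        if isinstance(el, SingleStrandSpec):
            for variant, mask in ss_opts[base]:
                L = len(variant)
                if pos + L > n:
                    continue
                window = s[pos:pos + L]
                if _mismatches(variant, window) > el.max_mismatches:
                    continue
                spans.append(ElementSpan(token, pos, pos + L, window, mask))
                extend(ei + 1, pos + L, spans, hx_choice)
                spans.pop()
        elif token.endswith("'"):
            v5, v3, mask, w5 = hx_choice[base]
            L = len(v3)
            if pos + L > n:
                return
            window = s[pos:pos + L]
            if _mismatches(v3, window) > 0:
                return
            if _pair_violations(d, w5, window) > el.mispair_allowance:
                return
            spans.append(ElementSpan(token, pos, pos + L, window, mask))
            extend(ei + 1, pos + L, spans, hx_choice)
            spans.pop()
        else:
            for v5, v3, mask in hx_opts[base]:
                L = len(v5)
                if pos + L > n:
                    continue
                window = s[pos:pos + L]
                if _mismatches(v5, window) > 0:
                    continue
                hx_choice[base] = (v5, v3, mask, window)
                spans.append(ElementSpan(token, pos, pos + L, window, mask))
                extend(ei + 1, pos + L, spans, hx_choice)
                spans.pop()
                del hx_choice[base]

    starts = _candidate_starts(s, d)
    if starts is None:
        starts = range(n)
    for start in starts:
        extend(0, start, [], {})
    return out


# ---------------------------------------------------------------------------
# Post-processing shared by both implementations
# ---------------------------------------------------------------------------

def _flip_match(m: MotifMatch, seq_len: int) -> MotifMatch:
    spans = tuple(ElementSpan(sp.element_id, seq_len - sp.end, seq_len - sp.start,
                              sp.realized, sp.mask) for sp in m.spans)
    return MotifMatch(m.sequence_id, m.strand, seq_len - m.end, seq_len - m.start, spans)


def _finalize(matches: list[MotifMatch], cfg: ScanConfig) -> list[MotifMatch]:
    # distinct optional-subset choices can realize identical spans; keep one
    # canonical representative (smallest mask tuple) so output is reproducible
    full = sorted(matches, key=lambda m: (m.sort_key(), m.strand,
                                          tuple(sp.mask for sp in m.spans)))
    ordered: list[MotifMatch] = []
    seen_keys: set = set()
    for m in full:
        key = (m.strand, m.sort_key())
        if key not in seen_keys:
            seen_keys.add(key)
            ordered.append(m)
    if cfg.overlap_policy == "leftmost_shortest_per_start":
        seen: set[tuple[str, int]] = set()
        kept = []
        for m in ordered:
            key = (m.strand, m.start)
            if key not in seen:
                seen.add(key)
                kept.append(m)
        ordered = kept
    if cfg.max_matches is not None:
        ordered = ordered[:cfg.max_matches]
    return ordered


# ---------------------------------------------------------------------------
# Post-hoc validation
# ---------------------------------------------------------------------------

def verify_match(seq: str, d: MotifDescriptor, m: MotifMatch) -> bool:
    """Re-check a match against sequence and descriptor.

    Raises :class:`InvalidMatchError` for structural problems (out-of-bounds
    or non-contiguous spans); returns False when the realized strings violate
    pattern or pairing constraints.
    """
    s = normalize_sequence(seq)
    if m.start < 0 or m.end > len(s) or len(m.spans) != len(d.map_order):
        raise InvalidMatchError("match out of bounds or span count mismatch")
    if m.strand == "-":
        s = revcomp(s)
        spans = [ElementSpan(sp.element_id, len(seq) - sp.end, len(seq) - sp.start,
                             sp.realized, sp.mask) for sp in m.spans]
        start, end = len(seq) - m.end, len(seq) - m.start
    else:
        spans, start, end = list(m.spans), m.start, m.end
    pos = start
    for token, sp in zip(d.map_order, spans):
        if sp.element_id != token or sp.start != pos or sp.end < sp.start or sp.end > len(s):
            raise InvalidMatchError(f"span {sp.element_id!r} not contiguous at {pos}")
        if s[sp.start:sp.end] != sp.realized:
            raise InvalidMatchError(f"span {sp.element_id!r} realized string disagrees with sequence")
        pos = sp.end
    if pos != end:
        raise InvalidMatchError("spans do not cover match interval")

    realized5: dict[str, str] = {}
    for token, sp in zip(d.map_order, spans):
        base = token.rstrip("'")
        el = d.elements[base]
        if isinstance(el, SingleStrandSpec):
            opts = dict(el.pattern.variants())
            good = any(len(v) == len(sp.realized) and
                       _mismatches(v, sp.realized) <= el.max_mismatches
                       for v in opts)
            if not good:
                return False
        else:
            variants = el.strand_variants()
            idx = 1 if token.endswith("'") else 0
            if not any(len(v[idx]) == len(sp.realized) and
                       _mismatches(v[idx], sp.realized) == 0 for v in variants):
                return False
            if token.endswith("'"):
                w5 = realized5.get(base)
                if w5 is None or len(w5) != len(sp.realized):
                    return False
                if _pair_violations(d, w5, sp.realized) > el.mispair_allowance:
                    return False
            else:
                realized5[base] = sp.realized
    return True


__all__ = [
    "ElementSpan", "MotifMatch", "ScanConfig",
    "scan_sequence", "brute_force_scan", "verify_match",
    "normalize_sequence", "revcomp",
    "ScanError", "InvalidSequenceError", "InvalidMatchError",
]
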