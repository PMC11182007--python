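"""Turn raw motif matches into ranked thermometer candidates.

Hard rules, each recorded as a named pass/fail flag on the candidate:

* ``sd_anchored``  — the descriptor carries an SD literal block in a helix 3'
  strand and an AUG anchor in its final single-strand element.
* ``fourU``        — the SD-paired strand contains a run of >= 4 U's whose
  partners overlap the SD block.
* ``wobble``       — that duplex region contains >= 2 G•U wobble pairs.
* ``spacing``      — the SD sits an acceptable distance upstream of the AUG.
* ``gene_link``    — the match lies directly in the 5'-UTR of an annotated
  gene (or, in ``orf_free`` mode, is followed by a long enough ORF).

Failing candidates are kept (sorted after all passers) so reports show why
each locus was rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import structure
from .descriptor import HelixSpec, MotifDescriptor, SingleStrandSpec
from .scanner import ElementSpan, MotifMatch


class CurationError(ValueError):
    pass


class NotSDAnchoredError(CurationError):
    """Descriptor lacks SD literals in a helix 3' strand or an AUG anchor."""


@dataclass(frozen=True)
class GeneAnnotation:
    sequence_id: str
    start: int          # 0-based half-open
    end: int
    strand: str
    gene_id: str
    product: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise CurationError(f"{self.gene_id}: end must exceed start")

    @property
    def cds_start(self) -> int:
        """Position of the first transcribed base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class FilterConfig:
    sd_spacing_min: int = 5
    sd_spacing_max: int = 10
    min_wobble_pairs: int = 2
    fourU_run_min: int = 4
    annotation_mode: str = "annotated"          # {annotated, orf_free}
    min_orf_codons: int = 50
    # "from_sd_end" counts nucleotides strictly between the SD 3' end and the
    # A of the AUG; this is the reading under which the built-in descriptor's
    # geometric range (7-10 nt) falls inside the canonical 5-10 nt window.
    spacing_convention: str = "from_sd_end"     # {from_sd_start, from_sd_end}

    def __post_init__(self):
        if not (0 <= self.sd_spacing_min <= self.sd_spacing_max):
            raise CurationError("require 0 <= sd_spacing_min <= sd_spacing_max")
        if self.annotation_mode not in ("annotated", "orf_free"):
            raise CurationError(f"unknown annotation_mode {self.annotation_mode!r}")
        if self.spacing_convention not in ("from_sd_start", "from_sd_end"):
            raise CurationError(f"unknown spacing_convention {self.spacing_convention!r}")


@dataclass(frozen=True)
class Candidate:
    match: MotifMatch
    sd_helix: str | None = None
    sd_local: tuple[int, int] | None = None      # motif-local SD span
    sd_span: ElementSpan | None = None           # reference-coordinate SD span
    start_codon_local: int | None = None
    start_codon_pos: int | None = None
    sd_spacing: int | None = None                # nt strictly between SD 3' end and the AUG
    fourU_local: tuple[int, int] | None = None
    wobble_count: int = 0
    hairpin_support: float = 0.0
    gene_link: GeneAnnotation | None = None
    gene_distance: int | None = None
    flags: tuple[tuple[str, bool], ...] = ()

    @property
    def flag_map(self) -> dict[str, bool]:
        return dict(self.flags)

    @property
    def all_pass(self) -> bool:
        return all(v for _, v in self.flags)

    def rank_key(self):
        dist = self.gene_distance if self.gene_distance is not None else 10 ** 9
        return (0 if self.all_pass else 1, dist, -self.hairpin_support,
                -self.wobble_count, self.match.start, self.match.strand)


# ---------------------------------------------------------------------------
# Descriptor anchors: SD literal block + AUG
# ---------------------------------------------------------------------------

def _literal_runs(positions) -> list[tuple[int, int, str]]:
    """Contiguous non-optional literal runs as (start, end, text)."""
    runs, cur = [], []
    for i, p in enumerate(positions):
        if p.is_literal and not p.optional:
            cur.append((i, p.symbol))
        elif cur:
            runs.append((cur[0][0], cur[-1][0] + 1, "".join(c for _, c in cur)))
            cur = []
    if cur:
        runs.append((cur[0][0], cur[-1][0] + 1, "".join(c for _, c in cur)))
    return runs


def sd_anchor(d: MotifDescriptor) -> tuple[str, tuple[int, int], str, int]:
    """Locate the SD block and AUG anchor in the *descriptor*.

    Returns ``(helix_name, (run_start, run_end) in the 3' pattern,
    final_ss_name, aug_offset_in_fixed_positions)``.  The SD block is the
    longest literal run among helix 3'-strand patterns (ties: the helix whose
    3' strand occurs last on the map); the AUG must be a fixed literal run of
    the final map element, a single strand.
    """
    best: tuple[int, int, str, tuple[int, int]] | None = None
    primed_pos = {t[:-1]: i for i, t in enumerate(d.map_order) if t.endswith("'")}
    for name in d.helix_names:
        h = d.elements[name]
        assert isinstance(h, HelixSpec)
        for start, end, text in _literal_runs(h.pattern3.positions):
            key = (end - start, primed_pos[name])
            if best is None or key > best[:2]:
                best = (end - start, primed_pos[name], name, (start, end))
    if best is None or best[0] < 3:
        raise NotSDAnchoredError("no SD literal block in any helix 3' strand")
    sd_helix, sd_run = best[2], best[3]

    last = d.map_order[-1]
    el = d.elements.get(last)
    if not isinstance(el, SingleStrandSpec):
        raise NotSDAnchoredError("final map element is not a single strand")
    aug_off = None
    for start, end, text in _literal_runs(el.pattern.positions):
        idx = text.find("AUG")
        if idx >= 0:
            aug_off = start + idx
            break
    if aug_off is None:
        raise NotSDAnchoredError("final single strand lacks an AUG anchor")
    n_opt_before = sum(1 for p in el.pattern.positions[:aug_off] if p.optional)
    return sd_helix, sd_run, last, aug_off - n_opt_before


def _local_offsets(m: MotifMatch) -> dict[str, int]:
    """Motif-local (5'→3') start offset of every element span."""
    out, pos = {}, 0
    for sp in m.spans:
        out[sp.element_id] = pos
        pos += len(sp.realized)
    return out


def _pattern_to_realized(positions, mask: tuple[bool, ...], pat_idx: int) -> int:
    """Map a pattern index to its realized-string index given a present-mask."""
    it = iter(mask)
    realized = 0
    for i, p in enumerate(positions):
        present = next(it) if p.optional else True
        if i == pat_idx:
            return realized
        if present:
            realized += 1
    raise CurationError("pattern index out of range")


def _helix_mask3(h: HelixSpec, joint_mask: tuple[bool, ...]) -> tuple[bool, ...]:
    """Present-mask of the 3' pattern implied by the joint optional mask."""
    three = tuple(reversed(h.pattern3.optional_indices))
    present = dict(zip(three, joint_mask))
    return tuple(present[i] for i in h.pattern3.optional_indices)


def locate_sd_and_start(m: MotifMatch, d: MotifDescriptor):
    """SD span and AUG position for one match.

    Returns ``(sd_span, start_codon_pos, info)`` where the span/position are
    in reference coordinates and ``info`` carries motif-local geometry used by
    the downstream rules.
    """
    sd_helix, (run_s, run_e), last_ss, aug_fixed_off = sd_anchor(d)
    h = d.elements[sd_helix]
    assert isinstance(h, HelixSpec)
    sp3 = m.span_for(sd_helix + "'")
    mask3 = _helix_mask3(h, sp3.mask)
    r_start = _pattern_to_realized(h.pattern3.positions, mask3, run_s)
    r_end = r_start + (run_e - run_s)

    sp5 = m.span_for(last_ss)
    aug_real = _pattern_to_realized(
        d.elements[last_ss].pattern.positions, sp5.mask,
        _fixed_to_pattern_index(d.elements[last_ss].pattern.positions, aug_fixed_off))

    local = _local_offsets(m)
    sd_local = (local[sd_helix + "'"] + r_start, local[sd_helix + "'"] + r_end)
    aug_local = local[last_ss] + aug_real

    sd_span = _local_to_reference(m, sd_local[0], sd_local[1], "SD")
    aug_ref = _local_to_reference(m, aug_local, aug_local + 3, "AUG")
    start_codon_pos = aug_ref.start if m.strand == "+" else aug_ref.end - 1
    info = {
        "sd_helix": sd_helix,
        "sd_local": sd_local,
        "aug_local": aug_local,
        "sd_spacing": aug_local - sd_local[1],
    }
    return sd_span, start_codon_pos, info


def _fixed_to_pattern_index(positions, fixed_off: int) -> int:
    seen = 0
    for i, p in enumerate(positions):
        if not p.optional:
            if seen == fixed_off:
                return i
            seen += 1
    raise CurationError("fixed offset out of range")


def _local_to_reference(m: MotifMatch, a: int, b: int, tag: str) -> ElementSpan:
    """Convert a motif-local [a, b) range to forward-reference coordinates."""
    if m.strand == "+":
        return ElementSpan(tag, m.start + a, m.start + b, m.realized[a:b])
    return ElementSpan(tag, m.end - b, m.end - a, m.realized[a:b])


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

def check_fourU(m: MotifMatch, d: MotifDescriptor, info: dict,
                cfg: FilterConfig | None = None):
    """fourU + wobble rule on the SD helix of a match.

    Returns ``(passed, fourU_local_span_or_None, wobble_count)``.  The rule
    looks for a run of >= ``fourU_run_min`` U's in the realized 5' strand
    whose antiparallel partners overlap the SD block, then counts G•U pairs
    over the union of that run and the positions pairing into the SD block.
    """
    cfg = cfg or FilterConfig()
    rules = d.pairing
    sd_helix = info["sd_helix"]
    sp5 = m.span_for(sd_helix)
    sp3 = m.span_for(sd_helix + "'")
    w5, w3 = sp5.realized, sp3.realized
    L = len(w5)
    local = _local_offsets(m)
    sd_s, sd_e = info["sd_local"]
    sd_in_strand = (sd_s - local[sd_helix + "'"], sd_e - local[sd_helix + "'"])

    def partner(i5: int) -> int:
        return L - 1 - i5

    # positions of the 5' strand whose partner lies inside the SD block
    sd_paired = {i for i in range(L) if sd_in_strand[0] <= partner(i) < sd_in_strand[1]}

    if cfg.fourU_run_min == 0 and cfg.min_wobble_pairs == 0:
        return True, None, _wobbles_in(w5, w3, set(range(L)))

    best_run: tuple[int, int] | None = None
    i = 0
    while i < L:
        if w5[i] == "U":
            j = i
            while j < L and w5[j] == "U":
                j += 1
            if j - i >= cfg.fourU_run_min and any(k in sd_paired for k in range(i, j)):
                if best_run is None or j - i > best_run[1] - best_run[0]:
                    best_run = (i, j)
            i = j
        else:
            i += 1
    if best_run is None:
        return False, None, _wobbles_in(w5, w3, sd_paired)
    region = set(range(*best_run)) | sd_paired
    wc = _wobbles_in(w5, w3, region)
    fourU_local = (local[sd_helix] + best_run[0], local[sd_helix] + best_run[1])
    return wc >= cfg.min_wobble_pairs, fourU_local, wc


def _wobbles_in(w5: str, w3: str, indices5: set[int]) -> int:
    L = len(w5)
    return sum(1 for i in sorted(indices5)
               if structure.classify_pair(w5[i], w3[L - 1 - i]) == "wobble")


def spacing_measure(info: dict, d: MotifDescriptor, cfg: FilterConfig) -> int:
    """Distance from the SD to the AUG under the configured convention.

    ``from_sd_end``: nucleotides strictly between the SD 3' end and the A of
    the AUG.  ``from_sd_start``: distance from the first SD base to the A.
    """
    if cfg.spacing_convention == "from_sd_end":
        return info["sd_spacing"]
    return info["aug_local"] - info["sd_local"][0]


def sd_spacing_ok(info: dict, d: MotifDescriptor, cfg: FilterConfig | None = None) -> bool:
    cfg = cfg or FilterConfig()
    v = spacing_measure(info, d, cfg)
    return cfg.sd_spacing_min <= v <= cfg.sd_spacing_max


def attach_annotation(m: MotifMatch, start_codon_pos: int,
                      annotations: list[GeneAnnotation]):
    """Link the gene whose annotated start coincides with the match AUG, else
    the nearest downstream gene start on the same strand.

    Returns ``(annotation_or_None, signed_distance_or_None)``; distance is in
    the direction of transcription (0 = exact 5'-UTR placement).
    """
    same = [a for a in annotations
            if a.sequence_id == m.sequence_id and a.strand == m.strand]
    best: tuple[int, GeneAnnotation] | None = None
    for a in same:
        if m.strand == "+":
            dist = a.start - start_codon_pos
        else:
            dist = start_codon_pos - (a.end - 1)
        if dist < 0:
            continue
        if best is None or dist < best[0]:
            best = (dist, a)
    if best is None:
        return None, None
    return best[1], best[0]


def orf_length_codons(seq: str, m: MotifMatch, start_codon_pos: int) -> int:
    """Sense codons (incl. the AUG) before the first in-frame stop."""
    from .scanner import normalize_sequence, revcomp
    s = normalize_sequence(seq)
    if m.strand == "-":
        s = revcomp(s)
        pos = len(s) - 1 - start_codon_pos
    else:
        pos = start_codon_pos
    stops = {"UAA", "UAG", "UGA"}
    n = 0
    while pos + 3 <= len(s):
        codon = s[pos:pos + 3]
        if codon in stops:
            return n
        n += 1
        pos += 3
    return n


# ---------------------------------------------------------------------------
# Assembly + ranking
# ---------------------------------------------------------------------------

def build_candidate(m: MotifMatch, d: MotifDescriptor,
                    annotations: list[GeneAnnotation] | None = None,
                    cfg: FilterConfig | None = None,
                    seq: str | None = None,
                    fold_cfg: structure.FoldConfig | None = None,
                    with_support: bool = True) -> Candidate:
    cfg = cfg or FilterConfig()
    annotations = annotations or []
    try:
        sd_span, start_codon_pos, info = locate_sd_and_start(m, d)
    except NotSDAnchoredError:
        return Candidate(match=m, flags=(("sd_anchored", False), ("fourU", False),
                                         ("wobble", False), ("spacing", False),
                                         ("gene_link", False)))
    passed_fourU, fourU_local, wc = check_fourU(m, d, info, cfg)
    run_ok = fourU_local is not None or (cfg.fourU_run_min == 0 and cfg.min_wobble_pairs == 0)
    spacing = sd_spacing_ok(info, d, cfg)

    link, dist = (None, None)
    if cfg.annotation_mode == "annotated":
        link, dist = attach_annotation(m, start_codon_pos, annotations)
        gene_ok = dist == 0
    else:
        if seq is None:
            raise CurationError("orf_free mode requires the subject sequence")
        codons = orf_length_codons(seq, m, start_codon_pos)
        gene_ok = codons >= cfg.min_orf_codons
        dist = 0 if gene_ok else None

    support = _fold_support(m, info, fold_cfg) if with_support else 0.0

    flags = (("sd_anchored", True),
             ("fourU", run_ok),
             ("wobble", passed_fourU),
             ("spacing", spacing),
             ("gene_link", gene_ok))
    return Candidate(match=m, sd_helix=info["sd_helix"], sd_local=info["sd_local"],
                     sd_span=sd_span, start_codon_local=info["aug_local"],
                     start_codon_pos=start_codon_pos, sd_spacing=info["sd_spacing"],
                     fourU_local=fourU_local, wobble_count=wc,
                     hairpin_support=support, gene_link=link, gene_distance=dist,
                     flags=flags)


def implied_helix_pairs(m: MotifMatch, sd_helix: str) -> list[tuple[int, int]]:
    """Motif-local index pairs implied by the SD helix of a match."""
    local = _local_offsets(m)
    sp5, sp3 = m.span_for(sd_helix), m.span_for(sd_helix + "'")
    L = len(sp5.realized)
    o5, o3 = local[sd_helix], local[sd_helix + "'"]
    return [(o5 + i, o3 + L - 1 - i) for i in range(L)]


def _fold_support(m: MotifMatch, info: dict,
                  fold_cfg: structure.FoldConfig | None) -> float:
    s = structure.nussinov_fold(m.realized, fold_cfg)
    return structure.hairpin_support(implied_helix_pairs(m, info["sd_helix"]), s)


def filter_and_rank(matches: list[MotifMatch], d: MotifDescriptor,
                    annotations: list[GeneAnnotation] | None = None,
                    cfg: FilterConfig | None = None,
                    seqs: dict[str, str] | None = None,
                    fold_cfg: structure.FoldConfig | None = None,
                    with_support: bool = True) -> list[Candidate]:
    """Curate matches into a deterministic total order: all-pass candidates
    first (nearest gene, strongest hairpin support, most wobbles, leftmost),
    then failures with their diagnostic flags."""
    cfg = cfg or FilterConfig()
    out = []
    for m in matches:
        seq = (seqs or {}).get(m.sequence_id)
        out.append(build_candidate(m, d, annotations, cfg, seq=seq,
                                   fold_cfg=fold_cfg, with_support=with_support))
    return sorted(out, key=lambda c: c.rank_key())


__all__ = [
    "GeneAnnotation", "FilterConfig", "Candidate",
    "sd_anchor", "locate_sd_and_start", "check_fourU", "sd_spacing_ok",
    "spacing_measure", "attach_annotation", "orf_length_codons",
    "build_candidate", "filter_and_rank", "implied_helix_pairs",
    "CurationError", "NotSDAnchoredError",
]
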