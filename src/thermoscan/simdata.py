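"""Synthetic genomes with planted motif instances, decoys, annotations, and
simulated reporter-assay readings.

Everything is driven by one seeded :class:`numpy.random.Generator`, so a
fixed seed reproduces fixtures byte for byte.  Backgrounds are i.i.d. with a
configurable GC fraction; each planted instance is followed by an open
reading frame starting at the instance's AUG so that annotation-based
curation has ground truth to link against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assay import AssayMeasurement
from .curation import GeneAnnotation, sd_anchor
from .descriptor import (
    HelixSpec,
    MotifDescriptor,
    RNA_BASES,
    sample_instance,
)
from .structure import classify_pair

STOP_CODONS = ("UAA", "UAG", "UGA")
DECOY_KINDS = ("shuffled", "pairing_broken", "sd_removed")


class SimError(ValueError):
    pass


@dataclass(frozen=True)
class PlantTruth:
    sequence_id: str
    name: str
    start: int
    end: int
    spans: tuple[tuple[str, int, int, str], ...]   # (token, start, end, realized)
    orf_start: int | None = None
    orf_end: int | None = None
    decoy: bool = False
    decoy_class: str | None = None


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 100_000
    gc_content: float = 0.5
    n_plants: int = 10
    n_decoys: int = 0
    seed: int = 0
    orf_codons: int = 50
    sequence_id: str = "synthetic_1"

    def __post_init__(self):
        if not (0 < self.gc_content < 1):
            raise SimError("gc_content must be in (0, 1)")
        if self.genome_length < 1 or self.n_plants < 0 or self.n_decoys < 0:
            raise SimError("invalid sizes")
        if self.orf_codons < 1:
            raise SimError("orf_codons must be >= 1")


def _background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(RNA_BASES)[rng.choice(4, size=n, p=p)])


def _rand_base(rng: np.random.Generator, exclude: str = "") -> str:
    options = [b for b in RNA_BASES if b not in exclude]
    return options[rng.integers(len(options))]


def _orf_tail(rng: np.random.Generator, head: str, orf_codons: int) -> str:
    """Extend ``head`` (bases already emitted after the AUG) into an ORF of
    ``orf_codons`` sense codons (AUG included) plus one stop codon.

    Returns only the bases to append after the instance.  Raises
    :class:`SimError` when the fixed head already contains an in-frame stop.
    """
    need = 3 * orf_codons  # total bases from A of AUG, AUG itself included
    emitted = "AUG" + head
    if len(emitted) > need:
        raise SimError("instance tail longer than requested ORF")
    for i in range(0, len(emitted) - 2, 3):
        if emitted[i:i + 3] in STOP_CODONS:
            raise SimError("premature stop codon inside planted instance")
    tail: list[str] = []
    total = len(emitted)
    rem = total % 3
    if rem:
        prefix = emitted[total - rem:]
        while True:
            add = [_rand_base(rng) for _ in range(3 - rem)]
            if prefix + "".join(add) not in STOP_CODONS:
                break
        tail += add
        total += len(add)
    while total < need:
        while True:
            codon = [_rand_base(rng) for _ in range(3)]
            if "".join(codon) not in STOP_CODONS:
                break
        tail += codon
        total += 3
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "".join(tail) + stop


def generate_genome(d: MotifDescriptor, cfg: SimConfig):
    """Build one synthetic sequence with planted instances and decoys.

    Returns ``(records, annotations, truth)`` where ``records`` is a list of
    ``(sequence_id, sequence)`` tuples, ``annotations`` are CDS features for
    the planted ORFs, and ``truth`` rows locate every plant/decoy.
    """
    rng = np.random.default_rng(cfg.seed)

    blocks: list[tuple[str, dict, str | None, bool, str | None]] = []
    for i in range(cfg.n_plants):
        for _ in range(100):
            try:
                seq, truth = sample_instance(d, rng)
                aug_local = _aug_local(d, truth)
                tail = _orf_tail(rng, seq[aug_local + 3:], cfg.orf_codons)
                break
            except SimError:
                continue
        else:
            raise SimError("could not sample a stop-free planted instance")
        blocks.append((seq + tail, truth, tail, False, None))
    for i in range(cfg.n_decoys):
        kind = DECOY_KINDS[i % len(DECOY_KINDS)]
        seq, truth = sample_instance(d, rng)
        decoy = make_decoy(seq, truth, d, kind, rng)
        blocks.append((decoy, truth, None, True, kind))

    total_block = sum(len(b[0]) for b in blocks)
    n_bg = cfg.genome_length - total_block
    k = len(blocks)
    if n_bg < k + 1:
        raise SimError(
            f"infeasible packing: {total_block} nt of blocks in a "
            f"{cfg.genome_length} nt genome")

    # split background into k+1 positive gaps (distinct cut points)
    if k:
        cuts = np.sort(rng.choice(n_bg - 1, size=k, replace=False) + 1)
        gap_bounds = np.concatenate(([0], cuts, [n_bg]))
        gaps = np.diff(gap_bounds)
    else:
        gaps = np.array([n_bg])

    parts: list[str] = []
    truth_rows: list[PlantTruth] = []
    annotations: list[GeneAnnotation] = []
    pos = 0
    n_plant = n_decoy = 0
    for bi, (block, truth, tail, is_decoy, kind) in enumerate(blocks):
        bg = _background(rng, int(gaps[bi]), cfg.gc_content)
        parts.append(bg)
        pos += len(bg)
        parts.append(block)
        inst_len = sum(e - s for (s, e, _r) in truth.values())
        spans = tuple((tok, pos + s, pos + e, r) for tok, (s, e, r) in truth.items())
        if is_decoy:
            n_decoy += 1
            spans = tuple((tok, s, e, block[s - pos:e - pos])
                          for tok, s, e, _r in spans)
            truth_rows.append(PlantTruth(
                cfg.sequence_id, f"decoy_{n_decoy}", pos, pos + len(block),
                spans, decoy=True, decoy_class=kind))
        else:
            n_plant += 1
            aug = pos + _aug_local_from_truth(truth)
            orf_end = aug + 3 * cfg.orf_codons + 3   # incl. stop codon
            truth_rows.append(PlantTruth(
                cfg.sequence_id, f"plant_{n_plant}", pos, pos + inst_len,
                spans, orf_start=aug, orf_end=orf_end))
            annotations.append(GeneAnnotation(
                cfg.sequence_id, aug, orf_end, "+", f"gene_{n_plant}",
                product=f"synthetic ORF downstream of plant_{n_plant}"))
        pos += len(block)
    parts.append(_background(rng, int(gaps[-1]), cfg.gc_content))
    genome = "".join(parts)
    assert len(genome) == cfg.genome_length
    return [(cfg.sequence_id, genome)], annotations, truth_rows


def _aug_local(d: MotifDescriptor, truth: dict) -> int:
    return _aug_local_from_truth(truth, d)


def _aug_local_from_truth(truth: dict, d: MotifDescriptor | None = None) -> int:
    # the AUG sits in the final map element; find it in that realized string
    last_tok = max(truth, key=lambda t: truth[t][0])
    s, _e, realized = truth[last_tok]
    idx = realized.find("AUG")
    if idx < 0:
        raise SimError("no AUG in final element realization")
    return s + idx


# ---------------------------------------------------------------------------
# Decoys
# ---------------------------------------------------------------------------

def make_decoy(seq: str, truth: dict, d: MotifDescriptor, kind: str,
               rng: np.random.Generator) -> str:
    if kind == "shuffled":
        return dinucleotide_shuffle(seq, rng)
    if kind == "pairing_broken":
        return _break_pairing(seq, truth, d, rng)
    if kind == "sd_removed":
        return _remove_sd(seq, truth, d, rng)
    raise SimError(f"unknown decoy kind {kind!r}")


def make_decoys(instances: list[tuple[str, dict]], d: MotifDescriptor, kind: str,
                rng: np.random.Generator | int | None = None) -> list[str]:
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return [make_decoy(seq, truth, d, kind, rng) for seq, truth in instances]


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Doublet-preserving shuffle (random Eulerian walk on the doublet graph)."""
    if len(seq) < 3:
        return seq
    for _ in range(200):
        edges: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            edges.setdefault(a, []).append(b)
        for k in edges:
            perm = rng.permutation(len(edges[k]))
            edges[k] = [edges[k][i] for i in perm]
        out = [seq[0]]
        ok = True
        for _i in range(len(seq) - 1):
            nxts = edges.get(out[-1])
            if not nxts:
                ok = False
                break
            out.append(nxts.pop(0))
        if ok:
            return "".join(out)
    return seq  # pathological composition; give up, keep original


def _sd_helix_positions(truth: dict, d: MotifDescriptor):
    name, (run_s, run_e), _ss, _off = sd_anchor(d)
    s5 = truth[name]
    s3 = truth[name + "'"]
    return name, s5, s3, (run_s, run_e)


def _realized_run_offset(positions, realized: str, run_s: int, run_e: int) -> int | None:
    """Realized index of a fixed literal run, resolved against the optional
    positions actually present in this realization."""
    run_text = "".join(p.symbol for p in positions[run_s:run_e])
    fixed_before = sum(1 for p in positions[:run_s] if not p.optional)
    opt_before = sum(1 for p in positions[:run_s] if p.optional)
    for off in range(fixed_before, fixed_before + opt_before + 1):
        if realized[off:off + len(run_text)] == run_text:
            return off
    return None


def _break_pairing(seq: str, truth: dict, d: MotifDescriptor,
                   rng: np.random.Generator) -> str:
    """Flip one base of the SD helix 5' strand so its realized pair violates
    the pairing rules.  Targets the 5' literal run (the fourU block) when one
    exists, which also destroys the descriptor literal; otherwise falls back
    to the first position with a pairing-breaking substitution."""
    name, (s5, e5, w5), (s3, e3, w3), _run = _sd_helix_positions(truth, d)
    h = d.elements[name]
    assert isinstance(h, HelixSpec)
    L = e5 - s5

    candidates = range(L)
    runs = _literal_runs5(h)
    if runs:
        run_s, run_e, _text = max(runs, key=lambda r: r[1] - r[0])
        off = _realized_run_offset(h.pattern5.positions, w5, run_s, run_e)
        if off is not None:
            candidates = range(off, off + (run_e - run_s))
    for i in candidates:
        partner = w3[L - 1 - i]
        bad = [b for b in RNA_BASES
               if b != w5[i] and not d.pairing.allows(b, partner)]
        if bad:
            chars = list(seq)
            chars[s5 + i] = bad[rng.integers(len(bad))]
            return "".join(chars)
    raise SimError("cannot break pairing for this helix")


def _literal_runs5(h: HelixSpec):
    runs, cur = [], []
    for i, p in enumerate(h.pattern5.positions):
        if p.is_literal and not p.optional:
            cur.append((i, p.symbol))
        elif cur:
            runs.append((cur[0][0], cur[-1][0] + 1, "".join(c for _, c in cur)))
            cur = []
    if cur:
        runs.append((cur[0][0], cur[-1][0] + 1, "".join(c for _, c in cur)))
    return runs


def _remove_sd(seq: str, truth: dict, d: MotifDescriptor,
               rng: np.random.Generator) -> str:
    """Randomize every SD literal position to a different base."""
    name, _s5, (s3, e3, w3), (run_s, run_e) = _sd_helix_positions(truth, d)
    h = d.elements[name]
    assert isinstance(h, HelixSpec)
    idx = _realized_run_offset(h.pattern3.positions, w3, run_s, run_e)
    if idx is None:
        raise SimError("SD literal not found in realization")
    chars = list(seq)
    for k in range(run_e - run_s):
        pos = s3 + idx + k
        chars[pos] = _rand_base(rng, exclude=chars[pos])
    return "".join(chars)


# ---------------------------------------------------------------------------
# Assay simulation
# ---------------------------------------------------------------------------

def simulate_assay(true_factors: dict[float, float], base_mu: float = 100.0,
                   cv: float = 0.1, n_reps: int = 3,
                   seed: int | np.random.Generator | None = 0,
                   construct_id: str = "construct",
                   reference_temp: float = 25.0,
                   od600: float = 0.5, time: float = 90.0, volume: float = 0.02,
                   scale: float = 1000.0) -> list[AssayMeasurement]:
    """Reporter readings whose Miller units target ``base_mu * factor``.

    A420 is drawn lognormally with unit mean and coefficient of variation
    ``cv`` around the value implied by the target Miller units and the fixed
    OD600/time/volume; ``cv=0`` reproduces the targets exactly.
    """
    if cv < 0:
        raise SimError("cv must be >= 0")
    if n_reps < 1:
        raise SimError("n_reps must be >= 1")
    if true_factors.get(reference_temp) != 1:
        raise SimError("reference temperature factor must be 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[AssayMeasurement] = []
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    for t in sorted(true_factors):
        target_mu = base_mu * true_factors[t]
        a420_center = target_mu * time * volume * od600 / scale
        for rep in range(1, n_reps + 1):
            noise = 1.0 if cv == 0 else float(
                rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma))
            out.append(AssayMeasurement(
                construct_id=construct_id, temperature=t, replicate=rep,
                A420=a420_center * noise, OD600=od600, time=time, volume=volume))
    return out


__all__ = [
    "PlantTruth", "SimConfig", "generate_genome",
    "make_decoy", "make_decoys", "dinucleotide_shuffle", "simulate_assay",
    "SimError", "DECOY_KINDS", "STOP_CODONS",
]
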