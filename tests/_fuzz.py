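"""Shared generators for fuzz/property tests."""

from __future__ import annotations

import numpy as np

from thermoscan.descriptor import (
    DescriptorError,
    MotifDescriptor,
    parse_descriptor,
)

BASES = "ACGU"
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def random_sequence(rng: np.random.Generator, n: int, alphabet: str = BASES) -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _random_ss_pattern(rng: np.random.Generator) -> str:
    n_fixed = int(rng.integers(1, 5))
    n_opt = int(rng.integers(0, 3))
    syms = [("N" if rng.random() < 0.6 else BASES[rng.integers(4)])
            for _ in range(n_fixed)]
    out = syms + ["*"] * n_opt
    perm = rng.permutation(len(out))
    return "".join(out[i] for i in perm)


def _random_helix_patterns(rng: np.random.Generator) -> tuple[str, str]:
    n_fixed = int(rng.integers(2, 5))
    n_opt = int(rng.integers(0, 2))
    p5 = []
    p3 = []
    for i in range(n_fixed):
        if rng.random() < 0.5:
            p5.append("N")
            p3.append("N")
        else:
            b = BASES[rng.integers(4)]
            p5.append(b)
            # complementary literal on the 3' side (antiparallel), or N
            p3.append(COMPLEMENT[b] if rng.random() < 0.7 else "N")
    p3 = p3[::-1]
    # optionals pair outside-in: prepend on 5', append on 3'
    return "*" * n_opt + "".join(p5), "".join(p3) + "*" * n_opt


def random_descriptor(rng: np.random.Generator) -> MotifDescriptor:
    """A small random valid descriptor (1-3 ss elements, 0-1 helix)."""
    for _ in range(50):
        with_helix = rng.random() < 0.7
        tokens: list[str] = []
        lines: list[str] = []
        si = 0

        def add_ss():
            nonlocal si
            si += 1
            name = f"s{si}"
            tokens.append(name)
            mm = int(rng.integers(0, 2))
            lines.append(f"{name} {mm} {_random_ss_pattern(rng)}")

        add_ss()
        if with_helix:
            p5, p3 = _random_helix_patterns(rng)
            tokens.append("h1")
            lines.append(f"h1 0:0 {p5}:{p3}")
            if rng.random() < 0.7:
                add_ss()
            tokens.append("h1'")
        if rng.random() < 0.7:
            add_ss()
        text = " ".join(tokens) + "\n" + "\n".join(lines) + "\n"
        try:
            return parse_descriptor(text)
        except DescriptorError:
            continue
    raise AssertionError("could not generate a valid random descriptor")
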