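# thermoscan

A tested library + CLI for descriptor-driven discovery of **fourU RNA
thermometers**: structural-motif scanning of genomes, candidate curation
(Shine–Dalgarno anchoring, fourU run, G•U wobble, SD–AUG spacing, gene
linkage), lightweight secondary-structure verification, stabilizing-mutation
design, and β-galactosidase reporter-assay quantification. Everything is
exercisable offline on synthetic genomes generated by the built-in
`simdata` module.

## The descriptor language

A motif is described by a *map* (element order; helices appear twice, once
per strand, and must nest) plus one definition line per element:

```
s1 h1 s2 h2 s3 h2' s4 h1' s5
s1 0  NNN******
h1 0:0 *NNNNN:NNNNN*
s2 0  N*
h2 0:0 *CUUUUNNNN*:*NNNNAGGAG*
s3 0  NNN****
s4 0  N*
s5 0  NAUG***
```

`A C G U` are literals (`T` → `U`), `N` matches any nucleotide, `*` marks an
optional position ("a nucleotide may or may not be present"); paired helix
optionals are jointly present/absent. The integer on a single-strand line is
the tolerated mismatch count; the `a:b` helix field is
mispairs:insertions (insertions must be 0). The descriptor above is bundled
as `thermoscan.descriptor.FOURU_DESCRIPTOR` — a terminal-hairpin scaffold
with four U's opposite the SD block and an AUG anchor.

## CLI

```sh
# synthetic fixture: genome + GFF3 + truth table + simulated assay CSV
thermoscan simulate --length 100000 --plants 50 --decoys 30 --seed 7 --out sim/

# end-to-end: scan -> curate -> fold-verify -> propose mutations
thermoscan run --descriptor fouru.txt --fasta sim/genome.fasta \
    --gff sim/genome.gff3 --out results/ --seed 7

# individual stages
thermoscan search --descriptor fouru.txt --fasta genome.fasta --bed hits.bed
thermoscan filter --descriptor fouru.txt --fasta genome.fasta --gff ann.gff3 --json
thermoscan fold GGGAAACCC
thermoscan mutate --descriptor fouru.txt --fasta genome.fasta
thermoscan assay --csv readings.csv --negative-control gyrA
```

`run` writes `matches.tsv` (+`matches.bed`), `candidates.tsv/json`,
`mutations.json`, and `run.json` (descriptor echo, seed, parameters,
versions). TSV reports are 1-based inclusive (stated in their header
comment); BED and the JSON reports are 0-based half-open. Reports are
byte-identical across reruns with equal inputs.

## Library sketch

```python
from thermoscan.descriptor import fouru_descriptor, sample_instance
from thermoscan.scanner import scan_sequence, brute_force_scan
from thermoscan.curation import filter_and_rank
from thermoscan.structure import nussinov_fold, propose_wobble_mutations
from thermoscan.assay import miller_units, heat_induction_profile

d = fouru_descriptor()
matches = scan_sequence(genome, d)                 # both strands, exhaustive
cands = filter_and_rank(matches, d, annotations)   # flags + deterministic rank
```

`brute_force_scan` is a slow exhaustive reference implementation with the
identical output contract — the scanner's testing oracle. Folding is a
weighted Nussinov model (G:C=3, A:U=2, G:U=1, min loop 3) standing in for a
thermodynamic folder; externally computed structures can be imported via
`structure.parse_dot_bracket`. Heat induction is the ratio of mean Miller
units at 37/42 °C to the 25 °C mean.

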