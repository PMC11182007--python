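"""File-format adapters and report writers.

Internals are 0-based half-open; the human-readable TSV reports use 1-based
inclusive coordinates and say so in a header comment.  BED output is 0-based
half-open as the format requires.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .assay import AssayMeasurement, HeatInductionProfile
from .curation import Candidate, GeneAnnotation
from .scanner import MotifMatch, normalize_sequence


class IOFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Multi-record FASTA → list of (id, RNA-normalised sequence).

    Case-insensitive; T→U; IUPAC ambiguity codes preserved.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise IOFormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise IOFormatError(f"{path}: missing '>' header")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise IOFormatError(f"{path}: record with empty header")
        records.append((rec.id, normalize_sequence(str(rec.seq))))
    if not records:
        raise IOFormatError(f"{path}: no records")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 subset
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """CDS/gene features from a GFF3 file (ID/product attributes honoured)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    out = []
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        gid = feat.attributes.get("ID", [feat.id or "feature"])[0]
        product = feat.attributes.get("product", [""])[0]
        out.append(GeneAnnotation(
            sequence_id=feat.seqid, start=feat.start - 1, end=feat.end,
            strand=feat.strand, gene_id=gid, product=product))
    return out


def write_gff3(path: str | Path, annotations: list[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = f"ID={a.gene_id}"
            if a.product:
                attrs += f";product={a.product}"
            fh.write("\t".join([
                a.sequence_id, "thermoscan", "CDS", str(a.start + 1), str(a.end),
                ".", a.strand, "0", attrs]) + "\n")


# ---------------------------------------------------------------------------
# Match / candidate reports
# ---------------------------------------------------------------------------

def matches_to_tsv(matches: list[MotifMatch], map_order: tuple[str, ...]) -> str:
    lines = ["# coordinates are 1-based inclusive"]
    cols = ["sequence_id", "strand", "start", "end", "score"] + list(map_order)
    lines.append("\t".join(cols))
    for m in matches:
        realized = {s.element_id: s.realized for s in m.spans}
        row = [m.sequence_id, m.strand, str(m.start + 1), str(m.end), str(m.score)]
        row += [realized.get(tok, "") for tok in map_order]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def matches_to_bed(matches: list[MotifMatch]) -> str:
    lines = []
    for i, m in enumerate(matches, 1):
        lines.append("\t".join([
            m.sequence_id, str(m.start), str(m.end), f"match_{i}",
            str(m.score), m.strand]))
    return "\n".join(lines) + ("\n" if lines else "")


def candidates_to_records(candidates: list[Candidate]) -> list[dict]:
    out = []
    for rank, c in enumerate(candidates, 1):
        m = c.match
        rec = {
            "rank": rank,
            "sequence_id": m.sequence_id,
            "strand": m.strand,
            "start": m.start,
            "end": m.end,
            "all_pass": c.all_pass,
            "sd_helix": c.sd_helix,
            "sd_start": c.sd_span.start if c.sd_span else None,
            "sd_end": c.sd_span.end if c.sd_span else None,
            "start_codon_pos": c.start_codon_pos,
            "sd_spacing": c.sd_spacing,
            "wobble_count": c.wobble_count,
            "hairpin_support": round(c.hairpin_support, 4),
            "gene_id": c.gene_link.gene_id if c.gene_link else None,
            "gene_product": c.gene_link.product if c.gene_link else None,
            "gene_distance": c.gene_distance,
            "motif": m.realized,
        }
        for name, ok in c.flags:
            rec[f"flag_{name}"] = ok
        out.append(rec)
    return out


def candidates_to_tsv(candidates: list[Candidate]) -> str:
    recs = candidates_to_records(candidates)
    if not recs:
        return "# coordinates are 0-based half-open\n"
    cols = list(recs[0])
    lines = ["# coordinates are 0-based half-open", "\t".join(cols)]
    for r in recs:
        lines.append("\t".join("" if r[c] is None else str(r[c]) for c in cols))
    return "\n".join(lines) + "\n"


def candidates_to_json(candidates: list[Candidate]) -> str:
    return json.dumps(candidates_to_records(candidates), indent=2) + "\n"


# ---------------------------------------------------------------------------
# Assay CSV
# ---------------------------------------------------------------------------

ASSAY_COLUMNS = ["construct_id", "temperature_C", "replicate", "A420", "A550",
                 "OD600", "time_min", "volume_mL"]


def read_assay_csv(path: str | Path) -> list[AssayMeasurement]:
    df = pd.read_csv(path)
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise IOFormatError(f"assay CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(AssayMeasurement(
            construct_id=str(row["construct_id"]),
            temperature=float(row["temperature_C"]),
            replicate=int(row["replicate"]),
            A420=float(row["A420"]),
            A550=float(row["A550"]),
            OD600=float(row["OD600"]),
            time=float(row["time_min"]),
            volume=float(row["volume_mL"]),
        ))
    return out


def write_assay_csv(path: str | Path, measurements: list[AssayMeasurement]) -> None:
    df = pd.DataFrame([{
        "construct_id": m.construct_id, "temperature_C": m.temperature,
        "replicate": m.replicate, "A420": m.A420, "A550": m.A550,
        "OD600": m.OD600, "time_min": m.time, "volume_mL": m.volume,
    } for m in measurements], columns=ASSAY_COLUMNS)
    df.to_csv(path, index=False)


def profile_to_json(profiles: list[HeatInductionProfile],
                    verdicts: dict[str, str] | None = None) -> str:
    out = []
    for p in profiles:
        mean, sd, ind, se = p.as_dicts()
        rec = {
            "construct_id": p.construct_id,
            "reference_temp": p.reference_temp,
            "mean_mu": {str(t): v for t, v in mean.items()},
            "sd_mu": {str(t): v for t, v in sd.items()},
            "induction": {str(t): v for t, v in ind.items()},
            "induction_se": {str(t): v for t, v in se.items()},
        }
        if verdicts and p.construct_id in verdicts:
            rec["verdict"] = verdicts[p.construct_id]
        out.append(rec)
    return json.dumps(out, indent=2) + "\n"


__all__ = [
    "read_fasta", "write_fasta", "read_gff3", "write_gff3",
    "matches_to_tsv", "matches_to_bed",
    "candidates_to_records", "candidates_to_tsv", "candidates_to_json",
    "read_assay_csv", "write_assay_csv", "profile_to_json",
    "ASSAY_COLUMNS", "IOFormatError",
]
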