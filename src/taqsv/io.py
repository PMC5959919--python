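"""Readers and writers for the standard file dialects at the boundary.

Internally everything is 0-based half-open; VCF output is 1-based, BED
and bedGraph half-open per their standards.  FASTA parsing goes through
Biopython; plain-text VCF is read through pysam.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO

from .genome import DualReference, Haplome, RepeatFeature, Variant
from .simulate import EventSpec, RestructuredGenome, TruthSet
from .tracks import CoverageTrack


# --- FASTA -----------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_restructured_fasta(restructured: RestructuredGenome, path: str | Path) -> None:
    write_fasta({name: c.seq for name, c in restructured.copies.items()}, path)


# --- BED / bedGraph --------------------------------------------------------

def write_repeats_bed(haplome: Haplome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in haplome.repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or r.family}\t{r.family}\n")


def read_repeats_bed(path: str | Path) -> list[RepeatFeature]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        family = f[4] if len(f) > 4 else (f[3] if len(f) > 3 else "other")
        out.append(RepeatFeature(f[0], int(f[1]), int(f[2]), family, f[3] if len(f) > 3 else ""))
    return out


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            for i, v in enumerate(vals):
                s = i * track.bin_size
                fh.write(f"{chrom}\t{s}\t{s + track.bin_size}\t{v:g}\n")


def read_bedgraph(path: str | Path, haplotype: str) -> CoverageTrack:
    values: dict[str, list[float]] = {}
    bin_size = None
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        chrom, s, e, v = line.split("\t")
        if bin_size is None:
            bin_size = int(e) - int(s)
        values.setdefault(chrom, []).append(float(v))
    if bin_size is None:
        raise ValueError(f"empty bedGraph {path}")
    return CoverageTrack(
        haplotype=haplotype,
        bin_size=bin_size,
        values={c: np.asarray(v, dtype=float) for c, v in values.items()},
    )


# --- VCF -------------------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">
##INFO=<ID=HOMPOS,Number=1,Type=Integer,Description="1-based position on the homolog chromosome">
##INFO=<ID=HOMCHROM,Number=1,Type=String,Description="Homolog chromosome">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variant_map_vcf(dual_ref: DualReference, path: str | Path) -> None:
    """Inter-haplotype variant map on parent-A coordinates (VCF 4.2)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for v in sorted(dual_ref.variants, key=lambda v: (v.chrom_a, v.pos_a)):
            info = f"TYPE={v.kind};HOMCHROM={v.chrom_b};HOMPOS={v.pos_b + 1}"
            fh.write(
                f"{v.chrom_a}\t{v.pos_a + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )


def read_variant_vcf(path: str | Path) -> list[Variant]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            kind = rec.info.get("TYPE", "SNV")
            chrom_b = rec.info.get("HOMCHROM", rec.chrom)
            pos_b = int(rec.info.get("HOMPOS", rec.pos)) - 1
            out.append(
                Variant(
                    rec.chrom, rec.pos - 1, str(chrom_b), pos_b, str(kind), rec.ref, rec.alts[0]
                )
            )
    return out


def read_calls_vcf(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Small-variant calls as the filter modules' table contract."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else "."
            vtype = "SNV" if len(rec.ref) == 1 and len(alt) == 1 else "InDel"
            depth = rec.info.get("DP", 0)
            alt_count = rec.info.get("AC", [0])
            alt_count = alt_count[0] if isinstance(alt_count, tuple) else alt_count
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos - 1,
                    "ref": rec.ref,
                    "alt": alt,
                    "type": vtype,
                    "depth": int(depth),
                    "alt_count": int(alt_count),
                    "sample": sample or (samples[0] if samples else "sample1"),
                }
            )
    return pd.DataFrame(rows)


# --- BEDPE -----------------------------------------------------------------

def junctions_to_bedpe(junction_calls: list, path: str | Path) -> None:
    with open(path, "w") as fh:
        for call in junction_calls:
            j = getattr(call, "junction", call)
            mech = getattr(getattr(call, "mechanism", None), "mechanism", "")
            la, lb = j.locus_a, j.locus_b
            fh.write(
                f"{la.haplotype}_{la.chrom}\t{la.pos}\t{la.pos + 1}\t"
                f"{lb.haplotype}_{lb.chrom}\t{lb.pos}\t{lb.pos + 1}\t"
                f"{mech}\t{j.n_clips}\t{la.strand}\t{lb.strand}\n"
            )


def truth_to_bedpe(truth: TruthSet, path: str | Path) -> None:
    junctions_to_bedpe(truth.junctions(), path)


# --- config / metadata -----------------------------------------------------

def load_event_spec(path: str | Path) -> EventSpec:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(EventSpec.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown event-spec keys: {sorted(unknown)}")
    for tup_key in ("sgc_len_range", "deletion_len_range"):
        if tup_key in raw:
            raw[tup_key] = tuple(raw[tup_key])
    return EventSpec(**raw)


def write_run_metadata(path: str | Path, **params) -> None:
    Path(path).write_text(json.dumps(params, indent=2, default=str) + "\n")
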