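"""Readers/writers for the interchange formats the pipeline emits.

All coordinates are 0-based half-open in memory and converted at the file
boundary: GFF3/VCF/AGP are written 1-based inclusive, BED-like tables
0-based half-open.  Files written by this module round-trip byte-
identically through their corresponding readers.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import dna
from .sim.genome import GeneModel
from .sim.reads import ReadPairs

FASTA_WIDTH = 60


# --- FASTA ------------------------------------------------------------------


def write_fasta(path, records: list[tuple[str, np.ndarray | str]], width: int = FASTA_WIDTH) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            if isinstance(seq, np.ndarray):
                seq = dna.decode(seq)
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> list[tuple[str, np.ndarray]]:
    return [(rec.id, dna.encode(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]


# --- FASTQ ------------------------------------------------------------------


def write_fastq_pair(prefix, rp: ReadPairs, quality_char: str = "I") -> tuple[Path, Path]:
    """Write a paired library to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq``
    (Phred+33, constant quality)."""
    p1, p2 = Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq")
    names = rp.names()
    qual = quality_char * rp.read_length
    for path, block in ((p1, rp.r1), (p2, rp.r2)):
        with open(path, "w") as fh:
            for name, row in zip(names, block):
                fh.write(f"@{name}\n{dna.decode(row)}\n+\n{qual}\n")
    return p1, p2


def read_fastq(path) -> tuple[list[str], np.ndarray]:
    """Uniform-length FASTQ into (names, encoded 2-D array)."""
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        names.append(rec.id)
        rows.append(dna.encode(str(rec.seq)))
    if not rows:
        return [], np.empty((0, 0), dtype=np.uint8)
    if len({len(r) for r in rows}) != 1:
        raise ValueError("reads must have uniform length")
    return names, np.vstack(rows)


# --- GFF3 -------------------------------------------------------------------


def write_gff3(path, genes: list[GeneModel], seqid: str = "chr1", source: str = "manihot") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.start, x.id)):
            attrs = f"ID={g.id}"
            if g.regime:
                attrs += f";regime={g.regime}"
            fh.write(
                "\t".join(
                    [
                        seqid,
                        source,
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            genes.append(
                GeneModel(
                    id=attrs.get("ID", f"{f[0]}:{f[3]}"),
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6],
                    regime=attrs.get("regime") or None,
                )
            )
    return genes


# --- VCF --------------------------------------------------------------------


def write_vcf(
    path,
    variants: pd.DataFrame,
    reference: np.ndarray,
    chrom: str = "chr1",
    sample_info: bool = True,
) -> None:
    """VCF 4.2 with internal events converted to anchored VCF records.

    ``variants`` uses the internal convention: SNV (pos, ref, alt), INS
    (insertion before ``pos``), DEL (``ref`` deleted starting at ``pos``).
    """
    ref_str = dna.decode(reference)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={len(reference)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n')
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        v = variants.sort_values("pos", kind="mergesort")
        for r in v.itertuples():
            vtype = getattr(r, "vtype", "SNV")
            depth = getattr(r, "depth", None)
            af = getattr(r, "alt_fraction", None)
            info = [f"TYPE={vtype}"]
            if depth is not None and not pd.isna(depth):
                info.append(f"DP={int(depth)}")
            if af is not None and not pd.isna(af):
                info.append(f"AF={af:.4f}")
            if vtype in ("SNV", "snv"):
                pos1, ref, alt = r.pos + 1, r.ref, r.alt
            elif vtype in ("INS", "insertion"):
                anchor = ref_str[r.pos - 1] if r.pos > 0 else "N"
                pos1, ref, alt = r.pos, anchor, anchor + r.alt
            else:  # deletion
                anchor = ref_str[r.pos - 1] if r.pos > 0 else "N"
                pos1, ref, alt = r.pos, anchor + r.ref, anchor
            fh.write(
                f"{chrom}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t{';'.join(info)}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Parse a VCF written by :func:`write_vcf` back to internal events."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos1, _, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in f[7].split(";")
            )
            if len(ref) == 1 and len(alt) == 1:
                rows.append((chrom, pos1 - 1, ref, alt, "SNV"))
            elif len(alt) > len(ref):
                rows.append((chrom, pos1, "", alt[1:], "INS"))
            else:
                rows.append((chrom, pos1, ref[1:], "", "DEL"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vtype"])


# --- AGP --------------------------------------------------------------------

AGP_COLUMNS = [
    "object",
    "object_beg",
    "object_end",
    "part_number",
    "component_type",
    "component_id",
    "component_beg",
    "component_end",
    "orientation",
]


def write_agp(path, agp: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for r in agp.itertuples(index=False):
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_agp(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append(f)
    df = pd.DataFrame(rows, columns=AGP_COLUMNS)
    for col in ("object_beg", "object_end", "part_number"):
        df[col] = df[col].astype(int)
    # gap rows keep their length in component_id; component rows their coords
    def _conv(v):
        try:
            return int(v)
        except ValueError:
            return v

    df["component_id"] = df["component_id"].map(_conv)
    df["component_beg"] = df["component_beg"].map(_conv)
    df["component_end"] = df["component_end"].map(_conv)
    return df


# --- TSV / checksums --------------------------------------------------------


def write_tsv(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
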