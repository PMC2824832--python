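"""Readers for the external input formats.

Coordinate conventions: BED is 0-based half-open; VCF and the TSV variant
catalog are 1-based.  Gene models are stored internally with 0-based
half-open exons (see :class:`oncopair.expression.GeneModel`).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import pandas as pd

from oncopair.allelic_imbalance import GeneModel, KnownVariant


def read_variants(path) -> List[KnownVariant]:
    """Read a known-variant catalog.

    Accepts a minimal VCF (``.vcf``: CHROM, POS, ID, REF, ALT columns; the
    first ALT allele is used) or a TSV with columns chrom, pos, ref, alt
    (1-based positions).
    """
    path = str(path)
    variants: List[KnownVariant] = []
    if path.endswith(".vcf"):
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                chrom, pos, _, ref, alt = fields[:5]
                variants.append(
                    KnownVariant(
                        chrom=chrom,
                        pos=int(pos),
                        ref=ref[0].upper(),
                        alt=alt.split(",")[0][0].upper(),
                    )
                )
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        for row in df.itertuples(index=False):
            variants.append(
                KnownVariant(chrom=row.chrom, pos=int(row.pos),
                             ref=str(row.ref).upper(), alt=str(row.alt).upper())
            )
    return variants


def read_gene_models_bed12(path) -> List[GeneModel]:
    """Read gene models from a BED12 file (0-based half-open blocks)."""
    genes: List[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError("BED12 requires 12 columns")
            chrom, start, _end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons))
    return genes


def read_gene_models_gff3(path) -> List[GeneModel]:
    """Read gene models from a GFF3 file (gene + exon features; exon
    ``Parent`` or ``gene_id`` attributes link exons to genes)."""
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = f
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID") or attr.get("gene_id")
                if gid:
                    meta[gid] = (chrom, strand)
            elif ftype == "exon":
                gid = attr.get("Parent") or attr.get("gene_id")
                if gid:
                    exons.setdefault(gid, []).append((int(start) - 1, int(end)))
                    meta.setdefault(gid, (chrom, strand))
    genes = []
    for gid, ex in exons.items():
        chrom, strand = meta[gid]
        genes.append(GeneModel(gene_id=gid, chrom=chrom, strand=strand, exons=ex))
    return genes


def read_read_starts_bed(path) -> Dict[str, "pd.Series"]:
    """Read a read-start track (BED: chrom, start, end per read) into
    per-chromosome sorted start arrays."""
    import numpy as np

    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1],
        names=["chrom", "start"], dtype={0: str, 1: int},
    )
    return {
        chrom: np.sort(grp["start"].to_numpy())
        for chrom, grp in df.groupby("chrom")
    }
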