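"""Readers and writers for the formats the tool touches.

BED3–BED6 evidence tracks, gene annotations (GTF/GFF3 via gffutils, plus a
simple 5-column TSV dialect), abundance tables, miRNA->target pair lists,
and the weighted edge-list / SIF network exports.
"""

from __future__ import annotations

import os
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils

from .intervals import AbundanceTable, EvidenceTrack, GeneModel, GenomicInterval

ANNOTATION_DIALECTS = ("gtf", "gff3", "tsv")

# GTF/GFF3 biotype -> internal regulatory type. TF/miRNA status usually needs
# an id-list overlay because biotypes do not mark transcription factors.
_BIOTYPE_MAP = {
    "protein_coding": "coding",
    "mirna": "miRNA",
    "mirna_gene": "miRNA",
}
_NONCODING_BIOTYPE_HINTS = ("rna", "pseudogene", "antisense", "lincrna", "lncrna")


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


def read_bed(path: str, label: Optional[str] = None, kind: str = "chip_peak") -> EvidenceTrack:
    """Read a BED3–BED6 file into an indexed :class:`EvidenceTrack`.

    BED is already 0-based half-open, so coordinates are taken verbatim.
    Columns 4–6 (name, score, strand) are kept when present; a score of "."
    is treated as absent. Track and browser lines and #-comments are skipped.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name, score, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not intervals:
        warnings.warn(f"{path}: empty BED file, track has no intervals", stacklevel=2)
    return EvidenceTrack(label or os.path.basename(path), kind, intervals)


def write_bed(track: EvidenceTrack, path: str) -> None:
    """Write a track as BED6 (missing name/score rendered as '.')."""
    with open(path, "w") as fh:
        for iv in track.intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# gene annotation


def _resolve_gene_type(
    biotype: Optional[str],
    gene_id: str,
    tf_ids: frozenset,
    mirna_ids: frozenset,
    unresolved: List[str],
) -> str:
    if gene_id in tf_ids:
        return "TF"
    if gene_id in mirna_ids:
        return "miRNA"
    if biotype:
        b = biotype.lower()
        if b in _BIOTYPE_MAP:
            return _BIOTYPE_MAP[b]
        if any(h in b for h in _NONCODING_BIOTYPE_HINTS):
            return "noncoding"
    unresolved.append(gene_id)
    return "coding"


def read_gene_annotation(
    path: str,
    dialect: str = "tsv",
    tf_ids: Iterable[str] = (),
    mirna_ids: Iterable[str] = (),
) -> List[GeneModel]:
    """Read gene models from GTF, GFF3 or the 5-column TSV dialect.

    TSV columns: gene_id, chrom, strand, tss (0-based), gene_type. For
    GTF/GFF3 the TSS is derived from each ``gene`` feature as the 5'-most
    transcribed position (start for + strand, end for - strand, converted
    from the 1-based inclusive convention), and gene_type comes from the
    biotype attribute overlaid with the supplied TF/miRNA id lists. Genes
    whose type cannot be resolved default to "coding" with one warning.
    """
    if dialect not in ANNOTATION_DIALECTS:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    tf_ids, mirna_ids = frozenset(tf_ids), frozenset(mirna_ids)
    genes: List[GeneModel] = []
    seen: set = set()
    unresolved: List[str] = []

    if dialect == "tsv":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    raise ParseError(f"{path}:{lineno}: expected 5 tab-separated fields")
                gid, chrom, strand, tss, gtype = fields[:5]
                if gid in seen:
                    raise ParseError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
                seen.add(gid)
                try:
                    genes.append(GeneModel(gid, chrom, strand, int(tss), gtype))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
        return genes

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        if gid in seen:
            raise ParseError(f"{path}: duplicate gene_id {gid!r}")
        seen.add(gid)
        if feat.strand not in ("+", "-"):
            raise ParseError(f"{path}: gene {gid!r} has unknown strand {feat.strand!r}")
        # gffutils start/end are 1-based inclusive
        tss = feat.start - 1 if feat.strand == "+" else feat.end - 1
        biotype = None
        for key in ("gene_biotype", "gene_type", "biotype"):
            if key in feat.attributes:
                biotype = feat.attributes[key][0]
                break
        gtype = _resolve_gene_type(biotype, gid, tf_ids, mirna_ids, unresolved)
        genes.append(GeneModel(gid, feat.seqid, feat.strand, tss, gtype))
    if unresolved:
        warnings.warn(
            f"{path}: {len(unresolved)} gene(s) without a resolvable type "
            f"defaulted to 'coding' (e.g. {unresolved[0]!r})",
            stacklevel=2,
        )
    return genes


def write_gene_annotation_tsv(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.gene_type}\n")


# ---------------------------------------------------------------------------
# abundance tables and pair lists


def read_abundance_table(path: str, label: str = "expression") -> AbundanceTable:
    """Read a 2+-column TSV of gene_id -> abundance.

    A header line is auto-detected (non-numeric second field on line 1).
    Negative abundances and duplicate ids are errors.
    """
    values: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            try:
                value = float(fields[1])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ParseError(f"{path}:{lineno}: non-numeric abundance {fields[1]!r}") from None
            gid = fields[0]
            if gid in values:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative abundance for {gid!r}")
            values[gid] = value
    return AbundanceTable(values, label=label)


def write_abundance_table(table: AbundanceTable, path: str) -> None:
    with open(path, "w") as fh:
        for gid, v in table.values.items():
            fh.write(f"{gid}\t{format(v, 'g')}\n")


def read_pair_list(path: str) -> List[Tuple[str, str]]:
    """Read a 2-column TSV of (regulator_id, target_id) pairs, order kept."""
    pairs: List[Tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            pairs.append((fields[0], fields[1]))
    return pairs


def write_pair_list(pairs: Iterable[Tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
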