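"""Genome and annotation input/output.

Reads genome sequences plus CDS annotations (GenBank, or FASTA with GFF3)
into a strand-aware internal model, and extracts mRNA-sense sequence
windows anchored on annotated start codons.  All internal coordinates are
0-based, half-open; the 1-based inclusive conventions of GenBank and GFF3
are converted at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from ._util import DNA_ALPHABET, revcomp

logger = logging.getLogger(__name__)


class GenomeFormatError(ValueError):
    """The input file could not be parsed in the requested format."""


class FeatureValidationError(ValueError):
    """An annotated feature is inconsistent with its genome sequence."""


@dataclass(frozen=True)
class GenomeRecord:
    """A single replicon: uppercase DNA sequence plus topology."""

    id: str
    sequence: str
    topology: str = "linear"  # {"linear", "circular"}

    def __post_init__(self) -> None:
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FeatureValidationError(
                f"genome {self.id}: non-ACGTN characters in sequence: {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Top-strand slice [start, end); wraps on circular genomes.

        Coordinates may run outside [0, length) only when the genome is
        circular, in which case they are interpreted modulo the length.
        """
        L = self.length
        if self.topology == "circular":
            if end - start > L:
                raise ValueError("window longer than circular genome")
            span = end - start
            start %= L
            end = start + span
            if end <= L:
                return self.sequence[start:end]
            return self.sequence[start:] + self.sequence[: end - L]
        if start < 0 or end > L:
            raise ValueError(f"slice [{start}, {end}) outside linear genome of length {L}")
        return self.sequence[start:end]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated CDS with a strand-aware start-codon anchor.

    ``start``/``end`` are 0-based half-open genome coordinates;
    ``start_codon_pos`` is the genome coordinate of the first base of the
    start codon (``start`` on the + strand, ``end - 1`` on the - strand).
    """

    gene_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    start_codon_pos: int = -1
    product: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise FeatureValidationError(
                f"feature {self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.start_codon_pos == -1:
            object.__setattr__(
                self,
                "start_codon_pos",
                self.start if self.strand == "+" else self.end - 1,
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptRegion:
    """mRNA-sense sequence window with the start codon position marked.

    ``mrna_sequence`` reads 5'->3' as transcribed (reverse complement of
    the genome top strand for - strand genes); ``anchor_offset`` is the
    index of the first start-codon base within it.
    """

    gene_id: str
    mrna_sequence: str
    anchor_offset: int

    def __len__(self) -> int:
        return len(self.mrna_sequence)


def _validate_feature(feature: GeneFeature, genome: GenomeRecord) -> None:
    if feature.end > genome.length:
        raise FeatureValidationError(
            f"feature {feature.gene_id}: end {feature.end} exceeds genome "
            f"{genome.id} length {genome.length}"
        )


def _disambiguate_ids(features: list[GeneFeature]) -> list[GeneFeature]:
    seen: dict[str, int] = {}
    out = []
    for f in features:
        n = seen.get(f.gene_id, 0)
        seen[f.gene_id] = n + 1
        if n:
            new_id = f"{f.gene_id}_{n + 1}"
            logger.warning("duplicate gene id %s renamed to %s", f.gene_id, new_id)
            f = GeneFeature(new_id, f.start, f.end, f.strand, f.start_codon_pos,
                            f.product, f.category)
        out.append(f)
    return out


def _feature_from_biopython(feat, index: int) -> GeneFeature:
    quals = feat.qualifiers
    gene_id = (quals.get("locus_tag") or quals.get("gene")
               or quals.get("protein_id") or [f"cds_{index}"])[0]
    product = (quals.get("product") or [""])[0]
    loc = feat.location
    if len(getattr(loc, "parts", [loc])) > 1:
        logger.warning(
            "feature %s has a compound location; flattened to outermost span", gene_id
        )
    start, end = int(loc.start), int(loc.end)
    strand = "-" if loc.strand == -1 else "+"
    return GeneFeature(gene_id, start, end, strand, product=product)


def read_genbank(path: str | Path) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Read a single-record GenBank flat file into the internal model."""
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise GenomeFormatError(f"cannot parse {path} as GenBank: {exc}") from exc
    topology = record.annotations.get("topology", "linear")
    genome = GenomeRecord(record.id or record.name, str(record.seq).upper(), topology)
    features = [
        _feature_from_biopython(f, i)
        for i, f in enumerate(record.features)
        if f.type == "CDS"
    ]
    for f in features:
        _validate_feature(f, genome)
    features = _disambiguate_ids(sorted(features, key=lambda f: (f.start, f.gene_id)))
    return genome, features


def read_fasta_gff3(
    fasta_path: str | Path, gff3_path: str | Path
) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Read a FASTA genome plus GFF3 CDS annotations."""
    import gffutils

    try:
        record = SeqIO.read(str(fasta_path), "fasta")
    except Exception as exc:  # noqa: BLE001
        raise GenomeFormatError(f"cannot parse {fasta_path} as FASTA: {exc}") from exc
    genome = GenomeRecord(record.id, str(record.seq).upper(), "linear")
    try:
        db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except gffutils.exceptions.EmptyInputError:
        return genome, []  # annotation file with no features
    except Exception as exc:  # noqa: BLE001
        raise GenomeFormatError(f"cannot parse {gff3_path} as GFF3: {exc}") from exc
    features: list[GeneFeature] = []
    for index, feat in enumerate(db.features_of_type("CDS", order_by="start")):
        attrs = feat.attributes
        gene_id = (attrs.get("locus_tag") or attrs.get("ID")
                   or attrs.get("Name") or [f"cds_{index}"])[0]
        # GFF3 is 1-based inclusive.
        f = GeneFeature(gene_id, feat.start - 1, feat.end,
                        feat.strand if feat.strand in "+-" else "+",
                        product=(attrs.get("product") or [""])[0])
        _validate_feature(f, genome)
        features.append(f)
    features = _disambiguate_ids(sorted(features, key=lambda f: (f.start, f.gene_id)))
    return genome, features


def read_genome(
    path: str | Path,
    annotation: str | Path | None = None,
    fmt: str | None = None,
) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Read a genome + CDS features from GenBank or FASTA+GFF3.

    ``fmt`` is ``"genbank"`` or ``"fasta+gff3"``; when omitted it is
    inferred from the file extension (and the presence of ``annotation``).
    """
    if fmt is None:
        fmt = "fasta+gff3" if annotation is not None else "genbank"
    if fmt == "genbank":
        return read_genbank(path)
    if fmt == "fasta+gff3":
        if annotation is None:
            raise ValueError("fasta+gff3 format requires an annotation path")
        return read_fasta_gff3(path, annotation)
    raise ValueError(f"unknown format {fmt!r}")


def extract_window(
    genome: GenomeRecord,
    feature: GeneFeature,
    upstream: int,
    downstream: int,
) -> TranscriptRegion:
    """mRNA-sense window spanning start codon - upstream .. CDS 3' end + downstream.

    ``upstream``/``downstream`` are counted in transcript orientation.  On
    circular genomes the window wraps; on linear genomes it is clipped at
    the sequence ends (with a logged note) and ``anchor_offset`` adjusted.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    _validate_feature(feature, genome)
    L = genome.length
    if feature.strand == "+":
        gstart = feature.start_codon_pos - upstream
        gend = feature.end + downstream
    else:
        gstart = feature.start - downstream
        gend = feature.start_codon_pos + 1 + upstream
    if genome.topology == "linear":
        cstart, cend = max(0, gstart), min(L, gend)
        if cstart >= cend:
            raise ValueError(
                f"window for {feature.gene_id} lies entirely outside the genome"
            )
        if (cstart, cend) != (gstart, gend):
            logger.info(
                "window for %s truncated to [%d, %d) at linear genome ends",
                feature.gene_id, cstart, cend,
            )
        gstart, gend = cstart, cend
    seq = genome.slice(gstart, gend)
    if feature.strand == "+":
        mrna = seq
        anchor = feature.start_codon_pos - gstart
    else:
        mrna = revcomp(seq)
        anchor = gend - 1 - feature.start_codon_pos
    return TranscriptRegion(feature.gene_id, mrna, anchor)


def to_seqrecord(genome: GenomeRecord, features: list[GeneFeature]) -> SeqRecord:
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="", annotations={
                           "molecule_type": "DNA",
                           "topology": genome.topology,
                       })
    for f in features:
        loc = FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1)
        sf = SeqFeature(loc, type="CDS",
                        qualifiers={"locus_tag": [f.gene_id]})
        if f.product:
            sf.qualifiers["product"] = [f.product]
        record.features.append(sf)
    return record


def write_genbank(genome: GenomeRecord, features: list[GeneFeature],
                  path: str | Path) -> None:
    SeqIO.write(to_seqrecord(genome, features), str(path), "genbank")


def write_fasta_gff3(genome: GenomeRecord, features: list[GeneFeature],
                     fasta_path: str | Path, gff3_path: str | Path) -> None:
    SeqIO.write(SeqRecord(Seq(genome.sequence), id=genome.id, description=""),
                str(fasta_path), "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for f in features:
            attrs = f"ID={f.gene_id};locus_tag={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write("\t".join([
                genome.id, "crispri_art", "CDS", str(f.start + 1), str(f.end),
                ".", f.strand, "0", attrs,
            ]) + "\n")


def gene_table(features: list[GeneFeature]):
    """Features as a plain table (gene_id, start, end, strand, product)."""
    import pandas as pd

    return pd.DataFrame(
        [(f.gene_id, f.start, f.end, f.strand, f.start_codon_pos, f.product)
         for f in features],
        columns=["gene_id", "start", "end", "strand", "start_codon_pos", "product"],
    )
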