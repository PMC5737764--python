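"""Transcript models and the reference genome.

A :class:`TranscriptModel` is the coding structure of one isoform: ordered
CDS exons in genomic coordinates plus strand.  Models are read from GTF
(``CDS`` features grouped by ``transcript_id``) via gffutils and sequence is
served from an indexed FASTA via pyfaidx.  All genomic coordinates are
0-based half-open internally; GTF's 1-based closed intervals are converted on
ingest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
from pyfaidx import Fasta

from .errors import ValidationError


@dataclass(frozen=True)
class TranscriptModel:
    """CDS structure of one transcript isoform.

    ``exons`` are (start, end) 0-based half-open genomic intervals of the CDS
    (stop codon included), stored in genomic order (ascending start); they
    are traversed 5'->3' according to ``strand``.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(
                    f"{self.transcript_id}: empty exon {start}-{end}"
                )
            if start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if self.coding_length % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length {self.coding_length} "
                "not divisible by 3"
            )

    @property
    def coding_length(self) -> int:
        """Coding length l in bases (stop codon included)."""
        return sum(end - start for start, end in self.exons)

    def contains(self, pos0: int) -> bool:
        """Whether the 0-based genomic position lies in the CDS."""
        return any(start <= pos0 < end for start, end in self.exons)

    def genomic_to_cds(self, pos0: int) -> int | None:
        """Map a 0-based genomic position to a 0-based CDS offset (5'->3')."""
        if self.strand == "+":
            offset = 0
            for start, end in self.exons:
                if start <= pos0 < end:
                    return offset + (pos0 - start)
                offset += end - start
        else:
            offset = 0
            for start, end in reversed(self.exons):
                if start <= pos0 < end:
                    return offset + (end - 1 - pos0)
                offset += end - start
        return None

    def cds_sequence(self, genome: "Genome") -> str:
        """Coding-strand CDS sequence, 5'->3'."""
        parts = [genome.fetch(self.chrom, start, end) for start, end in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Thin pyfaidx wrapper exposing 0-based half-open sequence access."""

    def __init__(self, fasta_path):
        self._fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fasta[chrom][start:end])

    def base(self, chrom: str, pos0: int) -> str:
        return self.fetch(chrom, pos0, pos0 + 1)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def length(self, chrom: str) -> int:
        return len(self._fasta[chrom])


class InMemoryGenome:
    """Genome backed by a plain dict of chromosome sequences.

    Same access surface as :class:`Genome`; used by the fixture generator so
    pipelines can run without touching disk.
    """

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {k: v.upper() for k, v in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    def base(self, chrom: str, pos0: int) -> str:
        return self.sequences[chrom][pos0]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


class TranscriptIndex:
    """Transcript collection with per-chromosome and per-gene lookup."""

    def __init__(self, models: list[TranscriptModel]):
        self.models = list(models)
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        self._by_gene: dict[str, list[TranscriptModel]] = {}
        self._by_id: dict[str, TranscriptModel] = {}
        for m in self.models:
            self._by_chrom.setdefault(m.chrom, []).append(m)
            self._by_gene.setdefault(m.gene, []).append(m)
            if m.transcript_id in self._by_id:
                raise ValidationError(f"duplicate transcript id {m.transcript_id}")
            self._by_id[m.transcript_id] = m

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    def overlapping(self, chrom: str, pos0: int) -> list[TranscriptModel]:
        return [m for m in self._by_chrom.get(chrom, ()) if m.contains(pos0)]

    def gene_isoforms(self, gene: str) -> list[TranscriptModel]:
        return list(self._by_gene.get(gene, ()))

    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def longest_isoform(self, gene: str) -> TranscriptModel:
        """The gene's longest-CDS isoform; ties break to the smallest id."""
        isoforms = self._by_gene[gene]
        return min(isoforms, key=lambda m: (-m.coding_length, m.transcript_id))


def load_transcripts(gtf_path) -> TranscriptIndex:
    """Parse transcript models from the CDS features of a GTF file."""
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        tid = feat.attributes["transcript_id"][0]
        gene = feat.attributes.get("gene_id", [tid])[0]
        entry = grouped.setdefault(
            tid, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        # GTF is 1-based closed; convert to 0-based half-open
        entry["exons"].append((feat.start - 1, feat.end))
    models = []
    for tid, entry in grouped.items():
        exons = tuple(sorted(entry["exons"]))
        models.append(
            TranscriptModel(
                gene=entry["gene"],
                transcript_id=tid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=exons,
            )
        )
    models.sort(key=lambda m: m.transcript_id)
    return TranscriptIndex(models)


def write_gtf(models: list[TranscriptModel], path) -> None:
    """Write transcript models as GTF CDS features (1-based closed)."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.exons[0][0], m.transcript_id)):
            for start, end in m.exons:
                attrs = f'gene_id "{m.gene}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\tmoipred\tCDS\t{start + 1}\t{end}\t.\t{m.strand}\t0\t{attrs}\n"
                )


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
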