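"""Variant annotation: consequence calling plus the full feature pipeline.

The two-stage workflow starts here: a raw substitution is first resolved to
transcript-level consequences against the CDS models (codon identified
respecting strand, amino acids translated with the standard codon table),
then every nonsynonymous consequence is expanded into an
:class:`AnnotationRecord` carrying the complete feature catalogue —
evolutionary constraint, allele frequencies, protein functional context,
network context, gene/transcript structure and transcript polymorphism
summaries.  Any feature whose resource lacks the relevant key is recorded as
missing (``None``), never silently defaulted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from . import catalogue as cat
from .errors import ParseError, ReferenceMismatchError, ValidationError
from .resources import GeneSet, ResourceBundle
from .transcripts import Genome, TranscriptIndex, TranscriptModel

_BASES = frozenset("ACGT")

NONSYNONYMOUS = "nonsynonymous"
SYNONYMOUS = "synonymous"
STOP_GAINED = "stop-gained"
STOP_LOST = "stop-lost"
NON_CODING = "non-coding"

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter, '*' for stop) under the standard codon table."""
    try:
        return _CODON_TO_AA[codon.upper()]
    except KeyError:
        raise ValidationError(f"cannot translate codon {codon!r}") from None


def translate_cds(seq: str) -> str:
    if len(seq) % 3 != 0:
        raise ValidationError(f"CDS length {len(seq)} not divisible by 3")
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3))


@dataclass(frozen=True)
class Variant:
    """One genomic single-base substitution (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos <= 0:
            raise ValidationError(f"variant position must be positive, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: alleles must be single bases in ACGT, "
                f"got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: ref and alt alleles are identical"
            )

    @property
    def pos0(self) -> int:
        return self.pos - 1

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Consequence:
    """Transcript-level effect of one variant."""

    variant: Variant
    transcript_id: str
    gene: str
    effect: str
    protein_pos: int | None = None  # 1-based codon index
    aa_ref: str | None = None
    aa_alt: str | None = None


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def call_consequence(
    variant: Variant,
    models: TranscriptIndex | Iterable[TranscriptModel],
    genome: Genome,
) -> list[Consequence]:
    """Call the transcript-level consequence of a substitution.

    Returns one :class:`Consequence` per transcript whose CDS contains the
    position; a variant outside every CDS yields a single non-coding call.
    Raises :class:`ReferenceMismatchError` when the REF allele disagrees with
    the genome.
    """
    if variant.chrom not in genome or variant.pos0 >= genome.length(variant.chrom):
        raise ValidationError(f"{variant}: position not covered by the genome")
    genome_base = genome.base(variant.chrom, variant.pos0)
    if genome_base != variant.ref:
        raise ReferenceMismatchError(
            f"{variant}: REF allele {variant.ref} disagrees with genome base "
            f"{genome_base}"
        )
    if isinstance(models, TranscriptIndex):
        hits = models.overlapping(variant.chrom, variant.pos0)
    else:
        hits = [
            m
            for m in models
            if m.chrom == variant.chrom and m.contains(variant.pos0)
        ]
    if not hits:
        return [Consequence(variant, transcript_id="", gene="", effect=NON_CODING)]
    out = []
    for model in hits:
        offset = model.genomic_to_cds(variant.pos0)
        codon_index = offset // 3
        within = offset % 3
        cds = model.cds_sequence(genome)
        ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
        if model.strand == "+":
            alt_base = variant.alt
        else:
            alt_base = _COMPLEMENT[variant.alt]
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        aa_ref = translate_codon(ref_codon)
        aa_alt = translate_codon(alt_codon)
        if aa_ref == aa_alt:
            effect = SYNONYMOUS
        elif aa_alt == "*":
            effect = STOP_GAINED
        elif aa_ref == "*":
            effect = STOP_LOST
        else:
            effect = NONSYNONYMOUS
        out.append(
            Consequence(
                variant=variant,
                transcript_id=model.transcript_id,
                gene=model.gene,
                effect=effect,
                protein_pos=codon_index + 1,
                aa_ref=aa_ref,
                aa_alt=aa_alt,
            )
        )
    out.sort(key=lambda c: c.transcript_id)
    return out


# ---------------------------------------------------------------------------
# feature kernels


def average_heterozygosity(snps: Sequence[tuple[float, float]], l: int) -> float:
    """Average heterozygosity of a SNP list over a transcript: sum(2*p*q)/l.

    ``p`` is the minor allele frequency and ``q`` the reference allele
    frequency of each SNP; ``l`` is the coding transcript length in bases.
    The per-SNP kernel 2pq is summed over the list so that the statistic is
    additive over disjoint SNP sets.
    """
    if l <= 0:
        raise ValidationError(f"coding length must be positive, got {l}")
    total = 0.0
    for p, q in snps:
        if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
            raise ValidationError(f"allele frequencies ({p}, {q}) outside [0, 1]")
        total += 2.0 * p * q
    return total / l


def snp_density(count: int, l: int) -> float:
    """SNPs per coding base."""
    if l <= 0:
        raise ValidationError(f"coding length must be positive, got {l}")
    return count / l


def expression_entropy(expr: Sequence[float]) -> float | None:
    """Shannon entropy (bits) of the tissue-expression distribution.

    Expression means are normalized to proportions p_t and the entropy
    -sum(p_t * log2 p_t) is returned, with 0*log(0) := 0.  Low values mean
    tissue-specific expression, log2(n_tissues) means perfectly uniform
    expression.  An all-zero vector has no defined distribution and returns
    ``None`` (missing).
    """
    values = np.asarray([v for v in expr if v is not None], dtype=float)
    if values.size == 0:
        return None
    if np.any(values < 0):
        raise ValidationError("negative expression value")
    total = values.sum()
    if total == 0:
        return None
    p = values / total
    nonzero = p[p > 0]
    return float(-(nonzero * np.log2(nonzero)).sum())


def shortest_path_to_set(
    gene: str, target: GeneSet | frozenset | set, net: nx.Graph
) -> int | None:
    """Minimum unweighted path length from ``gene`` to any member of ``target``.

    Returns 0 when the gene itself is a member, ``None`` (missing) when the
    gene is absent from the network or no member is reachable.
    """
    members = target.members if isinstance(target, GeneSet) else frozenset(target)
    if gene in members:
        return 0
    if gene not in net:
        return None
    best = None
    # single BFS from the query gene; distances to all reachable nodes
    for node, dist in nx.single_source_shortest_path_length(net, gene).items():
        if node in members and (best is None or dist < best):
            best = dist
    return best


def transcript_flags(
    consequence: Consequence, isoforms: Sequence[TranscriptModel]
) -> tuple[bool, str]:
    """(is_longest, 'full'|'partial') for one consequence of a variant.

    ``is_longest`` marks the gene's maximal-CDS isoform (ties break to the
    lexicographically smallest transcript id); the variant affects the gene
    "full" when it lies in the CDS of every isoform, else "partial".
    """
    if not isoforms:
        raise ValidationError("transcript_flags requires at least one isoform")
    longest = min(isoforms, key=lambda m: (-m.coding_length, m.transcript_id))
    is_longest = consequence.transcript_id == longest.transcript_id
    pos0 = consequence.variant.pos0
    full = all(m.contains(pos0) for m in isoforms)
    return is_longest, "full" if full else "partial"


# ---------------------------------------------------------------------------
# annotation records


@dataclass
class AnnotationRecord:
    """The full feature vector for one (variant, transcript) pair."""

    consequence: Consequence
    features: dict[str, object] = field(default_factory=dict)

    @property
    def variant(self) -> Variant:
        return self.consequence.variant

    @property
    def gene(self) -> str:
        return self.consequence.gene

    @property
    def transcript_id(self) -> str:
        return self.consequence.transcript_id

    @property
    def is_longest_isoform(self) -> bool:
        return bool(self.features.get("is_longest_isoform"))

    def row_id(self) -> tuple:
        return self.variant.key() + (self.transcript_id,)


@dataclass(frozen=True)
class AnnotationConfig:
    """Catalogue-shaping configuration shared by annotation and fixtures."""

    populations: tuple[str, ...] = cat.DEFAULT_POPULATIONS
    ethnicities: tuple[str, ...] = cat.DEFAULT_ETHNICITIES
    n_tissues: int = cat.DEFAULT_TISSUE_COUNT
    extra_numeric: tuple[str, ...] = ()

    def catalogue(self) -> cat.FeatureCatalogue:
        return cat.default_catalogue(
            populations=self.populations,
            ethnicities=self.ethnicities,
            n_tissues=self.n_tissues,
            extra_numeric=self.extra_numeric,
        )

    @property
    def tissues(self) -> list[str]:
        return cat.tissue_names(self.n_tissues)


def _gene_features(
    gene: str, bundle: ResourceBundle, config: AnnotationConfig
) -> dict[str, object]:
    feats: dict[str, object] = {}
    table = bundle.gene_table
    feats["dnds_macaque"] = table.value(gene, "dnds_macaque")
    feats["dnds_mouse"] = table.value(gene, "dnds_mouse")
    feats["pli"] = table.value(gene, "pli")
    for flag in ("seg_dup", "pseudogene", "paralog"):
        val = table.value(gene, flag)
        feats[flag] = None if val is None else bool(val)
    for net in cat.CENTRALITY_NETWORKS:
        feats[f"centrality_{net}"] = table.value(gene, f"centrality_{net}")
    expr = table.expression_vector(gene, config.tissues)
    if expr is None:
        for t in config.tissues:
            feats[f"expr_{t}"] = None
        feats["expression_entropy"] = None
    else:
        for t, v in zip(config.tissues, expr):
            feats[f"expr_{t}"] = v
        feats["expression_entropy"] = expression_entropy(expr)
    feats["shortest_path_dominant"] = shortest_path_to_set(
        gene, bundle.dominant_genes, bundle.network
    )
    feats["shortest_path_recessive"] = shortest_path_to_set(
        gene, bundle.recessive_genes, bundle.network
    )
    return feats


def _polymorphism_features(
    model: TranscriptModel, bundle: ResourceBundle, config: AnnotationConfig
) -> dict[str, object]:
    from .resources import NONSYNONYMOUS as POLY_NONSYN
    from .resources import SYNONYMOUS as POLY_SYN

    feats: dict[str, object] = {}
    l = model.coding_length
    for prefix, snp_class in (("syn", POLY_SYN), ("nonsyn", POLY_NONSYN)):
        snps = bundle.polymorphisms.snps(model.transcript_id, snp_class=snp_class)
        feats[f"{prefix}_snp_density"] = snp_density(len(snps), l)
        gerps = [s.gerp for s in snps if s.gerp is not None]
        feats[f"{prefix}_mean_gerp"] = (
            float(np.mean(gerps)) if gerps else None
        )
        feats[f"pct_{prefix}_in_gerp_element"] = (
            100.0 * sum(s.in_gerp_element for s in snps) / len(snps) if snps else None
        )
        for eth in config.ethnicities:
            eth_snps = bundle.polymorphisms.snps(
                model.transcript_id, snp_class=snp_class, ethnicity=eth
            )
            feats[f"{prefix}_het_{eth}"] = average_heterozygosity(
                [(s.p, s.q) for s in eth_snps], l
            )
    # fraction of the CDS covered by constrained elements, as a percent
    covered = 0
    for start, end in model.exons:
        for g_start, g_end in bundle.genomic_intervals.intervals(
            model.chrom, "gerp_element"
        ):
            lo, hi = max(start, g_start), min(end, g_end)
            if hi > lo:
                covered += hi - lo
    feats["pct_transcript_in_gerp_element"] = 100.0 * covered / l
    return feats


def annotate_variant(
    variant: Variant,
    bundle: ResourceBundle,
    models: TranscriptIndex,
    genome: Genome,
    config: AnnotationConfig | None = None,
) -> list[AnnotationRecord]:
    """Annotate one variant: one record per nonsynonymous consequence.

    Synonymous-only, stop-affecting and non-coding variants produce no
    records.  Missing resource entries become missing feature values; only a
    REF/genome disagreement raises.
    """
    config = config or AnnotationConfig()
    consequences = call_consequence(variant, models, genome)
    records = []
    for cons in consequences:
        if cons.effect != NONSYNONYMOUS:
            continue
        model = models[cons.transcript_id]
        feats: dict[str, object] = {}

        site = bundle.gerp_sites.get(variant.chrom, variant.pos)
        feats["gerp_score"] = site["gerp"] if site else None
        genomic_cats = bundle.genomic_intervals.categories_at(
            variant.chrom, variant.pos0
        )
        feats["in_gerp_element"] = "gerp_element" in genomic_cats
        feats["in_mirna_site"] = "mirna_site" in genomic_cats

        afs = bundle.allele_freqs.get(variant.chrom, variant.pos, variant.alt)
        for col in ["af_1kg"] + [f"af_1kg_{p}" for p in config.populations] + [
            "af_esp",
            "af_exac",
        ]:
            feats[col] = afs[col] if afs else None
        splice = bundle.splice_scores.get(variant.chrom, variant.pos, variant.alt)
        feats["splice_score"] = splice["splice_score"] if splice else None

        protein_cats = bundle.protein_intervals.categories_at(
            cons.transcript_id, cons.protein_pos
        )
        for dom in cat.DOMAIN_CATEGORIES:
            feats[f"in_{dom}"] = dom in protein_cats
        for ptm in cat.PTM_CATEGORIES:
            feats[f"ptm_{ptm}"] = f"ptm_{ptm}" in protein_cats
        feats["in_disordered"] = "disordered" in protein_cats

        feats.update(_gene_features(cons.gene, bundle, config))

        isoforms = models.gene_isoforms(cons.gene)
        is_longest, full_partial = transcript_flags(cons, isoforms)
        feats["transcript_length"] = float(model.coding_length)
        feats["is_longest_isoform"] = is_longest
        feats["affects_all_isoforms"] = full_partial

        feats.update(_polymorphism_features(model, bundle, config))

        records.append(AnnotationRecord(consequence=cons, features=feats))
    return records


def annotate_variants(
    variants: Iterable[Variant],
    bundle: ResourceBundle,
    models: TranscriptIndex,
    genome: Genome,
    config: AnnotationConfig | None = None,
) -> list[AnnotationRecord]:
    config = config or AnnotationConfig()
    records: list[AnnotationRecord] = []
    for variant in variants:
        records.extend(annotate_variant(variant, bundle, models, genome, config))
    return records


# ---------------------------------------------------------------------------
# variant input / annotation table output

ID_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "protein_pos",
    "aa_ref",
    "aa_alt",
    "effect",
]


def read_variants(path) -> list[Variant]:
    """Read substitutions from a VCF or a #CHROM/POS/REF/ALT text file.

    Multi-allelic records are decomposed into biallelic variants; non-SNV
    alleles are skipped.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        from cyvcf2 import VCF

        variants = []
        for rec in VCF(str(path)):
            for alt in rec.ALT:
                if len(rec.REF) == 1 and len(alt) == 1 and alt in _BASES and rec.REF in _BASES:
                    variants.append(Variant(rec.CHROM, rec.POS, rec.REF, alt))
        return variants
    header, rows = None, []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            header = line.lstrip("#").split("\t")
            continue
        rows.append((lineno, line.split("\t")))
    if header is None:
        raise ParseError(f"{path}: missing #CHROM header line")
    for col in ("CHROM", "POS", "REF", "ALT"):
        if col not in header:
            raise ParseError(f"{path}: required column {col} absent from header")
    idx = {c: header.index(c) for c in ("CHROM", "POS", "REF", "ALT")}
    variants = []
    for lineno, fields in rows:
        if len(fields) < len(header):
            raise ParseError(f"{path}:{lineno}: truncated row")
        try:
            pos = int(fields[idx["POS"]])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: POS is not an integer") from None
        for alt in fields[idx["ALT"]].split(","):
            ref = fields[idx["REF"]]
            if len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES:
                variants.append(Variant(fields[idx["CHROM"]], pos, ref, alt))
    return variants


def records_to_frame(
    records: Sequence[AnnotationRecord], catalogue: cat.FeatureCatalogue
) -> pd.DataFrame:
    """Annotation records as a DataFrame: identity columns + catalogue columns."""
    rows = []
    for rec in records:
        cons = rec.consequence
        row = {
            "chrom": cons.variant.chrom,
            "pos": cons.variant.pos,
            "ref": cons.variant.ref,
            "alt": cons.variant.alt,
            "gene": cons.gene,
            "transcript": cons.transcript_id,
            "protein_pos": cons.protein_pos,
            "aa_ref": cons.aa_ref,
            "aa_alt": cons.aa_alt,
            "effect": cons.effect,
        }
        for feat in catalogue:
            row[feat.name] = rec.features.get(feat.name)
        rows.append(row)
    return pd.DataFrame(rows, columns=ID_COLUMNS + catalogue.names)


def _frame_value(value, feat: cat.Feature):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if feat.kind == cat.BOOLEAN:
        return bool(int(value)) if not isinstance(value, bool) else value
    if feat.kind == cat.CATEGORICAL:
        return str(value)
    return float(value)


def frame_to_records(
    df: pd.DataFrame, catalogue: cat.FeatureCatalogue
) -> list[AnnotationRecord]:
    records = []
    for _, row in df.iterrows():
        cons = Consequence(
            variant=Variant(str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"]),
            transcript_id=row["transcript"],
            gene=row["gene"],
            effect=row["effect"],
            protein_pos=int(row["protein_pos"]) if pd.notna(row["protein_pos"]) else None,
            aa_ref=row["aa_ref"],
            aa_alt=row["aa_alt"],
        )
        feats = {
            feat.name: _frame_value(
                row[feat.name] if pd.notna(row[feat.name]) else None, feat
            )
            for feat in catalogue
        }
        records.append(AnnotationRecord(consequence=cons, features=feats))
    return records


def write_annotation_table(
    records: Sequence[AnnotationRecord], catalogue: cat.FeatureCatalogue, path
) -> None:
    df = records_to_frame(records, catalogue)
    out = df.copy()
    for feat in catalogue:
        if feat.kind == cat.BOOLEAN:
            out[feat.name] = df[feat.name].map(
                lambda v: "." if v is None else ("1" if v else "0")
            )
        elif feat.kind == cat.NUMERIC:
            out[feat.name] = df[feat.name].map(
                lambda v: "." if v is None or (isinstance(v, float) and math.isnan(v)) else format(float(v), "g")
            )
        else:
            out[feat.name] = df[feat.name].map(lambda v: "." if v is None else str(v))
    out.to_csv(path, sep="\t", index=False, na_rep=".")


def read_annotation_table(path, catalogue: cat.FeatureCatalogue) -> list[AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False, dtype={"chrom": str})
    missing_cols = [c for c in ID_COLUMNS + catalogue.names if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    df = df.where(pd.notna(df), None)
    return frame_to_records(df, catalogue)
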