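"""Synthetic fixtures: toy genome, transcript models, resources and variant pools.

The generator builds a complete offline stand-in for the real annotation
resources: a random multi-exon genome (both strands, valid start/stop
codons, no internal stops, some genes with an exon-skipped second isoform),
resource tables whose class-linked features are drawn from class-shifted
distributions, and class-labelled pools of genuine nonsynonymous variants.

The class-separation parameter ``delta`` scales every class-dependent shift:
at ``delta = 0`` the benign/dominant/recessive feature distributions are
identical (a null dataset on which cross-validated AUC must sit near 0.5)
and increasing ``delta`` monotonically separates them.  Signal features
mirror the families that dominate real-data importance rankings: allele
frequencies (benign variants common, pathogenic rare), GERP-style
conservation (pathogenic sites more constrained), dN/dS (benign genes less
constrained), the pLI haploinsufficiency score (high for dominant-disease
genes), and protein-interaction-network proximity to known dominant or
recessive disease genes.  Everything else (expression, centralities,
splice scores, PTM/disorder tracks, ...) is class-independent noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from . import catalogue as cat
from ._seeds import spawn_rng
from .annotate import (
    NONSYNONYMOUS,
    AnnotationConfig,
    AnnotationRecord,
    Variant,
    annotate_variants,
    call_consequence,
    translate_codon,
)
from .errors import ValidationError
from .features import CLASSES, LabeledPool
from .resources import (
    GENOMIC,
    PROTEIN,
    GENOMIC_CATEGORIES,
    GeneSet,
    GeneTable,
    IntervalTrack,
    PolymorphicSNP,
    PolymorphismTable,
    ResourceBundle,
    SiteTable,
    af_schema,
    gerp_schema,
    protein_categories,
    splice_schema,
    write_bundle,
)
from .transcripts import (
    InMemoryGenome,
    TranscriptIndex,
    TranscriptModel,
    reverse_complement,
    write_fasta,
    write_gtf,
)

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class FixtureConfig:
    """Tunable shape of one synthetic study.

    Defaults mirror the training-set composition used for model development:
    292 benign, 119 dominant (haploinsufficient) and 409 recessive genes
    contributing pools of 1024, 598 and 2413 candidate variants.
    """

    n_genes: Mapping[str, int] = field(
        default_factory=lambda: {"benign": 292, "dominant": 119, "recessive": 409}
    )
    n_variants: Mapping[str, int] = field(
        default_factory=lambda: {"benign": 1024, "dominant": 598, "recessive": 2413}
    )
    delta: float = 3.0
    missingness: float = 0.05
    n_signal: int = 5
    n_noise: int = 20
    n_tissues: int = cat.DEFAULT_TISSUE_COUNT
    min_codons: int = 60
    max_codons: int = 200
    second_isoform_fraction: float = 0.4
    genes_per_chrom: int = 50
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)

    def __post_init__(self):
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")
        if not (0.0 <= self.missingness <= 1.0):
            raise ValidationError("missingness must be in [0, 1]")
        for label in CLASSES:
            if self.n_genes[label] < 1 or self.n_variants[label] < 1:
                raise ValidationError("gene and variant counts must be >= 1")


def gene_names(config: FixtureConfig) -> dict[str, list[str]]:
    """Deterministic class assignment: consecutive blocks of G#### symbols."""
    out: dict[str, list[str]] = {}
    i = 0
    for label in CLASSES:
        out[label] = [f"G{j:04d}" for j in range(i, i + config.n_genes[label])]
        i += config.n_genes[label]
    return out


# ---------------------------------------------------------------------------
# reference generation


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random stop-free codons + one stop codon."""
    body = []
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(rng.choice(list(_BASES), size=3))
            if codon not in _STOPS:
                break
        body.append(codon)
    return "ATG" + "".join(body) + _STOPS[rng.integers(len(_STOPS))]


def _valid_skip(cds_parts: list[str]) -> bool:
    """Whether skipping the middle exon keeps a clean ORF."""
    skipped = cds_parts[0] + cds_parts[2]
    if len(skipped) % 3 != 0:
        return False
    aas = [translate_codon(skipped[i : i + 3]) for i in range(0, len(skipped), 3)]
    return "*" not in aas[:-1] and aas[-1] == "*"


def _build_gene(
    rng: np.random.Generator,
    gene: str,
    chrom: str,
    offset: int,
    config: FixtureConfig,
) -> tuple[str, list[TranscriptModel], int]:
    """Return (genomic sequence of the gene region, isoform models, new offset)."""
    wants_skip = rng.random() < config.second_isoform_fraction
    strand = "+" if rng.random() < 0.5 else "-"
    for _ in range(200):  # retry until the exon-skip isoform translates cleanly
        n_codons = int(rng.integers(config.min_codons, config.max_codons + 1))
        cds = _random_cds(rng, n_codons)
        n_exons = 3 if wants_skip else int(rng.integers(1, 4))
        if n_exons == 1:
            parts = [cds]
        else:
            if wants_skip:
                # middle exon length divisible by 3 so skipping preserves frame
                mid_codons = int(rng.integers(5, max(6, n_codons // 3)))
                first = int(rng.integers(3, n_codons - mid_codons - 3)) * 3
                parts = [
                    cds[:first],
                    cds[first : first + mid_codons * 3],
                    cds[first + mid_codons * 3 :],
                ]
            else:
                cuts = sorted(
                    rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False)
                )
                parts = [
                    cds[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(cds)])
                ]
        if wants_skip and not _valid_skip(parts):
            continue
        introns = [
            "".join(rng.choice(list(_BASES), size=int(rng.integers(20, 81))))
            for _ in range(len(parts) - 1)
        ]
        # transcribed region on the coding strand
        region = parts[0]
        coords: list[tuple[int, int]] = [(0, len(parts[0]))]
        for intron, part in zip(introns, parts[1:]):
            start = len(region) + len(intron)
            region = region + intron + part
            coords.append((start, start + len(part)))
        if strand == "-":
            L = len(region)
            genomic_seq = reverse_complement(region)
            coords = [(L - b, L - a) for a, b in coords]
            coords.sort()
        else:
            genomic_seq = region
        exons = tuple((offset + a, offset + b) for a, b in sorted(coords))
        models = [
            TranscriptModel(
                gene=gene,
                transcript_id=f"{gene}.t1",
                chrom=chrom,
                strand=strand,
                exons=exons,
            )
        ]
        if wants_skip:
            if strand == "+":
                keep = (exons[0], exons[2])
            else:
                keep = (exons[0], exons[2])
            models.append(
                TranscriptModel(
                    gene=gene,
                    transcript_id=f"{gene}.t2",
                    chrom=chrom,
                    strand=strand,
                    exons=keep,
                )
            )
        return genomic_seq, models, offset + len(genomic_seq)
    raise ValidationError(f"could not construct a valid gene model for {gene}")


def build_reference(
    config: FixtureConfig, seed: int
) -> tuple[InMemoryGenome, TranscriptIndex]:
    """Random genome + transcript models; deterministic per seed."""
    rng = spawn_rng(seed, 1)
    names = gene_names(config)
    all_genes = [g for label in CLASSES for g in names[label]]
    sequences: dict[str, list[str]] = {}
    models: list[TranscriptModel] = []
    spacer = 100
    chrom_idx, in_chrom, cursor = 1, 0, 0
    chrom = "chr1"
    sequences[chrom] = []
    for gene in all_genes:
        if in_chrom >= config.genes_per_chrom:
            chrom_idx += 1
            chrom = f"chr{chrom_idx}"
            sequences[chrom] = []
            in_chrom, cursor = 0, 0
        pad = "".join(rng.choice(list(_BASES), size=spacer))
        sequences[chrom].append(pad)
        cursor += spacer
        seq, gene_models, cursor = _build_gene(rng, gene, chrom, cursor, config)
        sequences[chrom].append(seq)
        models.extend(gene_models)
        in_chrom += 1
    genome = InMemoryGenome({c: "".join(parts) for c, parts in sequences.items()})
    return genome, TranscriptIndex(models)


def generate_reference(config: FixtureConfig, seed: int, out_dir) -> tuple[Path, Path]:
    """Write genome FASTA and transcript GTF files; returns their paths."""
    genome, index = build_reference(config, seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "genome.fa"
    gtf = out_dir / "models.gtf"
    write_fasta(genome.sequences, fasta)
    write_gtf(index.models, gtf)
    return fasta, gtf


# ---------------------------------------------------------------------------
# variant pools


def generate_variant_pools(
    models: TranscriptIndex,
    genome: InMemoryGenome,
    config: FixtureConfig,
    seed: int,
) -> dict[str, list[Variant]]:
    """Class-labelled pools of genuine nonsynonymous substitutions.

    Pool sizes match ``config.n_variants``; per-gene counts are spread as
    evenly as possible.  Every variant is unique by site and re-calls as
    nonsynonymous on the gene's primary isoform.
    """
    rng = spawn_rng(seed, 2)
    names = gene_names(config)
    pools: dict[str, list[Variant]] = {}
    used_sites: set[tuple[str, int]] = set()
    for label in CLASSES:
        genes = names[label]
        total = config.n_variants[label]
        base, extra = divmod(total, len(genes))
        pool: list[Variant] = []
        for gi, gene in enumerate(genes):
            n_var = base + (1 if gi < extra else 0)
            model = models[f"{gene}.t1"]
            cds = model.cds_sequence(genome)
            n_codons = len(cds) // 3
            # CDS offset of each genomic position, to map back after drawing
            made = 0
            attempts = 0
            while made < n_var and attempts < 200 * n_var:
                attempts += 1
                codon_idx = int(rng.integers(1, n_codons - 1))
                within = int(rng.integers(3))
                cds_off = codon_idx * 3 + within
                pos0 = _cds_to_genomic(model, cds_off)
                if (model.chrom, pos0) in used_sites:
                    continue
                codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
                aa_ref = translate_codon(codon)
                alts = []
                for b in _BASES:
                    if b == codon[within]:
                        continue
                    alt_codon = codon[:within] + b + codon[within + 1 :]
                    aa_alt = translate_codon(alt_codon)
                    if aa_alt != aa_ref and aa_alt != "*":
                        alts.append(b)
                if not alts:
                    continue
                alt_coding = alts[int(rng.integers(len(alts)))]
                ref_genomic = genome.base(model.chrom, pos0)
                if model.strand == "+":
                    alt_genomic = alt_coding
                else:
                    alt_genomic = reverse_complement(alt_coding)
                variant = Variant(model.chrom, pos0 + 1, ref_genomic, alt_genomic)
                used_sites.add((model.chrom, pos0))
                pool.append(variant)
                made += 1
            if made < n_var:
                raise ValidationError(
                    f"could not place {n_var} nonsynonymous variants in {gene}"
                )
        pools[label] = pool
    return pools


def _cds_to_genomic(model: TranscriptModel, cds_off: int) -> int:
    exons = model.exons if model.strand == "+" else tuple(reversed(model.exons))
    remaining = cds_off
    for start, end in exons:
        length = end - start
        if remaining < length:
            return start + remaining if model.strand == "+" else end - 1 - remaining
        remaining -= length
    raise ValidationError(f"CDS offset {cds_off} beyond transcript {model.transcript_id}")


# ---------------------------------------------------------------------------
# resources

# class-shift coefficients per signal family; multiplied by delta
_AF_SHIFT = {"benign": 1.2, "dominant": 0.0, "recessive": 0.0}
_GERP_SHIFT = {"benign": 0.0, "dominant": 1.0, "recessive": 1.0}
_PLI_SHIFT = {"benign": 0.0, "dominant": 1.3, "recessive": 0.0}
_DNDS_SHIFT = {"benign": 0.25, "dominant": 0.0, "recessive": 0.05}
_ELEM_SHIFT = {"benign": 0.0, "dominant": 0.08, "recessive": 0.08}
_DOMAIN_SHIFT = {"benign": 0.0, "dominant": 0.05, "recessive": 0.05}


def generate_resources(
    models: TranscriptIndex,
    pools: Mapping[str, Sequence[Variant]],
    config: FixtureConfig,
    seed: int,
) -> ResourceBundle:
    """Synthesize the full resource-table set covering all genes and pool sites.

    Class-linked features are drawn from class-shifted distributions scaled
    by ``config.delta``; ``config.missingness`` is the probability that any
    single resource value (site row, gene-table cell, network membership) is
    withheld, which downstream annotation reports as missing.
    """
    rng = spawn_rng(seed, 3)
    delta = config.delta
    miss = config.missingness
    names = gene_names(config)
    class_of = {g: label for label in CLASSES for g in names[label]}
    anno = config.annotation

    gerp_sites = SiteTable(gerp_schema())
    allele_freqs = SiteTable(af_schema(anno.populations))
    splice_scores = SiteTable(splice_schema())
    for label in CLASSES:
        for variant in pools[label]:
            if rng.random() >= miss:
                gerp = rng.normal(delta * _GERP_SHIFT[label], 1.0)
                gerp_sites.add(variant.chrom, variant.pos, {"gerp": round(gerp, 4)})
            if rng.random() >= miss:
                z = rng.normal(-6.0 + delta * _AF_SHIFT[label], 1.2)
                af = _sigmoid(z)
                values = {"af_1kg": af}
                for pop in anno.populations:
                    values[f"af_1kg_{pop}"] = _sigmoid(z + rng.normal(0, 0.3))
                values["af_esp"] = _sigmoid(z + rng.normal(0, 0.3))
                values["af_exac"] = _sigmoid(z + rng.normal(0, 0.3))
                allele_freqs.add(
                    variant.chrom,
                    variant.pos,
                    {k: round(v, 6) for k, v in values.items()},
                    ref=variant.ref,
                    alt=variant.alt,
                )
            if rng.random() >= miss:
                splice_scores.add(
                    variant.chrom,
                    variant.pos,
                    {"splice_score": round(rng.normal(0.0, 1.0), 4)},
                    ref=variant.ref,
                    alt=variant.alt,
                )

    genomic_track = IntervalTrack(GENOMIC, GENOMIC_CATEGORIES)
    protein_track = IntervalTrack(
        PROTEIN, protein_categories(cat.DOMAIN_CATEGORIES, cat.PTM_CATEGORIES)
    )
    gene_columns = (
        ["dnds_macaque", "dnds_mouse", "pli", "seg_dup", "pseudogene", "paralog"]
        + [f"centrality_{n}" for n in cat.CENTRALITY_NETWORKS]
        + [f"expr_{t}" for t in anno.tissues]
    )
    gene_table = GeneTable(gene_columns)
    polymorphisms = PolymorphismTable()

    for gene, label in class_of.items():
        isoforms = models.gene_isoforms(gene)
        primary = models.longest_isoform(gene)
        l = primary.coding_length
        # constrained-element intervals across the CDS exons
        elem_frac = float(
            np.clip(rng.normal(0.3 + delta * _ELEM_SHIFT[label], 0.05), 0.0, 0.9)
        )
        for start, end in primary.exons:
            span = int((end - start) * elem_frac)
            if span > 0:
                lo = start + int(rng.integers(0, end - start - span + 1))
                genomic_track.add(primary.chrom, lo, lo + span, "gerp_element")
        if rng.random() < 0.15:
            start, end = primary.exons[-1]
            mid = (start + end) // 2
            genomic_track.add(primary.chrom, mid, end + 10, "mirna_site")
        # protein-coordinate tracks per isoform
        for model in isoforms:
            n_aa = model.coding_length // 3
            dom_frac = float(
                np.clip(
                    rng.normal(0.25 + delta * _DOMAIN_SHIFT[label], 0.05), 0.0, 0.9
                )
            )
            for category in cat.DOMAIN_CATEGORIES:
                if rng.random() < 0.5:
                    span = max(1, int(n_aa * dom_frac * rng.uniform(0.3, 1.0)))
                    lo = 1 + int(rng.integers(0, max(1, n_aa - span)))
                    protein_track.add(model.transcript_id, lo, lo + span, category)
            for ptm in cat.PTM_CATEGORIES:
                if rng.random() < 0.3:
                    site = 1 + int(rng.integers(0, n_aa))
                    protein_track.add(model.transcript_id, site, site + 1, f"ptm_{ptm}")
            if rng.random() < 0.4:
                span = int(rng.integers(10, max(11, n_aa // 2)))
                lo = 1 + int(rng.integers(0, max(1, n_aa - span)))
                protein_track.add(model.transcript_id, lo, lo + span, "disordered")

        values: dict[str, float | None] = {}
        values["dnds_macaque"] = round(
            float(np.exp(rng.normal(math.log(0.25) + delta * _DNDS_SHIFT[label], 0.3))),
            4,
        )
        values["dnds_mouse"] = round(
            float(np.exp(rng.normal(math.log(0.20) + delta * _DNDS_SHIFT[label], 0.3))),
            4,
        )
        values["pli"] = round(
            _sigmoid(rng.normal(-2.0 + delta * _PLI_SHIFT[label], 1.0)), 4
        )
        for flag in ("seg_dup", "pseudogene", "paralog"):
            values[flag] = float(rng.random() < 0.2)
        for net in cat.CENTRALITY_NETWORKS:
            values[f"centrality_{net}"] = round(float(rng.exponential(0.1)), 5)
        expr = rng.dirichlet(np.full(config.n_tissues, 0.8)) * rng.uniform(50, 500)
        for t, v in zip(anno.tissues, expr):
            values[f"expr_{t}"] = round(float(v), 3)
        if miss > 0:  # withhold individual cells
            for col in list(values):
                if rng.random() < miss:
                    values[col] = None
        gene_table.add(gene, values)

        # per-transcript polymorphism lists
        gene_gerp_mean = delta * _GERP_SHIFT[label]
        for model in isoforms:
            lam_syn = model.coding_length * 0.02
            lam_non = model.coding_length * 0.02 * math.exp(-0.2 * delta * (label != "benign"))
            for snp_class, lam in (("synonymous", lam_syn), ("nonsynonymous", lam_non)):
                for _ in range(int(rng.poisson(lam))):
                    p = float(rng.beta(0.6, 4.0) * 0.5)
                    polymorphisms.add(
                        model.transcript_id,
                        PolymorphicSNP(
                            snp_class=snp_class,
                            p=round(p, 5),
                            q=round(1.0 - p, 5),
                            gerp=round(float(rng.normal(gene_gerp_mean, 1.0)), 4),
                            in_gerp_element=bool(rng.random() < elem_frac),
                            ethnicity=str(
                                anno.ethnicities[int(rng.integers(len(anno.ethnicities)))]
                            ),
                        ),
                    )

    network, gene_sets = _build_network(class_of, config, rng)
    return ResourceBundle(
        gerp_sites=gerp_sites,
        allele_freqs=allele_freqs,
        splice_scores=splice_scores,
        genomic_intervals=genomic_track,
        protein_intervals=protein_track,
        gene_table=gene_table,
        network=network,
        polymorphisms=polymorphisms,
        gene_sets=gene_sets,
    )


def _build_network(
    class_of: Mapping[str, str], config: FixtureConfig, rng: np.random.Generator
) -> tuple[nx.Graph, dict[str, GeneSet]]:
    """Interaction network with per-class hub stars.

    Known disease genes are synthetic hub nodes (D*/R* for the dominant and
    recessive lists, B* anchors).  Each fixture gene attaches to a random
    node of its matching star with probability 1 - exp(-delta) and to a
    uniformly random node otherwise, so network proximity carries class
    signal only when delta > 0.
    """
    n_hub = 20
    dom_nodes = [f"DIS_D{i:02d}" for i in range(1, n_hub + 1)]
    rec_nodes = [f"DIS_R{i:02d}" for i in range(1, n_hub + 1)]
    ben_nodes = [f"ANC_B{i:02d}" for i in range(1, n_hub + 1)]
    g = nx.Graph()
    for star in (dom_nodes, rec_nodes, ben_nodes):
        for node in star[1:]:
            g.add_edge(star[0], node)
    g.add_edge(dom_nodes[0], ben_nodes[0])
    g.add_edge(rec_nodes[0], ben_nodes[0])
    match = {"benign": ben_nodes, "dominant": dom_nodes, "recessive": rec_nodes}
    all_nodes = dom_nodes + rec_nodes + ben_nodes
    w = 1.0 - math.exp(-config.delta)
    for gene, label in class_of.items():
        if rng.random() < config.missingness:
            continue  # gene absent from the network entirely
        if rng.random() < w:
            anchor = match[label][int(rng.integers(n_hub))]
        else:
            anchor = all_nodes[int(rng.integers(len(all_nodes)))]
        g.add_edge(gene, anchor)
    gene_sets = {
        "dominant": GeneSet("dominant", frozenset(dom_nodes)),
        "recessive": GeneSet("recessive", frozenset(rec_nodes)),
        "haploinsufficient": GeneSet(
            "haploinsufficient", frozenset(dom_nodes[: n_hub // 2])
        ),
    }
    return g, gene_sets


# ---------------------------------------------------------------------------
# full fixture set


@dataclass
class FixtureSet:
    """Everything one synthetic study needs, in memory."""

    config: FixtureConfig
    seed: int
    genome: InMemoryGenome
    models: TranscriptIndex
    bundle: ResourceBundle
    variant_pools: dict[str, list[Variant]]

    def truth(self) -> dict[tuple, str]:
        return {
            v.key(): label
            for label, pool in self.variant_pools.items()
            for v in pool
        }

    def labeled_pools(self) -> dict[str, LabeledPool]:
        """Annotate every pool variant into class-labelled record pools."""
        pools = {}
        for label in CLASSES:
            records = annotate_variants(
                self.variant_pools[label],
                self.bundle,
                self.models,
                self.genome,
                self.config.annotation,
            )
            pools[label] = LabeledPool(label=label, records=records)
        return pools

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome.sequences, out_dir / "genome.fa")
        write_gtf(self.models.models, out_dir / "models.gtf")
        write_bundle(self.bundle, out_dir / "resources")
        with open(out_dir / "labels.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\tlabel\n")
            for label in CLASSES:
                for v in self.variant_pools[label]:
                    fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{label}\n")
        for label in CLASSES:
            write_vcf(
                self.variant_pools[label],
                self.genome,
                out_dir / f"pool_{label}.vcf",
            )


def generate_fixture_set(config: FixtureConfig | None = None, seed: int = 0) -> FixtureSet:
    """Reference, resources and labelled variant pools in one call."""
    config = config or FixtureConfig()
    genome, models = build_reference(config, seed)
    pools = generate_variant_pools(models, genome, config, seed)
    bundle = generate_resources(models, pools, config, seed)
    return FixtureSet(
        config=config,
        seed=seed,
        genome=genome,
        models=models,
        bundle=bundle,
        variant_pools=pools,
    )


def generate_labeled_pools(
    config: FixtureConfig | None = None, seed: int = 0
) -> dict[str, LabeledPool]:
    return generate_fixture_set(config, seed).labeled_pools()


def write_vcf(variants: Sequence[Variant], genome, path) -> None:
    """Minimal VCF 4.2 with contig headers."""
    chroms = sorted({v.chrom for v in variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom},length={genome.length(chrom)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# matrix-level fixture for classifier studies


def make_classification_matrix(
    n_per_class: int = 200,
    n_signal: int = 5,
    n_noise: int = 20,
    delta: float = 3.0,
    seed: int = 0,
    missing_rate: float = 0.0,
):
    """Labelled numeric matrix with class-shifted signal and pure-noise columns.

    Signal column ``j`` has class means ``delta * pattern`` where the pattern
    cycles through the three cyclic orders of (0, 1, 2), so every class pair
    is separated on every signal feature; noise columns are N(0, 1)
    regardless of class.
    """
    from .features import FeatureMatrix

    rng = spawn_rng(seed, 4)
    patterns = [(0.0, 1.0, 2.0), (2.0, 0.0, 1.0), (1.0, 2.0, 0.0)]
    n = n_per_class * 3
    labels = [c for c in CLASSES for _ in range(n_per_class)]
    columns = [f"signal_{j}" for j in range(n_signal)] + [
        f"noise_{j}" for j in range(n_noise)
    ]
    values = np.empty((n, n_signal + n_noise))
    for j in range(n_signal):
        pattern = patterns[j % 3]
        for k, c in enumerate(CLASSES):
            rows = slice(k * n_per_class, (k + 1) * n_per_class)
            values[rows, j] = rng.normal(delta * pattern[k], 1.0, size=n_per_class)
    values[:, n_signal:] = rng.normal(0.0, 1.0, size=(n, n_noise))
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan
    row_ids = [(f"row{i}",) for i in range(n)]
    return FeatureMatrix(row_ids=row_ids, columns=columns, values=values, labels=labels)
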