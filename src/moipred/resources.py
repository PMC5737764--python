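"""Annotation resource tables: schemas, loaders and writers.

Every external knowledge source the annotator consumes is expressed as one of
six generic containers, decoupling feature computation from any particular
upstream database:

* :class:`SiteTable` — per-site numeric values keyed by (chrom, pos[, alt]):
  conservation scores, per-dataset/per-population allele frequencies, splice
  scores.
* :class:`IntervalTrack` — labelled half-open intervals in genomic or protein
  coordinates: constrained elements, protein domains, PTM sites, disordered
  regions, miRNA binding sites.
* :class:`GeneTable` — per-gene numeric values and flags: dN/dS ratios, pLI,
  network centralities, per-tissue mean expression, duplication flags.
* :class:`GeneSet` — named gene lists (dominant / recessive disease genes,
  haploinsufficient genes).
* :class:`InteractionNetwork` — an undirected protein-protein interaction
  graph over gene symbols.
* :class:`PolymorphismTable` — per-transcript synonymous / nonsynonymous SNP
  lists with allele frequencies, conservation and ethnicity tags.

All on-disk formats are tab-delimited with a single header line and ``.`` for
missing values.  Loaders reject malformed rows with line-numbered errors and
type-check values against the declared invariants; lookups for absent keys
return ``None`` (an explicit missing marker), never a default number.
Genomic interval coordinates are 0-based half-open; protein intervals are
half-open over 1-based residue indices (``aa_start <= residue < aa_end``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import ParseError, ValidationError

MISSING = "."


def _parse_float(text: str, path, lineno: int, column: str) -> float | None:
    if text == MISSING or text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: column {column!r}: cannot parse {text!r} as a number"
        ) from None


def _parse_int(text: str, path, lineno: int, column: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: column {column!r}: cannot parse {text!r} as an integer"
        ) from None


def _read_rows(path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Read a tab-delimited file; return (header columns, [(lineno, fields)])."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file, expected a header line")
    header = lines[0].lstrip("#").rstrip("\n").split("\t")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} tab-separated fields, "
                f"found {len(fields)}"
            )
        rows.append((lineno, fields))
    return header, rows


def _write_table(path, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        if math.isnan(value):
            return MISSING
        return format(value, "g")
    return str(value)


# ---------------------------------------------------------------------------
# SiteTable


@dataclass(frozen=True)
class SiteSchema:
    """Declared value columns of a :class:`SiteTable`.

    ``bounds`` maps a column name to an inclusive (lo, hi) range checked at
    load time; allele-frequency columns must declare ``(0.0, 1.0)``.
    """

    columns: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    keyed_by_alt: bool = True

    def header(self) -> list[str]:
        key = ["chrom", "pos", "ref", "alt"] if self.keyed_by_alt else ["chrom", "pos"]
        return key + list(self.columns)


class SiteTable:
    """Per-site numeric annotations keyed by (chrom, 1-based pos[, alt])."""

    def __init__(self, schema: SiteSchema):
        self.schema = schema
        self._data: dict[tuple, dict[str, float | None]] = {}

    def __len__(self) -> int:
        return len(self._data)

    def _key(self, chrom: str, pos: int, alt: str | None):
        return (chrom, pos, alt) if self.schema.keyed_by_alt else (chrom, pos)

    def add(
        self,
        chrom: str,
        pos: int,
        values: Mapping[str, float | None],
        ref: str | None = None,
        alt: str | None = None,
    ) -> None:
        if pos <= 0:
            raise ValidationError(f"site position must be positive, got {pos}")
        for col, val in values.items():
            if col not in self.schema.columns:
                raise ValidationError(f"undeclared site column {col!r}")
            lo_hi = self.schema.bounds.get(col)
            if lo_hi is not None and val is not None:
                lo, hi = lo_hi
                if not (lo <= val <= hi):
                    raise ValidationError(
                        f"{col}={val} at {chrom}:{pos} outside [{lo}, {hi}]"
                    )
        key = self._key(chrom, pos, alt)
        if key in self._data:
            raise ValidationError(f"duplicate site record for {key}")
        record = {c: values.get(c) for c in self.schema.columns}
        if self.schema.keyed_by_alt:
            record["_ref"] = ref
        self._data[key] = record

    def get(
        self, chrom: str, pos: int, alt: str | None = None
    ) -> dict[str, float | None] | None:
        """Return the value dict for a site, or ``None`` when absent."""
        rec = self._data.get(self._key(chrom, pos, alt))
        if rec is None:
            return None
        return {c: rec[c] for c in self.schema.columns}

    def records(self):
        for key, rec in sorted(self._data.items()):
            yield key, rec


def load_site_table(path, schema: SiteSchema) -> SiteTable:
    header, rows = _read_rows(path)
    expected = schema.header()
    if header != expected:
        raise ParseError(
            f"{path}:1: header mismatch: expected {expected}, found {header}"
        )
    table = SiteTable(schema)
    for lineno, fields in rows:
        rec = dict(zip(header, fields))
        pos = _parse_int(rec["pos"], path, lineno, "pos")
        if pos <= 0:
            raise ValidationError(f"{path}:{lineno}: position {pos} is not positive")
        values = {
            col: _parse_float(rec[col], path, lineno, col) for col in schema.columns
        }
        try:
            table.add(
                rec["chrom"],
                pos,
                values,
                ref=rec.get("ref"),
                alt=rec.get("alt") if schema.keyed_by_alt else None,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return table


def write_site_table(table: SiteTable, path) -> None:
    rows = []
    for key, rec in table.records():
        if table.schema.keyed_by_alt:
            chrom, pos, alt = key
            row = [chrom, str(pos), _fmt(rec.get("_ref")), _fmt(alt)]
        else:
            chrom, pos = key
            row = [chrom, str(pos)]
        row += [_fmt(rec[c]) for c in table.schema.columns]
        rows.append(row)
    _write_table(path, table.schema.header(), rows)


# ---------------------------------------------------------------------------
# IntervalTrack

GENOMIC = "genomic"
PROTEIN = "protein"


class IntervalTrack:
    """Category-labelled half-open intervals in genomic or protein space.

    Genomic intervals are (chrom, start, end) with 0-based half-open
    coordinates; protein intervals are (transcript, aa_start, aa_end) over
    1-based residue indices, also half-open.
    """

    def __init__(self, space: str, vocabulary: Iterable[str]):
        if space not in (GENOMIC, PROTEIN):
            raise ValidationError(f"unknown interval space {space!r}")
        self.space = space
        self.vocabulary = frozenset(vocabulary)
        self._intervals: dict[str, list[tuple[int, int, str]]] = {}

    def add(self, seqkey: str, start: int, end: int, category: str) -> None:
        if start >= end:
            raise ValidationError(
                f"interval {seqkey}:{start}-{end}: start must be < end"
            )
        if category not in self.vocabulary:
            raise ValidationError(
                f"interval category {category!r} not in declared vocabulary"
            )
        self._intervals.setdefault(seqkey, []).append((start, end, category))

    def categories_at(self, seqkey: str, pos: int) -> set[str]:
        """All categories whose intervals contain ``pos`` (start <= pos < end)."""
        hits = set()
        for start, end, category in self._intervals.get(seqkey, ()):
            if start <= pos < end:
                hits.add(category)
        return hits

    def intervals(self, seqkey: str, category: str | None = None):
        for start, end, cat in self._intervals.get(seqkey, ()):
            if category is None or cat == category:
                yield start, end

    def covered_length(self, seqkey: str, category: str, bound: int) -> int:
        """Bases/residues of [0, bound) covered by ``category`` intervals."""
        mask_points: list[tuple[int, int]] = []
        for start, end in self.intervals(seqkey, category):
            mask_points.append((max(0, start), min(bound, end)))
        mask_points.sort()
        covered = 0
        cursor = 0
        for start, end in mask_points:
            start = max(start, cursor)
            if end > start:
                covered += end - start
                cursor = end
        return covered

    def records(self):
        for seqkey in sorted(self._intervals):
            for start, end, cat in sorted(self._intervals[seqkey]):
                yield seqkey, start, end, cat


def load_interval_track(path, space: str, vocabulary: Iterable[str]) -> IntervalTrack:
    header, rows = _read_rows(path)
    key_col = "chrom" if space == GENOMIC else "transcript"
    start_col = "start" if space == GENOMIC else "aa_start"
    end_col = "end" if space == GENOMIC else "aa_end"
    expected = [key_col, start_col, end_col, "category"]
    if header != expected:
        raise ParseError(
            f"{path}:1: header mismatch: expected {expected}, found {header}"
        )
    track = IntervalTrack(space, vocabulary)
    for lineno, fields in rows:
        seqkey, start, end, category = fields
        try:
            track.add(
                seqkey,
                _parse_int(start, path, lineno, start_col),
                _parse_int(end, path, lineno, end_col),
                category,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return track


def write_interval_track(track: IntervalTrack, path) -> None:
    key_col = "chrom" if track.space == GENOMIC else "transcript"
    start_col = "start" if track.space == GENOMIC else "aa_start"
    end_col = "end" if track.space == GENOMIC else "aa_end"
    rows = [
        [seqkey, str(start), str(end), cat] for seqkey, start, end, cat in track.records()
    ]
    _write_table(path, [key_col, start_col, end_col, "category"], rows)


# ---------------------------------------------------------------------------
# GeneTable


class GeneTable:
    """Per-gene numeric values: constraint, centrality, expression, flags.

    Columns are free-form; conventional names are ``dnds_macaque``,
    ``dnds_mouse``, ``pli``, ``seg_dup``/``pseudogene``/``paralog`` (0/1
    flags), ``centrality_<network>`` and ``expr_<tissue>``.  Invariants:
    pLI in [0,1]; dN/dS and expression values non-negative.
    """

    def __init__(self, columns: Sequence[str]):
        self.columns = tuple(columns)
        self._data: dict[str, dict[str, float | None]] = {}

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, gene: str) -> bool:
        return gene in self._data

    @property
    def genes(self) -> list[str]:
        return sorted(self._data)

    def add(self, gene: str, values: Mapping[str, float | None]) -> None:
        if not gene:
            raise ValidationError("blank gene symbol")
        if gene in self._data:
            raise ValidationError(f"duplicate gene record for {gene!r}")
        for col, val in values.items():
            if val is None:
                continue
            if col == "pli" and not (0.0 <= val <= 1.0):
                raise ValidationError(f"pli={val} for {gene} outside [0, 1]")
            if (col.startswith("dnds") or col.startswith("expr_")) and val < 0:
                raise ValidationError(f"{col}={val} for {gene} is negative")
        self._data[gene] = {c: values.get(c) for c in self.columns}

    def get(self, gene: str) -> dict[str, float | None] | None:
        rec = self._data.get(gene)
        return dict(rec) if rec is not None else None

    def value(self, gene: str, column: str) -> float | None:
        rec = self._data.get(gene)
        return rec.get(column) if rec is not None else None

    def expression_vector(self, gene: str, tissues: Sequence[str]):
        """Per-tissue means in ``tissues`` order, or None if gene absent."""
        rec = self._data.get(gene)
        if rec is None:
            return None
        return [rec.get(f"expr_{t}") for t in tissues]


def load_gene_table(path) -> GeneTable:
    header, rows = _read_rows(path)
    if header[0] != "gene":
        raise ParseError(f"{path}:1: first column must be 'gene', found {header[0]!r}")
    table = GeneTable(header[1:])
    for lineno, fields in rows:
        gene = fields[0]
        values = {
            col: _parse_float(val, path, lineno, col)
            for col, val in zip(header[1:], fields[1:])
        }
        try:
            table.add(gene, values)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return table


def write_gene_table(table: GeneTable, path) -> None:
    rows = []
    for gene in table.genes:
        rec = table.get(gene)
        rows.append([gene] + [_fmt(rec[c]) for c in table.columns])
    _write_table(path, ["gene"] + list(table.columns), rows)


# ---------------------------------------------------------------------------
# GeneSet


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene symbols (case-sensitive)."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if any(not m for m in self.members):
            raise ValidationError(f"gene set {self.name!r} contains a blank symbol")

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)


def load_gene_set(path, name: str) -> GeneSet:
    symbols = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        sym = line.strip()
        if not sym or sym.startswith("#"):
            continue
        symbols.append(sym)
    return GeneSet(name, frozenset(symbols))


def write_gene_set(gene_set: GeneSet, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(gene_set.members)))


# ---------------------------------------------------------------------------
# InteractionNetwork


def load_network(path) -> nx.Graph:
    """Load an undirected interaction network from a two-column edge list.

    Duplicate and reversed duplicate edges collapse to one; a header line
    starting with ``#`` is permitted.
    """
    graph = nx.Graph()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected two tab-separated symbols")
        a, b = (f.strip() for f in fields)
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: blank gene symbol in edge")
        graph.add_edge(a, b)
    return graph


def write_network(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(edge)) for edge in graph.edges()):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# PolymorphismTable

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
_SNP_CLASSES = (SYNONYMOUS, NONSYNONYMOUS)

#: tolerance on p + q <= 1 for multi-allelic sites
_PQ_TOL = 1e-6


@dataclass(frozen=True)
class PolymorphicSNP:
    """One population SNP observed within a transcript's CDS."""

    snp_class: str
    p: float  # minor allele frequency
    q: float  # reference allele frequency
    gerp: float | None
    in_gerp_element: bool
    ethnicity: str

    def __post_init__(self):
        if self.snp_class not in _SNP_CLASSES:
            raise ValidationError(f"unknown SNP class {self.snp_class!r}")
        if not (0.0 <= self.p <= 0.5):
            raise ValidationError(f"minor allele frequency p={self.p} outside [0, 0.5]")
        if not (0.0 <= self.q <= 1.0):
            raise ValidationError(f"reference allele frequency q={self.q} outside [0, 1]")
        if self.p + self.q > 1.0 + _PQ_TOL:
            raise ValidationError(f"p + q = {self.p + self.q} exceeds 1")


class PolymorphismTable:
    """Per-transcript synonymous/nonsynonymous SNP lists."""

    def __init__(self):
        self._data: dict[str, list[PolymorphicSNP]] = {}

    def add(self, transcript: str, snp: PolymorphicSNP) -> None:
        self._data.setdefault(transcript, []).append(snp)

    def snps(
        self,
        transcript: str,
        snp_class: str | None = None,
        ethnicity: str | None = None,
    ) -> list[PolymorphicSNP]:
        out = []
        for snp in self._data.get(transcript, ()):
            if snp_class is not None and snp.snp_class != snp_class:
                continue
            if ethnicity is not None and snp.ethnicity != ethnicity:
                continue
            out.append(snp)
        return out

    def transcripts(self) -> list[str]:
        return sorted(self._data)


_POLY_HEADER = ["transcript", "class", "p", "q", "gerp", "in_gerp_element", "ethnicity"]


def load_polymorphism_table(path) -> PolymorphismTable:
    header, rows = _read_rows(path)
    if header != _POLY_HEADER:
        raise ParseError(
            f"{path}:1: header mismatch: expected {_POLY_HEADER}, found {header}"
        )
    table = PolymorphismTable()
    for lineno, fields in rows:
        rec = dict(zip(header, fields))
        try:
            snp = PolymorphicSNP(
                snp_class=rec["class"],
                p=_parse_float(rec["p"], path, lineno, "p"),
                q=_parse_float(rec["q"], path, lineno, "q"),
                gerp=_parse_float(rec["gerp"], path, lineno, "gerp"),
                in_gerp_element=rec["in_gerp_element"] == "1",
                ethnicity=rec["ethnicity"],
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
        table.add(rec["transcript"], snp)
    return table


def write_polymorphism_table(table: PolymorphismTable, path) -> None:
    rows = []
    for transcript in table.transcripts():
        for snp in table.snps(transcript):
            rows.append(
                [
                    transcript,
                    snp.snp_class,
                    _fmt(snp.p),
                    _fmt(snp.q),
                    _fmt(snp.gerp),
                    "1" if snp.in_gerp_element else "0",
                    snp.ethnicity,
                ]
            )
    _write_table(path, _POLY_HEADER, rows)


# ---------------------------------------------------------------------------
# Bundle

#: canonical file names of a resource directory
BUNDLE_FILES = {
    "gerp_sites": "gerp_sites.tsv",
    "allele_freqs": "allele_freqs.tsv",
    "splice_scores": "splice_scores.tsv",
    "genomic_intervals": "genomic_intervals.tsv",
    "protein_intervals": "protein_intervals.tsv",
    "gene_table": "gene_table.tsv",
    "network": "network.tsv",
    "polymorphisms": "polymorphisms.tsv",
    "genes_dominant": "genes_dominant.txt",
    "genes_recessive": "genes_recessive.txt",
    "genes_haploinsufficient": "genes_haploinsufficient.txt",
}

GENOMIC_CATEGORIES = ("gerp_element", "mirna_site")


def protein_categories(domain_categories, ptm_categories) -> tuple[str, ...]:
    return tuple(domain_categories) + tuple(f"ptm_{p}" for p in ptm_categories) + (
        "disordered",
    )


@dataclass
class ResourceBundle:
    """Everything the annotator looks up, loaded from one directory."""

    gerp_sites: SiteTable
    allele_freqs: SiteTable
    splice_scores: SiteTable
    genomic_intervals: IntervalTrack
    protein_intervals: IntervalTrack
    gene_table: GeneTable
    network: nx.Graph
    polymorphisms: PolymorphismTable
    gene_sets: dict[str, GeneSet]

    @property
    def dominant_genes(self) -> GeneSet:
        return self.gene_sets["dominant"]

    @property
    def recessive_genes(self) -> GeneSet:
        return self.gene_sets["recessive"]


def gerp_schema() -> SiteSchema:
    return SiteSchema(columns=("gerp",), keyed_by_alt=False)


def af_schema(populations: Sequence[str]) -> SiteSchema:
    cols = ["af_1kg"] + [f"af_1kg_{p}" for p in populations] + ["af_esp", "af_exac"]
    return SiteSchema(
        columns=tuple(cols), bounds={c: (0.0, 1.0) for c in cols}, keyed_by_alt=True
    )


def splice_schema() -> SiteSchema:
    return SiteSchema(columns=("splice_score",), keyed_by_alt=True)


def load_bundle(
    directory,
    populations: Sequence[str],
    domain_categories: Sequence[str],
    ptm_categories: Sequence[str],
) -> ResourceBundle:
    d = Path(directory)
    gene_sets = {}
    for name in ("dominant", "recessive", "haploinsufficient"):
        p = d / BUNDLE_FILES[f"genes_{name}"]
        if p.exists():
            gene_sets[name] = load_gene_set(p, name)
    return ResourceBundle(
        gerp_sites=load_site_table(d / BUNDLE_FILES["gerp_sites"], gerp_schema()),
        allele_freqs=load_site_table(
            d / BUNDLE_FILES["allele_freqs"], af_schema(populations)
        ),
        splice_scores=load_site_table(
            d / BUNDLE_FILES["splice_scores"], splice_schema()
        ),
        genomic_intervals=load_interval_track(
            d / BUNDLE_FILES["genomic_intervals"], GENOMIC, GENOMIC_CATEGORIES
        ),
        protein_intervals=load_interval_track(
            d / BUNDLE_FILES["protein_intervals"],
            PROTEIN,
            protein_categories(domain_categories, ptm_categories),
        ),
        gene_table=load_gene_table(d / BUNDLE_FILES["gene_table"]),
        network=load_network(d / BUNDLE_FILES["network"]),
        polymorphisms=load_polymorphism_table(d / BUNDLE_FILES["polymorphisms"]),
        gene_sets=gene_sets,
    )


def write_bundle(bundle: ResourceBundle, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_site_table(bundle.gerp_sites, d / BUNDLE_FILES["gerp_sites"])
    write_site_table(bundle.allele_freqs, d / BUNDLE_FILES["allele_freqs"])
    write_site_table(bundle.splice_scores, d / BUNDLE_FILES["splice_scores"])
    write_interval_track(bundle.genomic_intervals, d / BUNDLE_FILES["genomic_intervals"])
    write_interval_track(bundle.protein_intervals, d / BUNDLE_FILES["protein_intervals"])
    write_gene_table(bundle.gene_table, d / BUNDLE_FILES["gene_table"])
    write_network(bundle.network, d / BUNDLE_FILES["network"])
    write_polymorphism_table(bundle.polymorphisms, d / BUNDLE_FILES["polymorphisms"])
    for name, gs in bundle.gene_sets.items():
        write_gene_set(gs, d / BUNDLE_FILES[f"genes_{name}"])
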