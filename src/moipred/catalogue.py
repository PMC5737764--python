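"""Feature catalogue: the fixed, ordered set of features an annotation run emits.

The classifier operates on a numeric matrix whose columns are defined once, at
configuration time, and shared by every annotation record.  A catalogue entry
is a (name, kind) pair; kinds are ``numeric`` (passed through unchanged),
``boolean`` (encoded to -1/+1) and ``categorical`` (two-level categories
become one -1/+1 column, wider ones one column per level).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

NUMERIC = "numeric"
BOOLEAN = "boolean"
CATEGORICAL = "categorical"

#: default population tags for per-dataset allele-frequency columns
DEFAULT_POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")
#: default ethnicity tags for the per-ethnicity heterozygosity columns
DEFAULT_ETHNICITIES = ("AFR", "AMR", "ASN", "EUR")
#: protein-domain categories tracked as presence flags
DOMAIN_CATEGORIES = ("pfam", "smart", "scop", "signal_peptide", "transmembrane")
#: post-translational modification categories tracked as presence flags
PTM_CATEGORIES = (
    "phosphorylation",
    "methylation",
    "acetylation",
    "oglcnac",
    "sumoylation",
    "ubiquitination",
)
#: centrality is reported within these biological networks
CENTRALITY_NETWORKS = ("metabolic", "genetic", "signaling")

DEFAULT_TISSUE_COUNT = 25


@dataclass(frozen=True)
class Feature:
    """One catalogue entry."""

    name: str
    kind: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (NUMERIC, BOOLEAN, CATEGORICAL):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == CATEGORICAL and len(self.levels) < 2:
            raise ValueError(f"categorical feature {self.name!r} needs >=2 levels")


class FeatureCatalogue:
    """Ordered, immutable collection of :class:`Feature` definitions."""

    def __init__(self, features: Iterable[Feature]):
        self.features: tuple[Feature, ...] = tuple(features)
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in catalogue")
        self._by_name = {f.name: f for f in self.features}

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Feature:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def digest(self) -> str:
        """Stable hash of names/kinds/levels; models refuse mismatched matrices."""
        text = "\n".join(
            f"{f.name}\t{f.kind}\t{','.join(f.levels)}" for f in self.features
        )
        return hashlib.sha256(text.encode()).hexdigest()

    def to_lines(self) -> list[str]:
        return [f"{f.name}\t{f.kind}\t{','.join(f.levels)}" for f in self.features]

    @classmethod
    def from_lines(cls, lines: Sequence[str]) -> "FeatureCatalogue":
        feats = []
        for line in lines:
            name, kind, levels = line.rstrip("\n").split("\t")
            feats.append(
                Feature(name, kind, tuple(levels.split(",")) if levels else ())
            )
        return cls(feats)


def tissue_names(n_tissues: int = DEFAULT_TISSUE_COUNT) -> list[str]:
    return [f"tissue{i + 1:02d}" for i in range(n_tissues)]


def default_catalogue(
    populations: Sequence[str] = DEFAULT_POPULATIONS,
    ethnicities: Sequence[str] = DEFAULT_ETHNICITIES,
    n_tissues: int = DEFAULT_TISSUE_COUNT,
    extra_numeric: Sequence[str] = (),
) -> FeatureCatalogue:
    """Build the standard catalogue covering every annotation feature family.

    The families are: evolutionary constraint (GERP, dN/dS), allele frequency
    and gene constraint (per-dataset/per-population AF, pLI), protein
    functional context (domains, PTMs, disorder, miRNA sites, splice score),
    network context (shortest paths to dominant/recessive disease genes,
    centralities, tissue expression and its Shannon entropy), gene/transcript
    structure, and transcript-level polymorphism summaries (density, mean
    GERP, GERP-element fractions, per-ethnicity average heterozygosity).

    ``extra_numeric`` appends additional plain numeric columns; the total
    feature count is therefore configurable.
    """
    f: list[Feature] = []
    # evolutionary
    f.append(Feature("gerp_score", NUMERIC))
    f.append(Feature("in_gerp_element", BOOLEAN))
    f.append(Feature("dnds_macaque", NUMERIC))
    f.append(Feature("dnds_mouse", NUMERIC))
    # allele frequency & constraint
    f.append(Feature("af_1kg", NUMERIC))
    for pop in populations:
        f.append(Feature(f"af_1kg_{pop}", NUMERIC))
    f.append(Feature("af_esp", NUMERIC))
    f.append(Feature("af_exac", NUMERIC))
    f.append(Feature("pli", NUMERIC))
    # functional
    for dom in DOMAIN_CATEGORIES:
        f.append(Feature(f"in_{dom}", BOOLEAN))
    for ptm in PTM_CATEGORIES:
        f.append(Feature(f"ptm_{ptm}", BOOLEAN))
    f.append(Feature("in_disordered", BOOLEAN))
    f.append(Feature("in_mirna_site", BOOLEAN))
    f.append(Feature("splice_score", NUMERIC))
    # network
    f.append(Feature("shortest_path_dominant", NUMERIC))
    f.append(Feature("shortest_path_recessive", NUMERIC))
    for net in CENTRALITY_NETWORKS:
        f.append(Feature(f"centrality_{net}", NUMERIC))
    for t in tissue_names(n_tissues):
        f.append(Feature(f"expr_{t}", NUMERIC))
    f.append(Feature("expression_entropy", NUMERIC))
    # gene / transcript
    f.append(Feature("transcript_length", NUMERIC))
    f.append(Feature("is_longest_isoform", BOOLEAN))
    f.append(Feature("affects_all_isoforms", CATEGORICAL, ("full", "partial")))
    f.append(Feature("seg_dup", BOOLEAN))
    f.append(Feature("pseudogene", BOOLEAN))
    f.append(Feature("paralog", BOOLEAN))
    # polymorphism summaries
    f.append(Feature("syn_snp_density", NUMERIC))
    f.append(Feature("nonsyn_snp_density", NUMERIC))
    f.append(Feature("syn_mean_gerp", NUMERIC))
    f.append(Feature("nonsyn_mean_gerp", NUMERIC))
    f.append(Feature("pct_syn_in_gerp_element", NUMERIC))
    f.append(Feature("pct_nonsyn_in_gerp_element", NUMERIC))
    f.append(Feature("pct_transcript_in_gerp_element", NUMERIC))
    for eth in ethnicities:
        f.append(Feature(f"syn_het_{eth}", NUMERIC))
        f.append(Feature(f"nonsyn_het_{eth}", NUMERIC))
    for name in extra_numeric:
        f.append(Feature(name, NUMERIC))
    return FeatureCatalogue(f)
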