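"""Isoform pair construction: paralog groups and spliceoform pairs.

Paralog pairs come from an Ensembl BioMart-style homology table filtered on
mean reciprocal sequence identity; groups are connected components of the
retained-pair graph projected onto quantified protein accessions.
Spliceoform pairs come from UniProt canonical/isoform accession conventions
(``P12345`` vs ``P12345-2``).  Pairs are canonically ordered (lexicographic)
so re-running on shuffled input yields identical pair lists and logFC signs.
"""

from __future__ import annotations

import itertools
import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HomologyRecord",
    "IsoformPair",
    "IsoformGroup",
    "mean_identity",
    "filter_paralog_pairs",
    "build_groups",
    "enumerate_pairs",
    "build_spliceoform_pairs",
    "annotate_ancestry",
    "build_paralog_pairs",
    "pairs_to_frame",
    "ANCIENT_TAXA",
]

logger = logging.getLogger(__name__)

# Clades at or deeper than the bilaterian common ancestor.  A gene family
# whose duplication predates Bilateria is classified "ancient"; anything
# younger (e.g. vertebrate- or rodent-specific duplications) is "recent".
ANCIENT_TAXA = frozenset({
    "Bilateria",
    "Opisthokonta",
    "Eukaryota",
    "Metazoa",
    "Eumetazoa",
    "Fungi/Metazoa group",
    "Cellular organisms",
})

_SPLICEOFORM_RE = re.compile(r"^(?P<base>[A-Za-z0-9_]+)(?:-(?P<iso>\d+))?$")


@dataclass(frozen=True)
class HomologyRecord:
    """One row of a paralog homology table (gene-level)."""

    gene_a: str
    gene_b: str
    identity_ab: float
    identity_ba: float
    paralog_type: str = ""
    ancestor_taxon: str = ""

    def __post_init__(self) -> None:
        for v in (self.identity_ab, self.identity_ba):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"percent identity out of [0, 100]: {v}")


@dataclass(slots=True)
class IsoformPair:
    """An ordered pair of protein accessions under comparison.

    ``accession_a`` is the lexicographically smaller accession; the ratio
    statistic downstream is glog2(a) − glog2(b), so signs are deterministic.
    """

    accession_a: str
    accession_b: str
    pair_type: str  # "paralog" | "spliceoform"
    mean_identity: float = float("nan")
    group_id: str = ""
    ancestry_class: str = "unclassified"  # "ancient" | "recent" | "unclassified"

    def __post_init__(self) -> None:
        if self.accession_a == self.accession_b:
            raise ValueError("pair members must differ")
        if self.accession_a > self.accession_b:
            self.accession_a, self.accession_b = self.accession_b, self.accession_a

    @property
    def pair_id(self) -> str:
        return f"{self.accession_a}|{self.accession_b}"


@dataclass
class IsoformGroup:
    """A connected set of mutually homologous quantified accessions."""

    group_id: str
    members: list[str]
    relations: list[tuple[str, str]] = field(default_factory=list)


def mean_identity(identity_ab: float, identity_ba: float) -> float:
    """Mean of the query→target and target→query percent identities."""
    for v in (identity_ab, identity_ba):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"percent identity out of [0, 100]: {v}")
    return (identity_ab + identity_ba) / 2.0


def _records_from_frame(records) -> list[HomologyRecord]:
    if isinstance(records, pd.DataFrame):
        return [
            HomologyRecord(
                gene_a=str(r.gene_id),
                gene_b=str(r.paralog_gene_id),
                identity_ab=float(r.perc_id),
                identity_ba=float(r.perc_id_r1),
                paralog_type=str(getattr(r, "paralog_type", "") or ""),
                ancestor_taxon=str(getattr(r, "ancestor", "") or ""),
            )
            for r in records.itertuples(index=False)
        ]
    return list(records)


def filter_paralog_pairs(
    records: Sequence[HomologyRecord] | pd.DataFrame,
    quantified_genes: set[str],
    min_identity: float = 50.0,
) -> list[HomologyRecord]:
    """Retain gene pairs with mean identity ≥ ``min_identity`` (inclusive)
    whose members both map to quantified proteins.

    Reversed duplicates (a,b)/(b,a) are collapsed to one record.  The
    default threshold of 50% keeps protein-family-level homology while
    excluding distant superfamilies.
    """
    if not (0.0 <= min_identity <= 100.0):
        raise ValueError("min_identity must be in [0, 100]")
    recs = _records_from_frame(records)
    seen: set[tuple[str, str]] = set()
    kept: list[HomologyRecord] = []
    n_in = 0
    for rec in recs:
        n_in += 1
        if rec.gene_a == rec.gene_b:
            continue
        key = tuple(sorted((rec.gene_a, rec.gene_b)))
        if key in seen:
            continue
        if mean_identity(rec.identity_ab, rec.identity_ba) < min_identity:
            continue
        if rec.gene_a not in quantified_genes or rec.gene_b not in quantified_genes:
            continue
        seen.add(key)
        kept.append(rec)
    logger.info("homology filter: %d records in, %d unique pairs retained "
                "(mean identity >= %.1f%%, both genes quantified)",
                n_in, len(kept), min_identity)
    return kept


def build_groups(
    retained_pairs: Sequence[HomologyRecord],
    accession_map: Mapping[str, Sequence[str]],
) -> list[IsoformGroup]:
    """Project retained gene pairs onto accessions and take connected components.

    ``accession_map`` maps gene → quantified accession(s); genes without any
    accession are skipped with a warning.  Each connected component of the
    resulting accession graph becomes one :class:`IsoformGroup`.
    """
    # union-find over accessions
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    relations: list[tuple[str, str]] = []
    skipped: set[str] = set()
    for rec in retained_pairs:
        accs_a = list(accession_map.get(rec.gene_a, []))
        accs_b = list(accession_map.get(rec.gene_b, []))
        for g, accs in ((rec.gene_a, accs_a), (rec.gene_b, accs_b)):
            if not accs:
                skipped.add(g)
        if not accs_a or not accs_b:
            continue
        for a, b in itertools.product(accs_a, accs_b):
            if a == b:
                continue
            union(a, b)
            relations.append(tuple(sorted((a, b))))
    if skipped:
        warnings.warn(f"genes with no quantified accession skipped: {sorted(skipped)}")

    components: dict[str, list[str]] = {}
    for acc in parent:
        components.setdefault(find(acc), []).append(acc)
    groups = []
    for i, root in enumerate(sorted(components), start=1):
        members = sorted(components[root])
        rels = sorted({r for r in relations if r[0] in members and r[1] in members})
        groups.append(IsoformGroup(group_id=f"G{i:04d}", members=members,
                                   relations=rels))
    if groups:
        mean_size = sum(len(g.members) for g in groups) / len(groups)
        logger.info("built %d isoform groups, mean size %.2f", len(groups), mean_size)
    return groups


def enumerate_pairs(group: IsoformGroup,
                    identity_lookup: Mapping[tuple[str, str], float] | None = None,
                    pair_type: str = "paralog") -> list[IsoformPair]:
    """All n(n−1)/2 unordered within-group pairs, canonically ordered."""
    members = sorted(group.members)
    if len(members) < 2:
        raise ValueError("group must have at least 2 members")
    gid = group.group_id
    nan = float("nan")
    if identity_lookup is None:
        return [IsoformPair(a, b, pair_type, nan, gid)
                for a, b in itertools.combinations(members, 2)]
    return [
        IsoformPair(a, b, pair_type,
                    identity_lookup.get((a, b), identity_lookup.get((b, a), nan)),
                    gid)
        for a, b in itertools.combinations(members, 2)
    ]


def split_isoform_accession(accession: str) -> tuple[str, int] | None:
    """Split ``P12345-2`` into ``("P12345", 2)``; canonical entries get 1."""
    m = _SPLICEOFORM_RE.match(accession)
    if m is None:
        return None
    iso = m.group("iso")
    return m.group("base"), int(iso) if iso else 1


def build_spliceoform_pairs(accessions: Iterable[str],
                            group_prefix: str = "S") -> list[IsoformPair]:
    """Pair every quantified isoform of a UniProt base accession.

    ``P12345`` (canonical) and ``P12345-N`` (alternative spliceoforms) share
    a gene by construction; each base accession with ≥2 quantified entries
    yields all pairwise combinations with ``pair_type = "spliceoform"``.
    """
    by_base: dict[str, list[str]] = {}
    for acc in accessions:
        parsed = split_isoform_accession(acc)
        if parsed is None:
            warnings.warn(f"malformed accession skipped: {acc!r}")
            continue
        by_base.setdefault(parsed[0], []).append(acc)
    pairs: list[IsoformPair] = []
    i = 0
    for base in sorted(by_base):
        members = sorted(set(by_base[base]))
        if len(members) < 2:
            continue
        i += 1
        gid = f"{group_prefix}{i:04d}"
        for a, b in itertools.combinations(members, 2):
            pairs.append(IsoformPair(a, b, pair_type="spliceoform",
                                     mean_identity=float("nan"), group_id=gid))
    return pairs


def annotate_ancestry(pair: IsoformPair, record: HomologyRecord,
                      ancient_taxa: frozenset[str] = ANCIENT_TAXA) -> IsoformPair:
    """Classify a pair's family origin from the homology record's LCA taxon.

    A last-common-ancestor clade at or deeper than Bilateria (configurable
    via ``ancient_taxa``) marks the duplication as ancient; any other known
    taxon label marks it recent; a missing label leaves it unclassified.
    """
    taxon = (record.ancestor_taxon or "").strip()
    if not taxon:
        pair.ancestry_class = "unclassified"
    elif taxon in ancient_taxa:
        pair.ancestry_class = "ancient"
    else:
        pair.ancestry_class = "recent"
    return pair


def build_paralog_pairs(
    homology: pd.DataFrame | Sequence[HomologyRecord],
    quantified_accessions: Iterable[str],
    gene_map: Mapping[str, str],
    min_identity: float = 50.0,
) -> tuple[list[IsoformPair], list[IsoformGroup]]:
    """End-to-end paralog pairing: filter → group → enumerate → annotate.

    ``gene_map`` maps accession → gene symbol (e.g. from FASTA ``GN=``
    fields).  Only accessions present in ``quantified_accessions`` enter
    groups.  Returns the canonical pair list and the groups.
    """
    quantified = set(quantified_accessions)
    acc_map: dict[str, list[str]] = {}
    for acc, gene in gene_map.items():
        if acc in quantified:
            acc_map.setdefault(gene, []).append(acc)
    quantified_genes = set(acc_map)
    retained = filter_paralog_pairs(homology, quantified_genes, min_identity)
    groups = build_groups(retained, acc_map)

    ident: dict[tuple[str, str], float] = {}
    taxon: dict[tuple[str, str], HomologyRecord] = {}
    for rec in retained:
        for a in acc_map.get(rec.gene_a, []):
            for b in acc_map.get(rec.gene_b, []):
                key = tuple(sorted((a, b)))
                ident[key] = mean_identity(rec.identity_ab, rec.identity_ba)
                taxon[key] = rec
    pairs: list[IsoformPair] = []
    for group in groups:
        for pair in enumerate_pairs(group, identity_lookup=ident):
            key = (pair.accession_a, pair.accession_b)
            if key in taxon:
                annotate_ancestry(pair, taxon[key])
            pairs.append(pair)
    logger.info("enumerated %d paralog pairs in %d groups", len(pairs), len(groups))
    return pairs, groups


def pairs_to_frame(pairs: Sequence[IsoformPair]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of a pair list."""
    return pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "accession_a": [p.accession_a for p in pairs],
            "accession_b": [p.accession_b for p in pairs],
            "pair_type": [p.pair_type for p in pairs],
            "mean_identity": [p.mean_identity for p in pairs],
            "group_id": [p.group_id for p in pairs],
            "ancestry_class": [p.ancestry_class for p in pairs],
        }
    )
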