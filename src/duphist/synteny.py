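"""Microsynteny blocks, tandem-duplication classification, and ancestral groups.

A duplicated region ("block") is called when two family genes are homologous
and at least ``min_flank_matches`` (default 3) of their 50 upstream/downstream
neighbors also form homologous pairs, matched one-to-one. Tandem duplication
is called by the coordinate rule: same chromosome, nearest-boundary distance
<= 60 kb, and at most 5 non-family gene loci in between. Blocks within and
between species are merged into ancestral-locus groups (connected components
over anchor pairs), labeled "A", "B", ... by decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .catalog import CatalogError, CatalogSet, GeneCatalog
from .homology import HomologyHit

DEFAULT_WINDOW = 50
DEFAULT_MIN_FLANK_MATCHES = 3
TANDEM_MAX_DISTANCE_BP = 60_000
TANDEM_MAX_INTERVENING = 5
FLANK_MIN_IDENTITY = 40.0   # relaxed floor for flanking (background) genes
FLANK_MIN_LENGTH = 150


@dataclass
class SyntenyBlock:
    anchor_a: str
    anchor_b: str
    species_a: str
    species_b: str
    flank_matches: tuple[tuple[str, str], ...]
    segment_size_a: int
    segment_size_b: int
    median_ks: float | None = None
    era: str | None = None

    @property
    def match_count(self) -> int:
        return len(self.flank_matches)

    @property
    def quality(self) -> float:
        return synteny_quality(self)

    @property
    def anchors(self) -> tuple[str, str]:
        return (self.anchor_a, self.anchor_b)


@dataclass
class AncestralGroup:
    group_id: str
    members: dict[str, list[str]] = field(default_factory=dict)  # species -> gene ids

    def all_members(self) -> list[str]:
        return [g for genes in self.members.values() for g in genes]

    @property
    def size(self) -> int:
        return len(self.all_members())


def build_homology_graph(hits: list[HomologyHit],
                         min_identity: float = FLANK_MIN_IDENTITY,
                         min_length: int = FLANK_MIN_LENGTH) -> nx.Graph:
    """Undirected graph of genes passing the (relaxed) homology floor."""
    g = nx.Graph()
    for h in hits:
        if h.identity > min_identity and h.aligned_length > min_length:
            g.add_edge(h.query, h.subject, score=h.score,
                       identity=h.identity, aligned_length=h.aligned_length)
    return g


def flanking_window(catalog: GeneCatalog, gene_id: str,
                    k: int = DEFAULT_WINDOW) -> tuple[list[str], list[str]]:
    """Up to k gene ids on each side of a gene, truncated at chromosome ends."""
    chrom, idx = catalog.locus_index(gene_id)
    genes = catalog.chromosomes[chrom]
    upstream = [g.gene_id for g in genes[max(0, idx - k) : idx]]
    downstream = [g.gene_id for g in genes[idx + 1 : idx + 1 + k]]
    return upstream, downstream


def _greedy_flank_matching(flanks_a: list[str], flanks_b: list[str],
                           graph: nx.Graph) -> list[tuple[str, str]]:
    """One-to-one matching of two flank sets, greedy by descending edge score.

    Prevents a single repetitive flanking gene from satisfying the match
    threshold on its own. Ties broken lexicographically for determinism.
    """
    set_b = set(flanks_b)
    candidates = []
    for a in flanks_a:
        if a not in graph:
            continue
        for b in graph.adj[a]:
            if b in set_b and a != b:
                candidates.append((graph.edges[a, b]["score"], a, b))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    matches = []
    for _, a, b in candidates:
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        matches.append((a, b))
    return matches


def detect_block(gene_a: str, gene_b: str, catalogs: CatalogSet, graph: nx.Graph,
                 k: int = DEFAULT_WINDOW,
                 min_flank_matches: int = DEFAULT_MIN_FLANK_MATCHES,
                 require_family: bool = True) -> SyntenyBlock | None:
    """Call a duplicated/syntenic region anchored on a homologous gene pair.

    Returns None when fewer than ``min_flank_matches`` one-to-one flank
    homolog pairs support the anchor.
    """
    if gene_a == gene_b:
        raise CatalogError("anchor genes must differ")
    ga, gb = catalogs.get(gene_a), catalogs.get(gene_b)
    if require_family and not (ga.is_family and gb.is_family):
        raise CatalogError("anchors must both be family members")
    if not graph.has_edge(gene_a, gene_b):
        return None
    up_a, down_a = flanking_window(catalogs.catalog_of(gene_a), gene_a, k)
    up_b, down_b = flanking_window(catalogs.catalog_of(gene_b), gene_b, k)
    flanks_a = up_a + down_a
    flanks_b = up_b + down_b
    matches = _greedy_flank_matching(flanks_a, flanks_b, graph)
    if len(matches) < min_flank_matches:
        return None
    return SyntenyBlock(
        anchor_a=gene_a, anchor_b=gene_b,
        species_a=catalogs.species_of(gene_a), species_b=catalogs.species_of(gene_b),
        flank_matches=tuple(matches),
        segment_size_a=1 + len(flanks_a), segment_size_b=1 + len(flanks_b),
    )


def synteny_quality(block: SyntenyBlock) -> float:
    """Percent quality: 2 x matches / total genes, matches include the anchor."""
    m = block.match_count + 1
    return 200.0 * m / (block.segment_size_a + block.segment_size_b)


def tandem_test(gene_a: str, gene_b: str, catalog: GeneCatalog,
                max_distance_bp: int = TANDEM_MAX_DISTANCE_BP,
                max_intervening: int = TANDEM_MAX_INTERVENING) -> bool:
    """Tandem-duplication rule, symmetric in its gene arguments.

    True iff both genes are family members on the same chromosome, their
    nearest span boundaries are within 60 kb, and at most 5 non-family gene
    loci lie strictly between the two spans (family genes in between extend
    the tandem chain instead of counting toward the limit).
    """
    a, b = catalog.get(gene_a), catalog.get(gene_b)
    if not (a.is_family and b.is_family) or a.chrom != b.chrom:
        return False
    left, right = (a, b) if a.start <= b.start else (b, a)
    gap = max(0, right.start - left.end - 1)
    if gap > max_distance_bp:
        return False
    intervening = sum(
        1 for g in catalog.chromosomes[a.chrom]
        if not g.is_family and g.start > left.end and g.end < right.start
    )
    return intervening <= max_intervening


def tandem_clusters(catalog: GeneCatalog, **kwargs) -> list[list[str]]:
    """Maximal tandem chains: pairwise tandem calls merged transitively."""
    fam = [g.gene_id for g in catalog.family_genes()]
    g = nx.Graph()
    g.add_nodes_from(fam)
    for i, a in enumerate(fam):
        for b in fam[i + 1 :]:
            if tandem_test(a, b, catalog, **kwargs):
                g.add_edge(a, b)
    clusters = [sorted(c) for c in nx.connected_components(g) if len(c) > 1]
    return sorted(clusters)


def intra_species_synteny(catalog: GeneCatalog, graph: nx.Graph,
                          k: int = DEFAULT_WINDOW,
                          min_flank_matches: int = DEFAULT_MIN_FLANK_MATCHES,
                          ) -> list[SyntenyBlock]:
    """Blocks for every within-species family homolog pair."""
    cats = CatalogSet([catalog])
    fam = sorted(g.gene_id for g in catalog.family_genes())
    blocks = []
    for i, a in enumerate(fam):
        for b in fam[i + 1 :]:
            if not graph.has_edge(a, b):
                continue
            blk = detect_block(a, b, cats, graph, k, min_flank_matches)
            if blk is not None:
                blocks.append(blk)
    return blocks


def cross_species_synteny(catalog_a: GeneCatalog, catalog_b: GeneCatalog,
                          graph: nx.Graph, k: int = DEFAULT_WINDOW,
                          min_flank_matches: int = DEFAULT_MIN_FLANK_MATCHES,
                          ) -> list[SyntenyBlock]:
    """Blocks for every cross-species family homolog pair."""
    if catalog_a.species == catalog_b.species:
        raise CatalogError("cross_species_synteny needs two distinct species")
    cats = CatalogSet([catalog_a, catalog_b])
    blocks = []
    for a in sorted(g.gene_id for g in catalog_a.family_genes()):
        for b in sorted(g.gene_id for g in catalog_b.family_genes()):
            if not graph.has_edge(a, b):
                continue
            blk = detect_block(a, b, cats, graph, k, min_flank_matches)
            if blk is not None:
                blocks.append(blk)
    return blocks


def subfunctionalized_partners(catalog: GeneCatalog, graph: nx.Graph,
                               k: int = DEFAULT_WINDOW,
                               min_flank_matches: int = DEFAULT_MIN_FLANK_MATCHES,
                               ) -> list[SyntenyBlock]:
    """Blocks pairing a family gene with a collinear non-family locus.

    These are the "N"-coded loci of retention analyses: a duplicated-block
    counterpart that is no longer a family member.
    """
    cats = CatalogSet([catalog])
    fam = sorted(g.gene_id for g in catalog.family_genes())
    famset = set(fam)
    blocks = []
    for a in fam:
        if a not in graph:
            continue
        for b in sorted(graph.adj[a]):
            if b in famset or b not in cats:
                continue
            blk = detect_block(a, b, cats, graph, k, min_flank_matches,
                               require_family=False)
            if blk is not None:
                blocks.append(blk)
    return blocks


def ancestral_groups(blocks: list[SyntenyBlock], catalogs: CatalogSet,
                     ) -> list[AncestralGroup]:
    """Connected components of the anchor-pair graph, labeled "A", "B", ...

    Components are ordered by (size descending, smallest gene id), so the
    labeling is invariant to block input order.
    """
    g = nx.Graph()
    for blk in blocks:
        g.add_edge(blk.anchor_a, blk.anchor_b)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    groups = []
    for i, comp in enumerate(comps):
        label = _letter_label(i)
        members: dict[str, list[str]] = {}
        for gene in comp:
            members.setdefault(catalogs.species_of(gene), []).append(gene)
        groups.append(AncestralGroup(group_id=label,
                                     members={s: sorted(v) for s, v in sorted(members.items())}))
    return groups


def _letter_label(i: int) -> str:
    label = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        label = chr(ord("A") + r) + label
    return label


def classify_family_pairs(blocks: list[SyntenyBlock], catalogs: CatalogSet,
                          ) -> dict[tuple[str, str], str]:
    """Label within-species family pairs as tandem or segmental.

    Tandem wins when both the coordinate rule and a block fire for the same
    pair; the two expansion classes are treated as disjoint.
    """
    labels: dict[tuple[str, str], str] = {}
    for blk in blocks:
        if blk.species_a == blk.species_b:
            pair = tuple(sorted(blk.anchors))
            labels[pair] = "segmental"
    for cat in catalogs.catalogs.values():
        fam = sorted(g.gene_id for g in cat.family_genes())
        for i, a in enumerate(fam):
            for b in fam[i + 1 :]:
                if tandem_test(a, b, cat):
                    labels[tuple(sorted((a, b)))] = "tandem"
    return labels
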