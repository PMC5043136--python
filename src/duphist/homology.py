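"""All-vs-all nucleotide homology search and paralog/ortholog calling.

The search role that BLASTN plays in genome-scale studies is filled here by
exact local alignment (Biopython's PairwiseAligner). Default scoring is
match +2, mismatch -1, affine gaps (open 20, extend 10): a local alignment
extends while its expected per-column score is positive, so a -1 mismatch
keeps ancient duplicates (Ks ~1.5-2, nucleotide identity ~50-55%) inside the
detectable range, where BLASTN's classic -3 would cut off near 60% identity;
unrelated sequences (~25% identity) still drift negative and yield only
short spurious islands. Gap costs are deliberately heavy — duplicates of
coding sequence rarely accumulate indels, and cheap gaps let random pairs
stitch matches into long fake alignments. The reporting floor (score 100)
sits well above the random-pair score tail at desk-scale catalog sizes.
Candidate pairs are prescreened by normalized edit distance between the two
protein translations (edlib): unrelated proteins sit near 0.84, while
duplicates remain below ~0.7 out to Ks ~3, so the quadratic all-vs-all scan
only aligns pairs that could plausibly clear the reporting floor. The
prescreen can be disabled (``prefilter=False``).

Calling rules:

* paralogs — same species, identity strictly > 40% and alignment strictly
  > 300 bp;
* orthologs — reciprocal best hits between two species with both alignments
  >= 300 bp.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from Bio import Align

from .catalog import CatalogSet, GeneCatalog
from .genetics import SequenceError

IUPAC_NT = set("ACGTRYSWKMBDHVN")

PARALOG_MIN_IDENTITY = 40.0   # strict >
PARALOG_MIN_LENGTH = 300      # strict > (bp)
ORTHOLOG_MIN_LENGTH = 300     # >= (bp)
DEFAULT_SCORE_FLOOR = 100.0


@dataclass(frozen=True)
class HomologyHit:
    query: str
    subject: str
    identity: float          # percent over all alignment columns, gaps included
    aligned_length: int      # alignment columns
    score: float
    query_coverage: float    # aligned query span / query length


@dataclass(frozen=True)
class GenePair:
    """An unordered, canonicalized pair with its alignment evidence."""

    gene_a: str
    gene_b: str
    species_a: str
    species_b: str
    evidence: tuple[HomologyHit, ...]

    @staticmethod
    def make(a: str, b: str, sp_a: str, sp_b: str, evidence) -> "GenePair":
        if (b, sp_b) < (a, sp_a):
            a, b, sp_a, sp_b = b, a, sp_b, sp_a
        return GenePair(a, b, sp_a, sp_b, tuple(evidence))

    @property
    def is_paralog(self) -> bool:
        return self.species_a == self.species_b


def _make_aligner(match: float = 2, mismatch: float = -1,
                  gap_open: float = 20, gap_extend: float = 10) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # a gap of length L costs gap_open + gap_extend * L
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


_ALIGNER = _make_aligner()


def _validate(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise SequenceError(f"{name}: empty sequence")
    bad = set(seq) - IUPAC_NT
    if bad:
        raise SequenceError(f"{name}: non-nucleotide characters {sorted(bad)}")
    return seq


def local_align(seq_a: str, seq_b: str, query_id: str = "a", subject_id: str = "b",
                aligner: Align.PairwiseAligner | None = None) -> HomologyHit:
    """Best local alignment of two nucleotide sequences.

    Identity counts identical columns over all alignment columns including
    gap columns; ambiguity codes never count as identical.
    """
    seq_a = _validate(seq_a, query_id)
    seq_b = _validate(seq_b, subject_id)
    aligner = aligner or _ALIGNER
    best = aligner.align(seq_a, seq_b)[0]
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    qstart, qend = best.aligned[0][0][0], best.aligned[0][-1][1]
    return HomologyHit(
        query=query_id, subject=subject_id,
        identity=100.0 * counts.identities / columns if columns else 0.0,
        aligned_length=int(columns),
        score=float(best.score),
        query_coverage=(qend - qstart) / len(seq_a),
    )


def all_vs_all(catalogs: GeneCatalog | list[GeneCatalog], *,
               score_floor: float = DEFAULT_SCORE_FLOOR,
               prefilter: bool = True, max_protein_distance: float = 0.75,
               aligner: Align.PairwiseAligner | None = None) -> list[HomologyHit]:
    """Best local hit for every unordered gene pair clearing the score floor.

    Self-hits are excluded; each pair is recorded once with the
    lexicographically smaller gene id as the query. The prescreen skips pairs
    whose protein translations have a normalized global edit distance above
    ``max_protein_distance`` — amino-acid divergence grows far more slowly
    than nucleotide divergence, so duplicates remain well separated from the
    unrelated-pair background even near Ks saturation. A score-only pass then
    discards sub-floor pairs before the (costlier) traceback.
    """
    import edlib

    if isinstance(catalogs, GeneCatalog):
        catalogs = [catalogs]
    genes = [g for cat in catalogs for g in cat.genes()]
    if len(genes) < 2:
        return []
    aligner = aligner or _ALIGNER
    seqs = {g.gene_id: _validate(g.cds, g.gene_id) for g in genes}
    prots = {g.gene_id: g.protein for g in genes} if prefilter else None
    hits: list[HomologyHit] = []
    order = sorted(seqs)
    for qid, sid in itertools.combinations(order, 2):
        if prefilter:
            dist = edlib.align(prots[qid], prots[sid], mode="NW",
                               task="distance")["editDistance"]
            if dist > max_protein_distance * max(len(prots[qid]), len(prots[sid])):
                continue
        if aligner.score(seqs[qid], seqs[sid]) < score_floor:
            continue
        hit = local_align(seqs[qid], seqs[sid], qid, sid, aligner)
        if hit.score >= score_floor:
            hits.append(hit)
    return hits


def call_paralogs(hits: list[HomologyHit], catalogs: CatalogSet | GeneCatalog,
                  min_identity: float = PARALOG_MIN_IDENTITY,
                  min_length: int = PARALOG_MIN_LENGTH) -> list[GenePair]:
    """Paralog pairs: identity strictly above 40%, alignment strictly over 300 bp.

    All hits must be within a single species; a cross-species hit is a
    contract violation.
    """
    cats = catalogs if isinstance(catalogs, CatalogSet) else CatalogSet([catalogs])
    pairs = []
    for h in hits:
        sp_q, sp_s = cats.species_of(h.query), cats.species_of(h.subject)
        if sp_q != sp_s:
            raise ValueError(f"cross-species hit {h.query}/{h.subject} in paralog calling")
        if h.identity > min_identity and h.aligned_length > min_length:
            pairs.append(GenePair.make(h.query, h.subject, sp_q, sp_s, [h]))
    return pairs


def best_hits(hits: list[HomologyHit], queries: set[str]) -> dict[str, HomologyHit]:
    """Per query, the best hit by (score, identity, lexicographic subject)."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        for q, s in ((h.query, h.subject), (h.subject, h.query)):
            if q not in queries:
                continue
            cand = HomologyHit(q, s, h.identity, h.aligned_length, h.score, h.query_coverage)
            cur = best.get(q)
            # ties broken by higher identity, then lexicographic subject id
            if cur is None or (cand.score, cand.identity) > (cur.score, cur.identity) or (
                    (cand.score, cand.identity) == (cur.score, cur.identity)
                    and cand.subject < cur.subject):
                best[q] = cand
    return best


def call_orthologs(hits_ab: list[HomologyHit], hits_ba: list[HomologyHit],
                   catalogs: CatalogSet,
                   min_length: int = ORTHOLOG_MIN_LENGTH) -> list[GenePair]:
    """Reciprocal-best-hit orthologs with both alignments >= 300 bp."""
    queries_a = {h.query for h in hits_ab}
    queries_b = {h.query for h in hits_ba}
    best_a = best_hits(hits_ab, queries_a)
    best_b = best_hits(hits_ba, queries_b)
    pairs = []
    for a, ha in sorted(best_a.items()):
        b = ha.subject
        hb = best_b.get(b)
        if hb is None or hb.subject != a:
            continue
        if ha.aligned_length >= min_length and hb.aligned_length >= min_length:
            pairs.append(GenePair.make(a, b, catalogs.species_of(a),
                                       catalogs.species_of(b), [ha, hb]))
    return pairs


def cross_species_hits(hits: list[HomologyHit], catalogs: CatalogSet,
                       species_a: str, species_b: str,
                       ) -> tuple[list[HomologyHit], list[HomologyHit]]:
    """Split an all-vs-all hit list into the two directed lists RBH needs.

    Returns (A-queries-vs-B, B-queries-vs-A); each hit is reoriented so its
    query belongs to the query species.
    """
    ab, ba = [], []
    for h in hits:
        sp = {catalogs.species_of(h.query): h.query, catalogs.species_of(h.subject): h.subject}
        if set(sp) != {species_a, species_b}:
            continue
        qa, qb = sp[species_a], sp[species_b]
        ab.append(HomologyHit(qa, qb, h.identity, h.aligned_length, h.score, h.query_coverage))
        ba.append(HomologyHit(qb, qa, h.identity, h.aligned_length, h.score, h.query_coverage))
    return ab, ba
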