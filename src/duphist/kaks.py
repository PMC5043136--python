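"""Pairwise Ka/Ks estimation: NG86 counting with Jukes-Cantor correction.

The workflow mirrors the field's standard protein-guided pipeline: align the
two proteins globally, back-translate the alignment onto the CDSs (gap
columns dropped), then count synonymous/nonsynonymous sites and differences
per Nei & Gojobori (1986) with equal pathway weighting, excluding mutation
pathways through stop codons, and correct both proportions for multiple hits
with the Jukes-Cantor formula.

Selection regimes follow the conventional reading of omega = Ka/Ks: < 0.5
strong purifying, [0.5, 1) relaxed purifying, 1 neutral, > 1 positive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import log

from Bio import Align
from Bio.Align import substitution_matrices

from .genetics import (
    CODON_TO_AA,
    STOP_CODONS,
    SYNONYMOUS_SITES,
    SequenceError,
    codons_of,
    translate_cds,
)

SATURATION_P = 0.75  # JC correction undefined at p >= 3/4


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class CodonAlignment:
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    dropped_codon_count: int = 0

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise AlignmentError("codon lists differ in length")
        for c in itertools.chain(self.codons_a, self.codons_b):
            if c not in CODON_TO_AA or c in STOP_CODONS:
                raise AlignmentError(f"invalid or stop codon {c!r} in codon alignment")

    def __len__(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KaKsResult:
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float | None
    Ks: float | None
    omega: float | None
    regime: str
    ks_saturated: bool = False
    ka_saturated: bool = False


# ---------------------------------------------------------------------------
# back-translation
# ---------------------------------------------------------------------------

def _strip_stop(cds: str) -> str:
    cods = codons_of(cds)
    return "".join(cods[:-1] if cods and cods[-1] in STOP_CODONS else cods)


def backtranslate_to_codon_alignment(protein_alignment: tuple[str, str],
                                     cds_a: str, cds_b: str) -> CodonAlignment:
    """Map an aligned protein pair back onto its source codons.

    ``protein_alignment`` is a pair of equal-length gapped strings. Columns
    with a gap in either sequence are dropped (and counted); each remaining
    amino-acid column becomes its source codon pair. The ungapped proteins
    must translate exactly from the CDSs (terminal stops excluded).
    """
    aln_a, aln_b = protein_alignment
    if len(aln_a) != len(aln_b):
        raise AlignmentError("protein alignment rows differ in length")
    cods_a = codons_of(_strip_stop(cds_a))
    cods_b = codons_of(_strip_stop(cds_b))
    for aln, cods, name in ((aln_a, cods_a, "a"), (aln_b, cods_b, "b")):
        prot = aln.replace("-", "")
        trans = "".join(CODON_TO_AA[c] for c in cods)
        if prot != trans:
            raise AlignmentError(f"protein {name} does not match its CDS translation")
    out_a, out_b = [], []
    dropped = 0
    ia = ib = 0
    for col_a, col_b in zip(aln_a, aln_b):
        ca = cb = None
        if col_a != "-":
            ca = cods_a[ia]
            ia += 1
        if col_b != "-":
            cb = cods_b[ib]
            ib += 1
        if ca is None or cb is None:
            dropped += 1
        else:
            out_a.append(ca)
            out_b.append(cb)
    return CodonAlignment(tuple(out_a), tuple(out_b), dropped)


_PROT_ALIGNER: Align.PairwiseAligner | None = None


def align_protein_pair(prot_a: str, prot_b: str) -> tuple[str, str]:
    """Global protein alignment (BLOSUM62, gap open 10, extend 1)."""
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        _PROT_ALIGNER = Align.PairwiseAligner(mode="global")
        _PROT_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
        _PROT_ALIGNER.open_gap_score = -10
        _PROT_ALIGNER.extend_gap_score = -1
    best = _PROT_ALIGNER.align(prot_a, prot_b)[0]
    return str(best[0]), str(best[1])


def pair_codon_alignment(cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-guided codon alignment of two CDSs."""
    return backtranslate_to_codon_alignment(
        align_protein_pair(translate_cds(cds_a), translate_cds(cds_b)), cds_a, cds_b)


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def ng86_sites(codons: list[str] | tuple[str, ...]) -> tuple[float, float]:
    """(N, S) for one codon sequence; N + S = 3 x codon count exactly."""
    s = 0.0
    for c in codons:
        if c in STOP_CODONS or c not in CODON_TO_AA:
            raise SequenceError(f"invalid or stop codon {c!r}")
        s += SYNONYMOUS_SITES[c]
    return 3 * len(codons) - s, s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Nd, Sd) for one codon pair, averaged over substitution pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    does, the differences are split equally between the two classes.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff)
    if k == 0:
        return 0.0, 0.0
    path_counts = []
    for order in itertools.permutations(diff):
        cur = c1
        nd = sd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            path_counts.append((nd, sd))
    if not path_counts:
        return k / 2, k / 2
    nd = sum(p[0] for p in path_counts) / len(path_counts)
    sd = sum(p[1] for p in path_counts) / len(path_counts)
    return nd, sd


def ng86_differences(alignment: CodonAlignment) -> tuple[float, float]:
    """(Nd, Sd) summed over all codon pairs of the alignment."""
    nd = sd = 0.0
    for a, b in zip(alignment.codons_a, alignment.codons_b):
        d = _pair_differences(a, b)
        nd += d[0]
        sd += d[1]
    return nd, sd


def _jc(p: float) -> float | None:
    if p >= SATURATION_P:
        return None
    return -0.75 * log(1 - 4 * p / 3)


def compute_kaks(alignment: CodonAlignment) -> KaKsResult:
    """Full NG86 result for one codon alignment.

    Sites are averaged over the two sequences; saturated proportions
    (p >= 3/4) leave the corresponding rate undefined and flagged rather
    than silently dropped.
    """
    if len(alignment) < 1:
        raise AlignmentError("empty codon alignment")
    na, sa = ng86_sites(alignment.codons_a)
    nb, sb = ng86_sites(alignment.codons_b)
    n, s = (na + nb) / 2, (sa + sb) / 2
    nd, sd = ng86_differences(alignment)
    pn, ps = nd / n, sd / s
    ka, ks = _jc(pn), _jc(ps)
    omega = ka / ks if (ka is not None and ks is not None and ks > 0) else None
    return KaKsResult(
        N=n, S=s, Nd=nd, Sd=sd, pN=pn, pS=ps, Ka=ka, Ks=ks, omega=omega,
        regime=classify_selection_omega(omega),
        ks_saturated=ks is None, ka_saturated=ka is None,
    )


def kaks_for_cds_pair(cds_a: str, cds_b: str) -> KaKsResult:
    """Convenience: protein-guided alignment then NG86 on one CDS pair."""
    return compute_kaks(pair_codon_alignment(cds_a, cds_b))


NEUTRAL_TOL = 1e-9


def classify_selection_omega(omega: float | None) -> str:
    """Selection regime from omega; omega == 1 (within 1e-9) is neutral."""
    if omega is None:
        return "undefined"
    if abs(omega - 1.0) <= NEUTRAL_TOL:
        return "neutral"
    if omega > 1.0:
        return "positive"
    if omega >= 0.5:
        return "relaxed_purifying"
    return "strong_purifying"


def classify_selection(result: KaKsResult) -> str:
    return classify_selection_omega(result.omega)
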