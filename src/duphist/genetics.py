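"""Codon-level machinery shared by the genome simulator and the Ka/Ks estimator.

Everything here is derived once, at import time, from the standard genetic
code (NCBI table 1): the sense-codon set, single-nucleotide neighbor lists
split into synonymous/nonsynonymous changes (stop-creating changes excluded),
and per-codon synonymous site counts in the Nei–Gojobori sense.
"""

from __future__ import annotations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_STD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, with '*' for the three stop codons
CODON_TO_AA: dict[str, str] = dict(_STD.forward_table)
for _stop in _STD.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: frozenset[str] = frozenset(_STD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))


class SequenceError(ValueError):
    """Raised for malformed coding sequences (bad length, stops, non-codons)."""


def codons_of(cds: str) -> list[str]:
    """Split a CDS into codons, validating length and alphabet."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise SequenceError(f"CDS length {len(cds)} is not a multiple of 3")
    cods = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for c in cods:
        if c not in CODON_TO_AA:
            raise SequenceError(f"invalid codon {c!r}")
    return cods


def translate_cds(cds: str) -> str:
    """Translate a CDS to protein; a single terminal stop is stripped.

    Internal stop codons are an error: the simulator never produces them and
    the Ka/Ks machinery cannot count sites for them.
    """
    cods = codons_of(cds)
    if cods and cods[-1] in STOP_CODONS:
        cods = cods[:-1]
    aa = []
    for i, c in enumerate(cods):
        r = CODON_TO_AA[c]
        if r == "*":
            raise SequenceError(f"internal stop codon at codon {i}")
        aa.append(r)
    return "".join(aa)


def _build_neighbor_tables():
    """For every sense codon, enumerate the 9 single-nucleotide neighbors.

    Changes that create a stop codon are dropped entirely; the rest are split
    into synonymous and nonsynonymous lists of (position, new_codon).
    """
    syn: dict[str, tuple[tuple[int, str], ...]] = {}
    non: dict[str, tuple[tuple[int, str], ...]] = {}
    for codon in SENSE_CODONS:
        s, n = [], []
        aa = CODON_TO_AA[codon]
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if alt in STOP_CODONS:
                    continue
                (s if CODON_TO_AA[alt] == aa else n).append((pos, alt))
        syn[codon] = tuple(s)
        non[codon] = tuple(n)
    return syn, non


SYN_CHANGES, NON_CHANGES = _build_neighbor_tables()


def _build_site_table() -> dict[str, float]:
    # NG86 synonymous sites per codon: at each position the synonymous
    # fraction of the non-stop single-nucleotide changes; each position
    # contributes one site in total.
    table = {}
    for codon in SENSE_CODONS:
        aa = CODON_TO_AA[codon]
        s = 0.0
        for pos in range(3):
            n_syn = 0
            n_tot = 0
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if alt in STOP_CODONS:
                    continue
                n_tot += 1
                if CODON_TO_AA[alt] == aa:
                    n_syn += 1
            if n_tot:
                s += n_syn / n_tot
        table[codon] = s
    return table


#: codon -> synonymous site count (0..3), stop pathways excluded
SYNONYMOUS_SITES: dict[str, float] = _build_site_table()
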