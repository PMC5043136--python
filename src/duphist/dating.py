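"""Ks-based dating of syntenic blocks and the ancestral-locus retention matrix.

Duplicated genes on a syntenic block arose simultaneously, so the median Ks
over the anchor pair and its flanking homolog pairs dates the block. Each
species carries a configuration of named large-scale duplication eras (e.g.
the rosid gamma triplication, the Arabidopsis alpha/beta duplications, the
salicoid duplication in Populus) as Ks intervals with a reference median;
a block is assigned to the era whose interval contains its median Ks, or left
unassigned. The retention matrix then lays out one row per ancestral-locus
group and, per species, one column per duplicate slot, each cell retained
(a family gene), subfunctionalized (an "N" locus: a collinear non-family
counterpart), or lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import pandas as pd
import yaml

from .catalog import CatalogSet
from .kaks import KaKsResult
from .synteny import AncestralGroup, SyntenyBlock


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Era:
    label: str
    reference_ks: float
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ConfigError(f"era {self.label}: lo must be < hi")
        if not self.lo <= self.reference_ks <= self.hi:
            raise ConfigError(f"era {self.label}: reference outside its interval")

    def contains(self, ks: float) -> bool:
        return self.lo <= ks <= self.hi


@dataclass
class EraConfig:
    """Per-species duplication eras and duplicate-slot multiplicities.

    ``slots`` is the number of descendant copies one post-benchmark ancestral
    locus is expected to have in each species (e.g. 4:2:1:1 for an
    Arabidopsis/Populus/Vitis/Carica-like clade measured against the shared
    triplication).
    """

    eras: dict[str, list[Era]] = field(default_factory=dict)
    slots: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for sp, eras in self.eras.items():
            ordered = sorted(eras, key=lambda e: e.lo)
            for e1, e2 in zip(ordered, ordered[1:]):
                if e2.lo < e1.hi:
                    raise ConfigError(f"{sp}: eras {e1.label}/{e2.label} overlap")

    def species_slots(self, species: str) -> int:
        return self.slots.get(species, 1)

    @classmethod
    def from_yaml(cls, path: str) -> "EraConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        eras = {
            sp: [Era(label=e["label"], reference_ks=float(e["reference_ks"]),
                     lo=float(e["interval"][0]), hi=float(e["interval"][1]))
                 for e in entry.get("eras", [])]
            for sp, entry in raw.items()
        }
        slots = {sp: int(entry.get("slots", 1)) for sp, entry in raw.items()}
        return cls(eras=eras, slots=slots)

    def to_yaml(self, path: str) -> None:
        raw = {
            sp: {
                "slots": self.slots.get(sp, 1),
                "eras": [
                    {"label": e.label, "reference_ks": e.reference_ks,
                     "interval": [e.lo, e.hi]}
                    for e in eras
                ],
            }
            for sp, eras in self.eras.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def default_rosid_config() -> EraConfig:
    """Ks intervals around published rosid-era medians.

    References: salicoid p ~0.27 and gamma ~1.54 in Populus; alpha ~0.86 and
    merged beta/gamma ~2.0 in Arabidopsis; gamma ~1.22 in Vitis and ~1.76 in
    Carica. The literature gives medians, not boundaries, so the intervals
    pad midway between neighboring eras and are fully configurable.
    """
    return EraConfig(
        eras={
            "populus": [Era("p", 0.27, 0.1, 0.6), Era("gamma", 1.54, 1.2, 2.6)],
            "arabidopsis": [Era("alpha", 0.86, 0.5, 1.3),
                            Era("beta_gamma", 2.0, 1.3, 2.6)],
            "vitis": [Era("gamma", 1.22, 0.9, 2.2)],
            "carica": [Era("gamma", 1.76, 0.8, 2.6)],
        },
        slots={"arabidopsis": 4, "populus": 2, "vitis": 1, "carica": 1},
    )


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------

KsTable = dict[tuple[str, str], "KaKsResult | float | None"]


def _lookup_ks(table: KsTable, a: str, b: str) -> float | None:
    v = table.get((a, b), table.get((b, a)))
    if isinstance(v, KaKsResult):
        return v.Ks
    return v


def block_median_ks(block: SyntenyBlock, kaks_table: KsTable) -> tuple[float | None, int]:
    """Median Ks over the anchor pair and flank pairs; (value, n contributing).

    Saturated/undefined Ks values are excluded; a block with no defined Ks is
    returned undated (None, 0) for the caller to flag.
    """
    values = []
    for a, b in (block.anchors, *block.flank_matches):
        ks = _lookup_ks(kaks_table, a, b)
        if ks is not None:
            values.append(ks)
    if not values:
        return None, 0
    return float(median(values)), len(values)


def assign_event_era(median_ks: float, species: str, config: EraConfig) -> str | None:
    """Era label of the interval containing the median Ks, else None."""
    if species not in config.eras:
        raise ConfigError(f"no era configuration for species {species!r}")
    for era in config.eras[species]:
        if era.contains(median_ks):
            return era.label
    return None


def date_blocks(blocks: list[SyntenyBlock], kaks_table: KsTable,
                config: EraConfig) -> list[SyntenyBlock]:
    """Fill median_ks and (for within-species blocks) era in place."""
    for blk in blocks:
        blk.median_ks, _ = block_median_ks(blk, kaks_table)
        if blk.species_a == blk.species_b and blk.median_ks is not None:
            blk.era = assign_event_era(blk.median_ks, blk.species_a, config)
    return blocks


# ---------------------------------------------------------------------------
# retention matrix
# ---------------------------------------------------------------------------

LOST = "lost"


@dataclass
class RetentionMatrix:
    """Ancestral-locus groups x per-species duplicate slots.

    Cells are "gene_id" (retained), "N:locus_id" (subfunctionalized) or
    "lost".
    """

    rows: list[str]
    columns: list[tuple[str, int]]  # (species, slot index)
    cells: dict[tuple[str, tuple[str, int]], str]

    def cell(self, group_id: str, species: str, slot: int) -> str:
        return self.cells[(group_id, (species, slot))]

    def counts(self) -> pd.DataFrame:
        recs = []
        species = sorted({c[0] for c in self.columns})
        for sp in species:
            cols = [c for c in self.columns if c[0] == sp]
            vals = [self.cells[(r, c)] for r in self.rows for c in cols]
            recs.append(dict(
                species=sp,
                retained=sum(1 for v in vals if v != LOST and not v.startswith("N:")),
                subfunctionalized=sum(1 for v in vals if v.startswith("N:")),
                lost=sum(1 for v in vals if v == LOST),
                slots=len(cols),
            ))
        return pd.DataFrame(recs)

    def to_frame(self) -> pd.DataFrame:
        data = {
            f"{sp}_slot{slot}": [self.cells[(r, (sp, slot))] for r in self.rows]
            for sp, slot in self.columns
        }
        return pd.DataFrame(data, index=pd.Index(self.rows, name="group"))


def build_retention_matrix(groups: list[AncestralGroup], blocks: list[SyntenyBlock],
                           catalogs: CatalogSet, config: EraConfig,
                           ) -> RetentionMatrix:
    """Assemble the retention matrix from grouped blocks.

    Per group and species, retained family genes fill the species' slots in
    gene-id order; non-family block counterparts of the group's genes fill
    remaining slots as subfunctionalized "N" loci; leftover slots are lost.
    A family gene may appear in at most one row (groups are disjoint by
    construction of connected components).
    """
    species = sorted(catalogs.catalogs)
    columns = [(sp, i) for sp in species for i in range(config.species_slots(sp))]
    # N-loci: non-family counterparts keyed by family anchor
    n_partners: dict[str, list[str]] = {}
    for blk in blocks:
        for fam, other in ((blk.anchor_a, blk.anchor_b), (blk.anchor_b, blk.anchor_a)):
            if catalogs.get(fam).is_family and not catalogs.get(other).is_family:
                n_partners.setdefault(fam, []).append(other)
    seen: set[str] = set()
    cells: dict[tuple[str, tuple[str, int]], str] = {}
    rows = []
    for grp in groups:
        rows.append(grp.group_id)
        for sp in species:
            n_slots = config.species_slots(sp)
            members = [g for g in grp.members.get(sp, []) if catalogs.get(g).is_family]
            for g in members:
                if g in seen:
                    raise ConfigError(f"gene {g} assigned to two groups")
                seen.add(g)
            filled = list(members[:n_slots])
            subfun = []
            for g in members:
                for partner in sorted(set(n_partners.get(g, []))):
                    if catalogs.species_of(partner) == sp and partner not in subfun:
                        subfun.append(partner)
            for slot in range(n_slots):
                col = (sp, slot)
                if slot < len(filled):
                    cells[(grp.group_id, col)] = filled[slot]
                elif slot - len(filled) < len(subfun):
                    cells[(grp.group_id, col)] = f"N:{subfun[slot - len(filled)]}"
                else:
                    cells[(grp.group_id, col)] = LOST
    return RetentionMatrix(rows=rows, columns=columns, cells=cells)


def count_ratios(counts: dict[str, int], benchmark: str) -> dict[str, float]:
    """Family-size ratios normalized to a benchmark species, 2 decimals."""
    base = counts[benchmark]
    return {sp: round(n / base, 2) for sp, n in counts.items()}


def expected_multiplicity_check(matrix: RetentionMatrix, config: EraConfig,
                                benchmark: str | None = None) -> pd.DataFrame:
    """Observed vs expected duplicate retention per species.

    Expected counts are rows x slots under the era multiplicities; ratios are
    also normalized to a benchmark species when given (the classic rosid
    benchmark is Vitis).
    """
    counts = matrix.counts().set_index("species")
    n_rows = len(matrix.rows)
    recs = []
    for sp, row in counts.iterrows():
        expected = n_rows * config.species_slots(sp)
        recs.append(dict(
            species=sp,
            observed_retained=int(row["retained"]),
            expected=expected,
            obs_over_exp=round(row["retained"] / expected, 2) if expected else float("nan"),
        ))
    out = pd.DataFrame(recs)
    if benchmark is not None:
        base = out.loc[out.species == benchmark, "observed_retained"].iloc[0]
        out["ratio_vs_benchmark"] = (out["observed_retained"] / base).round(2)
    return out
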