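"""Mapping solved abundances onto a fixed-rank taxonomy.

Reference-column mass belongs to its genome's strain.  Hypothetical-column
mass (genome i, bin h) is placed by finding a *partner* reference j whose
30-mer containment with i is close to h (|A30[i, j] − h| < δ) and assigning
the mass to the least common ancestor (LCA) of the two lineages — the
biologically informed reading of "an organism about h-similar to g_i".
A naive alternative maps each bin straight to a fixed rank (0.9→species,
0.8→genus, …); the ``sensitive``/``specific`` modes are hybrids taking the
deeper/shallower of LCA and fixed-rank assignments, while ``default`` is
pure LCA.

Profiles are emitted per rank with mass summed upward so every ancestor
carries at least its descendants' mass; percentages at a rank may total
less than 100 when mass is assigned above it (unassigned at deeper ranks).
The on-disk representation is the Bioboxes profiling format, version 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmer_core import CommonKmerMatrix
from .solver import AbundanceEntry

__all__ = [
    "RANKS",
    "Lineage",
    "TaxonomyTable",
    "ProfileEntry",
    "TaxProfile",
    "lca_rank",
    "fixed_rank_for_bin",
    "find_partner",
    "map_hypothetical",
    "build_profile",
]

RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)

#: A complete lineage: one (taxid, name) pair per rank, root-first.
Lineage = tuple[tuple[str, str], ...]

DEFAULT_DELTA = 0.05


@dataclass
class TaxonomyTable:
    """Complete fixed-rank lineages for every training genome."""

    lineages: dict[str, Lineage]

    def __post_init__(self) -> None:
        for gid, lin in self.lineages.items():
            self._check(gid, lin)

    @staticmethod
    def _check(gid: str, lin: Lineage) -> None:
        if len(lin) != len(RANKS):
            raise ValueError(
                f"genome {gid!r}: lineage has {len(lin)} ranks, "
                f"expected {len(RANKS)}"
            )
        for entry in lin:
            if len(entry) != 2 or not entry[0]:
                raise ValueError(f"genome {gid!r}: malformed lineage entry {entry!r}")

    def __getitem__(self, gid: str) -> Lineage:
        return self.lineages[gid]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for gid, lin in self.lineages.items():
                taxids = "|".join(t for t, _ in lin)
                names = "|".join(n for _, n in lin)
                fh.write(f"{gid}\t{taxids}\t{names}\n")

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        lineages: dict[str, Lineage] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                gid, taxids, names = line.split("\t")
                lin = tuple(zip(taxids.split("|"), names.split("|")))
                lineages[gid] = lin
        return cls(lineages=lineages)


def lca_rank(
    lineage_a: Lineage, lineage_b: Lineage
) -> tuple[int, tuple[str, str]] | None:
    """Deepest rank index at which the two lineages share a taxid.

    Returns ``(rank_index, (taxid, name))`` or None when even the
    superkingdoms differ (LCA is the unranked root).
    """
    for lin in (lineage_a, lineage_b):
        if len(lin) != len(RANKS) or any(len(e) != 2 or not e[0] for e in lin):
            raise ValueError("malformed lineage")
    deepest = None
    for r, (ea, eb) in enumerate(zip(lineage_a, lineage_b)):
        if ea[0] == eb[0]:
            deepest = (r, ea)
        else:
            break
    return deepest


def fixed_rank_for_bin(h: float) -> int:
    """Naive bin→rank map: 1.0→strain, 0.9→species, …, ≤0.3→superkingdom."""
    if not 0 < h <= 1:
        raise ValueError(f"bin must lie in (0, 1], got {h}")
    r = len(RANKS) - 1 - round((1.0 - h) * 10)
    return max(r, 0)


def find_partner(
    i: int, h: float, A30: CommonKmerMatrix, delta: float = DEFAULT_DELTA
) -> int | None:
    """Reference j ≠ i whose containment with i best matches bin h.

    Prefers candidates with |A30[i, j] − h| < δ; if none qualifies, falls
    back to the global argmin of |A30[i, j] − h|.  None when i is the
    only genome.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    M = len(A30.genome_ids)
    if M < 2:
        return None
    diffs = np.abs(A30.values[i] - h)
    diffs[i] = np.inf
    j = int(np.argmin(diffs))
    return j


def map_hypothetical(
    entry: tuple[int, float],
    A30: CommonKmerMatrix,
    taxonomy: TaxonomyTable,
    delta: float = DEFAULT_DELTA,
) -> tuple[int, tuple[str, str]]:
    """Assign one (genome_index, bin) column to a rank and taxon via LCA.

    Reference columns (bin 1.0) map to their genome's strain.  With no
    partner available (single-genome database) the fixed-rank map is the
    fallback.  Mass whose LCA is the unranked root is reported at
    superkingdom depth under genome i's own superkingdom, the shallowest
    rank representable in a fixed-rank profile.
    """
    i, h = entry
    lin_i = taxonomy[A30.genome_ids[i]]
    if h >= 1.0:
        return len(RANKS) - 1, lin_i[-1]
    j = find_partner(i, h, A30, delta=delta)
    if j is None:
        r = fixed_rank_for_bin(h)
        return r, lin_i[r]
    lca = lca_rank(lin_i, taxonomy[A30.genome_ids[j]])
    if lca is None:
        return 0, lin_i[0]
    return lca


def _assigned_rank(
    entry: tuple[int, float],
    A30: CommonKmerMatrix,
    taxonomy: TaxonomyTable,
    mode: str,
    delta: float,
) -> int:
    i, h = entry
    lca_r, _ = map_hypothetical(entry, A30, taxonomy, delta=delta)
    if h >= 1.0:
        return lca_r
    if mode == "default":
        return lca_r
    fixed_r = fixed_rank_for_bin(h)
    if mode == "sensitive":
        return max(lca_r, fixed_r)
    if mode == "specific":
        return min(lca_r, fixed_r)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class ProfileEntry:
    rank: str
    taxid: str
    taxpath: str
    taxpath_names: str
    percentage: float


@dataclass
class TaxProfile:
    """Rank-wise relative-abundance profile (percentages in [0, 100])."""

    entries: list[ProfileEntry] = field(default_factory=list)
    sample_id: str = "sample"

    def at_rank(self, rank: str) -> dict[str, float]:
        """taxid → percentage for one rank."""
        return {
            e.taxid: e.percentage for e in self.entries if e.rank == rank
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, TaxProfile):
            return NotImplemented
        if self.sample_id != other.sample_id:
            return False
        key = lambda e: (RANKS.index(e.rank), e.taxid)
        a, b = sorted(self.entries, key=key), sorted(other.entries, key=key)
        if len(a) != len(b):
            return False
        return all(
            x.rank == y.rank
            and x.taxid == y.taxid
            and x.taxpath == y.taxpath
            and x.taxpath_names == y.taxpath_names
            and abs(x.percentage - y.percentage) < 1e-9
            for x, y in zip(a, b)
        )


def build_profile(
    abundances: list[AbundanceEntry],
    taxonomy: TaxonomyTable,
    A30: CommonKmerMatrix,
    mode: str = "default",
    delta: float = DEFAULT_DELTA,
    sample_id: str = "sample",
) -> TaxProfile:
    """Rank-wise profile from normalized (genome, bin, mass) abundances.

    Each entry is assigned a rank per ``mode`` and its mass credited to
    genome i's ancestor taxa at that rank and every rank above, so the
    profile is upward consistent; mass assigned above a rank appears
    nowhere below it (allowed to stay unassigned there).
    """
    if mode not in ("default", "sensitive", "specific"):
        raise ValueError(f"unknown mode {mode!r}")
    total = sum(e.abundance for e in abundances)
    if abundances and abs(total - 1.0) > 1e-6:
        raise ValueError(f"abundances must be normalized (sum {total:.6g})")
    # (rank_index, taxid) -> [percentage, taxpath, taxpath_names]
    acc: dict[tuple[int, str], list] = {}
    for e in abundances:
        r_assign = _assigned_rank(
            (e.genome_index, e.bin), A30, taxonomy, mode, delta
        )
        lin = taxonomy[A30.genome_ids[e.genome_index]]
        for r in range(r_assign + 1):
            taxid = lin[r][0]
            key = (r, taxid)
            if key not in acc:
                acc[key] = [
                    0.0,
                    "|".join(t for t, _ in lin[: r + 1]),
                    "|".join(n for _, n in lin[: r + 1]),
                ]
            acc[key][0] += e.abundance * 100.0
    entries = [
        ProfileEntry(
            rank=RANKS[r],
            taxid=taxid,
            taxpath=path,
            taxpath_names=names,
            percentage=pct,
        )
        for (r, taxid), (pct, path, names) in sorted(
            acc.items(), key=lambda kv: (kv[0][0], -kv[1][0], kv[0][1])
        )
    ]
    return TaxProfile(entries=entries, sample_id=sample_id)
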