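"""Canonical miRNA seed-site scanning and targetome ranking.

Implements the screen that ranks miRNA seed families by the number of
canonical binding sites they hold in the 3' UTRs of a panel of repolarizing
ion-channel genes (the "channelome"): seed extraction, the 8mer / 7mer-m8 /
7mer-A1 site taxonomy, UTR scanning with 8mer subsumption, dual-dataset
expression gating, the family-by-gene binding-site count matrix, and the
final ranking.

Conventions
-----------
* A miRNA seed is mature-miRNA nucleotides 2-8 (1-based), a 7-nt RNA string.
* Site types on the target (UTR) strand, 5'->3':
  - ``7mer-m8``: reverse complement of the full seed (miRNA nt 2-8).
  - ``8mer``:    the 7mer-m8 match followed by a literal ``A`` (opposite
    miRNA position 1).
  - ``7mer-A1``: reverse complement of miRNA nt 2-7 followed by a literal
    ``A``.
* An 8mer window counts once: its internal 7mer-m8 and 7mer-A1 windows are
  suppressed (one physical site, one count). Distinct overlapping sites are
  each counted.
* Coordinates are 0-based half-open offsets on the supplied UTR sequence.
* UTRs may be given as DNA or RNA; scanning is alphabet-invariant. ``N``
  never matches.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class AlphabetError(ValueError):
    """Sequence contains characters outside the accepted nucleotide alphabet."""


def _normalize_rna(sequence: str, *, what: str = "sequence") -> str:
    """Uppercase and convert to the RNA alphabet; reject anything else."""
    seq = sequence.upper()
    if "T" in seq:
        logger.warning("%s contains T; converting to U (DNA -> RNA)", what)
        seq = seq.replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise AlphabetError(f"{what} contains invalid characters: {sorted(bad)}")
    return seq


def reverse_complement(rna: str) -> str:
    return rna.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3', RNA alphabet.

    ``T`` is auto-converted to ``U`` with a logged warning.  Sequences must
    be at least 8 nt so that a seed (positions 2-8) exists.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = _normalize_rna(self.sequence, what=f"miRNA {self.id}")
        if "N" in seq:
            raise AlphabetError(f"miRNA {self.id} contains N")
        if len(seq) < 8:
            raise ValueError(
                f"miRNA {self.id} is {len(seq)} nt; at least 8 nt required"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def seed(self) -> str:
        return self.sequence[1:8]


def seed_of(mirna: MatureMiRNA | str) -> str:
    """Seed heptamer: mature-miRNA nucleotides 2-8 (1-based).

    Accepts a :class:`MatureMiRNA` or a raw sequence string.
    """
    if isinstance(mirna, str):
        mirna = MatureMiRNA(id="<anonymous>", sequence=mirna)
    return mirna.seed


@dataclass(frozen=True)
class SeedFamily:
    """A group of miRNAs sharing one seed (nt 2-8)."""

    family_id: str
    seed: str
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seed = _normalize_rna(self.seed, what=f"seed of family {self.family_id}")
        if len(seed) != 7 or "N" in seed:
            raise ValueError(
                f"family {self.family_id}: seed must be 7 unambiguous nt, got {self.seed!r}"
            )
        object.__setattr__(self, "seed", seed)
        object.__setattr__(self, "members", tuple(self.members))


def group_into_families(mirnas: Iterable[MatureMiRNA]) -> list[SeedFamily]:
    """Group mature miRNAs into seed families by their shared seed heptamer.

    The family id is the lexicographically smallest member id, so grouping is
    deterministic regardless of input order.
    """
    by_seed: dict[str, list[str]] = defaultdict(list)
    for m in mirnas:
        by_seed[m.seed].append(m.id)
    families = []
    for seed, members in by_seed.items():
        members = sorted(members)
        families.append(SeedFamily(family_id=members[0], seed=seed, members=tuple(members)))
    families.sort(key=lambda f: f.family_id)
    return families


@dataclass(frozen=True)
class UTRRecord:
    """A 3' UTR sequence for one gene.

    DNA or RNA accepted; stored internally as RNA.  ``N`` is allowed and
    never matches any site.
    """

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        bad = set(seq) - set("ACGUN")
        if bad:
            raise AlphabetError(
                f"UTR {self.gene_id} contains invalid characters: {sorted(bad)}"
            )
        if not seq:
            raise ValueError(f"UTR {self.gene_id} is empty")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SeedSite:
    """One located canonical site in a UTR (0-based half-open coordinates)."""

    gene_id: str
    family_id: str
    site_type: str
    start: int
    end: int
    conserved: bool | None = None

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        expected = 8 if self.site_type == "8mer" else 7
        if self.end - self.start != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, "
                f"got [{self.start},{self.end})"
            )


def site_sequences(seed: str) -> dict[str, str]:
    """Target-strand (UTR) sequences for the three canonical site types.

    ``7mer-m8`` is the reverse complement of the seed; ``8mer`` appends a
    literal ``A``; ``7mer-A1`` is the reverse complement of seed positions
    1-6 (miRNA nt 2-7) plus a literal ``A``.
    """
    seed = _normalize_rna(seed, what="seed")
    if len(seed) != 7 or "N" in seed:
        raise ValueError(f"seed must be 7 unambiguous nt, got {seed!r}")
    m8 = reverse_complement(seed)
    return {
        "8mer": m8 + "A",
        "7mer-m8": m8,
        "7mer-A1": reverse_complement(seed[:6]) + "A",
    }


def scan_sites(utr: UTRRecord, family: SeedFamily) -> list[SeedSite]:
    """All canonical sites of ``family`` in ``utr``, without double counting.

    Every window matching the 8mer sequence is reported once as an 8mer; the
    7mer-m8 and 7mer-A1 windows it contains are suppressed.  Remaining
    windows matching either 7mer are reported.  Distinct sites may overlap.
    Output is sorted by start position (site-type order breaks ties at equal
    start, 8mer first).
    """
    seqs = site_sequences(family.seed)
    s = utr.sequence
    sites: list[SeedSite] = []

    # 8mer matches first; record the windows they claim.
    eight = seqs["8mer"]
    claimed_m8: set[int] = set()   # starts of 7mer-m8 windows inside an 8mer
    claimed_a1: set[int] = set()   # starts of 7mer-A1 windows inside an 8mer
    start = s.find(eight)
    while start != -1:
        sites.append(SeedSite(utr.gene_id, family.family_id, "8mer", start, start + 8))
        # 8mer = [m8 7-mer][A]; the A1 7-mer is its last 7 nt.
        claimed_m8.add(start)
        claimed_a1.add(start + 1)
        start = s.find(eight, start + 1)

    for site_type, key, claimed in (
        ("7mer-m8", "7mer-m8", claimed_m8),
        ("7mer-A1", "7mer-A1", claimed_a1),
    ):
        pattern = seqs[key]
        start = s.find(pattern)
        while start != -1:
            if start not in claimed:
                sites.append(
                    SeedSite(utr.gene_id, family.family_id, site_type, start, start + 7)
                )
            start = s.find(pattern, start + 1)

    sites.sort(key=lambda x: (x.start, SITE_TYPES.index(x.site_type)))
    return sites


def scan_sites_bruteforce(utr: UTRRecord, family: SeedFamily) -> list[SeedSite]:
    """Reference scanner: enumerate every 7- and 8-nt window explicitly.

    Independent of :func:`scan_sites` (no shared matching code path beyond
    the site-sequence definitions); used as the oracle in equivalence tests.
    """
    seqs = site_sequences(family.seed)
    s = utr.sequence
    n = len(s)
    sites: list[SeedSite] = []
    eight_starts = [i for i in range(n - 7) if s[i : i + 8] == seqs["8mer"]]
    for i in eight_starts:
        sites.append(SeedSite(utr.gene_id, family.family_id, "8mer", i, i + 8))
    inside_m8 = set(eight_starts)
    inside_a1 = {i + 1 for i in eight_starts}
    for i in range(n - 6):
        window = s[i : i + 7]
        if window == seqs["7mer-m8"] and i not in inside_m8:
            sites.append(SeedSite(utr.gene_id, family.family_id, "7mer-m8", i, i + 7))
        if window == seqs["7mer-A1"] and i not in inside_a1:
            sites.append(SeedSite(utr.gene_id, family.family_id, "7mer-A1", i, i + 7))
    sites.sort(key=lambda x: (x.start, SITE_TYPES.index(x.site_type)))
    return sites


@dataclass
class BindingSiteMatrix:
    """Seed-family x gene canonical-site counts over a gene panel."""

    counts: pd.DataFrame  # rows: family_id, columns: gene_id, int counts
    sites: list[SeedSite] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def targeted_genes(self, family_id: str) -> list[str]:
        row = self.counts.loc[family_id]
        return sorted(row.index[row > 0])


def count_matrix(
    utrs: Sequence[UTRRecord],
    families: Sequence[SeedFamily],
    conservation_filter: bool = False,
    conserved_sites: set[tuple[str, str, int]] | None = None,
) -> BindingSiteMatrix:
    """Binding-site count matrix: cell (family, gene) = number of canonical sites.

    When several UTR records share a gene id (transcript isoforms), the
    longest is scanned and the choice is logged.  With
    ``conservation_filter`` on, only sites whose ``(gene_id, family_id,
    start)`` appears in ``conserved_sites`` are counted; the filter without
    annotations is an error.
    """
    if not utrs:
        raise ValueError("no UTRs supplied")
    if not families:
        raise ValueError("no seed families supplied")
    if conservation_filter and conserved_sites is None:
        raise ValueError("conservation_filter requires conserved-site annotations")

    by_gene: dict[str, UTRRecord] = {}
    for u in utrs:
        prev = by_gene.get(u.gene_id)
        if prev is None or len(u.sequence) > len(prev.sequence):
            if prev is not None:
                logger.info(
                    "gene %s: multiple UTRs, scanning the longest (%d nt)",
                    u.gene_id, len(u.sequence),
                )
            by_gene[u.gene_id] = u

    genes = sorted(by_gene)
    fam_ids = [f.family_id for f in families]
    counts = pd.DataFrame(0, index=fam_ids, columns=genes, dtype=int)
    all_sites: list[SeedSite] = []
    for fam in families:
        for gene in genes:
            sites = scan_sites(by_gene[gene], fam)
            if conservation_filter:
                sites = [
                    s for s in sites
                    if (s.gene_id, s.family_id, s.start) in conserved_sites
                ]
            counts.loc[fam.family_id, gene] = len(sites)
            all_sites.extend(sites)

    return BindingSiteMatrix(
        counts=counts,
        sites=all_sites,
        provenance={
            "n_genes": len(genes),
            "n_families": len(fam_ids),
            "conservation_filter": conservation_filter,
        },
    )


def rank_families(matrix: BindingSiteMatrix) -> pd.DataFrame:
    """Rank seed families by total canonical-site count, descending.

    Ties break lexicographically by family id.  Returns a DataFrame with
    columns ``family_id``, ``total_sites``, ``n_genes_targeted``,
    ``targeted_genes`` (comma-joined), in rank order.
    """
    totals = matrix.row_totals()
    order = sorted(totals.index, key=lambda f: (-totals[f], f))
    rows = []
    for fam in order:
        genes = matrix.targeted_genes(fam)
        rows.append(
            {
                "family_id": fam,
                "total_sites": int(totals[fam]),
                "n_genes_targeted": len(genes),
                "targeted_genes": ",".join(genes),
            }
        )
    return pd.DataFrame(rows, columns=["family_id", "total_sites", "n_genes_targeted", "targeted_genes"])


def top_n_entities(
    table_a: pd.DataFrame | Mapping[str, float],
    table_b: pd.DataFrame | Mapping[str, float],
    n: int = 100,
) -> set[str]:
    """Ids ranked in the top-``n`` by abundance in *both* tables.

    This is the dual-dataset expression gate: an entity passes only if it is
    among the ``n`` most abundant in each profile independently.  The
    boundary tie-break is deterministic: abundance descending, then id
    ascending.
    """
    if n < 1:
        raise ValueError("n must be >= 1")

    def top(table) -> set[str]:
        if isinstance(table, pd.DataFrame):
            ids = table.iloc[:, 0].astype(str)
            abund = pd.to_numeric(table.iloc[:, 1])
            pairs = list(zip(ids, abund))
        else:
            pairs = [(str(k), float(v)) for k, v in table.items()]
        if not pairs:
            raise ValueError("empty abundance table")
        pairs.sort(key=lambda kv: (-kv[1], kv[0]))
        return {k for k, _ in pairs[:n]}

    return top(table_a) & top(table_b)


def filter_expressed_genes(
    expr_table: pd.DataFrame | Mapping[str, float], threshold: float = 1.0
) -> set[str]:
    """Genes with abundance strictly above ``threshold`` (TPM-like units)."""
    if isinstance(expr_table, pd.DataFrame):
        items = zip(expr_table.iloc[:, 0].astype(str), pd.to_numeric(expr_table.iloc[:, 1]))
    else:
        items = expr_table.items()
    return {g for g, v in items if v > threshold}
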