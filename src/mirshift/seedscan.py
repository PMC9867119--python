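"""Canonical miRNA seed-match scanning of 3'UTR sequences.

A miRNA "seed" is nucleotides 2-8 of the mature sequence (5' end, 1-based
miRNA numbering).  A canonical target site on a 3'UTR (sense strand, 5'->3')
is the Watson-Crick reverse complement of part or all of the seed:

==========  =========================================  ======
site type   UTR sense-strand sequence                  length
==========  =========================================  ======
8mer        revcomp(miRNA 2-8) followed by A           8
7mer-m8     revcomp(miRNA 2-8)                         7
7mer-A1     revcomp(miRNA 2-7) followed by A           7
6mer        revcomp(miRNA 2-7)                         6
==========  =========================================  ======

The trailing A opposite miRNA position 1 is a sequence match on the target,
not a base pair.  At a given locus only the strongest type is reported
(8mer > 7mer-m8 > 7mer-A1 > 6mer) and, per miRNA, sites are made
non-overlapping by a greedy left-to-right sweep.  Coordinates are 0-based
half-open on the UTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError

#: Site types in decreasing order of pairing strength.
MATCH_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

#: Site types counted as "targeting" by default (6mer excluded).
STRONG_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_PRECEDENCE = {t: i for i, t in enumerate(MATCH_TYPES)}
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_VALID = frozenset("ACGU")


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert DNA T to RNA U.

    Raises :class:`DataError` on any character outside {A, C, G, U, T}.
    """
    s = seq.upper().replace("T", "U")
    bad = set(s) - _VALID
    if bad:
        raise DataError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (already normalized)."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: identifier plus 5'->3' RNA sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if len(self.sequence) < 8:
            raise DataError(
                f"miRNA {self.id!r} is {len(self.sequence)} nt; "
                "at least 8 nt are required to define a seed"
            )

    @property
    def seed(self) -> str:
        """Seed region: positions 2-8 of the mature sequence (7 nt)."""
        return self.sequence[1:8]


def seed_of(mirna: MatureMiRNA) -> str:
    """Return the 7-nt seed (miRNA positions 2-8, 1-based)."""
    return mirna.seed


def match_strings(mirna: MatureMiRNA) -> dict[str, str]:
    """Map each canonical site type to its UTR sense-strand match string."""
    m8 = revcomp(mirna.seed)  # complement of positions 2-8, 7 nt
    m7 = m8[1:]  # complement of positions 2-7, 6 nt
    return {
        "8mer": m8 + "A",
        "7mer-m8": m8,
        "7mer-A1": m7 + "A",
        "6mer": m7,
    }


@dataclass(frozen=True)
class SeedSite:
    """A predicted miRNA site on a UTR, 0-based half-open interval."""

    utr_id: str
    start: int
    end: int
    match_type: str
    mirna_id: str

    def __post_init__(self):
        if self.match_type not in MATCH_TYPES:
            raise DataError(f"unknown match type {self.match_type!r}")
        expected = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[self.match_type]
        if self.end - self.start != expected:
            raise DataError(
                f"{self.match_type} site must span {expected} nt, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def scan_sites(utr_id: str, utr_seq: str, mirna: MatureMiRNA) -> list[SeedSite]:
    """Find all canonical sites of one miRNA on one UTR.

    Every occurrence of every match string is located; candidates are then
    resolved by a single greedy left-to-right sweep that prefers the
    strongest type at equal start positions and drops any candidate
    overlapping an already-accepted site.
    """
    seq = normalize_rna(utr_seq)
    candidates: list[tuple[int, int, int, str]] = []
    for mtype, s in match_strings(mirna).items():
        i = seq.find(s)
        while i != -1:
            candidates.append((i, _PRECEDENCE[mtype], i + len(s), mtype))
            i = seq.find(s, i + 1)
    candidates.sort()
    sites: list[SeedSite] = []
    cursor = 0
    for start, _prec, end, mtype in candidates:
        if start >= cursor:
            sites.append(SeedSite(utr_id, start, end, mtype, mirna.id))
            cursor = end
    return sites


def scan_all(
    utrs: dict[str, str],
    mirnas: list[MatureMiRNA],
    restrict_to: set[str] | None = None,
) -> list[SeedSite]:
    """Scan every UTR against every miRNA (optionally a subset by id)."""
    out: list[SeedSite] = []
    for m in mirnas:
        if restrict_to is not None and m.id not in restrict_to:
            continue
        for uid, seq in utrs.items():
            out.extend(scan_sites(uid, seq, m))
    return out


@dataclass
class SiteCounts:
    """Per-gene site tallies: total sites and distinct targeting miRNAs."""

    total: dict[str, int] = field(default_factory=dict)
    n_mirnas: dict[str, int] = field(default_factory=dict)
    by_mirna: dict[tuple[str, str], int] = field(default_factory=dict)


def count_sites(
    utrs: dict[str, str],
    mirnas: list[MatureMiRNA],
    restrict_to: set[str] | None = None,
    types: tuple[str, ...] = MATCH_TYPES,
) -> SiteCounts:
    """Tabulate site counts per gene.

    ``types`` limits which site classes count (pass :data:`STRONG_TYPES` to
    drop 6mers, the default convention for calling a gene "targeted").
    """
    counts = SiteCounts(
        total={u: 0 for u in utrs},
        n_mirnas={u: 0 for u in utrs},
    )
    allowed = set(types)
    for site in scan_all(utrs, mirnas, restrict_to):
        if site.match_type not in allowed:
            continue
        counts.total[site.utr_id] += 1
        key = (site.utr_id, site.mirna_id)
        counts.by_mirna[key] = counts.by_mirna.get(key, 0) + 1
    for (uid, _mid) in counts.by_mirna:
        counts.n_mirnas[uid] += 1
    return counts
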